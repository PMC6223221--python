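"""Gene-model selection and strand-aware partitioning of gene neighbourhoods.

All coordinates are 0-based, half-open (BED convention).  The transcript
start site (TSS) of a ``+`` strand gene is ``tx_start``; for a ``-`` strand
gene it is ``tx_end`` (the boundary just downstream of the first transcribed
base).  The transcript end site (TES) is the opposite boundary.

Each selected gene is partitioned into 12 named regions: four upstream
flank segments (``up2``, ``up5``, ``up10``, ``up20``, covering 0-2, 2-5,
5-10 and 10-20 kb upstream of the TSS in the direction of transcription),
four gene-body regions (``5UTR``, ``exon``, ``intron``, ``3UTR``) and four
downstream flank segments (``down2`` ... ``down20``) measured from the TES.
The promoter (TSS +/- 2 kb) is tiled by 20 consecutive 200 bp bins indexed
-10..-1 (upstream) and 1..10 (downstream); there is no bin 0 and bin 1
abuts the TSS on the transcribed side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The fixed set of region labels, in 5'->3' order along transcription.
REGION_LABELS = (
    "up20", "up10", "up5", "up2",
    "5UTR", "exon", "intron", "3UTR",
    "down2", "down5", "down10", "down20",
)

#: Nominal flank boundaries in bp (2, 5, 10, 20 kb).
DEFAULT_FLANK_BOUNDS = (2000, 5000, 10000, 20000)


@dataclass(frozen=True)
class GeneModel:
    """One chosen transcript of a gene, with CDS and exon structure.

    ``cds_start == cds_end`` marks a non-coding transcript.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.transcript_id}: tx_start >= tx_end")
        prev_end = self.tx_start
        for start, end in self.exons:
            if start < prev_end or end <= start or end > self.tx_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted, "
                    "non-overlapping and contained in the transcript span"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        """Boundary coordinate of the transcript start site."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        """Boundary coordinate of the transcript end site."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start


@dataclass(frozen=True)
class RegionAnnotation:
    """Named, strand-aware set of genomic intervals for one gene region."""

    gene_id: str
    region_label: str
    intervals: tuple[tuple[str, int, int], ...]
    strand: str


@dataclass(frozen=True)
class PromoterBin:
    """One 200 bp promoter bin; ``partial`` marks chromosome-edge clipping."""

    gene_id: str
    bin_index: int
    interval: tuple[str, int, int]
    strand: str
    partial: bool = False


# ---------------------------------------------------------------------------
# gene-table parsing


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Parse a refFlat-style table into gene models; malformed rows are skipped."""
    models: list[GeneModel] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                (gene, tx, chrom, strand, tx_start, tx_end,
                 cds_start, cds_end, exon_count, ex_starts, ex_ends) = fields[:11]
                starts = [int(x) for x in ex_starts.rstrip(",").split(",")]
                ends = [int(x) for x in ex_ends.rstrip(",").split(",")]
                if len(starts) != int(exon_count) or len(starts) != len(ends):
                    raise ValueError("exon count mismatch")
                models.append(GeneModel(
                    gene_id=gene, transcript_id=tx, chrom=chrom, strand=strand,
                    tx_start=int(tx_start), tx_end=int(tx_end),
                    cds_start=int(cds_start), cds_end=int(cds_end),
                    exons=tuple(zip(starts, ends)),
                ))
            except (ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("skipping malformed row %d of %s: %s", lineno, path, exc)
    if n_bad:
        logger.warning("%d malformed rows skipped in %s", n_bad, path)
    return models


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Parse BED12 gene models.  ``name`` is ``gene_id:transcript_id`` or a
    bare transcript id (then also used as the gene id)."""
    models: list[GeneModel] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
                gene_id, _, tx_id = name.partition(":")
                tx_id = tx_id or name
                models.append(GeneModel(
                    gene_id=gene_id, transcript_id=tx_id, chrom=chrom,
                    strand=strand, tx_start=start, tx_end=end,
                    cds_start=thick_start, cds_end=thick_end, exons=exons,
                ))
            except (ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("skipping malformed row %d of %s: %s", lineno, path, exc)
    if n_bad:
        logger.warning("%d malformed rows skipped in %s", n_bad, path)
    return models


def read_gene_table(path: str | Path, fmt: str = "refflat") -> list[GeneModel]:
    if fmt == "refflat":
        return read_refflat(path)
    if fmt == "bed12":
        return read_bed12(path)
    raise ValueError(f"unknown gene table format {fmt!r}")


# ---------------------------------------------------------------------------
# transcript selection


def select_transcripts(
    models: Iterable[GeneModel],
    mature_mrna_prefix: str = "NM_",
) -> list[GeneModel]:
    """Keep mature-mRNA transcripts, one per distinct (gene, TSS).

    Only transcripts whose accession starts with ``mature_mrna_prefix``
    (RefSeq ``NM_`` by default) are retained.  When a gene has several such
    transcripts sharing a TSS, the lexicographically smallest transcript id
    wins — a deterministic tie-break.
    """
    chosen: dict[tuple[str, str, int], GeneModel] = {}
    models = list(models)
    if not models:
        logger.warning("empty gene table: no transcripts to select")
        return []
    for g in models:
        if not g.transcript_id.startswith(mature_mrna_prefix):
            continue
        key = (g.gene_id, g.chrom, g.tss)
        held = chosen.get(key)
        if held is None or g.transcript_id < held.transcript_id:
            chosen[key] = g
    out = sorted(chosen.values(), key=lambda g: (g.chrom, g.tx_start, g.transcript_id))
    logger.info("selected %d / %d transcripts", len(out), len(models))
    return out


# ---------------------------------------------------------------------------
# region partition


def _clip(start: int, end: int, chrom_size: Optional[int]) -> tuple[int, int]:
    start = max(start, 0)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return start, end


def _subtract(span: tuple[int, int], blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Half-open complement of sorted, disjoint ``blocks`` within ``span``."""
    out = []
    cursor = span[0]
    for bs, be in blocks:
        bs, be = max(bs, span[0]), min(be, span[1])
        if bs >= be:
            continue
        if bs > cursor:
            out.append((cursor, bs))
        cursor = max(cursor, be)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def partition_regions(
    g: GeneModel,
    flank_bounds: Sequence[int] = DEFAULT_FLANK_BOUNDS,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[RegionAnnotation]:
    """Partition the +/-20 kb neighbourhood of ``g`` into the 12 regions.

    Flank segments are laid out in the direction of transcription from the
    TSS (upstream) and TES (downstream).  The gene body is split into
    ``5UTR`` (TSS to CDS start in transcript order), ``3UTR`` (CDS end to
    TES), ``exon`` (exonic bases within the CDS span) and ``intron`` (the
    CDS-span complement of exons), so the four body regions partition
    ``[tx_start, tx_end)`` for coding genes.  Non-coding genes get empty
    5UTR/exon/3UTR and ``intron`` = intra-gene gaps between exons.  All 12
    labels are always emitted, possibly with an empty interval list.
    """
    if len(flank_bounds) != 4 or list(flank_bounds) != sorted(flank_bounds):
        raise ValueError("flank_bounds must be 4 increasing bp values")
    chrom_size = (chrom_sizes or {}).get(g.chrom)
    b = (0,) + tuple(flank_bounds)
    up_labels = ("up2", "up5", "up10", "up20")
    down_labels = ("down2", "down5", "down10", "down20")

    regions: dict[str, list[tuple[int, int]]] = {label: [] for label in REGION_LABELS}

    for i, label in enumerate(up_labels):
        near, far = b[i], b[i + 1]
        if g.strand == "+":
            start, end = g.tss - far, g.tss - near
        else:
            start, end = g.tss + near, g.tss + far
        start, end = _clip(start, end, chrom_size)
        if start < end:
            regions[label].append((start, end))
    for i, label in enumerate(down_labels):
        near, far = b[i], b[i + 1]
        if g.strand == "+":
            start, end = g.tes + near, g.tes + far
        else:
            start, end = g.tes - far, g.tes - near
        start, end = _clip(start, end, chrom_size)
        if start < end:
            regions[label].append((start, end))

    if g.is_coding:
        cds_span = (g.cds_start, g.cds_end)
        if g.strand == "+":
            utr5 = (g.tx_start, g.cds_start)
            utr3 = (g.cds_end, g.tx_end)
        else:
            utr5 = (g.cds_end, g.tx_end)
            utr3 = (g.tx_start, g.cds_start)
        for label, (s, e) in (("5UTR", utr5), ("3UTR", utr3)):
            if s < e:
                regions[label].append((s, e))
        for es, ee in g.exons:
            s, e = max(es, cds_span[0]), min(ee, cds_span[1])
            if s < e:
                regions["exon"].append((s, e))
        regions["intron"] = _subtract(cds_span, regions["exon"])
    else:
        logger.info("non-coding gene %s: 5UTR/exon/3UTR empty", g.gene_id)
        regions["intron"] = _subtract((g.tx_start, g.tx_end), g.exons)

    return [
        RegionAnnotation(
            gene_id=g.gene_id,
            region_label=label,
            intervals=tuple((g.chrom, s, e) for s, e in regions[label]),
            strand=g.strand,
        )
        for label in REGION_LABELS
    ]


# ---------------------------------------------------------------------------
# promoter bins


def make_bins(
    g: GeneModel,
    half_width: int = 2000,
    bin_size: int = 200,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[PromoterBin]:
    """Tile TSS +/- ``half_width`` with consecutive ``bin_size`` bins.

    Bin ``k`` (k >= 1) covers ``[TSS + (k-1)*bin_size, TSS + k*bin_size)``
    in the direction of transcription; bin ``-k`` mirrors it upstream.
    Bins overhanging a chromosome edge are clipped and flagged ``partial``.
    """
    if half_width % bin_size != 0:
        raise ValueError("half_width must be divisible by bin_size")
    n = half_width // bin_size
    chrom_size = (chrom_sizes or {}).get(g.chrom)
    sign = 1 if g.strand == "+" else -1
    bins: list[PromoterBin] = []
    for k in list(range(-n, 0)) + list(range(1, n + 1)):
        # transcription-direction offsets of the bin boundaries
        if k > 0:
            lo_off, hi_off = (k - 1) * bin_size, k * bin_size
        else:
            lo_off, hi_off = k * bin_size, (k + 1) * bin_size
        a = g.tss + sign * lo_off
        c = g.tss + sign * hi_off
        start, end = (a, c) if a <= c else (c, a)
        cstart, cend = _clip(start, end, chrom_size)
        partial = (cstart, cend) != (start, end)
        if partial:
            logger.warning("bin %d of %s clipped at chromosome edge", k, g.gene_id)
        bins.append(PromoterBin(
            gene_id=g.gene_id, bin_index=k,
            interval=(g.chrom, cstart, cend), strand=g.strand,
            partial=partial,
        ))
    return bins


# ---------------------------------------------------------------------------
# tabular views


def regions_frame(annotations: Iterable[RegionAnnotation]) -> pd.DataFrame:
    """Long table of region intervals: gene_id, label, chrom, start, end, strand."""
    rows = []
    for a in annotations:
        for chrom, start, end in a.intervals:
            rows.append((a.gene_id, a.region_label, chrom, start, end, a.strand))
    return pd.DataFrame(rows, columns=["gene_id", "label", "chrom", "start", "end", "strand"])


def bins_frame(bins: Iterable[PromoterBin]) -> pd.DataFrame:
    """Long table of promoter-bin intervals; ``label`` is the bin index."""
    rows = []
    for b in bins:
        chrom, start, end = b.interval
        if start < end:
            rows.append((b.gene_id, b.bin_index, chrom, start, end, b.strand))
    return pd.DataFrame(rows, columns=["gene_id", "label", "chrom", "start", "end", "strand"])


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an interval frame as BED6 with ``name = gene_id|label``."""
    bed = pd.DataFrame({
        "chrom": frame["chrom"],
        "start": frame["start"],
        "end": frame["end"],
        "name": frame["gene_id"].astype(str) + "|" + frame["label"].astype(str),
        "score": 0,
        "strand": frame["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
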