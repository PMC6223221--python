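"""I/O for CpG methylation calls, sample manifests and reference FASTA.

Call tables are tab-delimited with one CpG per row.  The ``standard``
dialect has columns chrom, pos (0-based C of the CpG), strand, meth_level
(fraction in [0, 1]) and coverage (reads).  The ``bismark_cov`` dialect is
the Bismark coverage format (chrom, 1-based start, 1-based end, percent
methylation, count methylated, count unmethylated).

Calls on the ``-`` strand belong to the same CpG dyad as the ``+`` strand
cytosine one base upstream and can be collapsed onto it by a
coverage-weighted mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "meth_level", "coverage"]

#: Developmental stages of the default early-embryo design, in order.
DEFAULT_STAGES = ("zygote", "2cell", "4cell", "8cell", "morula", "ICM", "post")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    stage: str
    replicate: int
    path: Optional[str] = None


@dataclass
class SampleManifest:
    """Maps samples to stages and replicates; stage order is meaningful."""

    samples: list[Sample]
    stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stages:
            seen: list[str] = []
            for s in self.samples:
                if s.stage not in seen:
                    seen.append(s.stage)
            self.stages = seen
        keys = [(s.stage, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (stage, replicate) in manifest")
        for stage in self.stages:
            if not any(s.stage == stage for s in self.samples):
                raise ValueError(f"stage {stage!r} has no samples")

    def samples_of(self, stage: str) -> list[Sample]:
        return [s for s in self.samples if s.stage == stage]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.stage, s.replicate, s.path) for s in self.samples],
            columns=["sample_id", "stage", "replicate", "path"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        samples = [
            Sample(
                sample_id=entry["sample_id"],
                stage=entry["stage"],
                replicate=int(entry["replicate"]),
                path=entry.get("path"),
            )
            for entry in doc["samples"]
        ]
        return cls(samples=samples, stages=list(doc.get("stages", [])))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "stages": list(self.stages),
            "samples": [
                {"sample_id": s.sample_id, "stage": s.stage,
                 "replicate": s.replicate, "path": s.path}
                for s in self.samples
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CpG call reading


@dataclass
class CallQC:
    """Row accounting for one call file."""

    n_input: int = 0
    n_low_coverage: int = 0
    n_bad_level: int = 0
    n_bad_chrom: int = 0
    n_not_cpg: int = 0
    n_kept: int = 0


def _read_standard(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=CALL_COLUMNS, header=None,
        dtype={"chrom": str, "pos": np.int64, "strand": str,
               "meth_level": float, "coverage": np.int64},
    )
    return df


def _read_bismark_cov(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    return pd.DataFrame({
        "chrom": raw["chrom"],
        "pos": raw["start"].astype(np.int64) - 1,  # 1-based -> 0-based
        "strand": "+",
        "meth_level": raw["pct"] / 100.0,
        "coverage": (raw["n_meth"] + raw["n_unmeth"]).astype(np.int64),
    })


def read_cpg_calls(
    path: str | Path,
    coverage_min: int = 5,
    collapse_strands: bool = True,
    fasta=None,
    chroms: Optional[Sequence[str]] = None,
    dialect: str = "standard",
) -> tuple[pd.DataFrame, CallQC]:
    """Read one sample's CpG calls, filter, and collapse dyads.

    Rows with coverage below ``coverage_min`` (default >= 5 kept) or with a
    methylation level outside [0, 1] are dropped and counted.  When a
    ``pyfaidx.Fasta`` (or path) is supplied, calls on chromosomes absent
    from it, or whose reference dinucleotide is not CG, are rejected.
    With ``collapse_strands``, ``-`` strand calls are mapped to the ``+``
    strand C of the dyad (pos - 1) and merged by coverage-weighted mean.

    Returns a frame with columns chrom, pos, meth_level, coverage (sorted
    by chrom, pos) and a :class:`CallQC` record.
    """
    if dialect == "standard":
        df = _read_standard(path)
    elif dialect == "bismark_cov":
        df = _read_bismark_cov(path)
    else:
        raise ValueError(f"unknown call dialect {dialect!r}")
    if df.empty:
        logger.warning("empty call file %s", path)
    return filter_calls(df, coverage_min=coverage_min,
                        collapse_strands=collapse_strands, fasta=fasta,
                        chroms=chroms)


def filter_calls(
    df: pd.DataFrame,
    coverage_min: int = 5,
    collapse_strands: bool = True,
    fasta=None,
    chroms: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, CallQC]:
    """Apply the coverage/validity filters and dyad collapse to a raw call
    frame (columns chrom, pos, strand, meth_level, coverage)."""
    qc = CallQC(n_input=len(df))
    if df.empty:
        empty = pd.DataFrame(columns=["chrom", "pos", "meth_level", "coverage"])
        return empty, qc

    bad_level = (df["meth_level"] < 0) | (df["meth_level"] > 1) | df["meth_level"].isna()
    qc.n_bad_level = int(bad_level.sum())
    df = df[~bad_level]

    if chroms is not None:
        df = df[df["chrom"].isin(set(chroms))]

    if fasta is not None:
        fasta = _as_fasta(fasta)
        known = set(fasta.keys())
        bad_chrom = ~df["chrom"].isin(known)
        qc.n_bad_chrom = int(bad_chrom.sum())
        df = df[~bad_chrom]

    low = df["coverage"] < coverage_min
    qc.n_low_coverage = int(low.sum())
    df = df[~low].copy()

    if collapse_strands:
        minus = df["strand"] == "-"
        df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
        w = df["meth_level"] * df["coverage"]
        grouped = df.assign(_w=w).groupby(["chrom", "pos"], sort=True, as_index=False).agg(
            _w=("_w", "sum"), coverage=("coverage", "sum"))
        grouped["meth_level"] = grouped["_w"] / grouped["coverage"]
        df = grouped[["chrom", "pos", "meth_level", "coverage"]]
    else:
        df = df[["chrom", "pos", "meth_level", "coverage"]]

    if fasta is not None:
        keep = np.ones(len(df), dtype=bool)
        for i, (chrom, pos) in enumerate(zip(df["chrom"], df["pos"])):
            dinuc = str(fasta[chrom][int(pos):int(pos) + 2]).upper()
            keep[i] = dinuc == "CG"
        qc.n_not_cpg = int((~keep).sum())
        df = df[keep]

    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    qc.n_kept = len(df)
    return df, qc


def write_calls(df: pd.DataFrame, path: str | Path) -> None:
    """Write collapsed calls in the standard dialect (all ``+`` strand)."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"].astype(np.int64),
        "strand": "+",
        "meth_level": df["meth_level"],
        "coverage": df["coverage"].astype(np.int64),
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# reference FASTA


def _as_fasta(fasta):
    import pyfaidx

    if isinstance(fasta, (str, Path)):
        return pyfaidx.Fasta(str(fasta))
    return fasta


def cpg_positions(fasta, chrom: str) -> np.ndarray:
    """Sorted 0-based positions of the C of every CG dinucleotide.

    Case-insensitive; CG motifs cannot overlap so positions are unique.
    """
    fasta = _as_fasta(fasta)
    if chrom not in fasta:
        raise KeyError(f"chromosome {chrom!r} not present in FASTA")
    seq = np.frombuffer(str(fasta[chrom][:]).upper().encode("ascii"), dtype=np.uint8)
    if seq.size < 2:
        return np.empty(0, dtype=np.int64)
    hits = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
    return hits.astype(np.int64)
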