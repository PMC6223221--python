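"""Synthetic genome, methylome and expression generator with ground truth.

The generator emulates the structure of stage-resolved early-embryo WGBS
data: a global methylation level that drops after the zygote, stays low
through cleavage and the ICM, and rises sharply post-implantation; a
hypo-methylated promoter core around the TSS; a hyper-methylated 3'UTR; a
unimodal promoter CpG-density profile peaking in the first 200 bp
downstream of the TSS; and expression coupled to methylation with designed
correlation signs (negative around the promoter and 5'UTR, positive at the
3'UTR).  Named gene subsets are planted to switch from hypo- to
hyper-methylated at the post-implantation stage and to pass the
differential bin-1 filters, so recovery can be scored exactly.

Every random draw comes from one seeded generator: the same seed yields
byte-identical output files.

Mechanics: each CpG carries a design mean per stage.  CpGs in fixed zones
(promoter core, 3'UTR, planted subsets) take zone levels; the remaining
"floating" CpGs take a per-stage background level that is solved
analytically so the cohort's expected gene-level mean equals the requested
per-stage global target.  Observed per-CpG, per-sample levels are beta
noise around the design mean; coverage is negative binomial so the
minimum-coverage filter is exercised realistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation
from .annotation import GeneModel
from .methio import DEFAULT_STAGES, Sample, SampleManifest


def default_bin_profile() -> np.ndarray:
    """Mean CpG count per promoter bin (order -10..-1, 1..10), peak at bin 1."""
    idx = np.array(list(range(-10, 0)) + list(range(1, 11)), dtype=float)
    centres = np.where(idx > 0, idx - 0.5, idx + 0.5)  # bin midpoints in units of 200 bp
    return 1.0 + 11.0 * np.exp(-((centres - 0.5) ** 2) / (2 * 2.5**2))


def _default_designed_r() -> dict:
    d = {"up2": -0.3, "5UTR": -0.3, "3UTR": 0.3}
    for k in list(range(-4, 0)) + list(range(1, 7)):
        d[k] = -0.3
    return d


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator.  Levels are fractions in [0, 1]."""

    n_genes: int = 500
    seed: int = 0
    chrom: str = "chr1"
    chrom_length: Optional[int] = None          # auto-sized when None
    stages: Sequence[str] = DEFAULT_STAGES
    stage_means: Sequence[float] = (0.50, 0.35, 0.33, 0.32, 0.30, 0.30, 0.75)
    replicates_per_stage: int = 3
    promoter_hypo_level: Optional[Sequence[float]] = None  # per stage; default 0.12, 0.25 at last
    utr3_hyper_level: float = 0.85
    designed_r: dict = field(default_factory=_default_designed_r)
    cpg_profile: np.ndarray = field(default_factory=default_bin_profile)
    background_cpg_spacing: int = 100           # mean bp between background CpGs
    beta_sd: float = 0.05                       # per-CpG noise SD around the design mean
    region_gene_sd: float = 0.08                # per-gene, per-zone level scatter
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    dyad_split_fraction: float = 0.1            # CpGs reported on both strands
    expr_base: float = 3.0
    expr_slope: float = 1.5                     # log2-RPKM units per latent SD
    expr_noise: float = 0.3
    zero_expr_fraction: float = 0.02
    n_transition_genes: int = 50                # planted hypo -> hyper at the last stage
    n_diff_genes: int = 30                      # planted to pass the bin-1 filters
    transition_pre_level: float = 0.10
    transition_post_level: float = 0.90
    diff_level_from: float = 0.60               # bin-1 level at the penultimate stage
    diff_level_to: float = 0.20                 # bin-1 level at the last stage
    diff_expr_shift: float = 2.0                # log2 expression boost at the last stage

    def __post_init__(self) -> None:
        if len(self.stage_means) != len(self.stages):
            raise ValueError("stage_means must match stages in length")
        if self.promoter_hypo_level is None:
            self.promoter_hypo_level = (0.12,) * (len(self.stages) - 1) + (0.25,)
        if len(self.promoter_hypo_level) != len(self.stages):
            raise ValueError("promoter_hypo_level must match stages in length")
        if self.n_transition_genes + self.n_diff_genes > self.n_genes:
            raise ValueError("planted gene subsets exceed n_genes")


@dataclass
class SimulationResult:
    """In-memory simulation output plus ground truth."""

    config: SimulationConfig
    models: list            # selected GeneModel per gene
    gene_rows: list         # refFlat text rows (incl. decoy transcripts)
    chrom_length: int
    cpg_pos: np.ndarray     # planted CpG C positions, sorted
    mu: np.ndarray          # n_cpg x n_stages design means
    calls: dict             # sample_id -> raw call frame (chrom,pos,strand,meth_level,coverage)
    expression: pd.DataFrame  # genes x samples RPKM
    manifest: SampleManifest
    truth: dict

    def sequence(self) -> bytes:
        """Chromosome sequence: AT background with CG planted at cpg_pos."""
        base = np.tile(np.frombuffer(b"AT", dtype=np.uint8),
                       self.chrom_length // 2 + 1)[: self.chrom_length].copy()
        if self.cpg_pos.size:
            base[self.cpg_pos] = ord("C")
            base[self.cpg_pos + 1] = ord("G")
        return base.tobytes()

    def write(self, outdir: str | Path) -> dict:
        """Write FASTA, gene table, call files, expression, manifest, truth.

        Returns the path map.  Output is byte-identical for a fixed config.
        """
        outdir = Path(outdir)
        (outdir / "calls").mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "genes": outdir / "genes.refflat",
            "expression": outdir / "expression.tsv",
            "manifest": outdir / "manifest.yaml",
            "truth": outdir / "truth.json",
        }
        seq = self.sequence()
        with open(paths["fasta"], "wb") as fh:
            fh.write(f">{self.config.chrom}\n".encode())
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80])
                fh.write(b"\n")
        with open(paths["genes"], "w") as fh:
            for row in self.gene_rows:
                fh.write(row + "\n")
        samples = []
        for s in self.manifest.samples:
            rel = f"calls/{s.sample_id}.tsv"
            self.calls[s.sample_id].to_csv(
                outdir / rel, sep="\t", header=False, index=False,
                float_format="%.6g")
            samples.append(Sample(s.sample_id, s.stage, s.replicate, rel))
        manifest = SampleManifest(samples=samples, stages=list(self.manifest.stages))
        manifest.to_yaml(paths["manifest"])
        self.expression.to_csv(paths["expression"], sep="\t", float_format="%.6g",
                               index_label="gene_id")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping gene models with >= 40 kb spacing; decoy transcripts."""
    models: list[GeneModel] = []
    rows: list[str] = []
    cursor = 21_000
    for i in range(cfg.n_genes):
        length = int(rng.integers(3000, 8001))
        strand = "+" if rng.random() < 0.5 else "-"
        tx_start, tx_end = cursor, cursor + length
        cursor = tx_end + 41_000
        exons = ((tx_start, tx_start + 600),
                 (tx_start + 1200, tx_start + 1800),
                 (tx_end - 700, tx_end))
        cds_start, cds_end = tx_start + 250, tx_end - 350
        gene_id = f"G{i:04d}"
        tx_id = f"NM_{i:06d}"
        g = GeneModel(gene_id=gene_id, transcript_id=tx_id, chrom=cfg.chrom,
                      strand=strand, tx_start=tx_start, tx_end=tx_end,
                      cds_start=cds_start, cds_end=cds_end, exons=exons)
        models.append(g)
        rows.append(_refflat_row(g))
        u = rng.random()
        if u < 0.05:  # non-coding decoy sharing the TSS: must be filtered out
            rows.append(_refflat_row(GeneModel(
                gene_id=gene_id, transcript_id=f"NR_{i:06d}", chrom=cfg.chrom,
                strand=strand, tx_start=tx_start, tx_end=tx_end,
                cds_start=tx_start, cds_end=tx_start,
                exons=((tx_start, tx_end),))))
        elif u < 0.10:  # alternative mature transcript, same TSS: tie-break target
            rows.append(_refflat_row(GeneModel(
                gene_id=gene_id, transcript_id=f"NM_9{i:05d}", chrom=cfg.chrom,
                strand=strand, tx_start=tx_start, tx_end=tx_end,
                cds_start=cds_start, cds_end=cds_end,
                exons=((tx_start, tx_end),))))
    needed = (cursor - 41_000 + 21_000) if cfg.n_genes else 60_000
    if cfg.chrom_length is None:
        chrom_length = needed
    elif cfg.chrom_length < needed:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes "
            f"with 40 kb spacing; need >= {needed}")
    else:
        chrom_length = cfg.chrom_length
    return models, rows, chrom_length


def _refflat_row(g: GeneModel) -> str:
    starts = ",".join(str(s) for s, _ in g.exons) + ","
    ends = ",".join(str(e) for _, e in g.exons) + ","
    return "\t".join(str(x) for x in (
        g.gene_id, g.transcript_id, g.chrom, g.strand, g.tx_start, g.tx_end,
        g.cds_start, g.cds_end, len(g.exons), starts, ends))


def _plant_cpgs(cfg: SimulationConfig, models, chrom_length, rng):
    """CpG positions: per-bin promoter counts plus thinned background."""
    promoter_pos = []
    bin_order = list(range(-10, 0)) + list(range(1, 11))
    for g in models:
        bins = annotation.make_bins(g)
        by_index = {b.bin_index: b.interval for b in bins}
        for mean, k in zip(cfg.cpg_profile, bin_order):
            _, start, end = by_index[k]
            width_slots = max((end - start) // 2, 0)
            if width_slots == 0:
                continue
            count = min(int(rng.poisson(mean)), width_slots - 5)
            if count <= 0:
                continue
            offsets = np.sort(rng.choice(width_slots, size=count, replace=False))
            promoter_pos.append(start + 2 * offsets)
    # background CpGs on even slots outside promoter spans
    slots = np.arange(100, max(chrom_length - 100, 102), 2, dtype=np.int64)
    keep = rng.random(slots.size) < (2.0 / cfg.background_cpg_spacing)
    cand = slots[keep]
    if models:
        span_start = np.array([g.tss - 2002 for g in models])
        span_end = np.array([g.tss + 2002 for g in models])
        order = np.argsort(span_start)
        span_start, span_end = span_start[order], span_end[order]
        idx = np.searchsorted(span_start, cand, side="right") - 1
        inside = (idx >= 0) & (cand < span_end[np.clip(idx, 0, None)])
        cand = cand[~inside]
    parts = promoter_pos + [cand]
    pos = np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
    return pos.astype(np.int64)


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run the generator.  See the module docstring for the design model."""
    rng = np.random.default_rng(cfg.seed)
    stages = list(cfg.stages)
    n_stages = len(stages)
    models, gene_rows, chrom_length = _place_genes(cfg, rng)
    cpg_pos = _plant_cpgs(cfg, models, chrom_length, rng)
    n_cpg = cpg_pos.size
    n_genes = cfg.n_genes

    # --- gene assignment and zones -------------------------------------
    gene_of = np.full(n_cpg, -1, dtype=np.int64)
    t_off = np.zeros(n_cpg)          # transcription-direction offset from TSS
    zone = np.zeros(n_cpg, dtype=np.int8)   # 0 outside, 1 float, 2 hypo core, 3 3'UTR
    bin1 = np.zeros(n_cpg, dtype=bool)
    if models:
        nb_start = np.array([g.tx_start - 20_000 for g in models])
        nb_end = np.array([g.tx_end + 20_000 for g in models])
        idx = np.searchsorted(nb_start, cpg_pos, side="right") - 1
        inside = (idx >= 0) & (cpg_pos < nb_end[np.clip(idx, 0, None)])
        gene_of[inside] = idx[inside]
        tss = np.array([g.tss for g in models])
        sign = np.array([1 if g.strand == "+" else -1 for g in models])
        utr3_lo = np.array([g.cds_end if g.strand == "+" else g.tx_start for g in models])
        utr3_hi = np.array([g.tx_end if g.strand == "+" else g.cds_start for g in models])
        gi = np.clip(gene_of, 0, None)
        t_off = np.where(gene_of >= 0, sign[gi] * (cpg_pos - tss[gi]), 0)
        in_gene = gene_of >= 0
        zone[in_gene] = 1
        core = in_gene & (t_off >= -800) & (t_off < 1200)
        utr3 = in_gene & (cpg_pos >= utr3_lo[gi]) & (cpg_pos < utr3_hi[gi])
        zone[utr3] = 3
        zone[core] = 2          # the promoter core wins over UTR overlap
        bin1 = in_gene & (t_off >= 0) & (t_off < 200)

    # --- planted gene subsets ------------------------------------------
    perm = rng.permutation(n_genes)
    transition_idx = np.sort(perm[: cfg.n_transition_genes])
    diff_idx = np.sort(perm[cfg.n_transition_genes:
                            cfg.n_transition_genes + cfg.n_diff_genes])
    is_transition = np.zeros(n_genes, dtype=bool)
    is_transition[transition_idx] = True
    is_diff = np.zeros(n_genes, dtype=bool)
    is_diff[diff_idx] = True
    if n_genes:
        gi0 = np.clip(gene_of, 0, None)
        trans_cpg = (gene_of >= 0) & is_transition[gi0]
        diff_bin1_cpg = bin1 & (gene_of >= 0) & is_diff[gi0]
    else:
        trans_cpg = np.zeros(n_cpg, dtype=bool)
        diff_bin1_cpg = np.zeros(n_cpg, dtype=bool)

    # --- per-gene latent structure -------------------------------------
    z = rng.standard_normal(n_genes) if n_genes else np.empty(0)
    u = rng.standard_normal((n_genes, 3)) if n_genes else np.empty((0, 3))
    r_mag = float(np.mean([abs(v) for v in cfg.designed_r.values()])) if cfg.designed_r else 0.0
    rho_e = cfg.expr_slope / np.hypot(cfg.expr_slope, cfg.expr_noise)
    ratio = min(r_mag / rho_e, 0.99)
    coup_mag = cfg.region_gene_sd * ratio / np.sqrt(1 - ratio**2)
    coup = np.zeros(n_cpg)
    if n_genes:
        gi = np.clip(gene_of, 0, None)
        neg = (gene_of >= 0) & (t_off >= -2000) & (t_off < 1200)   # up2 + promoter core + 5'UTR
        coup[neg] = -coup_mag
        coup[zone == 3] = +coup_mag
        zone_col = np.select([zone == 2, zone == 3], [0, 1], default=2)
        offset = coup * z[gi] + cfg.region_gene_sd * u[gi, zone_col]
        offset[gene_of < 0] = 0.0
        offset[trans_cpg] = 0.0
        offset[diff_bin1_cpg] = 0.0
    else:
        offset = np.zeros(n_cpg)

    # --- per-stage design means with calibrated background level -------
    mu = np.zeros((n_cpg, n_stages))
    n_per_gene = np.bincount(gene_of[gene_of >= 0], minlength=n_genes) if n_genes else np.empty(0)
    backgrounds = []
    for s in range(n_stages):
        fixed_base = np.full(n_cpg, np.nan)
        fixed_base[zone == 2] = cfg.promoter_hypo_level[s]
        fixed_base[zone == 3] = cfg.utr3_hyper_level
        if s < n_stages - 1:
            fixed_base[trans_cpg] = cfg.transition_pre_level
        else:
            fixed_base[trans_cpg] = cfg.transition_post_level
        if s == n_stages - 2:
            fixed_base[diff_bin1_cpg] = cfg.diff_level_from
        elif s == n_stages - 1:
            fixed_base[diff_bin1_cpg] = cfg.diff_level_to
        is_fixed = ~np.isnan(fixed_base)
        floating = (gene_of >= 0) & ~is_fixed
        target = cfg.stage_means[s]
        if n_genes:
            gsel = gene_of >= 0
            fix_sum = np.bincount(gene_of[gsel & is_fixed],
                                  weights=fixed_base[gsel & is_fixed],
                                  minlength=n_genes)
            off_sum = np.bincount(gene_of[gsel], weights=offset[gsel],
                                  minlength=n_genes)
            nfloat = np.bincount(gene_of[floating], minlength=n_genes)
            ok = n_per_gene > 0
            A = np.mean((fix_sum[ok] + off_sum[ok]) / n_per_gene[ok]) if ok.any() else 0.0
            B = np.mean(nfloat[ok] / n_per_gene[ok]) if ok.any() else 0.0
            b_s = (target - A) / B if B > 0 else target
        else:
            b_s = target
        b_s = float(np.clip(b_s, 0.02, 0.98))
        backgrounds.append(b_s)
        col = np.where(is_fixed, fixed_base, b_s) + offset
        mu[:, s] = np.clip(col, 0.02, 0.98)

    # --- expression -----------------------------------------------------
    sample_list = [
        Sample(sample_id=f"{stage}_r{r}", stage=stage, replicate=r)
        for stage in stages for r in range(1, cfg.replicates_per_stage + 1)
    ]
    manifest = SampleManifest(samples=sample_list, stages=stages)
    gene_ids = [g.gene_id for g in models]
    log2e = {}
    for s_idx, stage in enumerate(stages):
        for r in range(1, cfg.replicates_per_stage + 1):
            vals = (cfg.expr_base + cfg.expr_slope * z
                    + rng.normal(0.0, cfg.expr_noise, n_genes))
            if s_idx == n_stages - 1:
                vals = vals + cfg.diff_expr_shift * is_diff
            log2e[f"{stage}_r{r}"] = vals
    expr = pd.DataFrame(log2e, index=pd.Index(gene_ids, name="gene_id"))
    rpkm = np.power(2.0, expr)
    if n_genes:
        zero_mask = (rng.random(rpkm.shape) < cfg.zero_expr_fraction) \
            & ~is_diff[:, None]
        rpkm = rpkm.mask(pd.DataFrame(zero_mask, index=rpkm.index,
                                      columns=rpkm.columns), 0.0)

    # --- per-sample methylation calls -----------------------------------
    calls: dict[str, pd.DataFrame] = {}
    for s_idx, stage in enumerate(stages):
        mu_s = mu[:, s_idx]
        for r in range(1, cfg.replicates_per_stage + 1):
            if cfg.beta_sd > 0 and n_cpg:
                sd = np.minimum(cfg.beta_sd, 0.45 * np.sqrt(mu_s * (1 - mu_s)))
                nu = mu_s * (1 - mu_s) / sd**2 - 1
                lev = rng.beta(mu_s * nu, (1 - mu_s) * nu)
            else:
                lev = mu_s.copy()
            k = cfg.coverage_dispersion
            cov = rng.negative_binomial(k, k / (k + cfg.coverage_mean), n_cpg) \
                if n_cpg else np.empty(0, dtype=int)
            split = rng.random(n_cpg) < cfg.dyad_split_fraction if n_cpg else np.empty(0, bool)
            plus = pd.DataFrame({
                "chrom": cfg.chrom, "pos": cpg_pos, "strand": "+",
                "meth_level": lev,
                "coverage": np.where(split, cov - cov // 2, cov),
            })
            minus = pd.DataFrame({
                "chrom": cfg.chrom, "pos": cpg_pos[split] + 1, "strand": "-",
                "meth_level": lev[split], "coverage": (cov // 2)[split],
            })
            df = pd.concat([plus, minus], ignore_index=True)
            df = df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)
            calls[f"{stage}_r{r}"] = df

    # --- ground truth ----------------------------------------------------
    if n_genes:
        ok = n_per_gene > 0
        gene_mu_sum = np.vstack([
            np.bincount(gene_of[gene_of >= 0], weights=mu[gene_of >= 0, s],
                        minlength=n_genes)
            for s in range(n_stages)
        ]).T
        expected_global = (gene_mu_sum[ok] / n_per_gene[ok, None]).mean(axis=0)
    else:
        expected_global = np.array(cfg.stage_means, dtype=float)
    truth = {
        "seed": cfg.seed,
        "n_genes": n_genes,
        "stages": stages,
        "stage_means_target": [float(x) for x in cfg.stage_means],
        "expected_global_by_stage": [float(x) for x in expected_global],
        "background_level_by_stage": backgrounds,
        "designed_r": {str(k): v for k, v in cfg.designed_r.items()},
        "transition_genes": [gene_ids[i] for i in transition_idx],
        "diff_genes": [gene_ids[i] for i in diff_idx],
        "transition_pre_level": cfg.transition_pre_level,
        "transition_post_level": cfg.transition_post_level,
        "cpg_peak_bin": 1,
        "n_cpg": int(n_cpg),
    }

    return SimulationResult(
        config=cfg, models=models, gene_rows=gene_rows,
        chrom_length=chrom_length, cpg_pos=cpg_pos, mu=mu,
        calls=calls, expression=rpkm, manifest=manifest, truth=truth,
    )
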