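import pytest

from methregions import cli, methio
from methregions.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic dataset shared by fast tests."""
    cfg = SimulationConfig(
        n_genes=60, seed=11, n_transition_genes=10, n_diff_genes=8)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Full pipeline result on the small dataset."""
    filtered = {
        sid: methio.filter_calls(df)[0] for sid, df in small_sim.calls.items()
    }
    cpg_index = {small_sim.config.chrom: small_sim.cpg_pos}
    return cli.run_pipeline(
        small_sim.models, filtered, small_sim.manifest,
        small_sim.expression, None, cpg_index)


def make_gene(gene_id="G1", tx="NM_1", chrom="chr1", strand="+",
              tx_start=100_000, tx_end=105_000, cds_start=None, cds_end=None,
              exons=None):
    from methregions.annotation import GeneModel

    if exons is None:
        exons = ((tx_start, tx_end),)
    if cds_start is None:
        cds_start = tx_start + 200
    if cds_end is None:
        cds_end = tx_end - 300
    return GeneModel(gene_id=gene_id, transcript_id=tx, chrom=chrom,
                     strand=strand, tx_start=tx_start, tx_end=tx_end,
                     cds_start=cds_start, cds_end=cds_end, exons=tuple(exons))
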