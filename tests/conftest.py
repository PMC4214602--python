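import numpy as np
import pytest

from rloopscape import synthetic_data as sd
from rloopscape.coverage import EnrichmentTrack


def small_spec(**overrides) -> sd.SimSpec:
    """A scaled-down simulation for fast unit tests."""
    base = dict(
        seed=7,
        contig_lengths={"chrI": 150_000, "chrII": 120_000, "chrM": 30_000},
        spacing=(1_500, 2_500),
        n_trna=12,
        n_spliced=12,
        n_intronless=12,
        retro_copies=4,
        retro_length=1_500,
        n_mito_genes=2,
        mito_gene_length=(2_000, 4_000),
        base_depth=10.0,
    )
    base.update(overrides)
    return sd.SimSpec(**base)


@pytest.fixture(scope="session")
def small_sim() -> sd.SimulatedGenome:
    return sd.make_genome(small_spec())


@pytest.fixture(scope="session")
def small_chip_reads(small_sim):
    return sd.simulate_reads(small_sim, "rnh", "chip")


def make_track(scores_by_contig: dict[str, np.ndarray], window_size: int = 50) -> EnrichmentTrack:
    """Wrap raw window scores as an enrichment track for profile tests."""
    return EnrichmentTrack(
        window_size=window_size,
        contig_lengths={c: len(v) * window_size for c, v in scores_by_contig.items()},
        scores={c: np.asarray(v, dtype=float) for c, v in scores_by_contig.items()},
        intergenic_mean=1.0,
    )
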