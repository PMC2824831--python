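import numpy as np
import pytest

from estkit.simdata import SimConfig, simulate_library, simulate_transcriptome

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def small_library():
    """A small clean simulated library shared across read-only tests."""
    cfg = SimConfig(
        seed=42, n_transcripts=8, n_clones=40,
        frac_insertless=0.0, frac_contaminant=0.0, frac_low_complexity=0.0,
    )
    transcriptome = simulate_transcriptome(cfg)
    records, clones, truth = simulate_library(transcriptome, cfg)
    return cfg, transcriptome, records, clones, truth
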