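import numpy as np
import pandas as pd
import pytest

from domscan import GenotypeMatrix, SimConfig, simulate_cohort


def make_gm(calls, positions=None, chrom="chr1", subpops=None, ref="A", alt="C"):
    """Hand-build a GenotypeMatrix from a (samples x sites) call list."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[:, None]
    S, L = calls.shape
    if positions is None:
        positions = np.arange(1, L + 1) * 100
    chroms = [chrom] * L if isinstance(chrom, str) else list(chrom)
    refs = [ref] * L if isinstance(ref, str) else list(ref)
    alts = [alt] * L if isinstance(alt, str) else list(alt)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    if subpops is None:
        subpops = ["popA"] * S
    samples = pd.DataFrame(
        {"sample": [f"s{i}" for i in range(S)], "subpop": subpops}
    )
    return GenotypeMatrix(calls=calls, sites=sites, samples=samples)


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two subpopulations with a planted sweep and shared homozygous tracts."""
    cfg = SimConfig(
        subpopulations=[("hyb", 25), ("land", 25)],
        chromosomes={"chr1": 20_000_000},
        fst=0.1,
        seed=7,
        sweeps=[("hyb", "chr1", 8_000_000, 9_000_000, 0.02)],
        roh=[
            (f"hyb_{i:03d}", "chr1", 4_000_000, 6_000_000) for i in range(4)
        ],
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def neutral_cohort():
    cfg = SimConfig(
        subpopulations=[("a", 30), ("b", 30)],
        chromosomes={"chr1": 10_000_000, "chr2": 10_000_000},
        fst=0.15,
        seed=11,
    )
    return cfg, simulate_cohort(cfg)
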