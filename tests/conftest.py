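import numpy as np
import pytest

from cinsig.genome import GenomeModel
from cinsig.simulate import SyntheticCohort, builtin_templates, simulate_sample


@pytest.fixture(scope="session")
def grch38() -> GenomeModel:
    return GenomeModel.grch38()


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Three 100 Mb chromosomes with centromeres at 50 Mb."""
    return GenomeModel.toy(n_chrom=3, length=100_000_000)


@pytest.fixture(scope="session")
def pure_template_cohort(grch38) -> SyntheticCohort:
    """Ten pure samples per built-in template, shared across tests."""
    names = list(builtin_templates())
    bundles = []
    for t_idx, t in enumerate(names):
        for i in range(10):
            weights = {n: (1.0 if n == t else 0.0) for n in names}
            bundles.append(
                simulate_sample(
                    weights, grch38, seed=[1234, t_idx, i],
                    sample=f"{t}_{i}", patient=f"{t}_{i}",
                )
            )
    return SyntheticCohort(
        samples=bundles, clinical=[], exposures=None, config={}, seed=1234
    )


def random_junctions(rng: np.random.Generator, n: int, sample: str = "S"):
    """Random junction set for clustering tests (mix of intra/inter events)."""
    from cinsig.types import make_junction

    chroms = ["chr1", "chr2", "chr3"]
    out = []
    for _ in range(n):
        c1 = str(rng.choice(chroms))
        p1 = int(rng.integers(1_000_000, 60_000_000))
        if rng.random() < 0.7:
            c2, p2 = c1, p1 + int(rng.integers(1_000, 8_000_000))
        else:
            c2 = str(rng.choice([c for c in chroms if c != c1]))
            p2 = int(rng.integers(1_000_000, 60_000_000))
        o1, o2 = rng.choice(["+", "-"], size=2)
        out.append(make_junction(sample, c1, p1, str(o1), c2, p2, str(o2)))
    return out
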