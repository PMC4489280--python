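import numpy as np
import pytest

from wescnv.hmm_caller import HMMModel
from wescnv.normalization import RatioProfile
from wescnv.targets_io import TargetGrid, TargetRegion


@pytest.fixture
def small_grid() -> TargetGrid:
    """Three targets on two chromosomes, matching the documented examples."""
    return TargetGrid(
        [
            TargetRegion("chr1", 101, 200, 0.40),
            TargetRegion("chr1", 301, 400, 0.55),
            TargetRegion("chr2", 51, 150, 0.60),
        ]
    )


def make_profile(values, mask=None, grid=None, sample_id="s", space="log2"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(len(values), dtype=bool)
    return RatioProfile(sample_id, values, np.asarray(mask, bool), space=space, grid=grid)


def random_model(rng: np.random.Generator, n_states: int) -> HMMModel:
    """A random valid HMM over copy numbers 0..n_states-1."""
    means = np.sort(rng.normal(0.0, 1.5, n_states))
    means += np.arange(n_states) * 0.05  # guarantee strict increase
    initial = rng.dirichlet(np.ones(n_states))
    return HMMModel(
        copy_numbers=tuple(range(n_states)),
        means=means,
        variance=float(rng.uniform(0.05, 0.5)),
        stay_prob=float(rng.uniform(0.6, 0.98)),
        initial=initial,
    )


def uniform_grid(n: int, chrom: str = "chr1", gc: float = 0.5, spacing: int = 1000,
                 length: int = 100) -> TargetGrid:
    """n equally spaced equal-GC targets on one chromosome."""
    return TargetGrid(
        [
            TargetRegion(chrom, 1 + i * spacing, 1 + i * spacing + length - 1, gc)
            for i in range(n)
        ]
    )
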