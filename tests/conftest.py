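import numpy as np
import pytest

from dsbchrom import SimulationParams, make_sites, simulate_chip_pair


@pytest.fixture(scope="session")
def small_params():
    """A compact genome that still holds several TADs and break domains."""
    return SimulationParams(genome=[("chr1", 40_000_000)], seed=3)


@pytest.fixture(scope="session")
def small_sites(small_params):
    sites, boundaries = make_sites(small_params, n_sites=10, min_separation=3_000_000)
    return sites, boundaries


@pytest.fixture(scope="session")
def chip_pair(small_params, small_sites):
    sites, boundaries = small_sites
    treated, untreated, truth = simulate_chip_pair(small_params, sites, boundaries)
    return treated, untreated, truth


def naive_insulation(matrix: np.ndarray, d: int) -> np.ndarray:
    """Independent double-loop insulation oracle.

    For each bin, gathers the upstream-x-downstream square elementwise in
    row-major order and takes the NaN-aware mean; bins with >50% masked
    squares or within d of an end get NaN. Normalization is
    log2(raw / chromosome mean of finite raws).
    """
    n = matrix.shape[0]
    raw = np.full(n, np.nan)
    for i in range(n):
        if i - d < 0 or i + d >= n:
            continue
        vals = []
        for a in range(i - d, i):
            for b in range(i + 1, i + d + 1):
                vals.append(matrix[a, b])
        vals = np.array(vals)
        if np.isnan(vals).sum() > 0.5 * len(vals):
            continue
        raw[i] = np.nanmean(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(raw / np.nanmean(raw))
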