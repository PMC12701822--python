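"""TAD-boundary constraint on the broad repair-factor domain.

Quantifies (i) the drop of RAD51-type ChIP enrichment across TAD boundaries
that lie at a set distance range from cut sites, against distance-matched
random control positions, and (ii) the difference in enrichment between two
conditions within signed distance bands around the cut (the readout used to
detect a broadened homology-search domain after perturbing loop extrusion).

"Normalized drop" at a boundary: the enrichment profile over boundary ±
flank is oriented so the cut-proximal side is on the left, divided by its
cut-proximal-side mean (so the proximal level is 1), and the drop is
1 − distal mean — a unitless fraction, invariant to global scaling of the
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .chip import StrandedCoverage, _as_cov_dict, _rebin, rpm_normalize
from .hic import CutSiteSet

__all__ = [
    "EnrichmentTrack",
    "BoundaryDropResult",
    "BandDifferenceResult",
    "enrichment_track",
    "boundary_drop",
    "sample_random_controls",
    "band_difference",
]


@dataclass
class EnrichmentTrack:
    """Per-bin treated-minus-untreated RPM for one chromosome."""

    chrom: str
    bin_size: int
    values: np.ndarray
    origin: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.values)


def enrichment_track(
    treated: "StrandedCoverage | Mapping[str, StrandedCoverage]",
    untreated: "StrandedCoverage | Mapping[str, StrandedCoverage]",
    out_bin: int,
) -> dict[str, EnrichmentTrack]:
    """Treated−untreated RPM per out_bin, per chromosome."""
    tcov = _as_cov_dict(treated)
    ucov = _as_cov_dict(untreated)
    out: dict[str, EnrichmentTrack] = {}
    for chrom in tcov:
        t = rpm_normalize(tcov[chrom])
        u = rpm_normalize(ucov[chrom])
        if out_bin % t.bin_size != 0 or t.bin_size != u.bin_size:
            raise ValueError("out_bin must be an integer multiple of the native bin")
        factor = out_bin // t.bin_size
        vals = _rebin(t.both, factor) - _rebin(u.both, factor)
        out[chrom] = EnrichmentTrack(
            chrom=chrom, bin_size=out_bin, values=vals, origin=t.origin
        )
    return out


@dataclass
class BoundaryDropResult:
    """Normalized enrichment drop at boundaries vs random control positions."""

    boundary_drops: np.ndarray
    control_drops: np.ndarray
    boundary_mean: float
    boundary_sem: float
    boundary_t: float
    boundary_p: float
    control_mean: float
    control_sem: float
    control_t: float
    control_p: float
    n_boundaries: int
    n_controls: int
    n_excluded: int
    dist_range: tuple[int, int]
    flank: int
    mean_profile: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False


@dataclass
class BandDifferenceResult:
    """Between-condition enrichment difference within signed distance bands."""

    bands: list[tuple[float, float]]
    per_site_a: list[np.ndarray]
    per_site_b: list[np.ndarray]
    difference: list[float]  # mean(B) − mean(A) per band
    t_statistic: list[float]
    p_value: list[float]
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# boundary drop
# ---------------------------------------------------------------------------


def _pair_profiles(
    tracks: Mapping[str, EnrichmentTrack],
    sites: CutSiteSet,
    positions: Sequence[tuple[str, int]],
    dist_range: tuple[int, int],
    flank: int,
) -> tuple[list[np.ndarray], int]:
    """Oriented boundary±flank profiles for qualifying (site, position) pairs.

    A pair qualifies when the position lies within ``dist_range`` of the cut;
    each profile is flipped so the cut-proximal side is on the left. Pairs
    with a non-positive proximal mean are excluded (counted).
    """
    lo, hi = dist_range
    profiles: list[np.ndarray] = []
    n_excluded = 0
    for chrom, pos, _ in sites:
        track = tracks.get(chrom)
        if track is None:
            continue
        half = flank // track.bin_size
        for bchrom, bpos in positions:
            if bchrom != chrom:
                continue
            dist = abs(bpos - pos)
            if not lo <= dist < hi:
                continue
            c = (bpos - track.origin) // track.bin_size
            if c - half < 0 or c + half > track.n_bins:
                continue
            prof = track.values[c - half : c + half].astype(float)
            if bpos < pos:  # cut is to the right: flip so proximal side is left
                prof = prof[::-1]
            proximal = float(prof[:half].mean())
            if proximal <= 0:
                n_excluded += 1
                continue
            profiles.append(prof / proximal)
    return profiles, n_excluded


def _group_stats(drops: np.ndarray) -> tuple[float, float, float, float, bool]:
    if len(drops) < 2 or np.allclose(drops, drops[0] if len(drops) else 0.0):
        mean = float(drops.mean()) if len(drops) else float("nan")
        return mean, float("nan"), float("nan"), float("nan"), True
    t, p = stats.ttest_1samp(drops, 0.0)
    return (
        float(drops.mean()),
        float(stats.sem(drops)),
        float(t),
        float(p),
        False,
    )


def boundary_drop(
    tracks: "Mapping[str, EnrichmentTrack] | EnrichmentTrack",
    sites: CutSiteSet,
    boundaries: Sequence[tuple[str, int]],
    dist_range: tuple[int, int] = (200_000, 700_000),
    flank: int = 100_000,
    controls: Sequence[tuple[str, int]] | None = None,
) -> BoundaryDropResult:
    """Normalized enrichment drop across boundaries near cut sites.

    Uses (site, boundary) pairs whose separation falls in ``dist_range``
    (half-open). Each profile over boundary ± flank is oriented cut-proximal
    side left and normalized to its proximal mean; the drop is 1 − distal
    mean. The identical computation runs on ``controls`` (random positions)
    when given. One-sample t-tests compare each group against zero drop.
    """
    if dist_range[0] >= dist_range[1]:
        raise ValueError("dist_range lower bound must be below upper bound")
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(tracks, EnrichmentTrack):
        tracks = {tracks.chrom: tracks}
    profiles, n_excluded = _pair_profiles(tracks, sites, boundaries, dist_range, flank)
    if not profiles:
        raise ValueError("no qualifying (site, boundary) pairs")
    half = len(profiles[0]) // 2
    drops = np.array([1.0 - p[half:].mean() for p in profiles])
    mean_profile = np.mean(profiles, axis=0)
    b_mean, b_sem, b_t, b_p, b_degen = _group_stats(drops)

    if controls:
        cprofiles, c_excluded = _pair_profiles(
            tracks, sites, controls, dist_range, flank
        )
        n_excluded += c_excluded
        cdrops = np.array([1.0 - p[half:].mean() for p in cprofiles])
    else:
        cdrops = np.array([])
    c_mean, c_sem, c_t, c_p, c_degen = _group_stats(cdrops)

    return BoundaryDropResult(
        boundary_drops=drops,
        control_drops=cdrops,
        boundary_mean=b_mean,
        boundary_sem=b_sem,
        boundary_t=b_t,
        boundary_p=b_p,
        control_mean=c_mean,
        control_sem=c_sem,
        control_t=c_t,
        control_p=c_p,
        n_boundaries=len(drops),
        n_controls=len(cdrops),
        n_excluded=n_excluded,
        dist_range=tuple(dist_range),
        flank=flank,
        mean_profile=mean_profile,
        degenerate=b_degen or (len(cdrops) > 0 and c_degen),
    )


def sample_random_controls(
    sites: CutSiteSet,
    boundaries: Sequence[tuple[str, int]],
    dist_range: tuple[int, int],
    n: int,
    seed: int,
    genome: Sequence[tuple[str, int]],
    flank: int = 100_000,
    exclude_cross_boundary: bool = False,
) -> list[tuple[str, int]]:
    """Random control positions with boundary-matched cut distances.

    Distances are drawn by inverse-CDF sampling from the empirical
    distribution of qualifying (site, boundary) separations, so the control
    set is distance-matched to the boundary set. Positions within ``flank``
    of any true boundary, or outside chromosome bounds, are rejected and
    redrawn. ``exclude_cross_boundary`` additionally rejects positions
    separated from their cut site by a boundary, keeping controls inside
    the damaged TAD (useful when the signal model is boundary-truncated, so
    controls sit in smooth-signal territory where the normalized drop is
    interpretable). Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = dist_range
    dists = []
    for chrom, pos, _ in sites:
        for bchrom, bpos in boundaries:
            if bchrom == chrom and lo <= abs(bpos - pos) < hi:
                dists.append(abs(bpos - pos))
    if not dists:
        raise ValueError("no qualifying (site, boundary) pairs to match")
    dists = np.sort(np.asarray(dists, dtype=float))
    lengths = dict(genome)
    bnd_by_chrom: dict[str, np.ndarray] = {}
    for bchrom, bpos in boundaries:
        bnd_by_chrom.setdefault(bchrom, [])
        bnd_by_chrom[bchrom].append(bpos)
    bnd_by_chrom = {c: np.asarray(v) for c, v in bnd_by_chrom.items()}

    rng = np.random.default_rng(seed)
    site_list = [s for s in sites if s[0] in lengths]
    if not site_list:
        raise ValueError("no sites on the provided genome")
    out: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 1000 * n
    quantiles = np.linspace(0, 1, len(dists))
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place control positions (exclusion infeasible)")
        chrom, spos, _ = site_list[rng.integers(len(site_list))]
        # inverse-CDF draw from the empirical distance distribution
        d = float(np.interp(rng.uniform(), quantiles, dists))
        side = 1 if rng.uniform() < 0.5 else -1
        pos = int(round(spos + side * d))
        if not flank <= pos < lengths[chrom] - flank:
            continue
        bnd = bnd_by_chrom.get(chrom)
        if bnd is not None and bnd.size:
            if np.min(np.abs(bnd - pos)) < flank:
                continue
            lo_p, hi_p = min(spos, pos), max(spos, pos)
            if exclude_cross_boundary and np.any((bnd > lo_p) & (bnd < hi_p)):
                continue
        out.append((chrom, pos))
    return out


# ---------------------------------------------------------------------------
# distance-band differences between conditions
# ---------------------------------------------------------------------------


def band_difference(
    chip_a: tuple,
    chip_b: tuple,
    sites: CutSiteSet,
    bands: Sequence[tuple[float, float]] = ((-1.5e6, 0.5e6), (0.5e6, 1.5e6)),
    out_bin: int = 10_000,
) -> BandDifferenceResult:
    """Per-band enrichment difference between two conditions.

    ``chip_a`` and ``chip_b`` are (treated, untreated) coverage pairs for
    each condition. Per site and condition, the mean treated−untreated RPM
    within each signed band (half-open [lo, hi) on the bin-center offset
    from the cut) is computed; an unpaired two-sided t-test over sites
    compares the conditions per band. The reported difference is
    mean(B) − mean(A).
    """
    bands = [tuple(b) for b in bands]
    for i, (lo, hi) in enumerate(bands):
        if lo >= hi:
            raise ValueError("band bounds must satisfy lo < hi")
        for lo2, hi2 in bands[i + 1 :]:
            if lo < hi2 and lo2 < hi:
                raise ValueError("bands must be non-overlapping")
    per_cond: list[list[np.ndarray]] = []
    for treated, untreated in (chip_a, chip_b):
        tracks = enrichment_track(treated, untreated, out_bin)
        per_band_vals: list[list[float]] = [[] for _ in bands]
        for chrom, pos, _ in sites:
            track = tracks.get(chrom)
            if track is None:
                continue
            offsets = (
                (np.arange(track.n_bins) + 0.5) * track.bin_size + track.origin - pos
            )
            for k, (lo, hi) in enumerate(bands):
                sel = (offsets >= lo) & (offsets < hi)
                if sel.any():
                    per_band_vals[k].append(float(track.values[sel].mean()))
        per_cond.append([np.asarray(v) for v in per_band_vals])
    a_vals, b_vals = per_cond
    if any(len(v) < 2 for v in a_vals) or any(len(v) < 2 for v in b_vals):
        raise ValueError("need at least 2 sites per condition in every band")
    diffs, ts, ps = [], [], []
    for va, vb in zip(a_vals, b_vals):
        t, p = stats.ttest_ind(vb, va)
        diffs.append(float(vb.mean() - va.mean()))
        ts.append(float(t))
        ps.append(float(p))
    return BandDifferenceResult(
        bands=bands,
        per_site_a=a_vals,
        per_site_b=b_vals,
        difference=diffs,
        t_statistic=ts,
        p_value=ps,
        n_a=len(a_vals[0]),
        n_b=len(b_vals[0]),
    )
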