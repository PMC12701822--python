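"""Synthetic paired Hi-C and ChIP-seq data around programmed DSBs.

Generates treated/untreated contact maps and stranded ChIP coverage with the
statistical structure the break-centered analyses assume:

* contact maps with power-law distance decay, TAD blocks, boundary
  insulation, and — in the treated map — a cross-shaped break-anchored
  stripe (linearly decaying over ~1 Mb) plus attenuated contacts across the
  cut;
* ChIP coverage as Poisson background plus, in the treated sample, a narrow
  cut-site peak (kb scale, resection/filament) and a broad domain (hundreds
  of kb, homology search), with strand asymmetry of opposite polarity on the
  two sides of the cut inside a short resection span, and optional domain
  truncation at the first TAD boundary on each side.

All stochastic draws in one generator call flow from a single
``numpy.random.Generator`` seeded by ``SimulationParams.seed``. Every
parameter actually used is recorded in a :class:`SimulationTruth` that
round-trips losslessly through YAML, so the same truth file regenerates
bit-identical data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chip import StrandedCoverage
from .hic import ContactMap, CutSiteSet

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "make_sites",
    "simulate_contact_pair",
    "simulate_chip_pair",
    "expected_contact_matrix",
    "expected_chip_tracks",
]


# ---------------------------------------------------------------------------
# parameters and truth record
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Generator parameters; defaults mirror the observed break-domain scales.

    Contact model: expected count at bin separation ``s`` is
    ``A * ((s + s0)/s0) ** (-alpha)``, multiplied by ``m_tad`` within a TAD
    and by ``f_bnd`` per boundary crossed. Treated maps add a break-anchored
    stripe ``(1 + k_stripe * g(d))`` with ``g`` decaying linearly to zero at
    ``stripe_extent`` (~1 Mb, the observed span of DSB-chromatin contacts),
    and attenuate cut-spanning pairs by ``f_cut``.

    ChIP model: background ``b`` reads/bin (derived from ``depth`` when not
    given) plus per site a narrow Gaussian (sigma_n, total reads
    narrow_amplitude) and a broad Gaussian (sigma_b, total reads
    broad_amplitude). Defaults sigma_n=2.5 kb and sigma_b=250 kb put the
    component FWHMs (5.9 kb / 589 kb) at the scale of the measured RAD51
    narrow peak and broad domain. Within ±resection_span of the cut a
    fraction ``phi`` of narrow-component reads moves to the strand matching
    3'-resection polarity (forward excess telomeric/right of the cut,
    reverse excess centromeric/left).
    """

    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 60_000_000)])
    # contact model
    contact_bin_size: int = 25_000
    alpha: float = 1.0
    s0: float = 25_000.0
    base_intensity: float = 150.0
    tad_size: int = 1_000_000
    m_tad: float = 2.0
    f_bnd: float = 0.5
    k_stripe: float = 2.0
    stripe_extent: int = 1_000_000
    f_cut: float = 0.4
    # ChIP model
    chip_bin_size: int = 100
    depth: float = 5e6
    background_rate: float | None = None
    narrow_amplitude: float = 5_000.0
    sigma_n: float = 2_500.0
    broad_amplitude: float = 100_000.0
    sigma_b: float = 250_000.0
    resection_span: float = 1_000.0
    phi: float = 0.8
    truncate_at_boundaries: bool = False
    # the simulated region is 1/genome_scale of the genome the library was
    # sequenced from; the rest contributes background reads to library size
    genome_scale: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not self.sigma_n < self.sigma_b:
            raise ValueError("sigma_n must be smaller than sigma_b")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if not 0.0 < self.f_bnd <= 1.0 or not 0.0 < self.f_cut <= 1.0:
            raise ValueError("f_bnd and f_cut must lie in (0, 1]")
        if self.m_tad < 1.0:
            raise ValueError("m_tad must be >= 1")
        if self.k_stripe < 0:
            raise ValueError("k_stripe must be non-negative")
        if self.genome_scale < 1.0:
            raise ValueError("genome_scale must be >= 1")
        for attr in ("contact_bin_size", "chip_bin_size", "tad_size", "stripe_extent"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    # -- genome helpers -----------------------------------------------------

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.genome:
            if name == chrom:
                return length
        raise ValueError(f"chromosome {chrom!r} not in genome spec")

    def tad_edges(self, chrom: str) -> np.ndarray:
        """Interior TAD-segment edges (= boundary positions) on a chromosome."""
        length = self.chrom_length(chrom)
        return np.arange(self.tad_size, length, self.tad_size, dtype=int)

    def n_chip_bins(self, chrom: str) -> int:
        return -(-self.chrom_length(chrom) // self.chip_bin_size)

    def total_chip_bins(self) -> int:
        return sum(self.n_chip_bins(c) for c, _ in self.genome)

    def chip_background(self) -> float:
        """Background reads/bin; derived from depth when not set explicitly."""
        if self.background_rate is not None:
            return self.background_rate
        return self.depth / self.total_chip_bins()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = [[name, int(length)] for name, length in self.genome]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        d["genome"] = [(name, int(length)) for name, length in d["genome"]]
        return cls(**d)


@dataclass
class SimulationTruth:
    """Record of the parameters and realized coordinates behind a dataset."""

    params: SimulationParams
    sites: list[tuple[str, int, int]]
    boundaries: list[tuple[str, int]]
    seed: int
    background_rate: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "params": self.params.to_dict(),
            "sites": [[c, int(p), int(r)] for c, p, r in self.sites],
            "boundaries": [[c, int(p)] for c, p in self.boundaries],
            "seed": int(self.seed),
            "background_rate": self.background_rate,
            "warnings": list(self.warnings),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            params=SimulationParams.from_dict(doc["params"]),
            sites=[(c, int(p), int(r)) for c, p, r in doc["sites"]],
            boundaries=[(c, int(p)) for c, p in doc["boundaries"]],
            seed=int(doc["seed"]),
            background_rate=doc.get("background_rate"),
            warnings=list(doc.get("warnings", [])),
        )

    @property
    def cut_sites(self) -> CutSiteSet:
        return CutSiteSet(list(self.sites), provenance="synthetic")


# ---------------------------------------------------------------------------
# site and boundary placement
# ---------------------------------------------------------------------------


def make_sites(
    params: SimulationParams,
    n_sites: int,
    min_separation: int,
    edge_margin: int = 2_000_000,
) -> tuple[CutSiteSet, list[tuple[str, int]]]:
    """Place cut sites and derive TAD-boundary positions.

    Sites are deterministic given ``params.seed``, at least ``min_separation``
    apart, and at least ``edge_margin`` (one analysis half-window) from
    chromosome ends. Each site gets a synthetic cleavage rank (1 = best).
    Boundaries are the interior TAD-segment edges.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(params.seed)
    spans = []
    for chrom, length in params.genome:
        span = length - 2 * edge_margin
        spans.append((chrom, span if span > 0 else 0))
    total_span = sum(s for _, s in spans)
    if total_span <= 0:
        raise ValueError("genome too short for the requested edge margin")

    # allocate site counts proportionally to usable span (largest remainder)
    quotas = [n_sites * s / total_span for _, s in spans]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True
    )
    for i in remainders:
        if sum(counts) >= n_sites:
            break
        counts[i] += 1
    # feasibility: each chromosome must fit its quota at min_separation
    for (chrom, span), k in zip(spans, counts):
        if k > 0 and span < (k - 1) * min_separation:
            raise ValueError(
                f"cannot place {k} sites {min_separation} bp apart on {chrom}: "
                f"usable span {span} bp"
            )

    sites: list[tuple[str, int, int]] = []
    for (chrom, span), k in zip(spans, counts):
        if k == 0:
            continue
        # min-separation sampling: uniform points in the compressed span,
        # sorted, then re-expanded by i*min_separation
        free = span - (k - 1) * min_separation
        pts = np.sort(rng.uniform(0, free, size=k))
        pos = edge_margin + pts + np.arange(k) * min_separation
        for p in pos:
            sites.append((chrom, int(p), 0))
    ranks = rng.permutation(len(sites)) + 1
    sites = [(c, p, int(r)) for (c, p, _), r in zip(sites, ranks)]
    boundaries = [
        (chrom, int(edge))
        for chrom, _ in params.genome
        for edge in params.tad_edges(chrom)
    ]
    return CutSiteSet(sites, provenance="synthetic"), boundaries


# ---------------------------------------------------------------------------
# contact-map simulation
# ---------------------------------------------------------------------------


def _check_sites_in_genome(params: SimulationParams, sites: CutSiteSet) -> None:
    for chrom, pos, _ in sites:
        length = params.chrom_length(chrom)  # raises for unknown chromosome
        if not 0 <= pos < length:
            raise ValueError(f"cut site {chrom}:{pos} outside chromosome (len {length})")


def expected_contact_matrix(
    params: SimulationParams, sites: CutSiteSet, chrom: str, treated: bool
) -> np.ndarray:
    """Analytic expected contact matrix for one chromosome.

    This is the mean field the Poisson sampler draws from; exposed so
    downstream statistics can be checked against exact expectations.
    """
    length = params.chrom_length(chrom)
    bsz = params.contact_bin_size
    n = -(-length // bsz)
    centers = (np.arange(n) + 0.5) * bsz
    sep = np.abs(centers[:, None] - centers[None, :])
    e = params.base_intensity * ((sep + params.s0) / params.s0) ** (-params.alpha)
    # TAD blocks and boundary insulation
    tad_id = (centers // params.tad_size).astype(int)
    same_tad = tad_id[:, None] == tad_id[None, :]
    e = np.where(same_tad, e * params.m_tad, e)
    crossings = np.abs(tad_id[:, None] - tad_id[None, :])
    e *= params.f_bnd ** crossings
    if treated:
        idx = np.arange(n)
        for _, pos, _ in sites.on(chrom):
            c = pos // bsz
            if not 0 <= c < n:
                continue
            d = np.abs(idx - c) * bsz
            g = np.clip(1.0 - d / params.stripe_extent, 0.0, None)
            factor = 1.0 + params.k_stripe * g
            # cross-shaped stripe: one end at the cut bin
            e[c, :] *= factor
            e[:, c] *= factor
            e[c, c] /= factor[c]  # the diagonal bin was scaled twice
            # attenuation of cut-spanning pairs
            left = idx < c
            right = idx > c
            e[np.ix_(left, right)] *= params.f_cut
            e[np.ix_(right, left)] *= params.f_cut
    return e


def simulate_contact_pair(
    params: SimulationParams, sites: CutSiteSet
) -> tuple[dict[str, ContactMap], dict[str, ContactMap], SimulationTruth]:
    """Poisson-sampled treated/untreated contact maps for every chromosome.

    Counts are drawn independently per upper-triangle bin from the expected
    matrices of :func:`expected_contact_matrix` and symmetrized. A trailing
    partial bin (chromosome length not divisible by the bin size) is allowed
    and flagged in the map metadata.
    """
    _check_sites_in_genome(params, sites)
    rng = np.random.default_rng(params.seed)
    treated: dict[str, ContactMap] = {}
    untreated: dict[str, ContactMap] = {}
    for chrom, length in params.genome:
        partial = length % params.contact_bin_size != 0
        meta = {"partial_last_bin": str(partial)}
        for out, is_treated in ((untreated, False), (treated, True)):
            e = expected_contact_matrix(params, sites, chrom, treated=is_treated)
            n = e.shape[0]
            iu = np.triu_indices(n)
            counts = np.zeros_like(e)
            counts[iu] = rng.poisson(e[iu])
            counts = counts + np.triu(counts, 1).T
            out[chrom] = ContactMap(
                chrom=chrom,
                bin_size=params.contact_bin_size,
                matrix=counts,
                metadata=dict(meta),
            )
    boundaries = [
        (chrom, int(edge))
        for chrom, _ in params.genome
        for edge in params.tad_edges(chrom)
    ]
    truth = SimulationTruth(
        params=params, sites=list(sites.sites), boundaries=boundaries, seed=params.seed
    )
    return treated, untreated, truth


# ---------------------------------------------------------------------------
# ChIP simulation
# ---------------------------------------------------------------------------


def expected_chip_tracks(
    params: SimulationParams,
    sites: CutSiteSet,
    chrom: str,
    boundaries: list[tuple[str, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Analytic expected reads/bin per strand for treated and untreated.

    Returns ``{"treated_fwd", "treated_rev", "untreated_fwd",
    "untreated_rev"}``. The broad component is zeroed beyond the first TAD
    boundary on each side of the cut when ``truncate_at_boundaries`` is set.
    """
    bsz = params.chip_bin_size
    n = params.n_chip_bins(chrom)
    centers = (np.arange(n) + 0.5) * bsz
    b = params.chip_background()
    t_fwd = np.full(n, b / 2.0)
    t_rev = np.full(n, b / 2.0)
    bnd = (
        sorted(p for c, p in boundaries if c == chrom)
        if boundaries is not None
        else list(params.tad_edges(chrom))
    )
    for _, pos, _ in sites.on(chrom):
        d = centers - pos
        # narrow component: total reads narrow_amplitude, Gaussian density
        lam_n = (
            params.narrow_amplitude
            * bsz
            / (params.sigma_n * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * (d / params.sigma_n) ** 2)
        )
        lam_b = (
            params.broad_amplitude
            * bsz
            / (params.sigma_b * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * (d / params.sigma_b) ** 2)
        )
        if params.truncate_at_boundaries and bnd:
            arr = np.asarray(bnd)
            left = arr[arr < pos]
            right = arr[arr > pos]
            lo = left.max() if left.size else -np.inf
            hi = right.min() if right.size else np.inf
            lam_b = np.where((centers > lo) & (centers < hi), lam_b, 0.0)
        # strand split: broad is symmetric; narrow is polarized inside the
        # resection span — forward excess on the right (telomeric) side,
        # reverse excess on the left (centromeric) side
        w_fwd = np.full(n, 0.5)
        inside = np.abs(d) <= params.resection_span
        w_fwd[inside & (d > 0)] = (1.0 + params.phi) / 2.0
        w_fwd[inside & (d < 0)] = (1.0 - params.phi) / 2.0
        t_fwd += lam_b / 2.0 + lam_n * w_fwd
        t_rev += lam_b / 2.0 + lam_n * (1.0 - w_fwd)
    u = np.full(n, b / 2.0)
    return {
        "treated_fwd": t_fwd,
        "treated_rev": t_rev,
        "untreated_fwd": u,
        "untreated_rev": u.copy(),
    }


def simulate_chip_pair(
    params: SimulationParams,
    sites: CutSiteSet,
    boundaries: list[tuple[str, int]] | None = None,
) -> tuple[
    dict[str, StrandedCoverage], dict[str, StrandedCoverage], SimulationTruth
]:
    """Poisson-sampled stranded ChIP coverage, treated and untreated.

    Library sizes are the realized genome-wide read totals of each sample.
    Cut sites closer than 2*sigma_b trigger a warning recorded in the truth
    (their signals superpose).
    """
    _check_sites_in_genome(params, sites)
    rng = np.random.default_rng(params.seed)
    warnings: list[str] = []
    for chrom, _ in params.genome:
        pos = np.sort(sites.positions(chrom))
        if pos.size > 1 and np.any(np.diff(pos) < 2 * params.sigma_b):
            warnings.append(
                f"cut sites on {chrom} closer than 2*sigma_b: broad domains superpose"
            )
    raw: dict[str, dict[str, np.ndarray]] = {}
    for chrom, _ in params.genome:
        exp = expected_chip_tracks(params, sites, chrom, boundaries)
        raw[chrom] = {key: rng.poisson(lam).astype(float) for key, lam in exp.items()}
    # library = reads realized here + background of the unsimulated genome
    rest = (params.genome_scale - 1.0) * params.chip_background() * params.total_chip_bins()
    lib_treated = rest + sum(
        r["treated_fwd"].sum() + r["treated_rev"].sum() for r in raw.values()
    )
    lib_untreated = rest + sum(
        r["untreated_fwd"].sum() + r["untreated_rev"].sum() for r in raw.values()
    )
    treated = {
        chrom: StrandedCoverage(
            chrom=chrom,
            bin_size=params.chip_bin_size,
            forward=r["treated_fwd"],
            reverse=r["treated_rev"],
            library_size=float(lib_treated),
            sample="treated",
        )
        for chrom, r in raw.items()
    }
    untreated = {
        chrom: StrandedCoverage(
            chrom=chrom,
            bin_size=params.chip_bin_size,
            forward=r["untreated_fwd"],
            reverse=r["untreated_rev"],
            library_size=float(lib_untreated),
            sample="untreated",
        )
        for chrom, r in raw.items()
    }
    bnd = boundaries if boundaries is not None else [
        (chrom, int(edge))
        for chrom, _ in params.genome
        for edge in params.tad_edges(chrom)
    ]
    truth = SimulationTruth(
        params=params,
        sites=list(sites.sites),
        boundaries=list(bnd),
        seed=params.seed,
        background_rate=params.chip_background(),
        warnings=warnings,
    )
    return treated, untreated, truth
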