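"""Site-centered Hi-C aggregation.

Containers and operations for binned chromatin contact matrices: reading and
writing dense per-chromosome maps, extracting square windows centered on
programmed double-strand-break (DSB) positions, averaging log2-ratio
differential maps across sites, and computing (differential) virtual-4C
profiles from break-adjacent viewpoints.

Coordinates are 0-based half-open throughout; a cut site is a single bp
position assigned to the bin containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "ContactMap",
    "CutSiteSet",
    "WindowStack",
    "AggregateMap",
    "Virtual4CProfile",
    "read_contact_map",
    "write_contact_map",
    "read_contact_container",
    "write_contact_container",
    "extract_windows",
    "stack_windows",
    "differential_map",
    "aggregate_mean",
    "virtual_4c",
    "site_virtual_4c",
    "differential_4c",
]

_SYMMETRY_RTOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Symmetric binned contact matrix for one chromosome.

    NaN entries mark masked bins. ``normalization`` is a pass-through tag
    (``"raw"`` or ``"balanced"``); all operations work on whatever scale the
    container provides and propagate the tag.
    """

    chrom: str
    bin_size: int
    matrix: np.ndarray
    origin: int = 0
    normalization: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        if self.origin % self.bin_size != 0:
            raise ValueError("origin must be a multiple of the bin size")
        finite = np.isfinite(self.matrix)
        sym_ok = finite & finite.T
        a = self.matrix[sym_ok]
        b = self.matrix.T[sym_ok]
        if a.size and not np.allclose(a, b, rtol=_SYMMETRY_RTOL, atol=1e-9):
            raise ValueError(
                f"contact matrix for {self.chrom} is asymmetric beyond tolerance"
            )

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, position: int) -> int:
        """Bin index containing a bp position."""
        return (position - self.origin) // self.bin_size

    def total(self) -> float:
        return float(np.nansum(self.matrix))


@dataclass
class CutSiteSet:
    """Programmed DSB positions with cleavage-strength ranks.

    ``sites`` is a list of ``(chromosome, position_bp, rank)``; rank 1 marks
    the most efficiently cleaved site. Ranks must be unique.
    """

    sites: list[tuple[str, int, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        ranks = [r for _, _, r in self.sites]
        if len(set(ranks)) != len(ranks):
            raise ValueError("cleavage ranks must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def on(self, chrom: str) -> "CutSiteSet":
        return CutSiteSet(
            [s for s in self.sites if s[0] == chrom], provenance=self.provenance
        )

    def positions(self, chrom: str | None = None) -> np.ndarray:
        return np.array(
            [p for c, p, _ in self.sites if chrom is None or c == chrom], dtype=int
        )

    def top(self, n: int) -> "CutSiteSet":
        """The n best-cleaved sites (lowest rank)."""
        best = sorted(self.sites, key=lambda s: s[2])[:n]
        return CutSiteSet(best, provenance=self.provenance)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, pos, rank in self.sites:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsite\t{rank}\t.\n")

    @classmethod
    def from_bed(cls, path: str | Path, provenance: str = "") -> "CutSiteSet":
        sites = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                sites.append((f[0], int(f[1]), int(float(f[4])) if len(f) > 4 else 0))
        return cls(sites, provenance=provenance)


@dataclass
class WindowStack:
    """Per-site square contact submatrices aligned on the cut bin."""

    windows: np.ndarray  # (n_sites, w, w)
    half_width: int
    bin_size: int
    site_ids: list[tuple[str, int, int]]
    valid: np.ndarray  # (n_sites,) bool

    def __post_init__(self) -> None:
        w = self.windows.shape[1]
        if w % 2 != 1 or self.windows.shape[2] != w:
            raise ValueError("windows must be square with odd side length")
        if len(self.site_ids) != self.windows.shape[0]:
            raise ValueError("site ids do not match window count")

    @property
    def center(self) -> int:
        return self.windows.shape[1] // 2

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def total(self) -> float:
        return float(np.nansum(self.windows[self.valid]))

    @staticmethod
    def concat(stacks: Sequence["WindowStack"]) -> "WindowStack":
        first = stacks[0]
        for s in stacks[1:]:
            if s.windows.shape[1:] != first.windows.shape[1:]:
                raise ValueError("cannot concatenate stacks of different shape")
            if s.bin_size != first.bin_size:
                raise ValueError("cannot concatenate stacks of different bin size")
        return WindowStack(
            windows=np.concatenate([s.windows for s in stacks]),
            half_width=first.half_width,
            bin_size=first.bin_size,
            site_ids=[i for s in stacks for i in s.site_ids],
            valid=np.concatenate([s.valid for s in stacks]),
        )


@dataclass
class AggregateMap:
    """Site-averaged aggregate of a window stack (log2 ratio or mean)."""

    matrix: np.ndarray
    n_sites: int
    epsilon: float
    operation: str  # "log2ratio" | "mean"

    @property
    def center(self) -> int:
        return self.matrix.shape[0] // 2

    def cross_mean(self) -> float:
        """Mean over the cross through the center (row+column, center excluded)."""
        c = self.center
        vals = np.concatenate([self.matrix[c, :], self.matrix[:, c]])
        vals = np.delete(vals, [c, self.matrix.shape[0] + c])
        return float(np.nanmean(vals))

    def off_cross_mean(self) -> float:
        """Mean over all bins excluding the center row and column."""
        c = self.center
        m = np.delete(np.delete(self.matrix, c, axis=0), c, axis=1)
        return float(np.nanmean(m))


@dataclass
class Virtual4CProfile:
    """One-locus-vs-all contact profile at a viewpoint."""

    viewpoint: tuple[str, int, int]  # chrom, start, end
    distance: np.ndarray  # signed bp, strictly increasing
    values: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        if len(self.distance) != len(self.values):
            raise ValueError("axis and values must have equal length")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance axis must be strictly increasing")


# ---------------------------------------------------------------------------
# dense-TSV and container IO
# ---------------------------------------------------------------------------


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """Write a contact map as dense TSV with ``#``-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={cmap.chrom}\n")
        fh.write(f"# bin_size={cmap.bin_size}\n")
        fh.write(f"# origin={cmap.origin}\n")
        fh.write(f"# normalization={cmap.normalization}\n")
        for key, val in sorted(cmap.metadata.items()):
            fh.write(f"# meta:{key}={val}\n")
        np.savetxt(fh, cmap.matrix, fmt="%.10g", delimiter="\t")


def read_contact_map(
    path: str | Path,
    chromosome: str | None = None,
    bin_size: int | None = None,
) -> ContactMap:
    """Read a dense-TSV contact map, checking symmetry and requested metadata.

    NaN entries (masked bins) are preserved; the symmetry check ignores them.
    """
    path = Path(path)
    header: dict[str, str] = {}
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key.startswith("meta:"):
                meta[key[5:]] = val
            else:
                header[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    chrom = header.get("chrom", "unknown")
    if chromosome is not None and chrom != chromosome:
        raise ValueError(f"chromosome {chromosome!r} not found in {path} (has {chrom!r})")
    bsz = int(header.get("bin_size", 0)) or (bin_size or 1)
    if bin_size is not None and bsz != bin_size:
        raise ValueError(f"requested bin size {bin_size}, file has {bsz}")
    return ContactMap(
        chrom=chrom,
        bin_size=bsz,
        matrix=matrix,
        origin=int(header.get("origin", 0)),
        normalization=header.get("normalization", "raw"),
        metadata=meta,
    )


def write_contact_container(
    maps: Mapping[str, ContactMap], path: str | Path
) -> None:
    """Write maps into a single-resolution HDF5 container.

    Layout mimics a pixel-table contact store: per chromosome, the non-zero
    upper-triangle pixels as (bin1_id, bin2_id, count) plus a mask of NaN
    bins. One resolution per file.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "dsbchrom-contacts-v1"
        for chrom, cmap in maps.items():
            g = f.create_group(chrom)
            g.attrs["bin_size"] = cmap.bin_size
            g.attrs["origin"] = cmap.origin
            g.attrs["n_bins"] = cmap.n_bins
            g.attrs["normalization"] = cmap.normalization
            m = cmap.matrix
            masked = ~np.isfinite(m).all(axis=0)
            iu = np.triu_indices(cmap.n_bins)
            counts = m[iu]
            keep = np.isfinite(counts) & (counts != 0)
            g.create_dataset("bin1_id", data=iu[0][keep].astype(np.int64))
            g.create_dataset("bin2_id", data=iu[1][keep].astype(np.int64))
            g.create_dataset("count", data=counts[keep])
            g.create_dataset("mask", data=np.flatnonzero(masked).astype(np.int64))


def read_contact_container(
    path: str | Path, chromosome: str | None = None
) -> dict[str, ContactMap]:
    """Read contact maps back from the HDF5 container."""
    out: dict[str, ContactMap] = {}
    with h5py.File(path, "r") as f:
        chroms = [chromosome] if chromosome is not None else list(f.keys())
        for chrom in chroms:
            if chrom not in f:
                raise ValueError(f"chromosome {chrom!r} not in container {path}")
            g = f[chrom]
            n = int(g.attrs["n_bins"])
            m = np.zeros((n, n))
            i = g["bin1_id"][:]
            j = g["bin2_id"][:]
            c = g["count"][:]
            m[i, j] = c
            m[j, i] = c
            masked = g["mask"][:]
            m[masked, :] = np.nan
            m[:, masked] = np.nan
            out[chrom] = ContactMap(
                chrom=chrom,
                bin_size=int(g.attrs["bin_size"]),
                matrix=m,
                origin=int(g.attrs["origin"]),
                normalization=str(g.attrs["normalization"]),
            )
    return out


# ---------------------------------------------------------------------------
# window extraction and aggregation
# ---------------------------------------------------------------------------


def extract_windows(
    cmap: ContactMap, sites: CutSiteSet, half_width: int, require_valid: bool = True
) -> WindowStack:
    """Square submatrices centered on the cut bin of each site.

    ``half_width`` must be a multiple of the bin size. Sites whose window
    exceeds chromosome bounds are kept in the stack but marked invalid
    (their windows are NaN-filled) and excluded from downstream averages.
    """
    if half_width % cmap.bin_size != 0:
        raise ValueError("half_width must be a multiple of the bin size")
    r = half_width // cmap.bin_size
    w = 2 * r + 1
    chrom_sites = sites.on(cmap.chrom)
    if len(chrom_sites) == 0:
        raise ValueError(f"no sites on chromosome {cmap.chrom}")
    n = cmap.n_bins
    windows = np.full((len(chrom_sites), w, w), np.nan)
    valid = np.zeros(len(chrom_sites), dtype=bool)
    for k, (_, pos, _) in enumerate(chrom_sites):
        c = cmap.bin_of(pos)
        if c - r >= 0 and c + r < n:
            windows[k] = cmap.matrix[c - r : c + r + 1, c - r : c + r + 1]
            valid[k] = True
    if require_valid and not valid.any():
        raise ValueError("no valid site windows within chromosome bounds")
    return WindowStack(
        windows=windows,
        half_width=half_width,
        bin_size=cmap.bin_size,
        site_ids=list(chrom_sites),
        valid=valid,
    )


def stack_windows(
    maps: Mapping[str, ContactMap], sites: CutSiteSet, half_width: int
) -> WindowStack:
    """Extract and concatenate windows over several chromosomes."""
    stacks = []
    for chrom, cmap in maps.items():
        if len(sites.on(chrom)) == 0:
            continue
        stacks.append(extract_windows(cmap, sites, half_width, require_valid=False))
    if not stacks:
        raise ValueError("no sites on any provided chromosome")
    combined = WindowStack.concat(stacks)
    if combined.n_valid == 0:
        raise ValueError("no valid site windows within chromosome bounds")
    return combined


def differential_map(
    treated: WindowStack, untreated: WindowStack, epsilon: float = 1.0
) -> AggregateMap:
    """Site-averaged log2 ratio of treated over untreated windows.

    Per site, elementwise log2((T+eps)/(U+eps)); the average across sites is
    NaN-aware and restricted to sites valid in both stacks.
    """
    if treated.windows.shape != untreated.windows.shape:
        raise ValueError("window stacks differ in shape")
    if treated.site_ids != untreated.site_ids:
        raise ValueError("window stacks are not aligned on the same sites")
    valid = treated.valid & untreated.valid
    if not valid.any():
        raise ValueError("no site valid in both stacks")
    t = treated.windows[valid]
    u = untreated.windows[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        # log difference (not log-of-ratio) keeps swap-antisymmetry exact
        ratio = np.log2(t + epsilon) - np.log2(u + epsilon)
    agg = np.nanmean(ratio, axis=0)
    return AggregateMap(
        matrix=agg, n_sites=int(valid.sum()), epsilon=epsilon, operation="log2ratio"
    )


def aggregate_mean(stack: WindowStack) -> AggregateMap:
    """NaN-aware mean of valid windows (no ratio)."""
    if stack.n_valid == 0:
        raise ValueError("no valid windows to aggregate")
    agg = np.nanmean(stack.windows[stack.valid], axis=0)
    return AggregateMap(matrix=agg, n_sites=stack.n_valid, epsilon=0.0, operation="mean")


# ---------------------------------------------------------------------------
# virtual 4C
# ---------------------------------------------------------------------------


def virtual_4c(
    cmap: ContactMap,
    viewpoint: tuple[int, int],
    flank: int,
    normalize: str = "none",
) -> Virtual4CProfile:
    """Contact profile of a viewpoint against its ±flank neighbourhood.

    Sums matrix rows over the bins overlapping the viewpoint interval; the
    axis is the signed distance of each bin center from the viewpoint center.
    ``normalize``: ``"none"`` or ``"per_million"`` (scale by 1e6 / map total).
    """
    if flank % cmap.bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    start, end = viewpoint
    b0 = (start - cmap.origin) // cmap.bin_size
    b1 = (end - 1 - cmap.origin) // cmap.bin_size
    if b0 < 0 or b1 >= cmap.n_bins:
        raise ValueError("viewpoint outside contact map")
    rows = cmap.matrix[b0 : b1 + 1]
    if not np.isfinite(rows).any():
        raise ValueError("viewpoint is fully masked")
    profile = np.nansum(rows, axis=0)
    r = flank // cmap.bin_size
    vc = (b0 + b1) // 2  # center bin of the viewpoint
    lo = max(vc - r, 0)
    hi = min(vc + r, cmap.n_bins - 1)
    vals = np.full(2 * r + 1, np.nan)
    vals[lo - (vc - r) : hi - (vc - r) + 1] = profile[lo : hi + 1]
    dist = (np.arange(vc - r, vc + r + 1) - vc) * cmap.bin_size
    if normalize == "per_million":
        total = cmap.total()
        if total <= 0:
            raise ValueError("cannot per-million normalize an empty map")
        vals = vals * (1e6 / total)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    vp = (cmap.chrom, start, end)
    return Virtual4CProfile(viewpoint=vp, distance=dist, values=vals, normalization=normalize)


def site_virtual_4c(
    cmap: ContactMap, position: int, flank: int, normalize: str = "none"
) -> Virtual4CProfile:
    """Break-centered 4C-like profile from the two bins flanking the cut bin.

    Uses the bins immediately left and right of the cut bin as viewpoints and
    averages the right profile with the mirrored left profile, so positive
    distances point away from the break on both sides.
    """
    b = cmap.bin_of(position)
    left = virtual_4c(
        cmap,
        (cmap.origin + (b - 1) * cmap.bin_size, cmap.origin + b * cmap.bin_size),
        flank,
        normalize,
    )
    right = virtual_4c(
        cmap,
        (cmap.origin + (b + 1) * cmap.bin_size, cmap.origin + (b + 2) * cmap.bin_size),
        flank,
        normalize,
    )
    vals = np.nanmean(np.stack([left.values[::-1], right.values]), axis=0)
    return Virtual4CProfile(
        viewpoint=(cmap.chrom, position, position + 1),
        distance=right.distance,
        values=vals,
        normalization=normalize,
    )


def differential_4c(
    treated_profiles: Iterable[Virtual4CProfile],
    untreated_profiles: Iterable[Virtual4CProfile],
    mode: str = "difference",
    epsilon: float = 1.0,
) -> Virtual4CProfile:
    """Site-averaged treated-minus-untreated (or log2 ratio) 4C profile."""
    treated = list(treated_profiles)
    untreated = list(untreated_profiles)
    if not treated or len(treated) != len(untreated):
        raise ValueError("need matched non-empty profile lists")
    axis = treated[0].distance
    for p in treated + untreated:
        if len(p.distance) != len(axis) or np.any(p.distance != axis):
            raise ValueError("profile axes do not match")
    t = np.nanmean(np.stack([p.values for p in treated]), axis=0)
    u = np.nanmean(np.stack([p.values for p in untreated]), axis=0)
    if mode == "difference":
        vals = t - u
    elif mode == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2((t + epsilon) / (u + epsilon))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Virtual4CProfile(
        viewpoint=treated[0].viewpoint,
        distance=axis,
        values=vals,
        normalization=f"{mode}:{treated[0].normalization}",
    )
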