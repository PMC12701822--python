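"""Config-driven orchestration: simulate → aggregate → report.

A :class:`PipelineConfig` (YAML) selects stages and parameters; the
pipeline executes them in dependency order, writes standard-format outputs
(BED6 sites/boundaries, bedGraph coverage, dense-TSV contact maps, TSV
tables with ``#`` metadata headers, YAML truth) into the output directory,
and produces a machine-readable JSON report. Runs are idempotent: the same
config and seed yield byte-identical report bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import boundaries as bnd_mod
from . import chip as chip_mod
from . import hic as hic_mod
from . import insulation as ins_mod
from . import synthetic as syn_mod

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("dsbchrom")

_STAGES = ("simulate", "hic", "insulation", "chip", "boundary", "bands")

_SIMULATION_KEYS = {
    "n_sites", "min_separation", "edge_margin",
    "contact_bin_size", "alpha", "s0", "base_intensity", "tad_size",
    "m_tad", "f_bnd", "k_stripe", "stripe_extent", "f_cut",
    "chip_bin_size", "depth", "background_rate",
    "narrow_amplitude", "sigma_n", "broad_amplitude", "sigma_b",
    "resection_span", "phi", "truncate_at_boundaries",
    "condition_b",
}
_CONDITION_B_KEYS = {"sigma_b_factor", "seed_offset"}
_ANALYSIS_KEYS = {
    "half_width", "epsilon", "square_size", "delta_window",
    "enrichment_window", "fine_half_width", "fine_bin",
    "coarse_half_width", "coarse_bin", "asym_half_width", "asym_bin",
    "asym_threshold", "boundary_dist_range", "boundary_flank",
    "boundary_bin", "n_controls", "bands", "band_bin",
}
_INPUT_KEYS = {
    "contact_treated", "contact_untreated", "sites", "boundaries",
}
_TOP_KEYS = {
    "seed", "genome", "stages", "simulation", "analysis", "inputs",
    "outdir", "write_matrices",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Unknown keys anywhere in the document are rejected before any
    computation runs.
    """

    seed: int = 0
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 60_000_000), ("chr2", 60_000_000)]
    )
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outdir: str = "dsbchrom_out"
    write_matrices: bool = False

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in _STAGES:
                raise ValueError(f"unknown stage {stage!r}; known: {_STAGES}")
        _reject_unknown(self.simulation, _SIMULATION_KEYS, "simulation")
        _reject_unknown(
            self.simulation.get("condition_b", {}) or {},
            _CONDITION_B_KEYS,
            "simulation.condition_b",
        )
        _reject_unknown(self.analysis, _ANALYSIS_KEYS, "analysis")
        _reject_unknown(self.inputs, _INPUT_KEYS, "inputs")
        self.genome = [(str(c), int(l)) for c, l in self.genome]

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        _reject_unknown(doc, _TOP_KEYS, "config")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = [[c, l] for c, l in self.genome]
        return d

    def sim_params(self, seed: int | None = None) -> syn_mod.SimulationParams:
        kwargs = {
            k: v
            for k, v in self.simulation.items()
            if k not in ("n_sites", "min_separation", "edge_margin", "condition_b")
        }
        return syn_mod.SimulationParams(
            genome=list(self.genome),
            seed=self.seed if seed is None else seed,
            **kwargs,
        )

    def ana(self, key: str, default):
        return self.analysis.get(key, default)


def _reject_unknown(doc: dict, allowed: set[str], where: str) -> None:
    if not isinstance(doc, dict):
        raise ValueError(f"{where} must be a mapping")
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    stages: dict
    provenance: dict
    warnings: list[str]

    def to_json(self) -> str:
        doc = {
            "stages": self.stages,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }
        return json.dumps(doc, indent=2, sort_keys=True, default=_jsonable)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round(x: float, digits: int = 10) -> float:
    """Stabilize report floats against platform printf jitter."""
    if x is None or not np.isfinite(x):
        return None if x is None else float(x)
    return float(round(float(x), digits))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the configured stages and write outputs plus a JSON report.

    Stage order follows dependencies: simulation (or input loading) first,
    then Hi-C aggregation, insulation, ChIP profiling, boundary and band
    statistics. A stage failure aborts with the stage name; outputs of
    completed stages are preserved.
    """
    out = Path(outdir) if outdir is not None else Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report_stages: dict = {}
    warnings: list[str] = []
    data: dict = {}

    stage_order = [s for s in _STAGES if s in config.stages]
    for stage in stage_order:
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out, data, report_stages, warnings)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    for stage in _STAGES:
        if stage not in stage_order:
            report_stages[stage] = {"status": "skipped"}

    cfg_text = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "dsbchrom_version": "0.1.0",
    }
    report = RunReport(stages=report_stages, provenance=provenance, warnings=warnings)
    report.write(out / "report.json")
    return report


def _needs_chip(config: PipelineConfig) -> bool:
    return bool({"chip", "boundary", "bands", "insulation"} & set(config.stages))


def _needs_contacts(config: PipelineConfig) -> bool:
    return bool({"hic", "insulation"} & set(config.stages))


def _stage_simulate(config, out, data, report, warnings):
    sim = config.simulation
    params = config.sim_params()
    sites, boundaries = syn_mod.make_sites(
        params,
        n_sites=int(sim.get("n_sites", 30)),
        min_separation=int(sim.get("min_separation", 3_000_000)),
        edge_margin=int(sim.get("edge_margin", 2_000_000)),
    )
    data["params"] = params
    data["sites"] = sites
    data["boundaries"] = boundaries
    sites.to_bed(out / "sites.bed")
    with open(out / "boundaries.bed", "w") as fh:
        for chrom, pos in boundaries:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tboundary\t0\t.\n")
    stage_info = {"n_sites": len(sites), "n_boundaries": len(boundaries)}
    if _needs_contacts(config):
        treated, untreated, truth = syn_mod.simulate_contact_pair(params, sites)
        data["contact_treated"] = treated
        data["contact_untreated"] = untreated
        truth.to_yaml(out / "truth_contacts.yaml")
        warnings.extend(truth.warnings)
        if config.write_matrices:
            for tag, maps in (("treated", treated), ("untreated", untreated)):
                for chrom, cmap in maps.items():
                    hic_mod.write_contact_map(cmap, out / f"contacts_{tag}_{chrom}.tsv")
        stage_info["contact_total_treated"] = _round(
            sum(m.total() for m in treated.values())
        )
        stage_info["contact_total_untreated"] = _round(
            sum(m.total() for m in untreated.values())
        )
    if _needs_chip(config):
        ctreated, cuntreated, ctruth = syn_mod.simulate_chip_pair(
            params, sites, boundaries
        )
        data["chip_treated"] = ctreated
        data["chip_untreated"] = cuntreated
        ctruth.to_yaml(out / "truth_chip.yaml")
        warnings.extend(ctruth.warnings)
        for tag, covs in (("treated", ctreated), ("untreated", cuntreated)):
            for chrom, cov in covs.items():
                chip_mod.write_bedgraph_pair(cov, out / f"chip_{tag}_{chrom}")
        lib = next(iter(ctreated.values())).library_size
        stage_info["chip_library_treated"] = _round(lib)
        stage_info["chip_library_untreated"] = _round(
            next(iter(cuntreated.values())).library_size
        )
    report["simulate"] = stage_info


def _load_inputs(config, data):
    """Load contact maps / site lists from configured paths when absent."""
    inp = config.inputs
    if "sites" not in data and "sites" in inp:
        data["sites"] = hic_mod.CutSiteSet.from_bed(inp["sites"], provenance="file")
    if "boundaries" not in data and "boundaries" in inp:
        bl = []
        with open(inp["boundaries"]) as fh:
            for line in fh:
                if line.strip() and not line.startswith(("#", "track")):
                    f = line.split("\t")
                    bl.append((f[0], (int(f[1]) + int(f[2])) // 2))
        data["boundaries"] = bl
    for key in ("contact_treated", "contact_untreated"):
        if key not in data and key in inp:
            paths = inp[key]
            if isinstance(paths, str):
                paths = [paths]
            maps = {}
            for p in paths:
                cmap = hic_mod.read_contact_map(p)
                maps[cmap.chrom] = cmap
            data[key] = maps


def _stage_hic(config, out, data, report, warnings):
    _load_inputs(config, data)
    if "contact_treated" not in data:
        raise ValueError("hic stage requires contact maps (simulate or inputs)")
    sites = data["sites"]
    half_width = int(config.ana("half_width", 1_500_000))
    epsilon = float(config.ana("epsilon", 1.0))
    t_stack = hic_mod.stack_windows(data["contact_treated"], sites, half_width)
    u_stack = hic_mod.stack_windows(data["contact_untreated"], sites, half_width)
    agg = hic_mod.differential_map(t_stack, u_stack, epsilon)
    np.savetxt(out / "aggregate_log2ratio.tsv", agg.matrix, delimiter="\t", fmt="%.10g")
    # differential break-centered 4C
    tprof, uprof = [], []
    for chrom, cmap in data["contact_treated"].items():
        ucmap = data["contact_untreated"][chrom]
        for _, pos, _ in sites.on(chrom):
            b = cmap.bin_of(pos)
            r = half_width // cmap.bin_size
            if b - r - 1 < 0 or b + r + 1 >= cmap.n_bins:
                continue
            tprof.append(hic_mod.site_virtual_4c(cmap, pos, half_width))
            uprof.append(hic_mod.site_virtual_4c(ucmap, pos, half_width))
    d4c = hic_mod.differential_4c(tprof, uprof) if tprof else None
    if d4c is not None:
        with open(out / "differential_4c.tsv", "w") as fh:
            fh.write(f"# n_sites={len(tprof)}\n")
            fh.write("distance\tvalue\n")
            for dd, vv in zip(d4c.distance, d4c.values):
                fh.write(f"{dd:.10g}\t{vv:.10g}\n")
    report["hic"] = {
        "n_sites": agg.n_sites,
        "epsilon": epsilon,
        "cross_mean_log2ratio": _round(agg.cross_mean()),
        "off_cross_mean_log2ratio": _round(agg.off_cross_mean()),
        "center_log2ratio": _round(float(agg.matrix[agg.center, agg.center])),
    }


def _stage_insulation(config, out, data, report, warnings):
    _load_inputs(config, data)
    if "contact_treated" not in data:
        raise ValueError("insulation stage requires contact maps")
    square = int(config.ana("square_size", 500_000))
    window = int(config.ana("delta_window", 50_000))
    t_tracks = {
        c: ins_mod.insulation_score(m, square)
        for c, m in data["contact_treated"].items()
    }
    u_tracks = {
        c: ins_mod.insulation_score(m, square)
        for c, m in data["contact_untreated"].items()
    }
    res = ins_mod.delta_insulation(t_tracks, u_tracks, data["sites"], window)
    with open(out / "delta_insulation.tsv", "w") as fh:
        fh.write(f"# square_size={square}\n# window={window}\n")
        fh.write("chrom\tposition\trank\tdelta_is\n")
        for (chrom, pos, rank), dv in zip(res.site_ids, res.delta):
            fh.write(f"{chrom}\t{pos}\t{rank}\t{dv:.10g}\n")
    info = {
        "n_sites": res.n,
        "mean_delta_is": _round(res.mean),
        "sem_delta_is": _round(res.sem),
        "t_statistic": _round(res.t_statistic),
        "p_value": _round(res.p_value),
        "fraction_sites_decreased": _round(res.fraction_negative),
        "degenerate": res.degenerate,
    }
    if "chip_treated" in data:
        enr_window = int(config.ana("enrichment_window", 20_000))
        enr = chip_mod.site_enrichment(
            data["chip_treated"], data["chip_untreated"],
            hic_mod.CutSiteSet(res.site_ids), enr_window,
        )
        corr = ins_mod.correlate_enrichment(res.drop, enr)
        info["spearman_rho_drop_vs_enrichment"] = _round(corr.rho)
        info["spearman_p"] = _round(corr.p_value)
    report["insulation"] = info


def _stage_chip(config, out, data, report, warnings):
    if "chip_treated" not in data:
        raise ValueError("chip stage requires ChIP coverage (simulate or inputs)")
    sites = data["sites"]
    fine = chip_mod.meta_profile(
        data["chip_treated"], data["chip_untreated"], sites,
        int(config.ana("fine_half_width", 15_000)),
        int(config.ana("fine_bin", 100)),
    )
    coarse = chip_mod.meta_profile(
        data["chip_treated"], data["chip_untreated"], sites,
        int(config.ana("coarse_half_width", 1_500_000)),
        int(config.ana("coarse_bin", 10_000)),
    )
    chip_mod.write_profile_tsv(fine, out / "meta_profile_fine.tsv")
    chip_mod.write_profile_tsv(coarse, out / "meta_profile_coarse.tsv")
    fit = chip_mod.fit_two_component(fine, coarse)
    asym = chip_mod.strand_asymmetry(
        data["chip_treated"], data["chip_untreated"], sites,
        int(config.ana("asym_half_width", 15_000)),
        int(config.ana("asym_bin", 100)),
        float(config.ana("asym_threshold", 0.1)),
    )
    chip_mod.write_profile_tsv(asym, out / "strand_asymmetry.tsv")
    warnings.extend(fit.warnings)
    report["chip"] = {
        "n_sites": fine.n_sites,
        "narrow_fwhm_bp": _round(fit.narrow_fwhm),
        "narrow_fwhm_se_bp": _round(fit.narrow_fwhm_se),
        "broad_fwhm_bp": _round(fit.broad_fwhm),
        "broad_fwhm_se_bp": _round(fit.broad_fwhm_se),
        "fit_converged": fit.converged,
        "asymmetry_extent_bp": _round(asym.extent),
        "asymmetry_switch_bp": _round(asym.switch_position),
        "asymmetry_defined": asym.defined,
    }


def _stage_boundary(config, out, data, report, warnings):
    if "chip_treated" not in data:
        raise ValueError("boundary stage requires ChIP coverage")
    dist_range = tuple(config.ana("boundary_dist_range", (200_000, 700_000)))
    flank = int(config.ana("boundary_flank", 100_000))
    tracks = bnd_mod.enrichment_track(
        data["chip_treated"], data["chip_untreated"],
        int(config.ana("boundary_bin", 10_000)),
    )
    controls = bnd_mod.sample_random_controls(
        data["sites"], data["boundaries"], dist_range,
        int(config.ana("n_controls", 200)),
        seed=config.seed + 104_729,
        genome=config.genome, flank=flank,
        exclude_cross_boundary=True,
    )
    res = bnd_mod.boundary_drop(
        tracks, data["sites"], data["boundaries"], dist_range, flank, controls
    )
    report["boundary"] = {
        "n_boundary_pairs": res.n_boundaries,
        "n_control_pairs": res.n_controls,
        "n_excluded_pairs": res.n_excluded,
        "boundary_drop_mean": _round(res.boundary_mean),
        "boundary_drop_sem": _round(res.boundary_sem),
        "boundary_p": _round(res.boundary_p),
        "control_drop_mean": _round(res.control_mean),
        "control_drop_sem": _round(res.control_sem),
        "control_p": _round(res.control_p),
    }


def _stage_bands(config, out, data, report, warnings):
    if "chip_treated" not in data:
        raise ValueError("bands stage requires ChIP coverage")
    cond_b = config.simulation.get("condition_b", {}) or {}
    factor = float(cond_b.get("sigma_b_factor", 1.5))
    seed_b = config.seed + int(cond_b.get("seed_offset", 7_919))
    params_b = dataclasses.replace(
        config.sim_params(seed=seed_b),
        sigma_b=config.sim_params().sigma_b * factor,
    )
    tb, ub, _ = syn_mod.simulate_chip_pair(params_b, data["sites"], data["boundaries"])
    bands = [tuple(b) for b in config.ana("bands", [(-1.5e6, 0.5e6), (0.5e6, 1.5e6)])]
    res = bnd_mod.band_difference(
        (data["chip_treated"], data["chip_untreated"]), (tb, ub),
        data["sites"], bands, int(config.ana("band_bin", 10_000)),
    )
    report["bands"] = {
        "bands_bp": [list(b) for b in res.bands],
        "difference": [_round(v) for v in res.difference],
        "t_statistic": [_round(v) for v in res.t_statistic],
        "p_value": [_round(v) for v in res.p_value],
        "sigma_b_factor": factor,
        "n_sites": res.n_a,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "hic": _stage_hic,
    "insulation": _stage_insulation,
    "chip": _stage_chip,
    "boundary": _stage_boundary,
    "bands": _stage_bands,
}
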