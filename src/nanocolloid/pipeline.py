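"""End-to-end "dispersion replay" workflow on synthetic data.

A single YAML-style configuration drives the whole chain per condition
(e.g. water vs 2 M proline at matched number concentration):

    simulate (MC)  ->  RDF  ->  PMF + features  ->  aggregation census
                   \\->  forward SAXS -> 2-Yukawa fit -> decomposition

All randomness flows from one seed (sub-seeds derived deterministically per
condition), and the emitted report carries the seed plus a settings hash so
a run is bit-reproducible.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import io as ncio
from .aggregation import DEFAULT_CUTOFF_FACTOR, find_clusters, monomer_fraction, pooled_census
from .potentials import Environment, TwoYukawaPotential, YukawaTerm
from .saxs import LogNormalSphereFF, SolutionState, decompose_fit, fit_saxs
from .simulate import Box, SimulationConfig, SyntheticSAXSSpec, run_mc, synthesize_saxs
from .structure import average_rdf, pmf_features, rdf_to_pmf

__all__ = ["RunConfig", "replay_pipeline"]

logger = logging.getLogger("nanocolloid")

_TOP_KEYS = {"seed", "environment", "stages", "box", "mc", "structure",
             "aggregation", "saxs", "conditions", "concentration_tolerance"}
_ENV_KEYS = {"temperature_K", "solvent", "dielectric_constant"}
_STAGE_KEYS = {"mc", "structure", "aggregation", "saxs"}
_BOX_KEYS = {"lengths_nm", "periodic"}
_MC_KEYS = {"n_sweeps_equilibration", "n_sweeps_production", "sample_interval",
            "max_displacement"}
_STRUCT_KEYS = {"bin_width_nm", "r_max_nm", "smoothing_window"}
_AGG_KEYS = {"cutoff_nm", "max_class"}
_SAXS_KEYS = {"q_min", "q_max", "n_q", "volume_fraction", "scale", "background",
              "noise_relative_sd", "closure", "form_factor", "fit_initial", "vary"}
_FF_KEYS = {"median_radius_nm", "lognormal_sigma"}
_COND_KEYS = {"label", "potential", "number_concentration_m3"}
_POT_KEYS = {"sigma_nm", "K1", "Z1", "K2", "Z2"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated replay configuration (see module docstring for the schema)."""

    raw: dict[str, Any] = field(repr=False)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        _check_keys(d, _TOP_KEYS, "top level")
        stages = d.get("stages", {})
        _check_keys(stages, _STAGE_KEYS, "stages")
        any_stochastic = stages.get("mc", False) or stages.get("saxs", False)
        if any_stochastic and "seed" not in d:
            raise ValueError("a seed is required when stochastic stages are enabled")
        _check_keys(d.get("environment", {}), _ENV_KEYS, "environment")
        _check_keys(d.get("box", {}), _BOX_KEYS, "box")
        _check_keys(d.get("mc", {}), _MC_KEYS, "mc")
        _check_keys(d.get("structure", {}), _STRUCT_KEYS, "structure")
        _check_keys(d.get("aggregation", {}), _AGG_KEYS, "aggregation")
        saxs = d.get("saxs", {})
        _check_keys(saxs, _SAXS_KEYS, "saxs")
        _check_keys(saxs.get("form_factor", {}), _FF_KEYS, "saxs.form_factor")
        for i, cond in enumerate(d.get("conditions", [])):
            _check_keys(cond, _COND_KEYS, f"conditions[{i}]")
            _check_keys(cond.get("potential", {}), _POT_KEYS, f"conditions[{i}].potential")
            if "label" not in cond:
                raise ValueError(f"conditions[{i}] needs a label")
        return cls(raw=d, seed=int(d.get("seed", 0)))

    @property
    def settings_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def environment(self) -> Environment:
        e = self.raw.get("environment", {})
        return Environment(temperature_K=e.get("temperature_K", 293.15),
                           solvent=e.get("solvent", "H2O"),
                           dielectric_constant=e.get("dielectric_constant"))

    def box(self) -> Box:
        b = self.raw.get("box", {})
        lengths = tuple(b.get("lengths_nm", (150.0, 150.0, 150.0)))
        periodic = tuple(b.get("periodic", (True, True, True)))
        return Box(lengths=lengths, periodic=periodic)

    def potential_for(self, cond: dict[str, Any]) -> TwoYukawaPotential:
        p = cond.get("potential", {})
        return TwoYukawaPotential(
            sigma=p.get("sigma_nm", 7.0),
            term_1=YukawaTerm(p.get("K1", 0.0), p.get("Z1", 1.0)),
            term_2=YukawaTerm(p.get("K2", 0.0), p.get("Z2", 1.0)),
            environment=self.environment())


def _condition_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(index,))
               .generate_state(1, dtype=np.uint32)[0]) % (2**31)


def replay_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Run the configured stages for every condition and emit one report.

    Returns the report dict; when ``outdir`` is given, also writes
    ``report.json`` plus per-condition RDF/PMF/census CSVs and SAXS artifacts.
    Any stage failure aborts with a stage-scoped error message.
    """
    raw = config.raw
    stages = raw.get("stages", {})
    conditions = raw.get("conditions", [])
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "seed": config.seed,
        "settings_hash": config.settings_hash,
        "environment": {
            "temperature_K": config.environment().temperature_K,
            "solvent": config.environment().solvent,
            "dielectric_constant": config.environment().dielectric_constant,
        },
        "conditions": {},
    }
    if not any(stages.values()) or not conditions:
        return _finish(report, out)

    box = config.box()
    mc_cfg = raw.get("mc", {})
    st_cfg = raw.get("structure", {})
    ag_cfg = raw.get("aggregation", {})
    sx_cfg = raw.get("saxs", {})

    fit_results = {}
    for idx, cond in enumerate(conditions):
        label = cond["label"]
        entry: dict[str, Any] = {}
        sub_seed = _condition_seed(config.seed, idx)
        pot = config.potential_for(cond)
        frames = None
        t0 = time.perf_counter()
        try:
            if stages.get("mc"):
                conc = cond.get("number_concentration_m3")
                if conc is None:
                    raise ValueError(f"condition {label!r} needs number_concentration_m3")
                n = int(round(conc * box.volume_m3))
                sim = SimulationConfig(
                    n_particles=n, box=box, potential=pot,
                    n_sweeps_equilibration=mc_cfg.get("n_sweeps_equilibration", 200),
                    n_sweeps_production=mc_cfg.get("n_sweeps_production", 500),
                    sample_interval=mc_cfg.get("sample_interval", 10),
                    max_displacement=mc_cfg.get("max_displacement", pot.sigma / 3.0),
                    seed=sub_seed)
                frames, stats = run_mc(sim)
                entry["n_particles"] = n
                entry["number_concentration_m3"] = n / box.volume_m3
                entry["mc_acceptance"] = stats.acceptance_fraction
                if out is not None:
                    ncio.write_centroids(frames[-1], out / f"{label}_frame.csv")
        except Exception as err:
            raise RuntimeError(f"stage 'mc' failed for condition {label!r}: {err}") from err

        try:
            if stages.get("structure") and frames is not None:
                bw = st_cfg.get("bin_width_nm", pot.sigma / 20.0)
                per_edges = [box.lengths[k] for k in range(3) if box.periodic[k]]
                rmax_default = (min(per_edges) / 2.0) if per_edges else min(box.lengths) / 2.0
                rmax = st_cfg.get("r_max_nm", rmax_default)
                rdf = average_rdf(frames, bw, rmax)
                pmf = rdf_to_pmf(rdf, config.environment())
                feats = pmf_features(pmf, st_cfg.get("smoothing_window", 3))
                entry["pmf_features"] = {
                    k: getattr(feats, k) for k in (
                        "has_well", "well_position", "well_depth",
                        "barrier_position", "barrier_height", "barrier_minus_well",
                        "secondary_minimum_position")}
                if out is not None:
                    ncio.write_rdf_csv(rdf, out / f"{label}_rdf.csv")
                    ncio.write_pmf_csv(pmf, out / f"{label}_pmf.csv")
                    ncio.write_features_json(feats, out / f"{label}_features.json")
        except Exception as err:
            raise RuntimeError(f"stage 'structure' failed for condition {label!r}: {err}") from err

        try:
            if stages.get("aggregation") and frames is not None:
                cutoff = ag_cfg.get("cutoff_nm", DEFAULT_CUTOFF_FACTOR * pot.sigma)
                assignments = [find_clusters(f, cutoff) for f in frames]
                cens = pooled_census(assignments, ag_cfg.get("max_class", 6))
                entry["census"] = {
                    "size_classes": cens.size_classes.tolist(),
                    "percentage": cens.percentage.tolist(),
                    "mole_fraction": cens.mole_fraction.tolist(),
                    "pooled_top": cens.pooled_top,
                }
                entry["monomer_percentage"] = monomer_fraction(cens)
                if out is not None:
                    ncio.write_census_csv(cens, out / f"{label}_census.csv")
        except Exception as err:
            raise RuntimeError(f"stage 'aggregation' failed for condition {label!r}: {err}") from err

        try:
            if stages.get("saxs"):
                ffd = sx_cfg.get("form_factor", {})
                ff = LogNormalSphereFF(
                    median_radius=ffd.get("median_radius_nm", pot.sigma / 4.0),
                    lognormal_sigma=ffd.get("lognormal_sigma", 0.1))
                q = np.linspace(sx_cfg.get("q_min", 0.05), sx_cfg.get("q_max", 3.0),
                                sx_cfg.get("n_q", 200))
                phi = sx_cfg.get("volume_fraction")
                if phi is None:
                    conc = cond.get("number_concentration_m3")
                    phi = SolutionState.from_number_concentration(conc, pot.sigma).volume_fraction
                spec = SyntheticSAXSSpec(
                    q_grid=q, form_factor=ff, potential=pot, volume_fraction=phi,
                    scale=sx_cfg.get("scale", 1.0),
                    background=sx_cfg.get("background", 0.0),
                    noise_relative_sd=sx_cfg.get("noise_relative_sd", 0.01),
                    seed=sub_seed, closure=sx_cfg.get("closure", "hnc"))
                curve = synthesize_saxs(spec)
                initial = dict(sx_cfg.get("fit_initial", {}))
                defaults = {"scale": spec.scale, "background": spec.background,
                            "K1": pot.term_1.K, "Z1": pot.term_1.Z,
                            "K2": pot.term_2.K, "Z2": pot.term_2.Z,
                            "phi": phi, "sigma": pot.sigma}
                for k, v in defaults.items():
                    initial.setdefault(k, v)
                vary = tuple(sx_cfg.get("vary", ("scale", "background", "K1", "Z1",
                                                 "K2", "Z2", "phi")))
                fit = fit_saxs(curve, ff, initial, vary=vary,
                               closure=sx_cfg.get("closure", "hnc"),
                               environment=config.environment())
                fit_results[label] = fit
                entry["saxs_fit"] = {"params": fit.params_dict(),
                                     "redchi": fit.redchi, "success": fit.success}
                if out is not None:
                    ncio.write_saxs_dat(curve, out / f"{label}_saxs.dat")
                    ncio.write_fit_json(fit, out / f"{label}_fit.json")
        except Exception as err:
            raise RuntimeError(f"stage 'saxs' failed for condition {label!r}: {err}") from err

        report["conditions"][label] = entry
        # wall time goes to the log only: reports must be byte-reproducible
        logger.info("condition %s done in %.1fs", label, time.perf_counter() - t0)

    # paired comparison when exactly two conditions are configured
    if len(conditions) == 2:
        la, lb = conditions[0]["label"], conditions[1]["label"]
        ca, cb = report["conditions"][la], report["conditions"][lb]
        comp: dict[str, Any] = {"pair": [la, lb]}
        tol = raw.get("concentration_tolerance", 0.2)
        na = ca.get("number_concentration_m3")
        nb = cb.get("number_concentration_m3")
        if na and nb and abs(na - nb) / max(na, nb) > tol:
            raise ValueError(
                f"paired conditions must be at matched number concentrations "
                f"(relative gap {abs(na - nb) / max(na, nb):.2f} > {tol})")
        if "monomer_percentage" in ca and "monomer_percentage" in cb:
            comp["delta_monomer_percentage"] = (ca["monomer_percentage"]
                                                - cb["monomer_percentage"])
        fa, fb = ca.get("pmf_features"), cb.get("pmf_features")
        if fa and fb and fa["has_well"] and fb["has_well"]:
            comp["delta_barrier_height"] = fa["barrier_height"] - fb["barrier_height"]
            comp["delta_well_depth"] = fa["well_depth"] - fb["well_depth"]
        if la in fit_results and lb in fit_results:
            r_grid = np.linspace(fit_results[la].potential.sigma,
                                 6.0 * fit_results[la].potential.sigma, 256)
            d = decompose_fit(fit_results[la], r_grid, other=fit_results[lb])
            comp["decomposition_delta_max_kT"] = {
                "total": float(np.max(np.abs(d["delta_total"]))),
                "attractive": float(np.max(np.abs(d["delta_attractive"]))),
                "repulsive": float(np.max(np.abs(d["delta_repulsive"]))),
            }
            if out is not None:
                np.savetxt(out / "decomposition_delta.csv",
                           np.column_stack([d["r"], d["delta_total"],
                                            d["delta_attractive"], d["delta_repulsive"]]),
                           delimiter=",", header="r_nm,delta_total_kT,"
                           "delta_attractive_kT,delta_repulsive_kT")
        report["comparison"] = comp

    return _finish(report, out)


def _finish(report: dict[str, Any], out: Path | None) -> dict[str, Any]:
    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    return report
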