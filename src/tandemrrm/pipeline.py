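"""Configuration-driven pipeline chaining simulate -> fit -> report stages.

A RunConfig (usually loaded from YAML) names an ordered list of stages;
each stage consumes the in-memory context left by earlier stages, writes
its tabular outputs under ``out_dir`` and appends to a human-readable
summary.  All randomness derives from the single config seed, so a rerun
with the same config produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import yaml

from . import csp as csp_mod
from . import io as tio
from . import itc as itc_mod
from . import rdc as rdc_mod
from . import relaxation as relax_mod
from . import synth
from .exceptions import PipelineError, TandemRRMError, ValidationError

__all__ = ["RunConfig", "run_pipeline", "VALID_STAGES", "DEMO_CONFIG"]

log = logging.getLogger("tandemrrm")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``stages`` is an ordered list of {"name": ..., "params": {...}} dicts.
    """

    seed: int = 0
    out_dir: str = "tandemrrm_out"
    field_MHz_1H: float = 500.0
    temperature_C: float = 25.0
    stages: list = dataclass_field(default_factory=list)

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {k: raw[k] for k in ("seed", "out_dir", "field_MHz_1H", "temperature_C", "stages")
                 if k in raw}
        return cls(**known)


def _fmt(x, nd=6):
    return f"{x:.{nd}g}"


# --- stage implementations --------------------------------------------------


def _stage_simulate_structure(cfg, ctx, out, p):
    structure = synth.gen_structure(
        n_residues=int(p.get("n_residues", 30)),
        geometry=p.get("geometry", "coil"),
        seed=cfg.seed,
        rotation_deg=float(p.get("rotation_deg", 90.0)),
    )
    ctx["structure"] = structure
    tio.write_pdb(structure, out / "structure.pdb")
    return f"structure: {p.get('geometry', 'coil')}, {len(structure.residue_numbers)} residues"


def _stage_simulate_rdc(cfg, ctx, out, p):
    if "structure" not in ctx:
        raise ValidationError("simulate_rdc requires a prior simulate_structure stage")
    tensor = rdc_mod.AlignmentTensor.from_parameters(
        float(p.get("Da_Hz", 10.6)), float(p.get("rhombicity", 0.23)),
        tuple(p.get("euler_deg", (30.0, 60.0, 40.0))),
    )
    rdcs = synth.gen_rdc_set(
        ctx["structure"], tensor,
        noise=synth.NoiseSpec(sd=float(p.get("noise_sd", 0.0)), seed=cfg.seed + 1),
    )
    ctx["rdcs"] = rdcs
    tio.write_rdc_table(rdcs, out / "rdcs.tsv")
    return f"rdc set: {len(rdcs)} couplings, noise sd {p.get('noise_sd', 0.0)} Hz"


def _stage_rdc_fit(cfg, ctx, out, p):
    if "rdcs" not in ctx or "structure" not in ctx:
        raise ValidationError("rdc_fit requires rdcs and a structure in context")
    model = rdc_mod.AlignmentModel(ctx["rdcs"], ctx["structure"])
    result = model.fit()
    da, rh, euler = result.params()
    (out / "rdc_fit.json").write_text(json.dumps({
        "Da_Hz": da, "rhombicity": rh, "euler_deg": list(euler),
        "r_factor_percent": result.r_factor_percent,
        "rmsd_Hz": result.rmsd_Hz, "n_rdcs": result.n_rdcs,
        "condition_number": result.condition_number,
    }, indent=1, sort_keys=True))
    log.info("rdc_fit: R-factor %.2f%% over %d couplings", result.r_factor_percent, result.n_rdcs)
    return result.summary()


def _stage_simulate_relaxation(cfg, ctx, out, p):
    rset = synth.gen_relaxation_set(
        tau_c_ns=float(p.get("tau_c_ns", 10.0)),
        field_MHz_1H=cfg.field_MHz_1H,
        n_residues=int(p.get("n_residues", 40)),
        noise=synth.NoiseSpec(sd=float(p.get("noise_sd", 0.0)), seed=cfg.seed + 2),
        temperature_K=cfg.temperature_K,
    )
    ctx["relaxation"] = rset
    ctx["MW_Da"] = float(p.get("MW_Da", 20000.0))
    tio.write_relaxation_table(rset, out / "relaxation.tsv")
    return f"relaxation set: {len(rset)} residues at {cfg.field_MHz_1H:g} MHz"


def _stage_tauc(cfg, ctx, out, p):
    if "relaxation" not in ctx:
        raise ValidationError("tauc requires a relaxation set in context")
    est = relax_mod.estimate_tumbling(ctx["relaxation"], MW_Da=ctx.get("MW_Da", 20000.0),
                                      noe_cutoff=p.get("noe_cutoff"))
    (out / "tumbling.json").write_text(json.dumps({
        "T1_mean_s": est.T1_mean_s, "T2_mean_s": est.T2_mean_s,
        "tau_c_calc_ns": est.tau_c_calc_ns, "tau_c_pred_ns": est.tau_c_pred_ns,
        "ratio": est.ratio, "verdict": est.verdict(),
        "n_residues_used": est.n_residues_used,
    }, indent=1, sort_keys=True))
    return est.summary()


def _stage_simulate_titration(cfg, ctx, out, p):
    import pandas as pd

    from .containers import PeakList

    n_res = int(p.get("n_residues", 20))
    rng = np.random.default_rng(cfg.seed + 3)
    ref = PeakList(pd.DataFrame({
        "residue_number": np.arange(1, n_res + 1),
        "residue_name": ["A"] * n_res,
        "dH_ppm": rng.uniform(7.0, 9.5, n_res).round(4),
        "dN_ppm": rng.uniform(105.0, 130.0, n_res).round(3),
        "intensity": np.full(n_res, 1e6),
    }), label="apo")
    shifted = rng.choice(np.arange(1, n_res + 1), size=max(3, n_res // 2), replace=False)
    delta_bound = {int(r): (float(rng.uniform(0.05, 0.25)) * float(rng.choice([-1, 1])),
                            float(rng.uniform(0.3, 1.5)) * float(rng.choice([-1, 1])))
                   for r in shifted}
    series = synth.gen_titration(
        ref,
        synth.ExchangeSpec(Kd_uM=float(p.get("Kd_uM", 52.0)), delta_bound=delta_bound,
                           kex_s=float(p.get("kex_s", 2000.0))),
        protein_conc_uM=float(p.get("protein_conc_uM", 200.0)),
        ligand_ratios=p.get("ratios", [0.0, 0.25, 0.5, 1.0, 2.0, 3.0]),
        noise=synth.NoiseSpec(sd=float(p.get("noise_sd", 0.0)), seed=cfg.seed + 4),
        broadening=bool(p.get("broadening", True)),
        field_MHz_1H=cfg.field_MHz_1H,
    )
    ctx["titration"] = series
    for ratio, pl in zip(series.ratios, series.points):
        tio.write_peaklist(pl, out / f"peaks_ratio_{ratio:g}.tsv")
    return f"titration: {len(series)} points, {n_res} residues, Kd {p.get('Kd_uM', 52.0)} uM"


def _stage_csp(cfg, ctx, out, p):
    if "titration" not in ctx:
        raise ValidationError("csp requires a titration in context")
    series = ctx["titration"]
    profile = csp_mod.csp_per_residue(series.reference, series.points[-1])
    profile.to_csv(out / "csp_profile.tsv", sep="\t", float_format="%.6g")
    large = sorted(csp_mod.classify_large(profile, float(p.get("threshold_ppm", 0.025))))
    if "structure" in ctx and p.get("map_to_structure", False):
        csp_mod.map_to_structure(profile, ctx["structure"], out / "csp_on_structure.pdb")
    ctx["csp_profile"] = profile
    return (f"csp: {int(profile['matched'].sum())} matched residues, "
            f"{len(large)} above {p.get('threshold_ppm', 0.025)} ppm: {large}")


def _stage_fit_kd(cfg, ctx, out, p):
    if "titration" not in ctx:
        raise ValidationError("fit_kd requires a titration in context")
    fit = csp_mod.fit_kd_from_titration(ctx["titration"], mode=p.get("mode", "global"))
    (out / "kd_fit.json").write_text(json.dumps({
        "Kd_uM": fit.Kd_uM, "Kd_stderr_uM": fit.Kd_stderr_uM,
        "residual_norm": fit.residual_norm,
        "n_points": fit.n_points, "n_residues": fit.n_residues,
    }, indent=1, sort_keys=True))
    log.info("fit_kd: Kd %.3g uM, residual norm %.3g", fit.Kd_uM, fit.residual_norm)
    return fit.summary()


def _stage_simulate_isotherm(cfg, ctx, out, p):
    from .containers import InjectionSchedule

    schedule = InjectionSchedule.standard(
        n_injections=int(p.get("n_injections", 30)),
        syringe_conc_uM=float(p.get("syringe_conc_uM", 7000.0)),
        cell_conc_uM=float(p.get("cell_conc_uM", 800.0)),
        n_pre=int(p.get("n_pre", 1)),
        cell_volume_ml=float(p.get("cell_volume_ml", 1.4)),
        temperature_C=cfg.temperature_C,
    )
    kind = p.get("model", "one_site")
    if kind == "one_site":
        model = itc_mod.OneSiteParams(float(p.get("n", 0.9)), float(p.get("Kd_uM", 139.0)),
                                      float(p.get("dH_kcal_mol", -5.0)))
    else:
        model = itc_mod.TwoSiteParams(float(p.get("Kd1_uM", 1.0)), float(p.get("Kd2_uM", 1.0)),
                                      float(p.get("dH1_kcal_mol", -10.0)),
                                      float(p.get("dH2_kcal_mol", -10.0)))
    iso = synth.gen_isotherm(model, schedule,
                             noise=synth.NoiseSpec(sd=float(p.get("noise_sd", 0.0)),
                                                   seed=cfg.seed + 5))
    ctx["isotherm"] = iso
    ctx["isotherm_kind"] = "one_site" if kind == "one_site" else "two_site_sequential"
    tio.write_isotherm(iso, out / "isotherm.csv")
    return f"isotherm: {len(iso)} injections, {kind} model"


def _stage_itc_fit(cfg, ctx, out, p):
    if "isotherm" not in ctx:
        raise ValidationError("itc_fit requires an isotherm in context")
    kind = p.get("model", ctx.get("isotherm_kind", "one_site"))
    fit = itc_mod.fit_isotherm(ctx["isotherm"], model_kind=kind)
    (out / "itc_fit.json").write_text(json.dumps({
        "model": kind, "params": fit.params,
        "residual_norm": fit.residual_norm, "c_value": fit.c_value,
        "n_used": fit.n_used,
    }, indent=1, sort_keys=True))
    log.info("itc_fit: %s, residual norm %.3g over %d injections",
             kind, fit.residual_norm, fit.n_used)
    return fit.summary()


VALID_STAGES = {
    "simulate_structure": _stage_simulate_structure,
    "simulate_rdc": _stage_simulate_rdc,
    "rdc_fit": _stage_rdc_fit,
    "simulate_relaxation": _stage_simulate_relaxation,
    "tauc": _stage_tauc,
    "simulate_titration": _stage_simulate_titration,
    "csp": _stage_csp,
    "fit_kd": _stage_fit_kd,
    "simulate_isotherm": _stage_simulate_isotherm,
    "itc_fit": _stage_itc_fit,
}

#: a small end-to-end demonstration configuration (seconds on one CPU)
DEMO_CONFIG = {
    "seed": 7,
    "out_dir": "tandemrrm_demo",
    "field_MHz_1H": 500,
    "temperature_C": 25,
    "stages": [
        {"name": "simulate_structure", "params": {"n_residues": 30, "geometry": "coil"}},
        {"name": "simulate_rdc", "params": {"Da_Hz": 10.6, "rhombicity": 0.23, "noise_sd": 0.5}},
        {"name": "rdc_fit"},
        {"name": "simulate_relaxation", "params": {"tau_c_ns": 10.0, "n_residues": 40, "MW_Da": 21854}},
        {"name": "tauc"},
        {"name": "simulate_titration", "params": {"Kd_uM": 52.0, "protein_conc_uM": 200.0}},
        {"name": "csp"},
        {"name": "fit_kd"},
        {"name": "simulate_isotherm", "params": {"model": "one_site", "n": 0.9, "Kd_uM": 139.0,
                                                  "dH_kcal_mol": -5.0}},
        {"name": "itc_fit"},
    ],
}


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages in order.

    Returns the final context; writes per-stage outputs plus ``summary.txt``
    and ``run_config.json`` under ``config.out_dir``.  Any stage error
    aborts with a PipelineError naming the stage.
    """
    cfg = RunConfig.from_dict(config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s.get("name") for s in cfg.stages if s.get("name") not in VALID_STAGES]
    if unknown:
        raise PipelineError(
            f"unknown stage(s) {unknown}; valid stages: {sorted(VALID_STAGES)}"
        )
    log.info("pipeline: seed=%d, %d stages -> %s", cfg.seed, len(cfg.stages), out)
    ctx: dict = {}
    summary = [f"tandemrrm pipeline (seed {cfg.seed}, field {cfg.field_MHz_1H:g} MHz, "
               f"T {cfg.temperature_C:g} C)"]
    for stage in cfg.stages:
        name = stage["name"]
        params = stage.get("params", {}) or {}
        log.info("stage %s: params %s", name, params)
        try:
            msg = VALID_STAGES[name](cfg, ctx, out, params)
        except TandemRRMError as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        summary.append(f"\n== {name} ==\n{msg}")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    (out / "run_config.json").write_text(json.dumps({
        "seed": cfg.seed, "out_dir": cfg.out_dir, "field_MHz_1H": cfg.field_MHz_1H,
        "temperature_C": cfg.temperature_C, "stages": cfg.stages,
    }, indent=1, sort_keys=True))
    return ctx
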