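"""ITC forward models and isotherm fitting.

Implements the two binding schemes needed for a protein-titrated-into-RNA
experiment (titrant in the syringe, titrand in the cell):

* one-site (Wiseman): n identical independent sites per cell molecule,
  bound titrant from the ligand-depletion quadratic;
* sequential two-site: macroscopic constants K1, K2 with the binding
  polynomial P = 1 + K1 X + K1 K2 X^2; free titrant X solved per injection
  by bracketed root finding on the mass balance.

Concentration bookkeeping uses the perfusion-cell convention: each
injection of volume v displaces cell liquid, diluting existing contents by
(1 - v/V0) while delivering syringe material; per-injection heats are
differences of cell heat content with the midpoint displacement
correction.  Heats are exothermic-negative, in ucal; enthalpies kcal/mol;
concentrations uM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from .containers import InjectionSchedule, Isotherm
from .exceptions import FitError, UnidentifiableError, ValidationError

__all__ = [
    "OneSiteParams",
    "TwoSiteParams",
    "concentrations_after_injection",
    "concentration_series",
    "heats_one_site",
    "heats_two_site",
    "fit_isotherm",
    "IsothermModel",
    "IsothermFitResult",
    "equivalence_ratio",
    "dilution_control",
]

#: ucal per (umol * kcal/mol)
_UCAL_PER_UMOL_KCAL = 1000.0


@dataclass
class OneSiteParams:
    """Wiseman one-site parameters: n sites per cell molecule, Kd (uM),
    dH (kcal/mol), constant per-injection offset (ucal)."""

    n: float = 1.0
    Kd_uM: float = 10.0
    dH_kcal_mol: float = -10.0
    q_offset_ucal: float = 0.0

    def __post_init__(self):
        if self.n <= 0 or self.Kd_uM <= 0:
            raise ValidationError("n and Kd must be positive")


@dataclass
class TwoSiteParams:
    """Sequential two-site parameters (macroscopic).

    Association constants are stored as dissociation constants in uM for
    unit consistency with the rest of the package: K1 = 1/Kd1, K2 = 1/Kd2.
    """

    Kd1_uM: float = 1.0
    Kd2_uM: float = 1.0
    dH1_kcal_mol: float = -10.0
    dH2_kcal_mol: float = -10.0
    q_offset_ucal: float = 0.0

    def __post_init__(self):
        if self.Kd1_uM <= 0 or self.Kd2_uM <= 0:
            raise ValidationError("Kd1 and Kd2 must be positive")


def concentration_series(schedule: InjectionSchedule):
    """Total titrant and titrand concentration (uM) in the cell after each
    injection.

    Each injection of volume v dilutes the existing cell contents by
    (1 - v/V0); the titrand is only diluted, the titrant additionally
    receives syringe_conc * v/V0 of fresh material.
    """
    v0_ul = schedule.cell_volume_ml * 1000.0
    titrant = np.empty(len(schedule))
    titrand = np.empty(len(schedule))
    x, m = 0.0, float(schedule.cell_conc_uM)
    for i, v in enumerate(schedule.volumes_ul):
        f = 1.0 - v / v0_ul
        x = x * f + schedule.syringe_conc_uM * v / v0_ul
        m = m * f
        titrant[i] = x
        titrand[i] = m
    return titrant, titrand


def concentrations_after_injection(schedule: InjectionSchedule, i: int):
    """(total titrant uM, total titrand uM) in the cell after injection
    ``i`` (1-based); i = 0 returns the nominal pre-titration cell."""
    if not 0 <= i <= len(schedule):
        raise ValidationError(f"injection index {i} out of range 0..{len(schedule)}")
    if i == 0:
        return 0.0, float(schedule.cell_conc_uM)
    titrant, titrand = concentration_series(schedule)
    return float(titrant[i - 1]), float(titrand[i - 1])


def _bound_one_site(x_total, sites_total, kd):
    """Bound titrant (uM) for single-site binding with depletion."""
    s = x_total + sites_total + kd
    disc = s * s - 4.0 * x_total * sites_total
    return (s - math.sqrt(max(disc, 0.0))) / 2.0


def _per_injection_heats(schedule, cumulative_ucal, q_offset):
    """Differences of cell heat content with the midpoint displacement
    correction: dq_i = Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1})/2."""
    v0_ul = schedule.cell_volume_ml * 1000.0
    q_prev = 0.0
    out = np.empty(len(schedule))
    for i, v in enumerate(schedule.volumes_ul):
        q_i = cumulative_ucal[i]
        out[i] = q_i - q_prev + (v / v0_ul) * 0.5 * (q_i + q_prev) + q_offset
        q_prev = q_i
    return out


def heats_one_site(params: OneSiteParams, schedule: InjectionSchedule) -> np.ndarray:
    """Per-injection heats (ucal) for the one-site model."""
    titrant, titrand = concentration_series(schedule)
    v0_l = schedule.cell_volume_ml / 1000.0
    cumulative = np.empty(len(schedule))
    for i in range(len(schedule)):
        bound = _bound_one_site(titrant[i], params.n * titrand[i], params.Kd_uM)
        cumulative[i] = params.dH_kcal_mol * bound * v0_l * _UCAL_PER_UMOL_KCAL
    return _per_injection_heats(schedule, cumulative, params.q_offset_ucal)


def _free_titrant_two_site(x_total, m_total, k1, k2):
    """Free titrant from X_t = X + M_t (K1 X + 2 K1 K2 X^2)/(1 + K1 X + K1 K2 X^2),
    solved by bracketed root finding (all concentrations uM, K in uM^-1)."""
    if x_total <= 0:
        return 0.0

    def g(x):
        p = 1.0 + k1 * x + k1 * k2 * x * x
        return x + m_total * (k1 * x + 2.0 * k1 * k2 * x * x) / p - x_total

    # g(0) = -X_t < 0, g(X_t) >= 0: always bracketed for positive inputs
    return brentq(g, 0.0, x_total, xtol=1e-15, rtol=1e-13)


def heats_two_site(params: TwoSiteParams, schedule: InjectionSchedule) -> np.ndarray:
    """Per-injection heats (ucal) for the sequential two-site model.

    Cumulative heat content Q = V0 * M_t * (dH1 * th1 + (dH1 + dH2) * th2)
    with th1, th2 the singly/doubly ligated species fractions from the
    binding polynomial.
    """
    k1 = 1.0 / params.Kd1_uM
    k2 = 1.0 / params.Kd2_uM
    titrant, titrand = concentration_series(schedule)
    v0_l = schedule.cell_volume_ml / 1000.0
    cumulative = np.empty(len(schedule))
    for i in range(len(schedule)):
        x = _free_titrant_two_site(titrant[i], titrand[i], k1, k2)
        p = 1.0 + k1 * x + k1 * k2 * x * x
        th1 = k1 * x / p
        th2 = k1 * k2 * x * x / p
        q_kcal_per_mol_cell = params.dH1_kcal_mol * th1 + (params.dH1_kcal_mol + params.dH2_kcal_mol) * th2
        cumulative[i] = q_kcal_per_mol_cell * titrand[i] * v0_l * _UCAL_PER_UMOL_KCAL
    return _per_injection_heats(schedule, cumulative, params.q_offset_ucal)


@dataclass
class IsothermFitResult:
    """Nonlinear least-squares fit of an ITC isotherm."""

    model_kind: str
    params: dict
    stderr: dict
    residuals: np.ndarray
    residual_norm: float
    c_value: float | None
    n_used: int
    lmfit_result: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"ITC isotherm fit ({self.model_kind})"]
        for k, v in self.params.items():
            se = self.stderr.get(k)
            se_s = f" +/- {se:.3g}" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {k:14s}: {v:.4g}{se_s}")
        if self.c_value is not None:
            lines.append(f"  Wiseman c     : {self.c_value:.3g}")
        lines.append(f"  injections    : {self.n_used}")
        lines.append(f"  residual norm : {self.residual_norm:.4g} ucal")
        return "\n".join(lines)


def _init_one_site(isotherm: Isotherm):
    """Heuristic start values: n from the steepest heat change, dH from the
    first usable injection, Kd from the transition width."""
    use = isotherm.usable
    ratio = isotherm.molar_ratio[use]
    q = isotherm.heats_ucal[use]
    sch = isotherm.schedule
    dq = np.diff(q)
    if len(dq):
        i_star = int(np.argmax(np.abs(dq)))
        n0 = float(np.clip(0.5 * (ratio[i_star] + ratio[i_star + 1]), 0.05, 10.0))
    else:
        n0 = 1.0
    moles_first = sch.syringe_conc_uM * sch.volumes_ul[use.argmax()] / 1e6  # umol
    dh0 = q[0] / (moles_first * _UCAL_PER_UMOL_KCAL) if moles_first > 0 else -10.0
    if not np.isfinite(dh0) or dh0 == 0:
        dh0 = -10.0
    # width of the transition in molar-ratio units ~ Kd/[cell]
    kd0 = max(0.05 * sch.cell_conc_uM, 1e-3)
    return n0, kd0, float(dh0)


def fit_isotherm(isotherm: Isotherm, model_kind: str = "one_site", init: dict | None = None,
                 fit_offset: bool = False) -> IsothermFitResult:
    """Levenberg-Marquardt fit of the matching forward model.

    ``model_kind``: "one_site", "two_site_sequential" or
    "two_site_independent" (independent sites = sequential constants with
    the statistical factor: K1 = 2k, K2 = k/2).  Injections with use_flag 0
    are excluded from the fit but kept in the concentration bookkeeping.
    """
    sch = isotherm.schedule
    use = isotherm.usable
    if use.sum() < 8:
        raise ValidationError(f"need >= 8 usable injections, have {int(use.sum())}")
    q_obs = isotherm.heats_ucal
    if np.ptp(q_obs[use]) < 1e-9 * max(1.0, np.abs(q_obs[use]).max()):
        raise UnidentifiableError("flat isotherm: binding parameters unidentifiable")
    init = dict(init or {})

    if model_kind == "one_site":
        n0, kd0, dh0 = _init_one_site(isotherm)
        p = lmfit.Parameters()
        p.add("n", value=init.get("n", n0), min=1e-3, max=100)
        p.add("log_Kd", value=math.log(init.get("Kd_uM", kd0)), min=-14, max=18)
        p.add("dH", value=init.get("dH_kcal_mol", dh0))
        p.add("q0", value=init.get("q_offset_ucal", 0.0), vary=fit_offset)

        def model(pars):
            prm = OneSiteParams(pars["n"].value, math.exp(pars["log_Kd"].value),
                                pars["dH"].value, pars["q0"].value)
            return heats_one_site(prm, sch)

    elif model_kind in ("two_site_sequential", "two_site_independent"):
        n0, kd0, dh0 = _init_one_site(isotherm)
        p = lmfit.Parameters()
        p.add("log_Kd1", value=math.log(init.get("Kd1_uM", kd0)), min=-14, max=18)
        p.add("log_Kd2", value=math.log(init.get("Kd2_uM", kd0 * 4)), min=-14, max=18)
        p.add("dH1", value=init.get("dH1_kcal_mol", dh0))
        p.add("dH2", value=init.get("dH2_kcal_mol", dh0))
        p.add("q0", value=init.get("q_offset_ucal", 0.0), vary=fit_offset)

        def model(pars):
            kd1 = math.exp(pars["log_Kd1"].value)
            kd2 = math.exp(pars["log_Kd2"].value)
            if model_kind == "two_site_independent":
                # independent identical sites k: macroscopic K1=2k, K2=k/2
                kd1, kd2 = kd1 / 2.0, kd2 * 2.0
            prm = TwoSiteParams(kd1, kd2, pars["dH1"].value, pars["dH2"].value,
                                pars["q0"].value)
            return heats_two_site(prm, sch)

    else:
        raise ValidationError(f"unknown model_kind '{model_kind}'")

    def residual(pars):
        return (model(pars) - q_obs)[use]

    result = lmfit.minimize(residual, p, method="leastsq")
    if not result.success:
        raise FitError(f"isotherm fit did not converge: {result.message}",
                       last_iterate={k: v.value for k, v in result.params.items()})

    rp = result.params
    if model_kind == "one_site":
        params = {
            "n": rp["n"].value,
            "Kd_uM": math.exp(rp["log_Kd"].value),
            "dH_kcal_mol": rp["dH"].value,
            "q_offset_ucal": rp["q0"].value,
        }
        stderr = {
            "n": rp["n"].stderr,
            "Kd_uM": (rp["log_Kd"].stderr or np.nan) * params["Kd_uM"],
            "dH_kcal_mol": rp["dH"].stderr,
            "q_offset_ucal": rp["q0"].stderr,
        }
        c = params["n"] * sch.cell_conc_uM / params["Kd_uM"]
        if not 1.0 <= c <= 1000.0:
            warnings.warn(
                f"Wiseman c = {c:.3g} outside [1, 1000]: fitted parameters are "
                "poorly determined in this regime"
            )
    else:
        params = {
            "Kd1_uM": math.exp(rp["log_Kd1"].value),
            "Kd2_uM": math.exp(rp["log_Kd2"].value),
            "dH1_kcal_mol": rp["dH1"].value,
            "dH2_kcal_mol": rp["dH2"].value,
            "q_offset_ucal": rp["q0"].value,
        }
        stderr = {
            "Kd1_uM": (rp["log_Kd1"].stderr or np.nan) * params["Kd1_uM"],
            "Kd2_uM": (rp["log_Kd2"].stderr or np.nan) * params["Kd2_uM"],
            "dH1_kcal_mol": rp["dH1"].stderr,
            "dH2_kcal_mol": rp["dH2"].stderr,
            "q_offset_ucal": rp["q0"].stderr,
        }
        c = None
    res_vec = np.asarray(result.residual)
    return IsothermFitResult(
        model_kind=model_kind,
        params=params,
        stderr={k: (float(v) if v is not None else np.nan) for k, v in stderr.items()},
        residuals=res_vec,
        residual_norm=float(np.linalg.norm(res_vec)),
        c_value=c,
        n_used=int(use.sum()),
        lmfit_result=result,
    )


class IsothermModel:
    """statsmodels-style front: IsothermModel(isotherm).fit() -> result."""

    def __init__(self, isotherm: Isotherm, model_kind: str = "one_site"):
        self.isotherm = isotherm
        self.model_kind = model_kind

    def fit(self, init: dict | None = None, fit_offset: bool = False) -> IsothermFitResult:
        return fit_isotherm(self.isotherm, self.model_kind, init=init, fit_offset=fit_offset)


def equivalence_ratio(isotherm: Isotherm, min_derivative_ucal: float = 0.5) -> dict:
    """Molar ratio at the isotherm's transition midpoint.

    Locates the extremum of the discrete derivative dq/dr over usable
    injections and refines it by a local quadratic through the three
    neighbouring derivative points.  Returns
    {"ratio", "found", "grid_spacing"}; a featureless isotherm (derivative
    extremum below ``min_derivative_ucal`` per unit ratio, or at the grid
    boundary) yields found=False.
    """
    use = isotherm.usable
    if use.sum() < 5:
        raise ValidationError("need >= 5 usable injections spanning the transition")
    # each injection's heat samples dQ/d(ratio) over its own molar-ratio
    # interval, so it is attributed to that interval's midpoint
    r_after = isotherm.molar_ratio
    r_before = np.concatenate([[0.0], r_after[:-1]])
    m = (0.5 * (r_before + r_after))[use]
    q = isotherm.heats_ucal[use]
    dr = np.diff(m)
    dq = np.diff(q) / dr
    mid = 0.5 * (m[:-1] + m[1:])
    spacing = float(np.median(dr))
    k = int(np.argmax(np.abs(dq)))
    if np.abs(dq[k]) < min_derivative_ucal:
        return {"ratio": float("nan"), "found": False, "grid_spacing": spacing}
    if k == 0 or k == len(dq) - 1:
        return {"ratio": float(mid[k]), "found": False, "grid_spacing": spacing}
    # quadratic through (mid, |dq|) around the extremum
    x = mid[k - 1:k + 2]
    y = np.abs(dq[k - 1:k + 2])
    denom = (y[0] - 2 * y[1] + y[2])
    if denom == 0:
        ratio = mid[k]
    else:
        ratio = x[1] + 0.5 * (x[2] - x[0]) / 2.0 * (y[0] - y[2]) / denom
    return {"ratio": float(ratio), "found": True, "grid_spacing": spacing}


def dilution_control(isotherm: Isotherm, threshold_ucal: float = 0.5) -> dict:
    """Summarise a titrant-into-buffer control run.

    Returns the mean and spread of usable heats and a verdict: "negligible"
    if |mean| < threshold (default 0.5 ucal), else "significant"; a
    significant constant offset should be subtracted before fitting.
    """
    q = isotherm.heats_ucal[isotherm.usable]
    mean = float(np.mean(q))
    sd = float(np.std(q))
    return {
        "offset_ucal": mean,
        "sd_ucal": sd,
        "negligible": abs(mean) < threshold_ucal,
        "verdict": "negligible" if abs(mean) < threshold_ucal else "significant",
    }
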