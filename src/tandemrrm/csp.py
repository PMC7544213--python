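"""Chemical-shift-perturbation analysis of amide HSQC titrations.

The combined 1H/15N perturbation per residue is

.. math:: \\Delta\\delta = \\sqrt{\\tfrac12\\left(\\Delta\\delta_H^2
          + (0.14\\,\\Delta\\delta_N)^2\\right)}

(the 0.14 weight rescales the wider 15N ppm range onto the 1H scale).
Under fast exchange an observed shift is the population-weighted average of
the free and bound endpoints, with the bound fraction given by the
single-site ligand-depletion quadratic; a global nonlinear fit of the
titration course yields the dissociation constant Kd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import PeakList, Structure, TitrationSeries
from .exceptions import UnidentifiableError, ValidationError

__all__ = [
    "NITROGEN_WEIGHT",
    "csp_distance",
    "csp_per_residue",
    "classify_large",
    "match_peaks",
    "fraction_bound",
    "intensity_attenuation",
    "map_to_structure",
    "TitrationModel",
    "BindingCurveFit",
    "fit_kd_from_titration",
]

#: 15N weight in the combined shift metric
NITROGEN_WEIGHT = 0.14


def csp_distance(dH_ppm, dN_ppm, nitrogen_weight: float = NITROGEN_WEIGHT):
    """Combined shift difference sqrt(0.5*(dH^2 + (w*dN)^2)), ppm."""
    dH = np.asarray(dH_ppm, dtype=float)
    dN = np.asarray(dN_ppm, dtype=float)
    return np.sqrt(0.5 * (dH**2 + (nitrogen_weight * dN) ** 2))


def csp_per_residue(ref: PeakList, other: PeakList,
                    nitrogen_weight: float = NITROGEN_WEIGHT) -> pd.DataFrame:
    """Per-residue shift deviations of ``other`` relative to ``ref``.

    Residues are paired by residue_number.  Returns a DataFrame indexed by
    residue_number with signed ``delta_dH``/``delta_dN`` (other - ref),
    the combined ``csp_avg``, and a ``matched`` flag; residues present in
    only one list appear with ``matched=False`` and NaN deviations.
    """
    a = ref.indexed()
    b = other.indexed()
    all_res = a.index.union(b.index).sort_values()
    common = a.index.intersection(b.index)
    out = pd.DataFrame(index=all_res)
    out.index.name = "residue_number"
    out["delta_dH"] = b["dH_ppm"].reindex(all_res) - a["dH_ppm"].reindex(all_res)
    out["delta_dN"] = b["dN_ppm"].reindex(all_res) - a["dN_ppm"].reindex(all_res)
    out["csp_avg"] = csp_distance(out["delta_dH"], out["delta_dN"], nitrogen_weight)
    out["matched"] = out.index.isin(common)
    out.loc[~out["matched"], ["delta_dH", "delta_dN", "csp_avg"]] = np.nan
    return out


def classify_large(profile: pd.DataFrame, threshold_ppm: float = 0.025) -> set[int]:
    """Residues whose combined CSP strictly exceeds the threshold
    (default 0.025 ppm, the usual cutoff for a significant perturbation)."""
    sel = profile["csp_avg"] > threshold_ppm
    return set(int(r) for r in profile.index[sel.fillna(False)])


def match_peaks(ref: PeakList, other: PeakList, max_dist_ppm: float = 0.1,
                nitrogen_weight: float = NITROGEN_WEIGHT) -> pd.DataFrame:
    """Greedy nearest-neighbour peak correspondence in weighted ppm space.

    Candidate pair distances use the combined-shift metric; pairs are
    accepted in ascending distance, each peak at most once, pairs beyond
    ``max_dist_ppm`` left unmatched.  Returns a DataFrame with columns
    ref_residue, other_residue, distance_ppm; unmatched peaks appear with
    the partner column as <NA>.
    """
    if len(ref) == 0 or len(other) == 0:
        raise ValidationError("peak lists must be non-empty")
    ra = ref.data
    rb = other.data
    dH = rb["dH_ppm"].to_numpy()[None, :] - ra["dH_ppm"].to_numpy()[:, None]
    dN = rb["dN_ppm"].to_numpy()[None, :] - ra["dN_ppm"].to_numpy()[:, None]
    dist = csp_distance(dH, dN, nitrogen_weight)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in order:
        if dist[i, j] > max_dist_ppm:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        pairs.append((int(ra["residue_number"].iloc[i]), int(rb["residue_number"].iloc[j]),
                      float(dist[i, j])))
    for i in range(len(ra)):
        if i not in used_a:
            pairs.append((int(ra["residue_number"].iloc[i]), pd.NA, np.nan))
    for j in range(len(rb)):
        if j not in used_b:
            pairs.append((pd.NA, int(rb["residue_number"].iloc[j]), np.nan))
    return pd.DataFrame(pairs, columns=["ref_residue", "other_residue", "distance_ppm"])


def fraction_bound(P_total_uM: float, L_total_uM: float, Kd_uM: float) -> float:
    """Fraction of protein bound under single-site binding with ligand
    depletion: fb = ((P+L+Kd) - sqrt((P+L+Kd)^2 - 4 P L)) / (2 P)."""
    if P_total_uM <= 0:
        raise ValidationError("P_total must be positive (fraction undefined at P = 0)")
    if L_total_uM < 0 or Kd_uM <= 0:
        raise ValidationError("L_total must be >= 0 and Kd > 0")
    s = P_total_uM + L_total_uM + Kd_uM
    disc = s * s - 4.0 * P_total_uM * L_total_uM
    fb = (s - math.sqrt(max(disc, 0.0))) / (2.0 * P_total_uM)
    return float(min(max(fb, 0.0), 1.0))


def intensity_attenuation(series: TitrationSeries) -> pd.DataFrame:
    """Per-residue intensity ratios I_point / I_reference.

    Columns are the titration ratios; residues with zero reference
    intensity get NaN and are listed in ``result.attrs['zero_reference']``.
    """
    ref = series.reference.indexed()["intensity"]
    out = pd.DataFrame(index=ref.index)
    out.index.name = "residue_number"
    zero = ref.index[ref == 0].tolist()
    for ratio, pl in zip(series.ratios, series.points):
        col = pl.indexed()["intensity"].reindex(ref.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = col / ref
        vals[ref == 0] = np.nan
        out[ratio] = vals
    out.attrs["zero_reference"] = zero
    return out


def map_to_structure(profile: pd.DataFrame, structure: Structure, out_path,
                     scale: float = 100.0) -> None:
    """Paint per-residue CSPs into a PDB B-factor column (csp_avg * scale).

    Residues present in the profile but absent from the structure trigger a
    warning; fully disjoint residue sets are an error.
    """
    from .io import write_pdb

    prof_res = set(int(r) for r in profile.index[profile["csp_avg"].notna()])
    struct_res = set(int(r) for r in structure.residue_numbers)
    if prof_res and not (prof_res & struct_res):
        raise ValidationError("profile and structure residue sets are disjoint")
    missing = sorted(prof_res - struct_res)
    if missing:
        warnings.warn(f"structure lacks residues present in CSP profile: {missing}")
    values = {
        int(res): float(profile.loc[res, "csp_avg"]) * scale
        for res in profile.index
        if not np.isnan(profile.loc[res, "csp_avg"])
    }
    write_pdb(structure, out_path, bfactor_values=values)


@dataclass
class BindingCurveFit:
    """Kd fit of a fast-exchange titration course."""

    Kd_uM: float
    Kd_stderr_uM: float
    delta_bound: pd.DataFrame          # per-residue (dH, dN) endpoint deltas, ppm
    fraction_bound: np.ndarray         # per titration point at the fitted Kd
    residual_norm: float
    n_points: int
    n_residues: int
    mode: str = "global"
    per_residue_Kd: pd.Series | None = None

    def summary(self) -> str:
        lines = [
            f"Fast-exchange titration fit ({self.mode} mode)",
            f"  Kd            : {self.Kd_uM:.3g} +/- {self.Kd_stderr_uM:.2g} uM",
            f"  points        : {self.n_points}   residues: {self.n_residues}",
            f"  residual norm : {self.residual_norm:.4g} ppm",
            "  fraction bound: " + ", ".join(f"{f:.3f}" for f in self.fraction_bound),
        ]
        if self.per_residue_Kd is not None:
            lines.append("  per-residue Kd (uM): " + ", ".join(
                f"{r}:{k:.3g}" for r, k in self.per_residue_Kd.items()))
        return "\n".join(lines)


class TitrationModel:
    """Global fast-exchange binding model for an HSQC titration.

    delta_obs(L) = delta_free + (delta_bound - delta_free) * fb(P, L, Kd)
    per residue and dimension, with one shared Kd (global mode) and linear
    per-residue endpoints.  The endpoints enter linearly, so for any trial
    Kd they are profiled out exactly and the optimisation is over Kd alone
    (variable projection); 15N residuals carry the 0.14 weight so both
    dimensions contribute on a common scale.
    """

    def __init__(self, series: TitrationSeries, P_total_uM: float | None = None,
                 L_totals_uM=None, nitrogen_weight: float = NITROGEN_WEIGHT):
        if len(series) < 3:
            raise ValidationError("Kd fitting requires >= 3 titration points")
        self.series = series
        self.P = float(P_total_uM if P_total_uM is not None else series.protein_conc_uM)
        self.L = np.asarray(
            L_totals_uM if L_totals_uM is not None else series.ligand_totals_uM, float
        )
        if self.L[0] != 0:
            raise ValidationError("first titration point must be ligand-free")
        self.w = nitrogen_weight
        ref = series.reference.indexed()
        res = ref.index
        for pl in series.points[1:]:
            res = res.intersection(pl.indexed().index)
        self.residues = res.sort_values()
        if len(self.residues) == 0:
            raise ValidationError("no residue observed at every titration point")
        # observed deviations from the reference, (n_res, n_points)
        self.dH = np.column_stack([
            pl.indexed()["dH_ppm"].reindex(self.residues) - ref["dH_ppm"].reindex(self.residues)
            for pl in series.points
        ])
        self.dN = np.column_stack([
            pl.indexed()["dN_ppm"].reindex(self.residues) - ref["dN_ppm"].reindex(self.residues)
            for pl in series.points
        ])

    def _fb(self, Kd: float) -> np.ndarray:
        return np.array([fraction_bound(self.P, L, Kd) if L > 0 else 0.0 for L in self.L])

    def _ssr_and_endpoints(self, Kd: float, rows=slice(None)):
        fb = self._fb(Kd)
        denom = float(np.sum(fb * fb))
        dH = self.dH[rows]
        dN = self.dN[rows]
        if denom == 0:
            return np.inf, None, fb
        bH = dH @ fb / denom
        bN = dN @ fb / denom
        rH = dH - np.outer(bH, fb)
        rN = (dN - np.outer(bN, fb)) * self.w
        ssr = float(np.sum(rH**2) + np.sum(rN**2))
        return ssr, (bH, bN), fb

    def _fit_kd(self, rows=slice(None), kd_bounds=(1e-3, 1e6)):
        # identifiability check: any measurable shift at all?
        max_shift = max(np.nanmax(np.abs(self.dH[rows])),
                        self.w * np.nanmax(np.abs(self.dN[rows])))
        if max_shift < 1e-6:
            raise UnidentifiableError(
                "titration shows no chemical-shift change; Kd unidentifiable "
                "(flat residual surface)"
            )
        res = minimize_scalar(
            lambda lk: self._ssr_and_endpoints(math.exp(lk), rows)[0],
            bounds=(math.log(kd_bounds[0]), math.log(kd_bounds[1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            from .exceptions import FitError
            raise FitError("Kd optimisation did not converge", last_iterate=res.x)
        return math.exp(res.x)

    def fit(self, mode: str = "global") -> BindingCurveFit:
        if mode not in ("global", "per_residue"):
            raise ValidationError(f"unknown mode '{mode}'")
        kd = self._fit_kd()
        ssr, (bH, bN), fb = self._ssr_and_endpoints(kd)
        n_obs = 2 * self.dH.size
        dof = max(n_obs - (1 + 2 * len(self.residues)), 1)
        s2 = ssr / dof
        # curvature of the profiled SSR in Kd -> standard error
        h = max(kd * 1e-4, 1e-8)
        f0 = ssr
        fp = self._ssr_and_endpoints(kd + h)[0]
        fm = self._ssr_and_endpoints(max(kd - h, 1e-12))[0]
        curv = (fp - 2 * f0 + fm) / (h * h)
        stderr = math.sqrt(2.0 * s2 / curv) if curv > 0 else float("inf")
        per_res = None
        if mode == "per_residue":
            kds = {}
            for i, r in enumerate(self.residues):
                kds[int(r)] = self._fit_kd(rows=slice(i, i + 1))
            per_res = pd.Series(kds, name="Kd_uM")
        endpoints = pd.DataFrame(
            {"delta_bound_dH": bH, "delta_bound_dN": bN}, index=self.residues
        )
        return BindingCurveFit(
            Kd_uM=float(kd),
            Kd_stderr_uM=float(stderr),
            delta_bound=endpoints,
            fraction_bound=fb,
            residual_norm=math.sqrt(ssr),
            n_points=len(self.series),
            n_residues=len(self.residues),
            mode=mode,
            per_residue_Kd=per_res,
        )


def fit_kd_from_titration(series: TitrationSeries, P_total_uM: float | None = None,
                          L_totals_uM=None, mode: str = "global") -> BindingCurveFit:
    """Convenience wrapper: build a TitrationModel and fit it."""
    return TitrationModel(series, P_total_uM, L_totals_uM).fit(mode=mode)
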