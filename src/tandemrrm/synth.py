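"""Synthetic-data generators for every input class of the pipeline.

Each generator draws from the forward model its matching analysis stage
inverts, so a zero-noise round trip recovers the generating parameters:

* toy protein structures (ideal helix/strand, torsion-sampled coil, or two
  coil domains with a recorded inter-domain rotation) with full backbone
  geometry including amide protons;
* RDC sets from a known alignment tensor (or one tensor per domain)
  applied to the structure's N-H vectors plus Gaussian noise;
* 15N relaxation tables (or raw decay series at the standard delay
  schedules) from rigid/model-free rates at a stated field;
* fast-exchange HSQC titration series with ligand-depletion binding,
  including fast-exchange-limit broadening Rex = pf*pb*dw^2/kex;
* ITC isotherms from the one-site or sequential two-site forward model.

All randomness comes from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    DecayCurve,
    InjectionSchedule,
    Isotherm,
    PeakList,
    RdcSet,
    RelaxationSet,
    Structure,
    TitrationSeries,
)
from .csp import fraction_bound
from .exceptions import GeometryError, ValidationError
from .itc import OneSiteParams, TwoSiteParams, heats_one_site, heats_two_site
from .rdc import AlignmentTensor, back_calc_rdc, nh_unit_vectors
from .relaxation import (
    NU_N_PER_NU_H,
    R1_DELAYS_MS,
    R2_DELAYS_MS,
    forward_relaxation_rates,
)

__all__ = [
    "NoiseSpec",
    "ExchangeSpec",
    "gen_structure",
    "gen_rdc_set",
    "gen_relaxation_set",
    "gen_decay_curves",
    "gen_titration",
    "gen_isotherm",
]


@dataclass
class NoiseSpec:
    """Additive Gaussian noise: sd in the units of the perturbed signal."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def draw(self, shape):
        if self.sd == 0:
            return np.zeros(shape)
        return np.random.default_rng(self.seed).normal(0.0, self.sd, size=shape)


@dataclass
class ExchangeSpec:
    """Two-state binding exchange for a titration generator.

    ``delta_bound`` maps residue_number -> (dH_ppm, dN_ppm) endpoint shifts
    of the bound state relative to free.  ``kex`` (s^-1) switches on
    fast-exchange-limit broadening; ``R2_0`` is the baseline linewidth
    proxy the broadening is measured against.
    """

    Kd_uM: float
    delta_bound: dict
    kex_s: float | None = None
    R2_0_s: float = 15.0

    def __post_init__(self):
        if self.Kd_uM <= 0:
            raise ValidationError("Kd must be positive")
        if self.kex_s is not None and self.kex_s <= 0:
            raise ValidationError("kex must be positive when given")


# ideal backbone internal coordinates (Engh-Huber-like)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.02}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}

_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF atom placement: position d with |cd|=bond, angle(b,c,d) and
    torsion(a,b,c,d) given in degrees."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _chain_torsions(n_residues: int, geometry: str, rng) -> list[tuple[float, float]]:
    if geometry in _TORSIONS:
        return [_TORSIONS[geometry]] * n_residues
    if geometry == "coil":
        # alternate 3-residue blocks between jittered alpha and beta basins:
        # reorients the chain every few residues, spreading N-H directions
        out = []
        for i in range(n_residues):
            base = _TORSIONS["helix"] if (i // 3) % 2 == 0 else _TORSIONS["strand"]
            out.append((base[0] + rng.uniform(-25, 25), base[1] + rng.uniform(-25, 25)))
        return out
    raise ValidationError(f"unknown geometry '{geometry}'")


def _build_backbone(n_residues: int, torsions, start_res: int = 1) -> pd.DataFrame:
    """Backbone N, H, CA, C, O atoms with ideal covalent geometry."""
    # seed the first three atoms
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords = {start_res: {"N": n0, "CA": ca0, "C": c0}}
    for i in range(1, n_residues):
        res = start_res + i
        prev = coords[res - 1]
        phi, psi = torsions[i]
        # psi of previous residue fixes N(i); omega = 180 fixes CA(i); phi fixes C(i)
        n_i = _place(prev["N"], prev["CA"], prev["C"], _BOND["C-N"],
                     _ANGLE["CA-C-N"], torsions[i - 1][1])
        ca_i = _place(prev["CA"], prev["C"], n_i, _BOND["N-CA"],
                      _ANGLE["C-N-CA"], 180.0)
        c_i = _place(prev["C"], n_i, ca_i, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        coords[res] = {"N": n_i, "CA": ca_i, "C": c_i}
    rows = []
    residues = sorted(coords)
    for idx, res in enumerate(residues):
        at = coords[res]
        rows.append((res, "ALA", "N", *at["N"]))
        # amide H: 1.02 A from N, in the C'(i-1)-N-CA plane, anti to the
        # bond bisector (absent for the first residue)
        if res - 1 in coords:
            u = at["N"] - coords[res - 1]["C"]
            v = at["N"] - at["CA"]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            h = at["N"] + _BOND["N-H"] * (u + v) / np.linalg.norm(u + v)
            rows.append((res, "ALA", "H", *h))
        rows.append((res, "ALA", "CA", *at["CA"]))
        rows.append((res, "ALA", "C", *at["C"]))
        # carbonyl O: anti to the next residue's N, i.e. at torsion
        # psi - 180 about the CA-C bond measured from N(i)
        psi = torsions[idx][1]
        o = _place(at["N"], at["CA"], at["C"], _BOND["C-O"], _ANGLE["CA-C-O"], psi - 180.0)
        rows.append((res, "ALA", "O", *o))
    return pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom_name", "x", "y", "z"])


def _rotation_matrix(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def gen_structure(n_residues: int, geometry: str = "helix", seed: int = 0,
                  rotation_deg: float = 90.0, translation_A: float = 30.0) -> Structure:
    """Generate a toy backbone structure.

    ``geometry``: "helix" (ideal alpha), "strand" (ideal beta), "coil"
    (seeded torsion sampling across the alpha/beta basins, giving
    orientationally well-spread N-H vectors), or "two_domain" (two coil
    domains of ``n_residues`` each; the second is rotated by
    ``rotation_deg`` about the x axis and translated by ``translation_A``,
    and the exact rotation is recorded in ``meta``).
    """
    if n_residues < 5:
        raise ValidationError("n_residues >= 5 required (tensor fitting needs >= 5 vectors)")
    rng = np.random.default_rng(seed)
    if geometry == "two_domain":
        # one continuous coil chain; the second half is then rigidly rotated
        # about x and translated, so every residue keeps its amide proton
        atoms = _build_backbone(2 * n_residues,
                                _chain_torsions(2 * n_residues, "coil", rng), start_res=1)
        R = _rotation_matrix([1.0, 0.0, 0.0], rotation_deg)
        second = atoms["residue_number"] > n_residues
        xyz = atoms.loc[second, ["x", "y", "z"]].to_numpy()
        xyz = (xyz - xyz.mean(axis=0)) @ R.T + xyz.mean(axis=0)
        xyz[:, 0] += translation_A
        atoms.loc[second, ["x", "y", "z"]] = xyz
        return Structure(
            atoms=atoms,
            domains={"D1": (1, n_residues), "D2": (n_residues + 1, 2 * n_residues)},
            meta={"geometry": geometry, "seed": seed, "rotation_deg": float(rotation_deg),
                  "translation_A": float(translation_A)},
        )
    atoms = _build_backbone(n_residues, _chain_torsions(n_residues, geometry, rng))
    return Structure(atoms=atoms, meta={"geometry": geometry, "seed": seed})


def gen_rdc_set(structure: Structure, tensor, noise: NoiseSpec | None = None,
                residues=None) -> RdcSet:
    """RDCs back-calculated from an alignment tensor plus Gaussian noise.

    ``tensor`` is a single AlignmentTensor, or a mapping of domain label ->
    tensor for a domain-labelled structure (each domain's couplings then
    come from its own tensor, emulating independently aligning domains).
    """
    noise = noise or NoiseSpec()
    vectors = nh_unit_vectors(structure, residues=residues)
    if isinstance(tensor, AlignmentTensor):
        per_res_tensor = {int(r): tensor for r in vectors.index}
    else:
        per_res_tensor = {}
        for lab, t in dict(tensor).items():
            lo, hi = structure.domains[lab]
            for r in vectors.index:
                if lo <= r <= hi:
                    per_res_tensor[int(r)] = t
        vectors = vectors.loc[[r for r in vectors.index if int(r) in per_res_tensor]]
    d = np.array([
        back_calc_rdc(per_res_tensor[int(r)], vectors.loc[[r]])[0] for r in vectors.index
    ])
    d = d + noise.draw(len(d))
    df = pd.DataFrame({
        "residue_number": vectors.index.to_numpy(int),
        "D_obs_Hz": d,
    })
    if noise.sd > 0:
        df["D_err_Hz"] = noise.sd
    if structure.domains:
        df["domain"] = [structure.domain_of(int(r)) for r in df["residue_number"]]
    return RdcSet(df, meta={"noise_sd": noise.sd, "seed": noise.seed})


def gen_relaxation_set(tau_c_ns: float, field_MHz_1H: float, n_residues: int,
                       S2_profile=None, noise: NoiseSpec | None = None,
                       seed: int = 0, temperature_K: float = 298.15) -> RelaxationSet:
    """Per-residue relaxation rates from the rigid/model-free forward model.

    ``S2_profile`` is an optional array (length n_residues) of order
    parameters; default rigid (S2 = 1).  Flexible residues (S2 < 1) use a
    100 ps internal correlation time.
    """
    if tau_c_ns <= 0:
        raise ValidationError("tau_c must be positive")
    noise = noise or NoiseSpec(seed=seed)
    s2 = np.ones(n_residues) if S2_profile is None else np.asarray(S2_profile, float)
    if len(s2) != n_residues:
        raise ValidationError("S2_profile length must equal n_residues")
    rows = []
    for i in range(n_residues):
        r1, r2, noe = forward_relaxation_rates(
            tau_c_ns, field_MHz_1H, S2=float(s2[i]),
            tau_e_ns=0.1 if s2[i] < 1.0 else 0.0,
        )
        rows.append((i + 1, r1, r2, noe))
    df = pd.DataFrame(rows, columns=["residue_number", "R1_s", "R2_s", "hetNOE"])
    rng = np.random.default_rng(noise.seed)
    if noise.sd > 0:
        # relative noise on rates, absolute on the NOE
        df["R1_s"] *= 1.0 + rng.normal(0, noise.sd, n_residues)
        df["R2_s"] *= 1.0 + rng.normal(0, noise.sd, n_residues)
        df["hetNOE"] += rng.normal(0, noise.sd, n_residues)
    return RelaxationSet(df, field_MHz_1H=field_MHz_1H, temperature_K=temperature_K)


def _nearest_schedule(field_MHz_1H: float, table) -> tuple:
    key = min(table, key=lambda f: abs(f - field_MHz_1H))
    return table[key]


def gen_decay_curves(rates_s, field_MHz_1H: float = 500.0, kind: str = "R1",
                     I0: float = 1e6, noise: NoiseSpec | None = None) -> list[DecayCurve]:
    """Exponential decay series I0*exp(-R t) at the standard delay
    schedules for the given experiment kind ("R1" or "R2") and field."""
    noise = noise or NoiseSpec()
    delays = np.array(_nearest_schedule(field_MHz_1H, R1_DELAYS_MS if kind == "R1" else R2_DELAYS_MS))
    curves = []
    rng = np.random.default_rng(noise.seed)
    for i, rate in enumerate(np.atleast_1d(rates_s)):
        y = I0 * np.exp(-rate * delays / 1e3)
        if noise.sd > 0:
            y = y * (1.0 + rng.normal(0, noise.sd, len(delays)))
        curves.append(DecayCurve(delays_ms=delays.copy(), intensities=y, residue_number=i + 1))
    return curves


def gen_titration(ref: PeakList, exchange: ExchangeSpec, protein_conc_uM: float,
                  ligand_ratios, noise: NoiseSpec | None = None, seed: int = 0,
                  field_MHz_1H: float = 850.0, broadening: bool = False) -> TitrationSeries:
    """Fast-exchange HSQC titration series.

    Observed shifts are population-weighted averages,
    delta_obs = (1-fb) delta_free + fb delta_bound, with the bound fraction
    from the single-site depletion quadratic.  With ``broadening`` the
    intensities are attenuated by R2_0/(R2_0 + Rex) with the
    fast-exchange-limit Rex = pf*pb*dw^2/kex, dw (rad/s) taken from the
    larger of the two dimensions' endpoint shift differences.
    """
    ratios = np.asarray(ligand_ratios, float)
    if ratios[0] != 0 or (np.diff(ratios) < 0).any() or (ratios < 0).any():
        raise ValidationError("ligand ratios must start at 0 and be nondecreasing")
    if broadening and exchange.kex_s is None:
        raise ValidationError("broadening requested but ExchangeSpec.kex_s not set")
    noise = noise or NoiseSpec(seed=seed)
    rng = np.random.default_rng(noise.seed)
    nu_h = field_MHz_1H * 1e6
    nu_n = field_MHz_1H * NU_N_PER_NU_H * 1e6
    points = []
    for ratio in ratios:
        L = ratio * protein_conc_uM
        fb = fraction_bound(protein_conc_uM, L, exchange.Kd_uM) if L > 0 else 0.0
        rows = []
        for row in ref.data.itertuples(index=False):
            res = int(row.residue_number)
            dbH, dbN = exchange.delta_bound.get(res, (0.0, 0.0))
            dh = row.dH_ppm + fb * dbH
            dn = row.dN_ppm + fb * dbN
            inten = row.intensity
            if broadening:
                dw = 2.0 * math.pi * max(abs(dbH) * 1e-6 * nu_h, abs(dbN) * 1e-6 * nu_n)
                rex = (1.0 - fb) * fb * dw**2 / exchange.kex_s
                inten = inten * exchange.R2_0_s / (exchange.R2_0_s + rex)
            if noise.sd > 0:
                dh += rng.normal(0, noise.sd)
                dn += rng.normal(0, noise.sd / 0.14)
            rows.append((res, row.residue_name, dh, dn, inten))
        points.append(PeakList(
            pd.DataFrame(rows, columns=["residue_number", "residue_name", "dH_ppm",
                                        "dN_ppm", "intensity"]),
            label=f"1:{ratio:g}",
        ))
    return TitrationSeries(points=points, ratios=ratios, protein_conc_uM=protein_conc_uM)


def gen_isotherm(model, schedule: InjectionSchedule, noise: NoiseSpec | None = None,
                 seed: int = 0) -> Isotherm:
    """Isotherm from the matching forward model plus Gaussian heat noise.

    ``model`` is a OneSiteParams or TwoSiteParams instance.
    """
    noise = noise or NoiseSpec(seed=seed)
    if isinstance(model, OneSiteParams):
        q = heats_one_site(model, schedule)
    elif isinstance(model, TwoSiteParams):
        q = heats_two_site(model, schedule)
    else:
        raise ValidationError("model must be OneSiteParams or TwoSiteParams")
    q = q + noise.draw(len(q))
    return Isotherm(schedule=schedule, heats_ucal=q,
                    meta={"noise_sd": noise.sd, "seed": noise.seed,
                          "model": type(model).__name__})
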