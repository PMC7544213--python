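"""Core in-memory containers shared across the analysis stages.

Tabular payloads are pandas DataFrames with fixed column contracts (the same
column names the TSV readers/writers use); thin dataclasses wrap them with
the metadata each stage needs (spectrometer field, cell geometry, domain
boundaries, ...).  Invariants are checked on construction: hard violations
raise :class:`~tandemrrm.exceptions.ValidationError`, soft ones emit
``UserWarning``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "PeakList",
    "TitrationSeries",
    "Structure",
    "RdcSet",
    "RelaxationSet",
    "DecayCurve",
    "InjectionSchedule",
    "Isotherm",
]

PEAKLIST_COLUMNS = ["residue_number", "residue_name", "dH_ppm", "dN_ppm", "intensity"]
RDC_COLUMNS = ["residue_number", "D_obs_Hz"]
RELAXATION_COLUMNS = ["residue_number", "R1_s", "R2_s", "hetNOE"]


@dataclass
class PeakList:
    """Amide peak list: one row per assigned backbone NH cross-peak.

    Parameters
    ----------
    data
        DataFrame with columns ``residue_number`` (int, unique),
        ``residue_name`` (1- or 3-letter code), ``dH_ppm``, ``dN_ppm``,
        ``intensity`` (>= 0, arbitrary units).
    label
        Free-text tag, e.g. the titration point ``"1:3"``.
    """

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).reset_index(drop=True)
        missing = [c for c in PEAKLIST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"peak list missing columns: {missing}")
        df["residue_number"] = df["residue_number"].astype(int)
        for col in ("dH_ppm", "dN_ppm", "intensity"):
            df[col] = df[col].astype(float)
        dup = df["residue_number"][df["residue_number"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate residue_number in peak list: {sorted(set(dup))}"
            )
        if (df["intensity"] < 0).any():
            raise ValidationError("negative intensity in peak list")
        out_h = df[(df["dH_ppm"] < 0) | (df["dH_ppm"] > 14)]
        if len(out_h):
            warnings.warn(
                f"dH_ppm outside [0, 14] for residues {out_h['residue_number'].tolist()}"
            )
        out_n = df[(df["dN_ppm"] < 90) | (df["dN_ppm"] > 140)]
        if len(out_n):
            warnings.warn(
                f"dN_ppm outside [90, 140] for residues {out_n['residue_number'].tolist()}"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue_number"].to_numpy()

    def indexed(self) -> pd.DataFrame:
        """Data indexed by residue_number."""
        return self.data.set_index("residue_number")


@dataclass
class TitrationSeries:
    """Peak lists recorded along a ligand titration.

    ``ratios`` are ligand:protein molar ratios, nondecreasing with the first
    point the ligand-free reference.  ``protein_conc_uM`` is the (constant)
    observed-species concentration; ligand totals are ``ratios * protein``.
    """

    points: Sequence[PeakList]
    ratios: Sequence[float]
    protein_conc_uM: float

    def __post_init__(self) -> None:
        if len(self.points) != len(self.ratios):
            raise ValidationError("one peak list required per titration ratio")
        r = np.asarray(self.ratios, dtype=float)
        if len(r) == 0:
            raise ValidationError("empty titration")
        if r[0] != 0:
            raise ValidationError("first titration point must be the apo reference (ratio 0)")
        if (np.diff(r) < 0).any() or (r < 0).any():
            raise ValidationError("titration ratios must be nonnegative and nondecreasing")
        self.ratios = r

    @property
    def reference(self) -> PeakList:
        return self.points[0]

    @property
    def ligand_totals_uM(self) -> np.ndarray:
        return self.ratios * float(self.protein_conc_uM)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Structure:
    """Protein coordinates: backbone (or all-atom) records in Å.

    ``atoms`` columns: residue_number, residue_name, atom_name, x, y, z.
    ``domains`` maps a label to an inclusive residue range, e.g.
    ``{"RRM1": (1, 93), "RRM2": (94, 189)}``; ranges must be disjoint.
    ``meta`` carries generator provenance (seed, recorded inter-domain
    rotation, ...).
    """

    atoms: pd.DataFrame
    domains: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.atoms).reset_index(drop=True)
        needed = ["residue_number", "residue_name", "atom_name", "x", "y", "z"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValidationError(f"structure missing columns: {missing}")
        df["residue_number"] = df["residue_number"].astype(int)
        for col in ("x", "y", "z"):
            df[col] = df[col].astype(float)
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise ValidationError("non-finite coordinates in structure")
        ranges = sorted(self.domains.items(), key=lambda kv: kv[1][0])
        for (la, (a0, a1)), (lb, (b0, b1)) in zip(ranges, ranges[1:]):
            if b0 <= a1:
                raise ValidationError(f"domain ranges overlap: {la} {a0}-{a1}, {lb} {b0}-{b1}")
        self.atoms = df

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.atoms["residue_number"].to_numpy())

    def coords(self, atom_name: str) -> pd.DataFrame:
        """x,y,z of one named atom per residue, indexed by residue_number."""
        sel = self.atoms[self.atoms["atom_name"] == atom_name]
        return sel.set_index("residue_number")[["x", "y", "z"]]

    def domain_of(self, residue_number: int) -> str | None:
        for label, (lo, hi) in self.domains.items():
            if lo <= residue_number <= hi:
                return label
        return None

    def domain_residues(self, label: str) -> np.ndarray:
        lo, hi = self.domains[label]
        res = self.residue_numbers
        return res[(res >= lo) & (res <= hi)]


@dataclass
class RdcSet:
    """Observed one-bond amide N-H residual dipolar couplings (Hz).

    Columns: residue_number (unique), D_obs_Hz, optional D_err_Hz, optional
    domain label.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).reset_index(drop=True)
        missing = [c for c in RDC_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"RDC table missing columns: {missing}")
        df["residue_number"] = df["residue_number"].astype(int)
        df["D_obs_Hz"] = df["D_obs_Hz"].astype(float)
        dup = df["residue_number"][df["residue_number"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate residue_number in RDC table: {sorted(set(dup))}")
        big = df[np.abs(df["D_obs_Hz"]) >= 60]
        if len(big):
            warnings.warn(
                f"|D_obs| >= 60 Hz (unusual for 1D_NH) at residues "
                f"{big['residue_number'].tolist()}"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue_number"].to_numpy()


@dataclass
class RelaxationSet:
    """Per-residue 15N relaxation rates at one field.

    Columns: residue_number, R1_s (s^-1), R2_s (s^-1), hetNOE.
    """

    data: pd.DataFrame
    field_MHz_1H: float = 500.0
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).reset_index(drop=True)
        missing = [c for c in RELAXATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"relaxation table missing columns: {missing}")
        df["residue_number"] = df["residue_number"].astype(int)
        for col in ("R1_s", "R2_s", "hetNOE"):
            df[col] = df[col].astype(float)
        if (df["R1_s"] <= 0).any() or (df["R2_s"] <= 0).any():
            raise ValidationError("R1 and R2 must be positive")
        high = df[df["hetNOE"] > 1.2]
        if len(high):
            warnings.warn(
                f"hetNOE > 1.2 (theoretical rigid limit exceeded) at residues "
                f"{high['residue_number'].tolist()}"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DecayCurve:
    """Single-residue intensity-vs-delay relaxation decay."""

    delays_ms: np.ndarray
    intensities: np.ndarray
    residue_number: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.delays_ms, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape:
            raise ValidationError("delays and intensities must have equal length")
        if len(t) < 3:
            raise ValidationError("decay curve needs >= 3 delay points")
        if len(np.unique(t)) != len(t):
            raise ValidationError("decay delays must be distinct")
        self.delays_ms = t
        self.intensities = y


@dataclass
class InjectionSchedule:
    """ITC injection schedule and cell composition.

    Convention (as in the experiments this models): the protein is the
    titrant in the syringe, the RNA the titrand in the cell.  ``use_flags``
    marks injections included in fitting (small pre-injections get 0 but are
    still tracked in the concentration bookkeeping).
    """

    volumes_ul: np.ndarray
    cell_volume_ml: float = 1.4
    syringe_conc_uM: float = 100.0
    cell_conc_uM: float = 10.0
    temperature_C: float = 25.0
    use_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_ul, dtype=float)
        if len(v) == 0 or (v <= 0).any():
            raise ValidationError("injection volumes must be positive")
        if self.cell_volume_ml <= 0:
            raise ValidationError("cell volume must be positive")
        if self.use_flags is None:
            flags = np.ones(len(v), dtype=int)
        else:
            flags = np.asarray(self.use_flags, dtype=int)
            if flags.shape != v.shape:
                raise ValidationError("use_flags must match injection count")
        if flags.sum() < 1:
            raise ValidationError("at least one usable injection required")
        self.volumes_ul = v
        self.use_flags = flags

    def __len__(self) -> int:
        return len(self.volumes_ul)

    @classmethod
    def standard(
        cls,
        n_injections: int = 30,
        syringe_conc_uM: float = 100.0,
        cell_conc_uM: float = 10.0,
        n_pre: int = 1,
        pre_volume_ul: float = 2.0,
        volume_ul: float = 10.0,
        cell_volume_ml: float = 1.4,
        temperature_C: float = 25.0,
    ) -> "InjectionSchedule":
        """The bench-standard schedule: ``n_pre`` small pre-injections
        (excluded from fitting) followed by equal main injections."""
        vols = np.concatenate(
            [np.full(n_pre, pre_volume_ul), np.full(n_injections - n_pre, volume_ul)]
        )
        flags = np.concatenate([np.zeros(n_pre, dtype=int), np.ones(n_injections - n_pre, dtype=int)])
        return cls(
            volumes_ul=vols,
            cell_volume_ml=cell_volume_ml,
            syringe_conc_uM=syringe_conc_uM,
            cell_conc_uM=cell_conc_uM,
            temperature_C=temperature_C,
            use_flags=flags,
        )


@dataclass
class Isotherm:
    """Integrated injection heats plus the schedule that produced them."""

    schedule: InjectionSchedule
    heats_ucal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.heats_ucal, dtype=float)
        if len(q) != len(self.schedule):
            raise ValidationError("one heat required per injection")
        self.heats_ucal = q

    def __len__(self) -> int:
        return len(self.heats_ucal)

    @property
    def molar_ratio(self) -> np.ndarray:
        """Cumulative titrant:titrand molar ratio in the cell after each
        injection (displacement-corrected)."""
        from .itc import concentration_series

        titrant, titrand = concentration_series(self.schedule)
        return titrant / titrand

    @property
    def usable(self) -> np.ndarray:
        return self.schedule.use_flags.astype(bool)
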