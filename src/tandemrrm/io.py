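"""Readers and writers for the package's plain-text formats.

All tabular formats are TSV/CSV with mandatory headers; ``#`` starts a
comment line anywhere.  PDB reading goes through Biopython's parser; the
writer emits the fixed-column ATOM subset directly so that per-residue
scalars (e.g. chemical-shift perturbations) can be painted into the
B-factor column.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .containers import (
    DecayCurve,
    InjectionSchedule,
    Isotherm,
    PeakList,
    RdcSet,
    RelaxationSet,
    Structure,
)
from .exceptions import ParseError, ValidationError

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_rdc_table",
    "write_rdc_table",
    "read_relaxation_table",
    "write_relaxation_table",
    "read_decay_table",
    "write_decay_table",
    "read_isotherm",
    "write_isotherm",
    "read_pdb",
    "write_pdb",
]


def _read_table(path, required, numeric):
    """Shared TSV/CSV reader: header row mandatory, '#' comments skipped,
    separator sniffed between tab and comma."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ParseError(f"{path}: no data lines")
    sep = "\t" if "\t" in lines[0] else ","
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            raise ParseError(
                f"{path}: non-numeric value in column '{col}' at data line {bad[0] + 2}"
            )
        df[col] = coerced
    return df


def read_peaklist(path, label: str = "") -> PeakList:
    """Read a TSV/CSV peak list (residue_number, residue_name, dH_ppm,
    dN_ppm, intensity)."""
    df = _read_table(
        path,
        required=["residue_number", "residue_name", "dH_ppm", "dN_ppm", "intensity"],
        numeric=["residue_number", "dH_ppm", "dN_ppm", "intensity"],
    )
    try:
        return PeakList(df, label=label or Path(path).stem)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_peaklist(peaklist: PeakList, path) -> None:
    with open(path, "w") as fh:
        if peaklist.label:
            fh.write(f"# label={peaklist.label}\n")
        peaklist.data.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_rdc_table(path) -> RdcSet:
    """Read a TSV/CSV RDC table (residue_number, D_obs_Hz [, D_err_Hz, domain])."""
    df = _read_table(
        path,
        required=["residue_number", "D_obs_Hz"],
        numeric=["residue_number", "D_obs_Hz", "D_err_Hz"],
    )
    try:
        return RdcSet(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_rdc_table(rdcs: RdcSet, path) -> None:
    rdcs.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_relaxation_table(path, field_MHz_1H=500.0, temperature_K=298.15) -> RelaxationSet:
    """Read a TSV/CSV relaxation rate table (residue_number, R1_s, R2_s, hetNOE)."""
    df = _read_table(
        path,
        required=["residue_number", "R1_s", "R2_s", "hetNOE"],
        numeric=["residue_number", "R1_s", "R2_s", "hetNOE"],
    )
    try:
        return RelaxationSet(df, field_MHz_1H=field_MHz_1H, temperature_K=temperature_K)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_relaxation_table(rset: RelaxationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# field_MHz_1H={rset.field_MHz_1H:g}\n")
        fh.write(f"# temperature_K={rset.temperature_K:g}\n")
        rset.data.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_decay_table(path) -> list[DecayCurve]:
    """Read a long-format decay table (residue_number, delay_ms, intensity)
    into one DecayCurve per residue."""
    df = _read_table(
        path,
        required=["residue_number", "delay_ms", "intensity"],
        numeric=["residue_number", "delay_ms", "intensity"],
    )
    curves = []
    for res, grp in df.groupby("residue_number", sort=True):
        curves.append(
            DecayCurve(
                delays_ms=grp["delay_ms"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                residue_number=int(res),
            )
        )
    return curves


def write_decay_table(curves, path) -> None:
    rows = []
    for c in curves:
        for t, y in zip(c.delays_ms, c.intensities):
            rows.append((c.residue_number, t, y))
    pd.DataFrame(rows, columns=["residue_number", "delay_ms", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


# --- isotherm CSV -----------------------------------------------------------

_ISO_HEADER_KEYS = {
    "cell_volume_mL": "cell_volume_ml",
    "syringe_conc_uM": "syringe_conc_uM",
    "cell_conc_uM": "cell_conc_uM",
    "temperature_C": "temperature_C",
}


def read_isotherm(path) -> Isotherm:
    """Read an isotherm CSV.

    Header comment lines carry the experiment metadata
    (``# cell_volume_mL=``, ``# syringe_conc_uM=``, ``# cell_conc_uM=``,
    ``# temperature_C=``); data rows are
    ``injection_index,volume_uL,heat_ucal,use_flag``.
    """
    meta = {}
    data_lines = []
    for ln in Path(path).read_text().splitlines():
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in _ISO_HEADER_KEYS:
                    meta[_ISO_HEADER_KEYS[key]] = float(val)
            continue
        data_lines.append(s)
    missing = [k for k, v in _ISO_HEADER_KEYS.items() if v not in meta]
    if missing:
        raise ParseError(f"{path}: missing isotherm header lines for {missing}")
    if not data_lines:
        raise ParseError(f"{path}: no injection rows")
    df = pd.read_csv(
        _io.StringIO("\n".join(data_lines)),
        names=["injection_index", "volume_uL", "heat_ucal", "use_flag"],
    )
    schedule = InjectionSchedule(
        volumes_ul=df["volume_uL"].to_numpy(float),
        cell_volume_ml=meta["cell_volume_ml"],
        syringe_conc_uM=meta["syringe_conc_uM"],
        cell_conc_uM=meta["cell_conc_uM"],
        temperature_C=meta["temperature_C"],
        use_flags=df["use_flag"].to_numpy(int),
    )
    return Isotherm(schedule=schedule, heats_ucal=df["heat_ucal"].to_numpy(float))


def write_isotherm(isotherm: Isotherm, path) -> None:
    sch = isotherm.schedule
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_mL={sch.cell_volume_ml:g}\n")
        fh.write(f"# syringe_conc_uM={sch.syringe_conc_uM:g}\n")
        fh.write(f"# cell_conc_uM={sch.cell_conc_uM:g}\n")
        fh.write(f"# temperature_C={sch.temperature_C:g}\n")
        for i, (v, q, f) in enumerate(
            zip(sch.volumes_ul, isotherm.heats_ucal, sch.use_flags), start=1
        ):
            fh.write(f"{i},{v:.6g},{q:.8g},{int(f)}\n")


# --- PDB --------------------------------------------------------------------


def read_pdb(path, model_index: int = 1, chain_id: str | None = None) -> Structure:
    """Read the ATOM subset of a PDB file into a Structure.

    ``model_index`` is 1-based; files without MODEL records count as a
    single model.  Alternate locations other than blank/'A' are dropped.
    Residue numbering is taken verbatim from the file.
    """
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise ParseError(f"{path}: no ATOM records")
    if not 1 <= model_index <= len(models):
        raise ParseError(f"{path}: model_index {model_index} out of range (1..{len(models)})")
    model = models[model_index - 1]
    chains = {ch.id: ch for ch in model.get_chains()}
    if chain_id is None:
        use = list(chains.values())
    elif chain_id in chains:
        use = [chains[chain_id]]
    else:
        raise ParseError(
            f"{path}: chain '{chain_id}' absent; available chains: {sorted(chains)}"
        )
    rows = []
    for chain in use:
        for res in chain.get_residues():
            hetflag, resseq, _icode = res.id
            if hetflag.strip():
                continue  # skip HETATM/water
            for atom in res.get_atoms():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                x, y, z = atom.get_coord()
                rows.append(
                    (int(resseq), res.get_resname().strip(), atom.get_name().strip(),
                     float(x), float(y), float(z))
                )
    if not rows:
        raise ParseError(f"{path}: no ATOM records")
    df = pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom_name", "x", "y", "z"])
    return Structure(atoms=df, meta={"source": str(path), "model_index": model_index})


_PDB_ELEMENT = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def write_pdb(structure: Structure, path, bfactor_values: Mapping[int, float] | None = None) -> None:
    """Write fixed-column PDB ATOM records.

    ``bfactor_values`` maps residue_number -> scalar painted into the
    B-factor column (%6.2f, clipped to [0, 999.99]); residues without a
    value get 0.00.
    """
    bf = dict(bfactor_values or {})
    with open(path, "w") as fh:
        serial = 0
        last_res = None
        for row in structure.atoms.itertuples(index=False):
            serial += 1
            resname = row.residue_name[:3].upper()
            value = float(bf.get(int(row.residue_number), 0.0))
            value = min(max(value, 0.0), 999.99)
            name = row.atom_name
            # columns 13-16: 1-letter element names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            element = _PDB_ELEMENT.get(name, name[0])
            fh.write(
                f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} A"
                f"{int(row.residue_number):4d}    "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{1.0:6.2f}{value:6.2f}"
                f"          {element:>2s}\n"
            )
            last_res = (resname, int(row.residue_number))
        if last_res is not None:
            fh.write(f"TER   {serial + 1:5d}      {last_res[0]:>3s} A{last_res[1]:4d}\n")
        fh.write("END\n")
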