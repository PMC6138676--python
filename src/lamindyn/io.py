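"""File readers and writers for every pipeline input and output.

Formats:

* intensity tables — TSV with columns ``residue_number, residue_name,
  experiment, delay_s, intensity, noise_rms`` where ``experiment`` is one of
  ``R1``, ``R2``, ``NOE_sat``, ``NOE_ref`` (delay empty for NOE rows);
* shift tables — TSV with ``residue_number, residue_name, dHN_ppm, dN_ppm,
  dCA_ppm`` or Sparky-style ``.list`` lines (``F451N-H  118.23  8.56``) for
  amide pairs;
* thermograms — TSV with ``temperature_C, cp_kcal_per_mol_K``;
* structures — PDB via biotite; multi-model files become ensembles,
  coordinates are converted Angstrom <-> nanometre at the boundary;
* per-residue results — CSV.

Readers log malformed rows with their line numbers and never silently
impute missing data.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from lamindyn.csp import ShiftTable
from lamindyn.dsc import CELSIUS_OFFSET, Thermogram
from lamindyn.ensemble import CoordinateEnsemble
from lamindyn.relaxation import DecaySeries, NOEPair, RelaxationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_shift_table",
    "read_sparky_list",
    "write_shift_table",
    "read_thermogram",
    "write_thermogram",
    "read_structure",
    "ensemble_from_structure",
    "write_pdb",
    "write_ensemble_pdb",
    "read_records_csv",
    "write_records_csv",
]

ANGSTROM_PER_NM = 10.0

INTENSITY_COLUMNS = [
    "residue_number",
    "residue_name",
    "experiment",
    "delay_s",
    "intensity",
    "noise_rms",
]
SHIFT_COLUMNS = ["residue_number", "residue_name", "dHN_ppm", "dN_ppm", "dCA_ppm"]


# ---------------------------------------------------------------------------
# intensity tables

def read_intensity_table(path: Union[str, Path]) -> tuple[list[DecaySeries], list[NOEPair]]:
    """Parse a TSV of decay intensities into DecaySeries and NOEPair objects.

    Rows are grouped per residue and experiment; a residue with a
    ``NOE_sat`` but no ``NOE_ref`` row (or vice versa) yields no NOE pair
    and a warning.  Non-monotone delays within a series raise ValueError.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    series: list[DecaySeries] = []
    pairs: list[NOEPair] = []
    for (res, exp), group in df.groupby(["residue_number", "experiment"], sort=True):
        res = int(res)
        if exp in ("R1", "R2"):
            g = group.sort_values("delay_s")
            bad = g["delay_s"].isna() | g["intensity"].isna()
            if bad.any():
                # +2: header line and 1-based numbering
                lines = [int(i) + 2 for i in g.index[bad]]
                logger.warning("%s: dropping malformed rows at lines %s", path, lines)
                g = g[~bad]
            if g["delay_s"].duplicated().any():
                raise ValueError(f"{path}: duplicate delays for residue {res} {exp}")
            series.append(
                DecaySeries(
                    residue=res,
                    experiment=str(exp),
                    delays=g["delay_s"].to_numpy(float),
                    intensities=g["intensity"].to_numpy(float),
                    noise_rms=float(g["noise_rms"].iloc[0]),
                )
            )
        elif exp not in ("NOE_sat", "NOE_ref"):
            raise ValueError(f"{path}: unknown experiment {exp!r} for residue {res}")

    noe = df[df["experiment"].isin(["NOE_sat", "NOE_ref"])]
    for res, group in noe.groupby("residue_number", sort=True):
        res = int(res)
        by_exp = {e: g for e, g in group.groupby("experiment")}
        if "NOE_sat" not in by_exp or "NOE_ref" not in by_exp:
            logger.warning("%s: residue %d has an incomplete NOE pair; skipped", path, res)
            continue
        pairs.append(
            NOEPair(
                residue=res,
                intensity_sat=float(by_exp["NOE_sat"]["intensity"].iloc[0]),
                intensity_ref=float(by_exp["NOE_ref"]["intensity"].iloc[0]),
                noise_rms=float(group["noise_rms"].iloc[0]),
            )
        )
    return series, pairs


def write_intensity_table(
    series: Iterable[DecaySeries],
    pairs: Iterable[NOEPair],
    path: Union[str, Path],
    residue_names: Optional[Mapping[int, str]] = None,
) -> None:
    """Write decay series and NOE pairs to the intensity TSV format."""
    names = residue_names or {}
    rows = []
    for s in series:
        for d, i in zip(s.delays, s.intensities):
            rows.append((s.residue, names.get(s.residue, "X"), s.experiment, d, i, s.noise_rms))
    for p in pairs:
        rows.append((p.residue, names.get(p.residue, "X"), "NOE_sat", "", p.intensity_sat, p.noise_rms))
        rows.append((p.residue, names.get(p.residue, "X"), "NOE_ref", "", p.intensity_ref, p.noise_rms))
    pd.DataFrame(rows, columns=INTENSITY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shift tables

def read_shift_table(path: Union[str, Path], variant: str = "") -> ShiftTable:
    """Read a TSV shift table into a ShiftTable (missing shifts stay NaN)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SHIFT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df = df.set_index("residue_number")
    return ShiftTable(variant=variant or Path(path).stem, shifts=df)


def read_sparky_list(path: Union[str, Path], variant: str = "") -> ShiftTable:
    """Read Sparky-style amide peak-list lines like ``F451N-H 118.23 8.56``.

    The group name encodes the one-letter residue code and number; the two
    columns are the 15N and 1H shifts in ppm.  Calpha shifts are absent in
    this format.  Unparseable lines are logged with their line number.
    """
    records: dict[int, tuple[Optional[float], Optional[float], Optional[float]]] = {}
    names: dict[int, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            text = line.strip()
            if not text or text.lower().startswith(("assignment", "w1", "#")):
                continue
            parts = text.split()
            if len(parts) < 3:
                logger.warning("%s:%d: unparseable line %r", path, lineno, text)
                continue
            label = parts[0]
            try:
                core = label.split("-")[0]  # e.g. F451N
                resname = core[0]
                num_part = "".join(ch for ch in core[1:] if ch.isdigit())
                res = int(num_part)
                d_n = float(parts[1])
                d_hn = float(parts[2])
            except (ValueError, IndexError):
                logger.warning("%s:%d: unparseable line %r", path, lineno, text)
                continue
            records[res] = (d_hn, d_n, None)
            names[res] = resname
    if not records:
        raise ValueError(f"{path}: no assignments parsed")
    return ShiftTable.from_records(variant or Path(path).stem, records, residue_names=names)


def write_shift_table(table: ShiftTable, path: Union[str, Path]) -> None:
    df = table.shifts.reset_index()
    df = df.rename(columns={df.columns[0]: "residue_number"})
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# thermograms

def read_thermogram(path: Union[str, Path]) -> Thermogram:
    df = pd.read_csv(path, sep="\t")
    required = {"temperature_C", "cp_kcal_per_mol_K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return Thermogram(
        temperature_K=df["temperature_C"].to_numpy(float) + CELSIUS_OFFSET,
        cp=df["cp_kcal_per_mol_K"].to_numpy(float),
    )


def write_thermogram(thermogram: Thermogram, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "temperature_C": thermogram.temperature_C,
            "cp_kcal_per_mol_K": thermogram.cp,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# structures

def read_structure(path: Union[str, Path]):
    """Read a PDB file into a biotite AtomArrayStack (Angstrom).

    Multi-model files become multi-frame stacks.  Alternate locations other
    than 'A'/blank are dropped (biotite's first-altloc policy); HETATM-only
    files raise ValueError.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, altloc="first", extra_fields=["b_factor"])
    mask = ~stack.hetero
    if not mask.any():
        raise ValueError(f"{path}: no ATOM records")
    return stack[..., mask]


def ensemble_from_structure(stack) -> CoordinateEnsemble:
    """Convert a biotite AtomArray/AtomArrayStack (Angstrom) to nm coordinates."""
    coords = struc.coord(stack)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    return CoordinateEnsemble(
        coords=coords / ANGSTROM_PER_NM,
        residue_numbers=np.asarray(stack.res_id),
        atom_names=np.asarray(stack.atom_name),
        residue_names=np.asarray(stack.res_name),
    )


def write_pdb(atoms, path: Union[str, Path]) -> None:
    """Write a biotite AtomArray/AtomArrayStack to PDB (fixed-width fields)."""
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def _atom_array_from_labels(ensemble: CoordinateEnsemble, frame: np.ndarray):
    atoms = struc.AtomArray(ensemble.n_atoms)
    atoms.coord = frame * ANGSTROM_PER_NM
    atoms.res_id = np.asarray(ensemble.residue_numbers, dtype=int)
    atoms.atom_name = np.asarray(ensemble.atom_names, dtype="U6")
    atoms.res_name = (
        np.asarray(ensemble.residue_names, dtype="U5")
        if ensemble.residue_names is not None
        else np.full(ensemble.n_atoms, "GLY", dtype="U5")
    )
    atoms.chain_id = np.full(ensemble.n_atoms, "A", dtype="U4")
    atoms.element = np.array([str(n)[:1].upper() for n in ensemble.atom_names], dtype="U2")
    atoms.hetero = np.zeros(ensemble.n_atoms, dtype=bool)
    return atoms


def write_ensemble_pdb(ensemble: CoordinateEnsemble, path: Union[str, Path]) -> None:
    """Write a CoordinateEnsemble (nm) as a multi-model PDB (Angstrom)."""
    arrays = [_atom_array_from_labels(ensemble, frame) for frame in ensemble.coords]
    stack = struc.stack(arrays)
    write_pdb(stack, path)


# ---------------------------------------------------------------------------
# relaxation records

def write_records_csv(records: Sequence[RelaxationRecord], path: Union[str, Path]) -> None:
    """Per-residue rates CSV: residue, R1, R1_err, R2, R2_err, NOE, NOE_err."""
    rows = [
        (r.residue, r.r1, r.r1_err, r.r2, r.r2_err, r.noe, r.noe_err) for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"]
    )
    df.to_csv(path, index=False, float_format="%.4g")


def read_records_csv(path: Union[str, Path]) -> list[RelaxationRecord]:
    df = pd.read_csv(path)

    def opt(v) -> Optional[float]:
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return [
        RelaxationRecord(
            residue=int(row["residue"]),
            r1=opt(row.get("R1")),
            r1_err=opt(row.get("R1_err")),
            r2=opt(row.get("R2")),
            r2_err=opt(row.get("R2_err")),
            noe=opt(row.get("NOE")),
            noe_err=opt(row.get("NOE_err")),
        )
        for _, row in df.iterrows()
    ]
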