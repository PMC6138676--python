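"""Chemical-shift perturbation (CSP) mapping between two protein variants.

The combined amide perturbation per residue is

    d_amide = sqrt(dHN^2 + (dN/5)^2)

where dHN and dN are the 1H and 15N amide shift differences between the two
variants; the 1/5 scaling compensates the larger 15N shift range and is part
of the statistic's definition (not configurable).  Calpha shift differences
are reported signed (variant A minus variant B) together with the Pearson
r^2 of the two Calpha shift sets — near-unity r^2 indicates an unchanged
secondary structure.  Residues missing an assignment in either variant
propagate as absent, never as zero: imputing zeros would fabricate
"unperturbed" signal exactly where peaks are unobservable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftTable",
    "PerturbationRecord",
    "csp",
    "ca_diff",
    "classify",
    "map_to_structure",
]

#: default amide-perturbation significance threshold, ppm
DEFAULT_THRESHOLD_PPM = 0.15

#: B-factor sentinel for residues without a value
MISSING_BFACTOR = -1.0


@dataclass(frozen=True)
class ShiftTable:
    """Assigned backbone chemical shifts for one variant.

    ``shifts`` is indexed by residue number with columns ``residue_name``,
    ``dHN_ppm``, ``dN_ppm``, ``dCA_ppm``; any shift may be NaN (absent).
    """

    variant: str
    shifts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dHN_ppm", "dN_ppm", "dCA_ppm"}
        missing = required - set(self.shifts.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        if self.shifts.index.has_duplicates:
            raise ValueError("residue numbers must be unique")
        vals = self.shifts[list(required)].to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError("shift values must be finite or NaN")

    @classmethod
    def from_records(
        cls,
        variant: str,
        records: Mapping[int, tuple[Optional[float], Optional[float], Optional[float]]],
        residue_names: Optional[Mapping[int, str]] = None,
    ) -> "ShiftTable":
        """Build from {residue: (dHN, dN, dCA)}; None entries become NaN."""
        idx = sorted(records)
        df = pd.DataFrame(
            {
                "residue_name": [
                    (residue_names or {}).get(i, "X") for i in idx
                ],
                "dHN_ppm": [records[i][0] for i in idx],
                "dN_ppm": [records[i][1] for i in idx],
                "dCA_ppm": [records[i][2] for i in idx],
            },
            index=pd.Index(idx, name="residue_number"),
        ).astype({"dHN_ppm": float, "dN_ppm": float, "dCA_ppm": float})
        return cls(variant=variant, shifts=df)


@dataclass(frozen=True)
class PerturbationRecord:
    """Per-residue shift perturbation between two variants."""

    residue: int
    d_amide: Optional[float] = None
    d_ca: Optional[float] = None
    above_threshold: bool = False

    def __post_init__(self) -> None:
        if self.d_amide is not None and self.d_amide < 0:
            raise ValueError("d_amide must be non-negative")
        if self.above_threshold and self.d_amide is None:
            raise ValueError("above_threshold requires d_amide")


def _warn_name_mismatches(a: ShiftTable, b: ShiftTable, shared: pd.Index) -> None:
    if "residue_name" not in a.shifts.columns or "residue_name" not in b.shifts.columns:
        return
    na = a.shifts.loc[shared, "residue_name"]
    nb = b.shifts.loc[shared, "residue_name"]
    bad = shared[(na != nb).to_numpy()]
    for res in bad:
        logger.warning(
            "residue %d name mismatch between variants: %r vs %r",
            res, a.shifts.loc[res, "residue_name"], b.shifts.loc[res, "residue_name"],
        )


def csp(table_a: ShiftTable, table_b: ShiftTable) -> list[PerturbationRecord]:
    """Combined amide CSP and Calpha difference per shared residue.

    d_amide is computed where both variants carry both amide shifts; d_ca
    where both carry the Calpha shift.  Residues present in only one table,
    or lacking the needed shifts, yield absent components.

    Raises
    ------
    ValueError
        If no residue has amide shifts in both tables.
    """
    shared = table_a.shifts.index.intersection(table_b.shifts.index)
    _warn_name_mismatches(table_a, table_b, shared)

    records: list[PerturbationRecord] = []
    n_amide = 0
    for res in shared:
        ra, rb = table_a.shifts.loc[res], table_b.shifts.loc[res]
        d_amide = None
        if not any(
            math.isnan(v) for v in (ra.dHN_ppm, rb.dHN_ppm, ra.dN_ppm, rb.dN_ppm)
        ):
            dhn = ra.dHN_ppm - rb.dHN_ppm
            dn = ra.dN_ppm - rb.dN_ppm
            d_amide = math.sqrt(dhn**2 + (dn / 5.0) ** 2)
            n_amide += 1
        d_ca = None
        if not (math.isnan(ra.dCA_ppm) or math.isnan(rb.dCA_ppm)):
            d_ca = ra.dCA_ppm - rb.dCA_ppm
        records.append(PerturbationRecord(residue=int(res), d_amide=d_amide, d_ca=d_ca))
    if n_amide == 0:
        raise ValueError("tables share no residue with complete amide shifts")
    return records


def ca_diff(
    table_a: ShiftTable, table_b: ShiftTable
) -> tuple[pd.Series, Optional[float]]:
    """Signed Calpha shift differences (A - B) and Pearson r^2 of A vs B.

    r^2 is None when fewer than 3 shared residues carry Calpha shifts in
    both tables; the differences are still returned.
    """
    shared = table_a.shifts.index.intersection(table_b.shifts.index)
    ca_a = table_a.shifts.loc[shared, "dCA_ppm"]
    ca_b = table_b.shifts.loc[shared, "dCA_ppm"]
    both = ~(ca_a.isna() | ca_b.isna())
    diffs = (ca_a - ca_b)[both]
    diffs.name = "dCA_diff_ppm"
    if both.sum() < 3:
        return diffs, None
    r = np.corrcoef(ca_a[both], ca_b[both])[0, 1]
    return diffs, float(r**2)


def classify(
    records: Iterable[PerturbationRecord],
    threshold: float = DEFAULT_THRESHOLD_PPM,
) -> list[PerturbationRecord]:
    """Flag residues whose d_amide strictly exceeds ``threshold`` (ppm).

    Returns new records with ``above_threshold`` set; values equal to the
    threshold are not flagged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [
        replace(r, above_threshold=(r.d_amide is not None and r.d_amide > threshold))
        for r in records
    ]


def map_to_structure(values: Mapping[int, float], structure):
    """Write per-residue values into the B-factor column of a structure.

    Parameters
    ----------
    values : mapping residue number -> value
        E.g. ``{r.residue: r.d_amide for r in records if r.d_amide is not None}``.
    structure : biotite.structure.AtomArray
        Residues are matched by ``res_id``; every atom of a matched residue
        gets the value, unmatched residues get the sentinel -1.00.

    Returns
    -------
    biotite.structure.AtomArray
        A copy with the ``b_factor`` annotation set.
    """
    annotated = structure.copy()
    res_ids = annotated.res_id
    if not any(int(r) in values for r in np.unique(res_ids)):
        raise ValueError("no structure residue matches a record")
    b = np.full(annotated.array_length(), MISSING_BFACTOR)
    for res, val in values.items():
        b[res_ids == res] = val
    annotated.set_annotation("b_factor", b)
    return annotated
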