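"""Stage orchestration for the wild-type vs mutant comparison workflow.

Each stage is a thin function over the analysis modules that reads the
documented file formats, runs the computation and writes CSV/PDB reports.
:func:`run_compare` wires the stages together for two input arms and writes
a comparative summary (means +/- SD of NOE, R2/R1, tau_c, Tm, enthalpies,
Rg per arm).  Stages whose inputs are absent are skipped with a logged
notice, never silently imputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from lamindyn import __version__
from lamindyn import io as ldio
from lamindyn.config import RunConfig
from lamindyn.csp import ca_diff, classify, csp
from lamindyn.diffusion import DiffusionResult, SpinParameters, diffusion_from_records
from lamindyn.dsc import TwoStateFit, fit_twostate, find_tm, integrate_enthalpy
from lamindyn.ensemble import pca, radius_of_gyration, rmsd_series, rmsf
from lamindyn.relaxation import (
    RelaxationRecord,
    RelaxationSummary,
    compute_noe,
    fit_decay,
    summarize_records,
)

logger = logging.getLogger(__name__)

__all__ = ["ArmInputs", "ArmResult", "CompareReport", "fit_rates_stage", "run_compare"]

#: conventional file names inside an input arm directory
INTENSITY_FILE = "intensities.tsv"
SHIFT_FILE = "shifts.tsv"
DSC_FILE = "dsc.tsv"
ENSEMBLE_FILE = "ensemble.pdb"


@dataclass(frozen=True)
class ArmInputs:
    """Paths for one arm (wild type or mutant); any may be None."""

    label: str
    intensities: Optional[Path] = None
    shifts: Optional[Path] = None
    dsc: Optional[Path] = None
    ensemble: Optional[Path] = None

    @classmethod
    def from_directory(cls, label: str, directory: Union[str, Path]) -> "ArmInputs":
        d = Path(directory)

        def maybe(name: str) -> Optional[Path]:
            p = d / name
            return p if p.exists() else None

        return cls(
            label=label,
            intensities=maybe(INTENSITY_FILE),
            shifts=maybe(SHIFT_FILE),
            dsc=maybe(DSC_FILE),
            ensemble=maybe(ENSEMBLE_FILE),
        )


@dataclass
class ArmResult:
    label: str
    records: Optional[list[RelaxationRecord]] = None
    relaxation: Optional[RelaxationSummary] = None
    diffusion: Optional[DiffusionResult] = None
    dsc_fit: Optional[TwoStateFit] = None
    dsc_tm_C: Optional[float] = None
    dsc_dh_cal: Optional[float] = None
    rg_mean_nm: Optional[float] = None
    rmsd_mean_nm: Optional[float] = None
    pc1_fraction: Optional[float] = None
    skipped: list[str] = field(default_factory=list)


@dataclass
class CompareReport:
    arms: list[ArmResult]
    all_requested_ran: bool
    output_dir: Path


def fit_rates_stage(
    intensity_path: Union[str, Path],
    config: RunConfig = RunConfig(),
) -> list[RelaxationRecord]:
    """Fit every decay series and NOE pair in an intensity table."""
    series, pairs = ldio.read_intensity_table(intensity_path)
    by_residue: dict[int, dict] = {}
    for s in series:
        fit = fit_decay(s, n_mc=config.mc_draws, seed=config.seed)
        if not fit.converged:
            logger.warning("residue %d %s: fit did not converge; component absent", s.residue, s.experiment)
            continue
        slot = by_residue.setdefault(s.residue, {})
        key = s.experiment.lower()
        slot[key] = fit.rate
        slot[f"{key}_err"] = fit.sigma_rate
    for p in pairs:
        noe, err = compute_noe(p)
        slot = by_residue.setdefault(p.residue, {})
        slot["noe"], slot["noe_err"] = noe, err
    return [RelaxationRecord(residue=res, **vals) for res, vals in sorted(by_residue.items())]


def _spin_params(config: RunConfig) -> SpinParameters:
    return SpinParameters(
        field_mhz=config.field_mhz,
        r_nh_angstrom=config.r_nh_angstrom,
        csa_ppm=config.csa_ppm,
    )


def _run_relaxation_arm(arm: ArmInputs, result: ArmResult, config: RunConfig, outdir: Path) -> None:
    records = fit_rates_stage(arm.intensities, config)
    result.records = records
    ldio.write_records_csv(records, outdir / f"{arm.label}_rates.csv")
    result.relaxation = summarize_records(records)
    try:
        result.diffusion = diffusion_from_records(
            records,
            params=_spin_params(config),
            sd_multiplier=config.exclusion_sd_multiplier,
            bracket_ns=config.tauc_bracket_ns,
        )
    except ValueError as exc:
        logger.warning("%s: tau_c estimation skipped (%s)", arm.label, exc)
        result.skipped.append("diffusion")
        return
    rows = []
    for rec in records:
        reason = result.diffusion.residues_excluded.get(rec.residue, "")
        rows.append((rec.residue, rec.ratio, reason == "", reason))
    pd.DataFrame(rows, columns=["residue", "r2_r1", "included", "reason"]).to_csv(
        outdir / f"{arm.label}_diffusion.csv", index=False, float_format="%.4g"
    )


def _run_csp_arms(wt: ArmInputs, mut: ArmInputs, config: RunConfig, outdir: Path) -> dict:
    table_a = ldio.read_shift_table(wt.shifts, variant=wt.label)
    table_b = ldio.read_shift_table(mut.shifts, variant=mut.label)
    records = classify(csp(table_a, table_b), threshold=config.csp_threshold_ppm)
    diffs, r2 = ca_diff(table_a, table_b)
    rows = [
        (r.residue, r.d_amide, r.d_ca, r.above_threshold) for r in records
    ]
    pd.DataFrame(
        rows, columns=["residue", "d_amide_ppm", "d_ca_ppm", "above_threshold"]
    ).to_csv(outdir / "csp.csv", index=False, float_format="%.3f")
    amides = [r.d_amide for r in records if r.d_amide is not None]
    return {
        "n_above_threshold": sum(r.above_threshold for r in records),
        "d_amide_mean": float(np.mean(amides)) if amides else None,
        "ca_r2": r2,
    }


def _run_dsc_arm(arm: ArmInputs, result: ArmResult, config: RunConfig, outdir: Path) -> None:
    thermogram = ldio.read_thermogram(arm.dsc)
    result.dsc_tm_C = find_tm(thermogram)
    result.dsc_dh_cal = integrate_enthalpy(thermogram)
    result.dsc_fit = fit_twostate(thermogram)
    m = result.dsc_fit.model
    pd.DataFrame(
        [
            (
                m.tm_C,
                m.dh_cal,
                m.dh_vh,
                m.baseline_slope,
                m.baseline_intercept,
                result.dsc_fit.rms_residual,
            )
        ],
        columns=[
            "Tm_C",
            "dHcal_kcal_mol",
            "dHvH_kcal_mol",
            "baseline_slope",
            "baseline_intercept",
            "rms_residual",
        ],
    ).to_csv(outdir / f"{arm.label}_dsc.csv", index=False, float_format="%.4g")


def _run_ensemble_arm(arm: ArmInputs, result: ArmResult, config: RunConfig, outdir: Path) -> None:
    stack = ldio.read_structure(arm.ensemble)
    ens = ldio.ensemble_from_structure(stack)
    rg = radius_of_gyration(ens)
    result.rg_mean_nm = float(np.mean(rg))
    rmsds = rmsd_series(ens, reference=0)
    result.rmsd_mean_nm = float(np.mean(rmsds))
    selection = None if config.pca_selection == "all" else "CA"
    if ens.n_frames > 3:
        res = pca(ens, atom_selection=selection)
        result.pc1_fraction = float(res.variance_fractions[0])
    else:
        logger.warning("%s: too few frames for PCA; skipped", arm.label)
        result.skipped.append("pca")
    sel = ens.select(ens.ca_mask()) if ens.ca_mask().any() else ens
    fluct = rmsf(sel) if sel.n_frames >= 2 else None
    df = pd.DataFrame({"frame": np.arange(ens.n_frames), "rmsd_nm": rmsds, "rg_nm": rg})
    df.to_csv(outdir / f"{arm.label}_ensemble.csv", index=False, float_format="%.4f")
    if fluct is not None:
        pd.DataFrame(
            {"residue": sel.residue_numbers, "rmsf_nm": fluct}
        ).to_csv(outdir / f"{arm.label}_rmsf.csv", index=False, float_format="%.4f")


def run_compare(
    wildtype: ArmInputs,
    mutant: ArmInputs,
    config: RunConfig = RunConfig(),
    output_dir: Optional[Union[str, Path]] = None,
) -> CompareReport:
    """Run every stage whose inputs are present for both arms.

    Writes per-stage CSVs, a comparative ``summary.csv`` and a ``run.json``
    log (package version, seed, config hash).  Raises ValueError when
    neither arm provides any input.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = [wildtype, mutant]
    if not any(
        getattr(a, k) for a in arms for k in ("intensities", "shifts", "dsc", "ensemble")
    ):
        raise ValueError("no inputs present in either arm")

    results = []
    for arm in arms:
        result = ArmResult(label=arm.label)
        if arm.intensities:
            _run_relaxation_arm(arm, result, config, outdir)
        else:
            result.skipped.append("relaxation")
            logger.info("%s: no intensity table; relaxation stage skipped", arm.label)
        if arm.dsc:
            _run_dsc_arm(arm, result, config, outdir)
        else:
            result.skipped.append("dsc")
            logger.info("%s: no thermogram; DSC stage skipped", arm.label)
        if arm.ensemble:
            _run_ensemble_arm(arm, result, config, outdir)
        else:
            result.skipped.append("ensemble")
            logger.info("%s: no ensemble; ensemble stage skipped", arm.label)
        results.append(result)

    csp_summary = None
    if wildtype.shifts and mutant.shifts:
        csp_summary = _run_csp_arms(wildtype, mutant, config, outdir)
    else:
        logger.info("CSP stage skipped (needs shift tables for both arms)")
        for r in results:
            r.skipped.append("csp")

    rows = []
    for r in results:
        rows.append(
            {
                "arm": r.label,
                "NOE_mean": r.relaxation.noe_mean if r.relaxation else None,
                "NOE_sd": r.relaxation.noe_sd if r.relaxation else None,
                "R2_R1_mean": r.relaxation.ratio_mean if r.relaxation else None,
                "R2_R1_sd": r.relaxation.ratio_sd if r.relaxation else None,
                "tauc_ns": r.diffusion.tauc_ns if r.diffusion else None,
                "Tm_C": r.dsc_tm_C,
                "dHcal_kcal_mol": r.dsc_dh_cal,
                "Rg_nm": r.rg_mean_nm,
                "RMSD_nm": r.rmsd_mean_nm,
                "PC1_fraction": r.pc1_fraction,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False, float_format="%.4g")

    config_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    log = {
        "lamindyn_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash,
        "csp": csp_summary,
        "skipped": {r.label: r.skipped for r in results},
    }
    with open(outdir / "run.json", "w") as handle:
        json.dump(log, handle, indent=2)

    all_ran = not any(r.skipped for r in results)
    return CompareReport(arms=results, all_requested_ran=all_ran, output_dir=outdir)
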