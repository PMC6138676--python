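"""Run configuration for the comparison pipeline.

A flat YAML mapping; unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Attributes
    ----------
    field_mhz : proton Larmor frequency, MHz.
    r_nh_angstrom : N-H bond length, Angstrom.
    csa_ppm : 15N chemical shift anisotropy, ppm.
    tauc_bracket_ns : (low, high) search bracket for tau_c, ns.
    exclusion_sd_multiplier : width of the R2/R1 and NOE exclusion bands, SDs.
    csp_threshold_ppm : amide-CSP significance threshold, ppm.
    mc_draws : Monte-Carlo draws for rate uncertainties.
    seed : global seed for synthetic noise.
    dsc_t_min_C / dsc_t_max_C : DSC scan window, Celsius.
    dsc_flank_fraction : fraction of the scan used per flank for the
        automatic linear baseline.
    pca_selection : atom selection for the covariance ("CA" or "all").
    output_dir : where the pipeline writes its reports.
    """

    field_mhz: float = 600.13
    r_nh_angstrom: float = 1.02
    csa_ppm: float = -160.0
    tauc_bracket_ns: tuple[float, float] = (0.1, 100.0)
    exclusion_sd_multiplier: float = 1.0
    csp_threshold_ppm: float = 0.15
    mc_draws: int = 500
    seed: int = 0
    dsc_t_min_C: float = 16.0
    dsc_t_max_C: float = 80.0
    dsc_flank_fraction: float = 0.15
    pca_selection: str = "CA"
    output_dir: str = "lamindyn_out"

    def __post_init__(self) -> None:
        for name in ("field_mhz", "r_nh_angstrom", "csp_threshold_ppm",
                     "exclusion_sd_multiplier", "dsc_flank_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mc_draws < 100:
            raise ValueError("mc_draws must be at least 100")
        lo, hi = self.tauc_bracket_ns
        if not (0 < lo < hi):
            raise ValueError("tauc_bracket_ns must be an increasing positive pair")
        if self.pca_selection not in ("CA", "all"):
            raise ValueError("pca_selection must be 'CA' or 'all'")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        """Load a config, rejecting unknown keys."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "tauc_bracket_ns" in data:
            data["tauc_bracket_ns"] = tuple(data["tauc_bracket_ns"])
        return cls(**data)
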