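"""Coordinate-ensemble statistics: superposition, RMSD, RMSF, Rg, PCA.

The workhorse is Kabsch superposition — the closed-form least-squares
optimal rigid-body fit obtained from the SVD of the weighted covariance of
the two point sets, with the usual determinant sign correction so that only
proper rotations are returned.  All ensemble statistics superpose frames
first (RMSD onto an explicit reference; RMSF and PCA onto the ensemble mean
with one refinement iteration) and are therefore invariant under a global
rigid motion of every frame.

PCA ("essential dynamics") diagonalises the 3N x 3N covariance of the
selected atoms about their mean; the leading eigenvectors are the dominant
collective motions and the eigenvalue fractions their share of the total
positional variance.  Porcupine export writes the mean structure and the
mean displaced along a chosen mode as a two-model ensemble, so any viewer
can draw per-atom arrows between paired atoms.

Coordinates are in nanometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "CoordinateEnsemble",
    "PCAResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "superpose_to_mean",
    "radius_of_gyration",
    "pca",
    "porcupine_export",
]

#: standard atomic masses (Da) for Rg weighting; unit mass if unknown
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


@dataclass(frozen=True)
class CoordinateEnsemble:
    """Frames x atoms x 3 coordinate array (nm) with per-atom labels."""

    coords: np.ndarray
    residue_numbers: np.ndarray
    atom_names: np.ndarray
    residue_names: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_numbers", np.asarray(self.residue_numbers))
        object.__setattr__(self, "atom_names", np.asarray(self.atom_names))
        if self.residue_numbers.size != coords.shape[1] or self.atom_names.size != coords.shape[1]:
            raise ValueError("labels must match the atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, mask: np.ndarray) -> "CoordinateEnsemble":
        return CoordinateEnsemble(
            coords=self.coords[:, mask, :],
            residue_numbers=self.residue_numbers[mask],
            atom_names=self.atom_names[mask],
            residue_names=None if self.residue_names is None else self.residue_names[mask],
        )

    def ca_mask(self) -> np.ndarray:
        return self.atom_names == "CA"


@dataclass(frozen=True)
class PCAResult:
    """Essential-dynamics decomposition of an ensemble.

    ``eigenvectors`` has shape (n_components, 3*n_atoms), rows orthonormal,
    eigenvalues (nm^2) descending; ``projections`` holds the per-frame
    scores (n_frames, n_components); ``mean`` is the flattened mean
    structure the covariance was taken about.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fractions: np.ndarray
    projections: np.ndarray
    mean: np.ndarray


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` is the least-squares fit; the
    rotation is proper (det = +1) via sign correction of the smallest
    singular direction.  ``rmsd`` is the weighted root-mean-square deviation
    after superposition, in the coordinate units.

    Raises
    ------
    ValueError
        On mismatched shapes, fewer than 3 atoms, or a degenerate (collinear
        / coincident) configuration where the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (n_atoms, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_t = w @ target
    a = (mobile - mu_m) * w[:, None]
    b = target - mu_t
    h = a.T @ b  # 3x3 weighted covariance
    u, s, vt = np.linalg.svd(h)
    # a collinear/coincident point set leaves >=2 singular values ~0
    scale = max(s[0], 1e-300)
    if s[1] / scale < 1e-12:
        raise ValueError("degenerate (collinear or coincident) atom configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_t - rot @ mu_m
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - target) ** 2)))
    return rot, trans, rmsd


def rmsd_series(
    ensemble: CoordinateEnsemble,
    reference: Union[np.ndarray, int] = 0,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame RMSD (nm) after Kabsch superposition onto a reference.

    ``reference`` is a frame index or an explicit (n_atoms, 3) array.
    """
    ref = (
        ensemble.coords[reference]
        if isinstance(reference, (int, np.integer))
        else np.asarray(reference, dtype=float)
    )
    if ref.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference must match the ensemble atom count")
    return np.array(
        [kabsch_superpose(frame, ref, weights)[2] for frame in ensemble.coords]
    )


def superpose_to_mean(ensemble: CoordinateEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto the ensemble mean, one refinement iteration.

    Frames are fit to the raw mean, the mean is recomputed from the fitted
    frames, and the frames are fit once more — a deterministic reference
    that avoids privileging any single frame.

    Returns (aligned coordinates, mean structure).
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least two frames")
    coords = ensemble.coords
    mean = coords.mean(axis=0)
    for _ in range(2):
        aligned = np.empty_like(coords)
        for f, frame in enumerate(coords):
            rot, trans, _ = kabsch_superpose(frame, mean)
            aligned[f] = frame @ rot.T + trans
        mean = aligned.mean(axis=0)
        coords = aligned
    return coords, mean


def rmsf(ensemble: CoordinateEnsemble) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (nm) about the mean structure."""
    aligned, mean = superpose_to_mean(ensemble)
    dev = aligned - mean
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def radius_of_gyration(
    ensemble_or_frame: Union[CoordinateEnsemble, np.ndarray],
    masses: Optional[np.ndarray] = None,
) -> Union[float, np.ndarray]:
    """Mass-weighted radius of gyration (nm).

    For a single (n_atoms, 3) frame returns a float; for an ensemble
    returns the per-frame array.  With ``masses=None``, standard atomic
    masses are looked up from the first letter of the atom name when an
    ensemble is given, and unit masses are used otherwise.
    """
    if isinstance(ensemble_or_frame, CoordinateEnsemble):
        frames = ensemble_or_frame.coords
        if masses is None:
            masses = np.array(
                [ATOMIC_MASSES.get(str(n)[:1].upper(), 1.0) for n in ensemble_or_frame.atom_names]
            )
        single = False
    else:
        frames = np.asarray(ensemble_or_frame, dtype=float)[None, :, :]
        if masses is None:
            masses = np.ones(frames.shape[1])
        single = True
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = np.einsum("fak,a->fk", frames, masses) / total
    sq = np.sum(np.sum((frames - com[:, None, :]) ** 2, axis=2) * masses, axis=1) / total
    rg = np.sqrt(sq)
    return float(rg[0]) if single else rg


def pca(
    ensemble: CoordinateEnsemble,
    atom_selection: Union[str, np.ndarray, None] = "CA",
) -> PCAResult:
    """Essential dynamics: eigendecomposition of the positional covariance.

    Frames are superposed onto the ensemble mean first (same alignment as
    :func:`rmsf`).  ``atom_selection`` is "CA" (default), an explicit
    boolean mask, or None for all atoms.  Eigenvalues are sorted descending
    and tiny negative round-off values are clipped to zero.
    """
    if ensemble.n_frames <= 3:
        raise ValueError("need more than 3 frames for a meaningful covariance")
    if atom_selection is None:
        sub = ensemble
    elif isinstance(atom_selection, str):
        if atom_selection != "CA":
            raise ValueError("atom_selection must be 'CA', a boolean mask, or None")
        mask = ensemble.ca_mask()
        sub = ensemble.select(mask) if mask.any() else ensemble
    else:
        sub = ensemble.select(np.asarray(atom_selection))

    aligned, mean = superpose_to_mean(sub)
    flat = aligned.reshape(sub.n_frames, -1)
    mu = flat.mean(axis=0)
    centered = flat - mu
    cov = centered.T @ centered / (sub.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    projections = centered @ evecs.T
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_fractions=fractions,
        projections=projections,
        mean=mu,
    )


def porcupine_export(
    result: PCAResult,
    component: int = 0,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean structure and mean + scale*sqrt(eigenvalue)*mode, as two frames.

    Returns ``(model_1, model_2)`` each of shape (n_atoms, 3): the first is
    the mean structure, the second the mean displaced along the chosen
    component by one scaled standard deviation.  Paired atoms define the
    porcupine arrows.  A zero-eigenvalue component with nonzero scale yields
    identical models (logged, not an error).
    """
    if not 0 <= component < result.eigenvalues.size:
        raise ValueError("component index out of range")
    lam = result.eigenvalues[component]
    if lam == 0 and scale != 0:
        import logging

        logging.getLogger(__name__).warning(
            "component %d has zero eigenvalue; porcupine models are identical", component
        )
    mean = result.mean.reshape(-1, 3)
    displaced = (
        result.mean + scale * np.sqrt(lam) * result.eigenvectors[component]
    ).reshape(-1, 3)
    return mean, displaced
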