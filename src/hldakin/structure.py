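"""Structural primitives: optimal-superposition RMSD, state labeling, FPT.

Configurations of a two-state system are classified as folded or unfolded by
their backbone RMSD to a folded reference structure.  Frames falling between
the folded cutoff ``t_F`` and the unfolded cutoff ``t_U`` belong to the
barrier region and are excluded from state-restricted training ensembles to
avoid cross-contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StateLabels",
    "FOLDED",
    "UNFOLDED",
    "EXCLUDED",
    "kabsch_rmsd",
    "rmsd_series",
    "assign_states",
    "first_passage_time",
]

FOLDED = "folded"
UNFOLDED = "unfolded"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class StateLabels:
    """Per-frame state labels with the thresholds that produced them."""

    labels: tuple[str, ...]
    t_F: float
    t_U: float

    def __post_init__(self) -> None:
        if not self.t_F < self.t_U:
            raise ValueError(f"t_F ({self.t_F}) must be < t_U ({self.t_U})")
        bad = {lab for lab in self.labels} - {FOLDED, UNFOLDED, EXCLUDED}
        if bad:
            raise ValueError(f"unknown state labels: {bad}")

    def mask(self, state: str) -> np.ndarray:
        return np.asarray([lab == state for lab in self.labels])

    def counts(self) -> dict[str, int]:
        return {s: int(self.mask(s).sum()) for s in (FOLDED, UNFOLDED, EXCLUDED)}


def _as_coords(x: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n_atoms, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between two frames over all proper rigid motions.

    Both frames are centered and the optimal proper rotation (reflections
    are never applied) is found by the Kabsch procedure; the returned value
    is ``sqrt(mean |R x_i + t - y_i|^2)`` at the optimum.  Symmetric in its
    arguments and invariant to rigid motion of either frame.

    Raises
    ------
    ValueError
        On atom-count mismatch, fewer than 3 atoms, or an all-collinear
        reference (the rotation is then underdetermined).
    """
    mob = _as_coords(mobile, "mobile")
    ref = _as_coords(reference, "reference")
    if mob.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: mobile has {mob.shape[0]}, reference {ref.shape[0]}"
        )
    if mob.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinear (rank <= 1) reference leaves a free rotation axis
    if np.linalg.matrix_rank(ref_c, tol=1e-9 * max(1.0, np.abs(ref_c).max())) < 2:
        raise ValueError("reference atoms are collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    # recompute the residual explicitly: the solver's reported rssd loses
    # half the precision near zero
    diff = rot.apply(mob_c) - ref_c
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_series(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch RMSD of each frame in ``(n_frames, n_atoms, 3)`` to a reference."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
    return np.asarray([kabsch_rmsd(f, reference) for f in frames])


def assign_states(rmsd: np.ndarray, t_F: float, t_U: float) -> StateLabels:
    """Label frames folded / unfolded / excluded by RMSD thresholds.

    ``RMSD <= t_F`` is folded and ``RMSD >= t_U`` is unfolded, both
    boundary-inclusive; everything strictly between is excluded.
    """
    if not t_F < t_U:
        raise ValueError(f"t_F ({t_F}) must be < t_U ({t_U})")
    rmsd = np.asarray(rmsd, dtype=float)
    labels = np.full(rmsd.shape, EXCLUDED, dtype=object)
    labels[rmsd <= t_F] = FOLDED
    labels[rmsd >= t_U] = UNFOLDED
    return StateLabels(labels=tuple(labels), t_F=float(t_F), t_U=float(t_U))


def first_passage_time(
    rmsd: np.ndarray, dt: float, t_FPT: float
) -> float | None:
    """Time of the first frame with ``RMSD >= t_FPT``; ``None`` if never.

    Frame 0 is at time 0, so an immediately-crossed series returns 0.0.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    rmsd = np.asarray(rmsd, dtype=float)
    if rmsd.size == 0:
        raise ValueError("empty RMSD series")
    hits = np.flatnonzero(rmsd >= t_FPT)
    if hits.size == 0:
        return None
    return float(hits[0] * dt)
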