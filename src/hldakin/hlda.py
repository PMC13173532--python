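"""Harmonic Linear Discriminant Analysis (HLDA) collective variables.

HLDA builds a one-dimensional linear collective variable (CV) that maximally
separates two metastable ensembles (folded ``F`` and unfolded ``U``) while
minimising within-state fluctuations.  Unlike classical LDA, the within-class
scatter is the *harmonic* average of the per-state covariances,

    S_w = (Sigma_F^-1 + Sigma_U^-1)^-1,

which weights each state by the inverse of its fluctuations and is the choice
appropriate for metastable basins of very different widths.  The between-class
scatter for two states reduces to the rank-1 matrix

    S_b = (1/2) (mu_F - mu_U)(mu_F - mu_U)^T,

so the generalized eigenproblem ``S_b W = lambda S_w W`` has the closed-form
solution ``W proportional to S_w^-1 (mu_F - mu_U)`` with leading eigenvalue
``lambda = (1/2) dmu^T S_w^-1 dmu``.  ``lambda`` is a dimensionless score of
how separable the two ensembles are along the CV; the CV itself is
``s(R) = sum_{p<q} W_pq d_pq(R)`` over the kept pairwise distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .descriptors import DescriptorMatrix
from .structure import FOLDED, UNFOLDED, StateLabels

__all__ = [
    "StateStats",
    "HLDAModel",
    "state_statistics",
    "harmonic_within_scatter",
    "between_scatter",
    "solve_hlda",
    "project",
]

# ridge engaged when cond(Sigma) exceeds this
_COND_LIMIT = 1e10
_RIDGE_EPS = 1e-6


@dataclass(frozen=True)
class StateStats:
    """Sample mean and covariance of one metastable ensemble."""

    mean: np.ndarray
    cov: np.ndarray
    n_samples: int
    state: str = ""

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape inconsistent with mean")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class HLDAModel:
    """A fitted two-state HLDA collective variable.

    ``weights`` is the unit-norm leading eigenvector over the kept descriptor
    pairs, signed so the CV increases from the folded toward the unfolded
    ensemble.  ``eigenvalue`` is the separation score lambda.  ``separated``
    is False when lambda is numerically zero (identical state means).
    """

    weights: np.ndarray
    eigenvalue: float
    pairs: tuple[tuple[int, int], ...]
    mean_folded: np.ndarray
    mean_unfolded: np.ndarray
    s_w: np.ndarray
    s_b: np.ndarray
    global_mean: np.ndarray
    separated: bool = True
    sign_convention: str = "s(mu_U) > s(mu_F)"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.separated and not np.isclose(np.linalg.norm(w), 1.0, atol=1e-8):
            raise ValueError("weights must be unit-norm")
        object.__setattr__(self, "weights", w)

    @property
    def weight_by_pair(self) -> dict[tuple[int, int], float]:
        return {pq: float(w) for pq, w in zip(self.pairs, self.weights)}


def _regularized(cov: np.ndarray) -> np.ndarray:
    """Add a small ridge when the covariance is badly conditioned.

    Pruning is the first line of defence against ill-conditioning; the ridge
    ``eps * tr(Sigma)/p * I`` only engages when the condition number still
    exceeds 1e10 after pruning (e.g. degenerate toy inputs).
    """
    cov = np.asarray(cov, dtype=float)
    eigvals = np.linalg.eigvalsh(cov)
    lo, hi = eigvals[0], eigvals[-1]
    if hi <= 0:
        ridge = _RIDGE_EPS * max(1.0, np.trace(cov)) / cov.shape[0]
        return cov + ridge * np.eye(cov.shape[0])
    if lo <= 0 or hi / lo > _COND_LIMIT:
        ridge = _RIDGE_EPS * np.trace(cov) / cov.shape[0]
        return cov + ridge * np.eye(cov.shape[0])
    return cov


def state_statistics(
    matrix: DescriptorMatrix, labels: StateLabels | np.ndarray
) -> dict[str, StateStats]:
    """Per-state sample mean and unbiased covariance of the descriptors.

    Excluded frames are ignored.  A state with fewer frames than descriptors
    plus one yields a rank-deficient covariance; a warning is emitted and the
    downstream solver falls back to ridge regularization.
    """
    lab_seq = labels.labels if isinstance(labels, StateLabels) else tuple(labels)
    if len(lab_seq) != matrix.n_frames:
        raise ValueError("label count must equal the number of frames")
    lab = np.asarray(lab_seq, dtype=object)
    out: dict[str, StateStats] = {}
    for state in (FOLDED, UNFOLDED):
        rows = matrix.values[lab == state]
        if rows.shape[0] < 2:
            raise ValueError(f"state '{state}' has {rows.shape[0]} frames; need >= 2")
        if rows.shape[0] < matrix.n_descriptors + 1:
            warnings.warn(
                f"state '{state}' has {rows.shape[0]} frames for "
                f"{matrix.n_descriptors} descriptors; covariance is singular and "
                "will be ridge-regularized",
                stacklevel=2,
            )
        out[state] = StateStats(
            mean=rows.mean(axis=0),
            cov=np.cov(rows, rowvar=False, ddof=1).reshape(
                matrix.n_descriptors, matrix.n_descriptors
            ),
            n_samples=rows.shape[0],
            state=state,
        )
    return out


def harmonic_within_scatter(cov_f: np.ndarray, cov_u: np.ndarray) -> np.ndarray:
    """Harmonic average of the state covariances: ``(S_F^-1 + S_U^-1)^-1``."""
    cov_f = _regularized(np.atleast_2d(np.asarray(cov_f, dtype=float)))
    cov_u = _regularized(np.atleast_2d(np.asarray(cov_u, dtype=float)))
    if cov_f.shape != cov_u.shape:
        raise ValueError("state covariances must have identical shapes")
    try:
        inv_sum = linalg.inv(cov_f) + linalg.inv(cov_u)
        s_w = linalg.inv(inv_sum)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "within-class scatter is singular even after regularization; "
            "prune descriptors more aggressively"
        ) from exc
    return 0.5 * (s_w + s_w.T)


def between_scatter(mean_f: np.ndarray, mean_u: np.ndarray) -> np.ndarray:
    """Two-state between-class scatter ``(1/2) dmu dmu^T`` (rank <= 1)."""
    mu_f = np.atleast_1d(np.asarray(mean_f, dtype=float))
    mu_u = np.atleast_1d(np.asarray(mean_u, dtype=float))
    if mu_f.shape != mu_u.shape:
        raise ValueError("state means must have identical shapes")
    dmu = mu_f - mu_u
    return 0.5 * np.outer(dmu, dmu)


def solve_hlda(
    stats: dict[str, StateStats],
    pairs: tuple[tuple[int, int], ...] | None = None,
) -> HLDAModel:
    """Solve the two-state HLDA problem by its rank-1 closed form.

    ``W proportional to S_w^-1 (mu_F - mu_U)``, ``lambda = (1/2) dmu^T S_w^-1 dmu``.
    The eigenvector is normalized to unit Euclidean norm and signed so the
    projected unfolded mean exceeds the projected folded mean (the CV
    increases folded -> unfolded).  A model with ``lambda`` below machine
    tolerance is flagged ``separated=False``.
    """
    f, u = stats[FOLDED], stats[UNFOLDED]
    if f.mean.shape != u.mean.shape:
        raise ValueError("state dimensions differ")
    dim = f.mean.size
    if pairs is None:
        pairs = tuple((0, i + 1) for i in range(dim))
    if len(pairs) != dim:
        raise ValueError("pair labels must match the descriptor dimension")

    s_w = harmonic_within_scatter(f.cov, u.cov)
    s_b = between_scatter(f.mean, u.mean)
    dmu = f.mean - u.mean
    global_mean = 0.5 * (f.mean + u.mean)

    raw = linalg.solve(s_w, dmu, assume_a="pos")
    eigenvalue = 0.5 * float(dmu @ raw)
    scale = max(1.0, float(dmu @ dmu))
    if eigenvalue <= 1e3 * np.finfo(float).eps * scale:
        return HLDAModel(
            weights=np.zeros(dim),
            eigenvalue=0.0,
            pairs=tuple(pairs),
            mean_folded=f.mean,
            mean_unfolded=u.mean,
            s_w=s_w,
            s_b=s_b,
            global_mean=global_mean,
            separated=False,
        )
    w = raw / np.linalg.norm(raw)
    if w @ u.mean <= w @ f.mean:
        w = -w
    return HLDAModel(
        weights=w,
        eigenvalue=eigenvalue,
        pairs=tuple(pairs),
        mean_folded=f.mean,
        mean_unfolded=u.mean,
        s_w=s_w,
        s_b=s_b,
        global_mean=global_mean,
        separated=True,
    )


def solve_hlda_eig(stats: dict[str, StateStats]) -> tuple[float, np.ndarray]:
    """Leading eigenpair of ``S_b W = lambda S_w W`` via a dense generalized
    eigensolver.  Kept as the multi-purpose fallback and as an independent
    cross-check of the rank-1 closed form; returns ``(lambda, unit W)``.
    """
    f, u = stats[FOLDED], stats[UNFOLDED]
    s_w = harmonic_within_scatter(f.cov, u.cov)
    s_b = between_scatter(f.mean, u.mean)
    vals, vecs = linalg.eigh(s_b, s_w)
    lead = int(np.argmax(vals))
    w = vecs[:, lead]
    return float(vals[lead]), w / np.linalg.norm(w)


def project(matrix: DescriptorMatrix, model: HLDAModel) -> np.ndarray:
    """Project frames onto the CV: ``s = sum_{p<q} W_pq d_pq`` per frame.

    Columns are matched to the model's pairs by label, so the matrix may
    carry extra descriptors or a different column order.
    """
    missing = [pq for pq in model.pairs if pq not in matrix.pairs]
    if missing:
        raise ValueError(f"descriptor matrix lacks pairs required by the model: {missing}")
    sub = matrix.select(model.pairs)
    return sub.values @ model.weights
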