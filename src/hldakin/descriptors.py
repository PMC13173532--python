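"""Pairwise-distance descriptor matrices and redundancy pruning.

The descriptor space for a two-state peptide system is the set of backbone
(Calpha) distances between residue pairs ``(p, q)`` with ``p < q``.  Highly
correlated descriptors make the per-state covariance matrices ill-conditioned,
so redundant columns are removed by an iterative Spearman-correlation filter
before any discriminant analysis is attempted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptorMatrix",
    "PruningReport",
    "compute_pair_distances",
    "prune_descriptors",
    "pair_label",
]


def pair_label(p: int, q: int) -> str:
    """Canonical column name ``d_p_q`` for the residue pair (p, q), p < q."""
    if not p < q:
        raise ValueError(f"pair labels require p < q, got ({p}, {q})")
    return f"d_{p}_{q}"


@dataclass(frozen=True)
class DescriptorMatrix:
    """Frames-by-descriptors matrix of inter-residue distances.

    Parameters
    ----------
    values
        Array of shape ``(n_frames, n_descriptors)``; distances (or toy
        descriptor values) per frame.
    pairs
        One ``(p, q)`` residue pair per column, ``p < q``, unique.
    frame_labels
        Optional per-frame state labels (e.g. ``"folded"`` / ``"unfolded"``).
    """

    values: np.ndarray
    pairs: tuple[tuple[int, int], ...]
    frame_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("descriptor values must be 2-D (frames x descriptors)")
        pairs = tuple((int(p), int(q)) for p, q in self.pairs)
        if values.shape[1] != len(pairs):
            raise ValueError(
                f"{values.shape[1]} columns but {len(pairs)} pair labels"
            )
        if len(set(pairs)) != len(pairs):
            raise ValueError("pair labels must be unique")
        for p, q in pairs:
            if not p < q:
                raise ValueError(f"pair ({p}, {q}) violates p < q")
        if not np.all(np.isfinite(values)):
            raise ValueError("descriptor values must be finite")
        if self.frame_labels is not None and len(self.frame_labels) != values.shape[0]:
            raise ValueError("frame_labels length must equal the number of frames")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [pair_label(p, q) for p, q in self.pairs]

    @property
    def residues(self) -> list[int]:
        """Sorted residue indices touched by at least one pair."""
        return sorted({r for pq in self.pairs for r in pq})

    def column(self, pair: tuple[int, int]) -> np.ndarray:
        return self.values[:, self.pairs.index((int(pair[0]), int(pair[1])))]

    def select(self, pairs: Sequence[tuple[int, int]]) -> "DescriptorMatrix":
        """Return a copy restricted to (and ordered by) the given pairs."""
        idx = [self.pairs.index((int(p), int(q))) for p, q in pairs]
        return replace(
            self,
            values=self.values[:, idx],
            pairs=tuple(self.pairs[i] for i in idx),
        )

    def restrict_frames(self, mask: np.ndarray) -> "DescriptorMatrix":
        mask = np.asarray(mask, dtype=bool)
        labels = (
            tuple(np.asarray(self.frame_labels, dtype=object)[mask])
            if self.frame_labels is not None
            else None
        )
        return replace(self, values=self.values[mask], frame_labels=labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.frame_labels is not None:
            df.insert(0, "state", list(self.frame_labels))
        return df


@dataclass(frozen=True)
class PruningReport:
    """Account of a Spearman-correlation pruning pass.

    ``dropped`` maps each removed pair to ``(partner_pair, rho)`` — the kept
    (or later-removed) partner it was correlated with and the correlation at
    the moment of removal.  Zero-variance columns are recorded with partner
    ``None`` and ``rho = nan``.
    """

    kept: tuple[tuple[int, int], ...]
    dropped: tuple[tuple[tuple[int, int], tuple[int, int] | None, float], ...]
    cutoff: float

    @property
    def dropped_pairs(self) -> list[tuple[int, int]]:
        return [entry[0] for entry in self.dropped]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "descriptor": pair_label(*pq),
                "status": "dropped",
                "partner": pair_label(*partner) if partner is not None else "",
                "rho_at_removal": rho,
            }
            for pq, partner, rho in self.dropped
        ] + [
            {"descriptor": pair_label(*pq), "status": "kept", "partner": "", "rho_at_removal": np.nan}
            for pq in self.kept
        ]
        return pd.DataFrame(rows)


def compute_pair_distances(
    frames: np.ndarray,
    residue_indices: Sequence[int] | None = None,
    min_separation: int = 2,
) -> DescriptorMatrix:
    """Euclidean Calpha–Calpha distances for all residue pairs per frame.

    Parameters
    ----------
    frames
        Coordinates of shape ``(n_frames, n_residues, 3)``; one position
        (the Calpha atom) per residue.
    residue_indices
        Residue numbering for the second axis (default ``1..n``); separation
        is measured on this numbering.
    min_separation
        Minimum ``|p - q|``; sequence-adjacent backbone distances are nearly
        constant and only ill-condition the state covariances, so the default
        skips neighbours closer than 2.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, n_residues, 3)")
    if not np.all(np.isfinite(frames)):
        raise ValueError("coordinates contain non-finite values")
    n_res = frames.shape[1]
    if residue_indices is None:
        residue_indices = list(range(1, n_res + 1))
    if len(residue_indices) != n_res:
        raise ValueError("residue_indices length must match coordinate axis 1")

    pairs: list[tuple[int, int]] = []
    cols: list[np.ndarray] = []
    for i, j in itertools.combinations(range(n_res), 2):
        p, q = sorted((int(residue_indices[i]), int(residue_indices[j])))
        if abs(p - q) < min_separation:
            continue
        pairs.append((p, q))
        cols.append(np.linalg.norm(frames[:, i] - frames[:, j], axis=1))
    if not pairs:
        raise ValueError("no residue pairs satisfy the separation filter")
    return DescriptorMatrix(values=np.column_stack(cols), pairs=tuple(pairs))


def _mean_abs_offdiag(corr: np.ndarray, i: int, active: np.ndarray) -> float:
    others = active.copy()
    others[i] = False
    if not others.any():
        return 0.0
    return float(np.nanmean(np.abs(corr[i, others])))


def prune_descriptors(
    matrix: DescriptorMatrix,
    cutoff: float = 0.93,
) -> tuple[DescriptorMatrix, PruningReport]:
    """Iteratively drop one descriptor from every over-correlated pair.

    The Spearman correlation matrix of all columns is computed once; while any
    pair of remaining columns has ``|rho| > cutoff`` the worst-offending pair
    is found and one member removed.  The member discarded is the one with the
    larger mean ``|rho|`` to all other remaining descriptors (ties broken by
    lexicographic pair label), which makes the result independent of column
    order.  Absolute correlation is used throughout: an anti-correlated
    duplicate carries no extra information either.

    Zero-variance columns are dropped up front (their rank correlation is
    undefined) and recorded in the report with an ``nan`` correlation.

    Returns the pruned matrix and a :class:`PruningReport` accounting for
    every input column.  The postcondition ``max |rho| <= cutoff`` over kept
    pairs is asserted on every run.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if matrix.n_frames < 2:
        raise ValueError("pruning needs at least 2 frames")

    values = matrix.values
    pairs = list(matrix.pairs)
    dropped: list[tuple[tuple[int, int], tuple[int, int] | None, float]] = []

    variances = values.var(axis=0)
    active = variances > 0.0
    for i in np.flatnonzero(~active):
        dropped.append((pairs[i], None, float("nan")))

    if active.sum() >= 2:
        corr = np.full((len(pairs), len(pairs)), np.nan)
        idx = np.flatnonzero(active)
        sub, _ = stats.spearmanr(values[:, idx])
        sub = np.atleast_2d(sub)
        corr[np.ix_(idx, idx)] = sub

        while True:
            act = np.flatnonzero(active)
            if len(act) < 2:
                break
            absc = np.abs(corr[np.ix_(act, act)])
            np.fill_diagonal(absc, 0.0)
            worst = np.nanmax(absc)
            if not worst > cutoff:
                break
            # all pairs attaining the worst correlation; pick the label-wise
            # smallest so the iteration order never depends on column order
            offenders = [
                tuple(sorted((act[a], act[b]), key=lambda k: pairs[k]))
                for a, b in zip(*np.where(absc >= worst - 1e-15))
                if a < b
            ]
            i, j = min(offenders, key=lambda ij: (pairs[ij[0]], pairs[ij[1]]))
            # discard the member more redundant overall
            mi = _mean_abs_offdiag(corr, i, active)
            mj = _mean_abs_offdiag(corr, j, active)
            if mi > mj or (mi == mj and pairs[i] > pairs[j]):
                out, partner = i, j
            else:
                out, partner = j, i
            dropped.append((pairs[out], pairs[partner], float(corr[out, partner])))
            active[out] = False

    kept_idx = np.flatnonzero(active)
    pruned = matrix.select([pairs[i] for i in kept_idx])
    report = PruningReport(
        kept=tuple(pairs[i] for i in kept_idx),
        dropped=tuple(dropped),
        cutoff=float(cutoff),
    )

    if pruned.n_descriptors >= 2:
        check, _ = stats.spearmanr(pruned.values)
        check = np.atleast_2d(np.asarray(check))
        np.fill_diagonal(check, 0.0)
        if np.nanmax(np.abs(check)) > cutoff + 1e-12:
            raise AssertionError("pruning postcondition violated: residual |rho| > cutoff")
    return pruned, report
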