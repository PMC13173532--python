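"""Per-residue kinetic importance scores and mutant screening reports.

The CV weights live on residue *pairs*; a residue-level score is obtained by
averaging the magnitude of every kept pairwise weight that touches a residue,

    I_r = (1/|N_r|) sum_{q in N_r} |W_rq|,

where ``N_r`` is the set of partners of residue ``r`` in the kept descriptor
set.  Residues with large ``I_r`` contribute strongly to the folded/unfolded
separation and act as kinetic hot spots: perturbing them is most likely to
reshape the barrier.  The average deliberately runs over the *kept*
(post-pruning) pairs only — those are the pairs that define the CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hlda import HLDAModel

__all__ = [
    "ResidueImportanceProfile",
    "ScreeningReport",
    "residue_importance",
    "rank_hotspots",
    "screen_mutants",
]

FASTER = "faster"
SLOWER = "slower"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ResidueImportanceProfile:
    """Raw and max-normalized per-residue importance scores.

    ``unscored`` lists residues present in the original descriptor set but
    absent from every kept pair (``|N_r| = 0``); they carry no measured
    importance and are reported as missing rather than zero.
    """

    residues: tuple[int, ...]
    scores: np.ndarray
    normalized: np.ndarray
    n_partners: tuple[int, ...]
    unscored: tuple[int, ...] = ()
    all_zero: bool = False

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        norm = np.asarray(self.normalized, dtype=float)
        if np.any(scores < 0):
            raise ValueError("importance scores must be non-negative")
        if not self.all_zero and norm.size and not np.isclose(norm.max(), 1.0):
            raise ValueError("normalized profile must have max exactly 1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "normalized", norm)

    def score_of(self, residue: int) -> float:
        return float(self.scores[self.residues.index(residue)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "n_partners": self.n_partners,
                "importance": self.scores,
                "normalized": self.normalized,
            }
        )


@dataclass(frozen=True)
class ScreeningReport:
    """One row per mutant: separation score and predicted kinetic direction."""

    rows: pd.DataFrame
    reference_id: str
    reference_eigenvalue: float
    tolerance: float

    def direction_of(self, mutant_id: str) -> str:
        return str(self.rows.set_index("mutant")["direction"].loc[mutant_id])


def residue_importance(model: HLDAModel) -> ResidueImportanceProfile:
    """Aggregate |W_pq| into per-residue scores I_r (kept pairs only)."""
    residues = sorted({r for pq in model.pairs for r in pq})
    totals = {r: 0.0 for r in residues}
    counts = {r: 0 for r in residues}
    for (p, q), w in zip(model.pairs, model.weights):
        totals[p] += abs(float(w))
        totals[q] += abs(float(w))
        counts[p] += 1
        counts[q] += 1
    scored = [r for r in residues if counts[r] > 0]
    unscored = tuple(r for r in residues if counts[r] == 0)
    scores = np.asarray([totals[r] / counts[r] for r in scored])
    all_zero = bool(np.all(scores == 0.0)) or not scored
    normalized = scores.copy() if all_zero else scores / scores.max()
    return ResidueImportanceProfile(
        residues=tuple(scored),
        scores=scores,
        normalized=normalized,
        n_partners=tuple(counts[r] for r in scored),
        unscored=unscored,
        all_zero=all_zero,
    )


def rank_hotspots(
    profile: ResidueImportanceProfile, top_k: int | None = None
) -> list[int]:
    """Residues sorted by importance, descending; ties by residue index.

    ``top_k`` beyond the residue count returns the full ranking.
    """
    order = sorted(
        range(len(profile.residues)),
        key=lambda i: (-profile.scores[i], profile.residues[i]),
    )
    ranked = [profile.residues[i] for i in order]
    return ranked if top_k is None else ranked[:top_k]


def screen_mutants(
    reference_model: HLDAModel,
    mutant_models: dict[str, HLDAModel],
    tolerance: float = 0.05,
    reference_id: str = "reference",
    mutated_residues: dict[str, int] | None = None,
    wt_profile: ResidueImportanceProfile | None = None,
) -> ScreeningReport:
    """Classify each mutant's predicted kinetic direction from its lambda.

    A mutant whose separation score exceeds the reference by more than the
    relative ``tolerance`` is predicted ``slower`` (larger effective barrier),
    one below it ``faster``; within the band, ``neutral``.  Mutants flagged
    as non-separated are marked unreliable.
    """
    lam_ref = reference_model.eigenvalue
    records = []
    for mid, model in mutant_models.items():
        lam = model.eigenvalue
        if lam > lam_ref * (1.0 + tolerance):
            direction = SLOWER
        elif lam < lam_ref * (1.0 - tolerance):
            direction = FASTER
        else:
            direction = NEUTRAL
        site = (mutated_residues or {}).get(mid)
        site_importance = (
            wt_profile.score_of(site)
            if wt_profile is not None and site in (wt_profile.residues if wt_profile else ())
            else np.nan
        )
        records.append(
            {
                "mutant": mid,
                "eigenvalue": lam,
                "direction": direction,
                "mutated_residue": site if site is not None else pd.NA,
                "site_importance": site_importance,
                "reliable": model.separated,
            }
        )
    rows = pd.DataFrame(
        records,
        columns=[
            "mutant",
            "eigenvalue",
            "direction",
            "mutated_residue",
            "site_importance",
            "reliable",
        ],
    )
    return ScreeningReport(
        rows=rows,
        reference_id=reference_id,
        reference_eigenvalue=lam_ref,
        tolerance=float(tolerance),
    )
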