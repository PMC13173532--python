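"""High-level screening workflows tying the generator to the CV machinery.

These are the package's canonical recipes: sample within-basin ensembles from
a two-state spec, apply the exclusion-band state labeling, prune redundant
descriptors and fit the HLDA CV — the same loop a screening study runs once
per candidate mutant.
"""

from __future__ import annotations

import numpy as np

from .descriptors import DescriptorMatrix, prune_descriptors
from .hlda import HLDAModel, solve_hlda, state_statistics
from .structure import EXCLUDED, FOLDED, UNFOLDED
from .synthetic import TwoStateToySpec, map_to_descriptors, simulate_double_well

__all__ = ["state_restricted_descriptors", "fit_hlda_from_basins"]


def state_restricted_descriptors(
    spec: TwoStateToySpec,
    n_steps: int = 20_000,
    dt: float = 5e-4,
    band: float = 0.5,
    seed: int = 0,
) -> DescriptorMatrix:
    """Within-basin descriptor samples with exclusion-band state labels.

    One unbiased run is started in each well.  Frames are labeled by the
    latent coordinate — folded for ``x <= -band*a``, unfolded for
    ``x >= band*a``, excluded in between — so rare spontaneous escapes during
    the sampling runs cannot cross-contaminate the state statistics (the toy
    analog of the RMSD ``t_F``/``t_U`` exclusion rule).
    """
    a = spec.well_separation
    rows, labels = [], []
    s = seed
    for x0 in (-a, a):
        traj = simulate_double_well(spec, n_steps=n_steps, dt=dt, x0=x0, seed=s)
        mat = map_to_descriptors(traj, spec, seed=s + 1)
        state = np.where(
            traj.x <= -band * a,
            FOLDED,
            np.where(traj.x >= band * a, UNFOLDED, EXCLUDED),
        )
        rows.append(mat.values)
        labels += list(state)
        s += 1000
    return DescriptorMatrix(
        values=np.vstack(rows), pairs=spec.pairs, frame_labels=tuple(labels)
    )


def fit_hlda_from_basins(
    spec: TwoStateToySpec,
    seed: int = 0,
    n_steps: int = 20_000,
    dt: float = 5e-4,
    band: float = 0.5,
    prune_cutoff: float | None = 0.93,
) -> HLDAModel:
    """Sample both basins, prune redundant descriptors and fit the HLDA CV."""
    matrix = state_restricted_descriptors(spec, n_steps=n_steps, dt=dt, band=band, seed=seed)
    labels = np.asarray(matrix.frame_labels, dtype=object)
    if prune_cutoff is not None:
        matrix, _ = prune_descriptors(matrix, cutoff=prune_cutoff)
    stats = state_statistics(matrix, labels)
    return solve_hlda(stats, pairs=matrix.pairs)
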