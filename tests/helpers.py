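"""Shared end-to-end helpers and independent oracles for the test suite."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_rmsd(mobile, reference, n_starts=30, seed=0):
    """Independent oracle: direct numeric minimization over rotation angles."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ rot.T - ref) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def within_basin_matrix(spec, seed, n_steps=4000, dt=5e-4, band=0.5):
    """State-restricted descriptor samples with exclusion-band labels."""
    from hldakin.workflow import state_restricted_descriptors

    matrix = state_restricted_descriptors(
        spec, n_steps=n_steps, dt=dt, band=band, seed=seed
    )
    return matrix, np.asarray(matrix.frame_labels, dtype=object)


def fit_toy_model(spec, seed, n_steps=4000, prune_cutoff=None):
    """Convenience end-to-end HLDA fit on state-restricted toy samples."""
    from hldakin.workflow import fit_hlda_from_basins

    return fit_hlda_from_basins(
        spec, seed=seed, n_steps=n_steps, prune_cutoff=prune_cutoff
    )


def analytic_toy_lambda(spec):
    """Closed-form separation score of the linear-Gaussian toy.

    Within-well x variance is kT a^2 / (8 dU) (harmonic approximation), the
    state means are offsets +- a b, so lambda = 1/2 dmu^T S_w^-1 dmu with
    Sigma = var_x b b^T + diag(sigma^2) and S_w = Sigma / 2.
    """
    a = spec.well_separation
    var_x = spec.temperature_factor * a**2 / (8.0 * spec.barrier_height)
    b = spec.loading_vector
    sigma = np.diag(spec.descriptor_noise_sd**2) + var_x * np.outer(b, b)
    dmu = 2.0 * a * b
    return float(dmu @ np.linalg.solve(sigma / 2.0, dmu)) / 2.0
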