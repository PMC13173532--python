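"""Synthetic two-state systems: double-well Langevin dynamics in a latent
slow mode, linear mapping to a pairwise-distance-like descriptor space, and
Gaussian-hill biased escape runs.

The generator emulates the statistical structure of state-restricted MD
ensembles of a small two-state folder: a single dominant slow coordinate
``x`` in a symmetric double well ``U(x) = dU ((x/a)^2 - 1)^2`` (minima at
``x = -a`` for "folded" and ``x = +a`` for "unfolded", barrier ``dU`` in kT),
overdamped dynamics, and descriptors that respond linearly to the slow mode,

    d_j(t) = offset_j + b_j x(t) + Normal(0, sigma_j^2),

so each basin is a unimodal Gaussian cloud in descriptor space.  "Mutations"
are parameter perturbations of this latent Hamiltonian — most usefully the
well separation ``a``, which changes the folded/unfolded separability and,
through the Kramers prefactor, the escape time.  Everything is in reduced
units with kT = 1 by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .descriptors import DescriptorMatrix

__all__ = [
    "TwoStateToySpec",
    "LatentTrajectory",
    "BiasedRun",
    "toy_pairs",
    "default_toy_spec",
    "potential",
    "simulate_double_well",
    "sample_unbiased_fpts",
    "map_to_descriptors",
    "make_mutant",
    "run_biased_escape",
    "biased_escape_records",
    "generate_toy_coordinates",
]

# overdamped Euler-Maruyama is accurate (and stable) when the step resolves
# the stiffest curvature the walker can see; |x| <= 1.5 a bounds the range
# visited before the instability guard trips
_STABILITY_LIMIT = 0.1


def toy_pairs(n_residues: int, min_separation: int = 2) -> tuple[tuple[int, int], ...]:
    """Residue-pair labels (p, q), 1-based, |p - q| >= min_separation."""
    return tuple(
        (p, q)
        for p, q in itertools.combinations(range(1, n_residues + 1), 2)
        if q - p >= min_separation
    )


@dataclass(frozen=True, eq=False)
class TwoStateToySpec:
    """Parameters of a synthetic two-state system (the "mutant" knob).

    ``barrier_height`` (dU) and ``temperature_factor`` (kT) are in the same
    reduced energy unit; ``well_separation`` (a) sets the latent minima at
    ``+-a``; ``friction`` is the overdamped gamma (inverse time).  The
    descriptor map is per-pair: slope ``loading_vector``, baseline
    ``descriptor_offsets`` and noise ``descriptor_noise_sd``.
    """

    barrier_height: float
    well_separation: float
    friction: float = 1.0
    temperature_factor: float = 1.0
    loading_vector: np.ndarray = field(default_factory=lambda: np.ones(1))
    descriptor_offsets: np.ndarray | None = None
    descriptor_noise_sd: np.ndarray | float = 0.1
    n_residues: int = 10
    min_separation: int = 2

    def __post_init__(self) -> None:
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")
        if self.well_separation <= 0:
            raise ValueError("well_separation must be positive")
        if self.friction <= 0 or self.temperature_factor <= 0:
            raise ValueError("friction and temperature_factor must be positive")
        b = np.asarray(self.loading_vector, dtype=float)
        pairs = toy_pairs(self.n_residues, self.min_separation)
        if b.size != len(pairs):
            raise ValueError(
                f"loading_vector has {b.size} entries but {self.n_residues} residues "
                f"at min_separation {self.min_separation} give {len(pairs)} pairs"
            )
        offsets = (
            np.zeros(b.size)
            if self.descriptor_offsets is None
            else np.asarray(self.descriptor_offsets, dtype=float)
        )
        if offsets.size != b.size:
            raise ValueError("descriptor_offsets length must match loading_vector")
        sd = np.broadcast_to(
            np.asarray(self.descriptor_noise_sd, dtype=float), (b.size,)
        ).copy()
        if np.any(sd < 0):
            raise ValueError("descriptor_noise_sd must be non-negative")
        object.__setattr__(self, "loading_vector", b)
        object.__setattr__(self, "descriptor_offsets", offsets)
        object.__setattr__(self, "descriptor_noise_sd", sd)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TwoStateToySpec):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in self.__dataclass_fields__
        )

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return toy_pairs(self.n_residues, self.min_separation)


def default_toy_spec(
    n_residues: int = 10,
    focus_residue: int = 3,
    barrier_height: float = 5.0,
    well_separation: float = 1.0,
    focus_loading: float = 0.5,
    background_loading: float = 0.05,
    descriptor_noise_sd: float = 0.25,
    baseline_offset: float = 1.0,
) -> TwoStateToySpec:
    """A ten-residue-like toy whose slow-mode loading concentrates on every
    pair touching ``focus_residue`` — that residue is the planted kinetic
    hot spot the importance analysis should recover."""
    pairs = toy_pairs(n_residues)
    b = np.asarray(
        [focus_loading if focus_residue in pq else background_loading for pq in pairs]
    )
    offsets = baseline_offset + 0.1 * np.arange(len(pairs))
    return TwoStateToySpec(
        barrier_height=barrier_height,
        well_separation=well_separation,
        loading_vector=b,
        descriptor_offsets=offsets,
        descriptor_noise_sd=descriptor_noise_sd,
        n_residues=n_residues,
    )


@dataclass(frozen=True)
class LatentTrajectory:
    """Uniformly sampled latent-coordinate series (x[0] at t = 0)."""

    times: np.ndarray
    x: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if t.size != x.size or t.size < 1:
            raise ValueError("times and x must be equal-length and non-empty")
        if t.size > 1:
            steps = np.diff(t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
                raise ValueError("time grid must be uniform and increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ValueError("trajectory contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass(frozen=True)
class BiasedRun:
    """A Gaussian-hill biased escape attempt and its bias bookkeeping."""

    trajectory: LatentTrajectory
    s_series: np.ndarray
    bias_energy: np.ndarray  # V(s(t), t)/kT, one entry per frame
    hill_times: np.ndarray
    hill_centers: np.ndarray
    hill_heights: np.ndarray
    hill_width: float
    crossed: bool
    biased_fpt: float | None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.bias_energy) < -1e-12):
            raise ValueError("bias energy series must be non-negative")
        if self.crossed and self.biased_fpt is None:
            raise ValueError("crossed run must carry a biased FPT")


def potential(spec: TwoStateToySpec, x: np.ndarray | float) -> np.ndarray | float:
    """Double-well potential ``dU ((x/a)^2 - 1)^2`` in kT-compatible units."""
    a = spec.well_separation
    return spec.barrier_height * ((np.asarray(x) / a) ** 2 - 1.0) ** 2


def _check_stability(spec: TwoStateToySpec, dt: float) -> None:
    a = spec.well_separation
    # max |U''| over |x| <= 1.5 a: U'' = (4 dU / a^2) (3 (x/a)^2 - 1)
    max_curv = 4.0 * spec.barrier_height / a**2 * (3.0 * 1.5**2 - 1.0)
    if dt * max_curv / spec.friction >= _STABILITY_LIMIT:
        raise ValueError(
            f"dt = {dt} too large for barrier_height = {spec.barrier_height}, "
            f"well_separation = {a}: dt * max|U''| / gamma = "
            f"{dt * max_curv / spec.friction:.3g} >= {_STABILITY_LIMIT}"
        )


def simulate_double_well(
    spec: TwoStateToySpec,
    n_steps: int,
    dt: float,
    x0: float | None = None,
    seed: int = 0,
) -> LatentTrajectory:
    """Overdamped Euler-Maruyama integration of the latent double well.

    ``x_{n+1} = x_n - dt U'(x_n)/gamma + sqrt(2 kT dt / gamma) xi_n``; the
    long-run distribution is Boltzmann ``exp(-U/kT)``.  Deterministic given
    ``(spec, seed)``.  The walker leaving ``|x| > 10 a`` aborts with an
    error naming the step size.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    _check_stability(spec, dt)
    a = spec.well_separation
    if x0 is None:
        x0 = -a
    c_force = 4.0 * spec.barrier_height / a**4  # U'(x) = c x (x^2 - a^2)
    amp = math.sqrt(2.0 * spec.temperature_factor * dt / spec.friction)
    inv_gamma = dt / spec.friction
    noise = np.random.default_rng(seed).standard_normal(n_steps)
    xs = np.empty(n_steps + 1)
    xs[0] = x = float(x0)
    a2, bound = a * a, 10.0 * a
    for i in range(n_steps):
        # parenthesization matches the biased integrator so a zero-bias run
        # is bitwise identical at the same seed
        x = x - inv_gamma * (c_force * x * (x * x - a2)) + amp * noise[i]
        if not -bound < x < bound:
            raise ValueError(
                f"integration unstable at step {i} (|x| > 10 a) with dt = {dt} "
                f"for spec(barrier_height={spec.barrier_height}, "
                f"well_separation={a})"
            )
        xs[i + 1] = x
    times = dt * np.arange(n_steps + 1)
    return LatentTrajectory(times=times, x=xs, seed=seed)


def sample_unbiased_fpts(
    spec: TwoStateToySpec,
    n_events: int,
    dt: float,
    stop: float = 0.0,
    x0: float | None = None,
    max_steps: int = 20_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Brute-force unbiased first-passage times to ``x >= stop``.

    Integrates ``n_events`` independent walkers in lockstep (vectorized over
    walkers) and returns the crossing time of each.  Raises if any walker
    fails to cross within ``max_steps``.
    """
    _check_stability(spec, dt)
    a = spec.well_separation
    if x0 is None:
        x0 = -a
    c_force = 4.0 * spec.barrier_height / a**4
    amp = math.sqrt(2.0 * spec.temperature_factor * dt / spec.friction)
    inv_gamma = dt / spec.friction
    rng = np.random.default_rng(seed)
    x = np.full(n_events, float(x0))
    fpt = np.full(n_events, np.nan)
    active = np.ones(n_events, dtype=bool)
    if x0 >= stop:
        return np.zeros(n_events)
    for step in range(1, max_steps + 1):
        xa = x[active]
        xa = xa - inv_gamma * c_force * xa * (xa * xa - a * a) + amp * rng.standard_normal(
            xa.size
        )
        x[active] = xa
        hit = np.zeros_like(active)
        hit[active] = xa >= stop
        fpt[hit] = step * dt
        active &= ~hit
        if not active.any():
            return fpt
    raise RuntimeError(
        f"{int(active.sum())} of {n_events} walkers failed to cross within "
        f"{max_steps} steps"
    )


def map_to_descriptors(
    latent: LatentTrajectory, spec: TwoStateToySpec, seed: int = 0
) -> DescriptorMatrix:
    """Descriptor matrix ``d_j(t) = offset_j + b_j x(t) + Normal(0, sigma_j^2)``."""
    rng = np.random.default_rng(seed)
    x = latent.x[:, None]
    values = (
        spec.descriptor_offsets[None, :]
        + spec.loading_vector[None, :] * x
        + spec.descriptor_noise_sd[None, :]
        * rng.standard_normal((latent.x.size, spec.loading_vector.size))
    )
    return DescriptorMatrix(values=values, pairs=spec.pairs)


def make_mutant(spec: TwoStateToySpec, **deltas: float | np.ndarray) -> TwoStateToySpec:
    """A perturbed copy of a spec: each keyword is *added* to that field.

    ``make_mutant(spec, well_separation=0.5)`` increases the separation by
    0.5.  Perturbations must leave the spec valid (positive barrier and
    separation, non-negative noise); the original is unchanged.
    """
    updates = {}
    for name, delta in deltas.items():
        current = getattr(spec, name, None)
        if current is None:
            raise ValueError(f"unknown spec field: {name!r}")
        updates[name] = np.asarray(current) + np.asarray(delta) if isinstance(
            current, np.ndarray
        ) else current + delta
    return replace(spec, **updates)


def run_biased_escape(
    spec: TwoStateToySpec,
    cv_weights: np.ndarray,
    hill_height: float = 0.5,
    hill_width: float | None = None,
    pace: float = 5.0,
    stop: float = 0.0,
    max_steps: int = 2_000_000,
    dt: float = 5e-4,
    x0: float | None = None,
    seed: int = 0,
    well_tempered_factor: float | None = None,
) -> BiasedRun:
    """Escape run under the double well plus Gaussian hills on the CV.

    The biasing coordinate is the CV evaluated on the *noise-free* descriptor
    map, ``s(x) = w . offsets + (w . b) x`` — descriptor noise models
    measurement error and exerts no force.  Hills of ``hill_height`` (kT) and
    ``hill_width`` (CV units; default 0.2 a |w . b|, a tenth of the basin
    separation along s) are deposited at the walker's current ``s`` every
    ``1/pace`` time units, evaluated by direct summation.  With
    ``well_tempered_factor`` gamma_wt > 1, deposited heights are scaled by
    ``exp(-V/((gamma_wt - 1) kT))``.

    The run stops at the first frame with ``x >= stop`` (biased FPT, frame 0
    at time 0) or after ``max_steps`` with ``crossed=False``.  With
    ``hill_height = 0`` the dynamics is step-for-step identical to
    :func:`simulate_double_well` at the same seed.
    """
    w = np.asarray(cv_weights, dtype=float)
    if w.size != spec.loading_vector.size:
        raise ValueError("cv_weights dimension does not match the descriptor set")
    if not math.isclose(float(np.linalg.norm(w)), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError("cv_weights must be unit-norm")
    if hill_height < 0:
        raise ValueError("hill_height must be non-negative")
    if pace <= 0:
        raise ValueError("pace must be positive")
    if well_tempered_factor is not None and well_tempered_factor <= 1:
        raise ValueError("well_tempered_factor must exceed 1")
    _check_stability(spec, dt)

    a = spec.well_separation
    kT = spec.temperature_factor
    if x0 is None:
        x0 = -a
    c0 = float(w @ spec.descriptor_offsets)
    c1 = float(w @ spec.loading_vector)
    if hill_width is None:
        hill_width = 0.2 * a * abs(c1)
        if hill_width == 0.0:
            raise ValueError("CV is orthogonal to the slow mode; give hill_width explicitly")
    stride = max(1, int(round(1.0 / (pace * dt))))

    c_force = 4.0 * spec.barrier_height / a**4
    amp = math.sqrt(2.0 * kT * dt / spec.friction)
    inv_gamma = dt / spec.friction
    noise = np.random.default_rng(seed).standard_normal(max_steps)

    centers: list[float] = []
    heights: list[float] = []
    h_times: list[float] = []
    xs = [float(x0)]
    s_series: list[float] = []
    v_series: list[float] = []
    x = float(x0)
    crossed = False
    biased_fpt: float | None = None
    inv_w2 = 1.0 / (hill_width * hill_width)

    for step in range(max_steps + 1):
        s = c0 + c1 * x
        if centers:
            d = s - np.asarray(centers)
            g = np.asarray(heights) * np.exp(-0.5 * d * d * inv_w2)
            v = float(g.sum())
            dv_ds = float(-(g * d).sum() * inv_w2)
        else:
            v, dv_ds = 0.0, 0.0
        s_series.append(s)
        v_series.append(v / kT)
        if x >= stop:
            crossed = True
            biased_fpt = step * dt
            break
        if step == max_steps:
            break
        if step > 0 and step % stride == 0:
            h = hill_height
            if well_tempered_factor is not None:
                h *= math.exp(-v / ((well_tempered_factor - 1.0) * kT))
            centers.append(s)
            heights.append(h)
            h_times.append(step * dt)
        x = x - inv_gamma * (c_force * x * (x * x - a * a) + dv_ds * c1) + amp * noise[step]
        if not -10.0 * a < x < 10.0 * a:
            raise ValueError(
                f"biased integration unstable at step {step} with dt = {dt}"
            )
        xs.append(x)

    traj = LatentTrajectory(
        times=dt * np.arange(len(xs)), x=np.asarray(xs), seed=seed
    )
    return BiasedRun(
        trajectory=traj,
        s_series=np.asarray(s_series),
        bias_energy=np.asarray(v_series),
        hill_times=np.asarray(h_times),
        hill_centers=np.asarray(centers),
        hill_heights=np.asarray(heights),
        hill_width=float(hill_width),
        crossed=crossed,
        biased_fpt=biased_fpt,
    )


def biased_escape_records(
    spec: TwoStateToySpec,
    cv_weights: np.ndarray,
    n_runs: int,
    seed: int = 0,
    **kwargs,
):
    """Run ``n_runs`` seeded biased escapes and rescale them to FPT records.

    Seeds are drawn from a generator seeded with ``seed`` so runs are
    independent yet reproducible.  Returns ``(records, runs)``.
    """
    from .kinetics import censored_record, rescale_fpt

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    records = []
    runs = []
    for s in run_seeds:
        run = run_biased_escape(spec, cv_weights, seed=int(s), **kwargs)
        dt = run.trajectory.dt
        if run.crossed:
            records.append(rescale_fpt(run.bias_energy, dt, run.biased_fpt))
        else:
            records.append(
                censored_record(run.bias_energy, dt, run.bias_energy.size * dt)
            )
        runs.append(run)
    return records, runs


def generate_toy_coordinates(
    ref_folded: np.ndarray,
    ref_unfolded: np.ndarray,
    occupancy: Sequence[str],
    fluctuation_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Toy multi-frame coordinates: per-frame reference plus isotropic jitter.

    ``occupancy`` picks the reference per frame (``"folded"``/``"unfolded"``).
    """
    folded = np.asarray(ref_folded, dtype=float)
    unfolded = np.asarray(ref_unfolded, dtype=float)
    if folded.shape != unfolded.shape:
        raise ValueError(
            f"reference atom counts differ: {folded.shape} vs {unfolded.shape}"
        )
    if fluctuation_sd < 0:
        raise ValueError("fluctuation_sd must be non-negative")
    bad = set(occupancy) - {"folded", "unfolded"}
    if bad:
        raise ValueError(f"occupancy entries must be folded/unfolded, got {bad}")
    rng = np.random.default_rng(seed)
    frames = np.empty((len(occupancy),) + folded.shape)
    for i, state in enumerate(occupancy):
        ref = folded if state == "folded" else unfolded
        frames[i] = ref + fluctuation_sd * rng.standard_normal(ref.shape)
    return frames
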