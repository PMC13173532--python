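# Methods

This note records the models, estimators and design choices behind
`hldakin`, and what the synthetic testbed does and does not establish about
real molecular systems.

## The screening model

The package treats a conformational transition as escape from a metastable
basin over a single dominant barrier, projected onto one linear collective
variable (CV). Three assumptions underpin everything:

1. **Two well-defined metastable ensembles.** Within each basin the
   descriptor distribution is approximately unimodal (Gaussian to second
   order), so per-state means μ_I and covariances Σ_I summarize it.
2. **A single dominant slow mode.** The folded→unfolded transition is
   captured by one direction in descriptor space; the HLDA eigenvector is an
   estimate of that direction.
3. **Poisson escape statistics.** Dwell times in the folded basin are long
   compared to intra-basin relaxation, so unbiased first-passage times (FPTs)
   are exponential, `p(t) = k e^{−kt}`.

### HLDA

For two states the generalized eigenproblem `S_b W = λ S_w W` with
`S_b = ½ Δμ Δμᵀ` (rank 1) and harmonic within-class scatter
`S_w = (Σ_F⁻¹ + Σ_U⁻¹)⁻¹` has the closed-form solution
`W ∝ S_w⁻¹ Δμ`, `λ = ½ Δμᵀ S_w⁻¹ Δμ`. The implementation uses the closed
form (exact, no iteration) and keeps a dense generalized eigensolver as an
independently tested fallback. Conventions the algebra does not fix:

- **W is unit-Euclidean-norm** and signed so the CV **increases from folded
  to unfolded** (`Wᵀμ_U > Wᵀμ_F`). λ is invariant under both choices; the
  conventions make weights comparable across systems.
- **Covariances are unbiased** (n−1 denominator).
- **Ridge regularization** `ε·tr(Σ)/p·I` with ε = 1e−6 engages only when a
  state covariance has condition number above 1e10 (descriptor pruning is
  the primary defence; the ridge covers degenerate inputs).
- λ below ~1e3·machine-ε is flagged "no separation" rather than returning a
  meaningless eigenvector.

### Descriptor pruning

Redundant pairwise distances ill-condition Σ_I. The filter computes the
Spearman matrix once and repeatedly removes one member of the
worst-offending pair until no |ρ| exceeds the cutoff (default 0.93).
Choices the rule itself leaves open, fixed here for determinism:

- **Absolute** correlation — an anti-correlated duplicate is equally
  redundant.
- The member discarded is the one with the **larger mean |ρ|** to all other
  remaining descriptors; ties break lexicographically on the pair label, and
  among equally offending pairs the label-wise smallest is processed first.
  The result is therefore invariant to input column order, and the operation
  is idempotent.
- Zero-variance columns (rank correlation undefined) are dropped up front
  and recorded with an `nan` correlation in the report.
- Pair enumeration skips residue pairs closer than `min_separation = 2`
  along the chain: sequence-adjacent backbone distances are nearly constant
  and contribute only conditioning problems.

### Residue importance and screening

`I_r` averages |W_pq| over the **kept** (post-pruning) pairs touching
residue r — those are the pairs that define the CV. Residues pruned out of
every pair are reported as *unscored*, not as zero, to avoid implying
measured unimportance. Profiles are reported max-normalized (top residue
= 1). Mutant screening classifies direction by relative λ with a ±5%
neutral band; the band is a reporting choice, not a physical constant.

### State labeling and first passage

Frames are labeled by RMSD to a folded reference: folded for RMSD ≤ t_F,
unfolded for RMSD ≥ t_U, excluded in between (boundaries inclusive, per the
≤/≥ convention). The exclusion band keeps barrier-region frames out of the
training statistics. Defaults t_F = 0.25, t_U = 0.57 (nm for real
structures). RMSD uses optimal superposition over proper rotations only
(Kabsch via `scipy`'s `align_vectors`, residual recomputed explicitly for
full precision near zero); the backbone definition defaults to Cα atoms,
with the atom selection exposed in the PDB reader. First passage is the
time stamp of the first frame at or above the threshold, frame 0 = time 0.

### Kinetics from biased runs

Each biased run's physical FPT is the left Riemann sum
`t* = Σ_{t<τ} Δt·exp(V(t)/kT)` over its bias-energy series; the
acceleration factor is α = t*/τ ≥ 1. The rate is estimated by
**progressive exponential survival fitting**: for each cutoff m, the
empirical survival at the m fastest rescaled times, `S(t_(i)) = 1 − i/n`,
is fitted to `exp(−kt)` by nonlinear least squares; the m maximizing R²
wins. Key conventions:

- n in the survival level is the **total** record count: slower and
  never-crossed runs act as right-censoring. Discarding them would bias k
  upward (tested explicitly).
- R² is computed on survival values (`1 − SS_res/SS_tot`); a log-survival
  objective is available (`objective="log_survival"`). A CDF-space mode is
  deliberately absent — its residuals are identical to the survival
  residuals.
- A type-II censored maximum-likelihood rate
  `k̂ = m / (Σ_{i≤m} t_i + (n−m) t_m)` is computed at the selected cutoff as
  a cross-check and used to seed the nonlinear fit.
- A fixed fastest-fraction mode (e.g. 1/8) reproduces the fixed-subset
  fitting protocol.
- The percentile bootstrap interval resamples records and re-evaluates the
  censored-ML rate at the point fit's cutoff fraction (a full nonlinear
  scan per replicate would dominate runtime without changing the interval).

Exponentiality is validated two ways: a KS test against Exp(k̂) with the
rate treated as known, and a Lilliefors variant with the rate re-estimated
from the sample, whose null distribution is generated by seeded parametric
bootstrap (default 1000 replicates; the statistic is scale-free under the
exponential null, so the bootstrap rate is irrelevant). Screening criteria
p > 0.2 (KS) and p > 0.05 (Lilliefors) are reported as pass flags.
Note that the *fastest fraction* of a sample is a truncated sample: testing
it directly against a full exponential is invalid, so validation always runs
on the full crossed set.

Free-energy profiles are Boltzmann inversions of a histogram,
`F(s) = −kT log p̂(s)`, min-shifted to zero with empty bins masked. The
parabolic-basin barrier solves
`½κ_F(s−s_F)² = ½κ_U(s−s_U)² + ΔF` for the crossing between the minima and
returns the folded-side height; with unequal curvatures two crossings can
lie in the interval and the lower-energy one is taken (escape proceeds
through the lowest available crossing).

The threshold scan recomputes FPTs, MFPTs and the metric↔log-MFPT-ratio
correlation on a grid of first-passage thresholds. The reference system is
included in the correlation at log-ratio 0; log is natural.

## The synthetic testbed

`TwoStateToySpec` defines a latent double well `U(x) = ΔU((x/a)² − 1)²`
(minima ±a; barrier ΔU in kT) integrated by overdamped Euler–Maruyama,
`x' = x − Δt U′(x)/γ + √(2kTΔt/γ)·ξ`, in reduced units (kT = γ = 1).
Inertia adds nothing to a statistics testbed. The step check
`Δt·max|U″|/γ < 0.1` (max over |x| ≤ 1.5a) plus a hard |x| > 10a abort
guard the integration. Descriptors respond linearly to the slow mode,
`d_j = offset_j + b_j x + N(0, σ_j²)`, so each basin is a Gaussian cloud —
exactly the regime HLDA assumes.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| ΔU | 5 kT | rare-event regime (MFPT ~ 15–20 time units) still samplable by brute force for cross-checks |
| a | 1.0 | length unit; "mutations" move it (Kramers prefactor makes MFPT ∝ a² at fixed ΔU, so separation and slowness rise together, mirroring the parabolic-basin picture) |
| Δt | 5e−4 | satisfies the stability bound up to ΔU ≈ 8 |
| loadings b | 0.5 on every pair touching one focus residue, 0.05 elsewhere | plants a known kinetic hot spot the importance analysis must recover |
| descriptor noise σ | 0.25 | keeps pooled folded+unfolded correlations between hot-spot descriptors near 0.8, below the 0.93 pruning cutoff, while λ stays O(50); with σ ≈ 0.1 the pruning rule itself would collapse the planted hot-spot pairs to a single column |
| hill height / width | 0.5 kT / 0.2·a·|w·b| | small relative to ΔU; width ~10% of the basin separation along s |
| deposition pace | 5 per time unit (acceleration runs), 0.5 (distribution-validation runs) | 5 keeps deposition ~8 well-relaxation times apart and gives α ≈ 10; shape validation needs gentler deposition (see limitations) |
| state sampling | 20 000 steps per basin, exclusion band at ±0.5a | ~500 effective slow-mode samples per state; the band keeps spontaneous escapes during sampling out of the state statistics |

Biasing acts on the noise-free CV `s(x) = w·offset + (w·b)x` — descriptor
noise models measurement error and exerts no force. Hills are summed
directly (runs are short); an optional well-tempered factor scales deposited
heights. A zero-height run is bitwise identical to the unbiased integrator
at the same seed, which pins down the integration path.

**What the toy does not emulate:** multiple competing pathways or
intermediates, anharmonic/multimodal basins, nonlinear descriptor response,
state boundaries that move under mutation, and solvent/friction anisotropy.
Passing tests therefore demonstrate the correctness of the estimators and
the internal consistency of the screening logic under its stated
assumptions — not that λ predicts kinetics for any particular real protein.

## Numerical and statistical notes

- All generators are pure functions of (spec, seed); every stochastic test
  is seeded.
- The survival-fit scan is exhaustive over integer cutoffs (records number
  in the hundreds; no need for anything cleverer).
- At the default pace the *rescaled* FPT distribution is measurably
  non-exponential even though its mean is preserved (the biased escape time
  is dominated by deterministic hill filling). This is the known
  infrequent-metadynamics trade-off between acceleration and distribution
  fidelity; it is why the validation protocol uses pace 0.5, and why MFPT
  comparisons against brute force are held to a factor-2 standard rather
  than a distributional one.
- The parabolic-basin barrier overestimates the true ΔU of the quartic well
  (~7.5 vs 5 kT for the wild-type toy): harmonic curvatures understate the
  width of anharmonic basins. Its value is in *trends* across mutants, not
  absolute heights.
- Problem sizes used in the shipped study: 20 000 steps per basin for CV
  fits, 200 escapes for wild-type kinetics, 50 escapes × 5 seeds per mutant
  for the threshold scan, 100 brute-force events for the unbiased reference.

## Known limitations

- Two states only at the public surface; the multi-state eigensolver exists
  but has no workflow around it.
- The acceleration-factor estimator is the instantaneous-bias integral; a
  running-average variant is not implemented.
- Lilliefors p-values are bootstrap estimates with resolution 1/(n_boot+1).
- The CLI `scan` command requires a JSON manifest; it does not discover
  trajectory files on its own.
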