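# hldakin

Interpretable linear collective variables and rare-event kinetics for
two-state molecular systems — a toolkit for predicting how discrete
perturbations ("mutations") reshape a free-energy barrier and its unfolding
rate from **within-basin sampling alone**, without ever simulating a
transition.

It is aimed at molecular simulators and peptide/protein engineers who want a
cheap, physically grounded screen of candidate mutations before committing to
expensive rare-event calculations.

## The method

A two-state system (folded *F* / unfolded *U*) is described by pairwise
backbone distances `d_pq` between residues *p* < *q*. After removing
redundant descriptors (iterative Spearman filter, drop one member of any pair
with |ρ| > 0.93), harmonic linear discriminant analysis (HLDA) finds the
one-dimensional projection that best separates the two metastable ensembles:

- between-class scatter (two states):  `S_b = ½ (μ_F − μ_U)(μ_F − μ_U)ᵀ`
- within-class scatter (harmonic):     `S_w = (Σ_F⁻¹ + Σ_U⁻¹)⁻¹`
- CV weights: leading eigenvector **W** of `S_w⁻¹ S_b`, with the closed form
  `W ∝ S_w⁻¹ (μ_F − μ_U)` and leading eigenvalue
  `λ = ½ Δμᵀ S_w⁻¹ Δμ`

The CV is `s(R) = Σ_{p<q} W_pq d_pq(R)`. Three quantities drive the
screening logic:

1. **Residue importance** `I_r = (1/|N_r|) Σ_{q∈N_r} |W_rq|` — residues
   whose distances carry large CV weight are kinetic hot spots: mutating
   them is most likely to change the barrier.
2. **Separation score λ** — computed per mutant, it tracks the effective
   barrier: larger folded/unfolded separation (Marcus-like parabolic-basin
   picture) means a higher crossing point and slower unfolding.
3. **MFPT from accelerated sampling** — repulsive Gaussian hills deposited
   on the CV accelerate escape; each biased first-passage time τ is mapped
   back to physical time via `t* = Σ Δt·exp(V/k_BT)`, and the rate k is the
   maximizer of R² over progressive exponential survival fits
   `S(t) = exp(−kt)` of the fastest samples (uncrossed runs enter as
   right-censoring). MFPT = 1/k.

Because no all-atom data ship with the package, a synthetic two-state
generator (overdamped Langevin dynamics in a double well
`U(x) = ΔU((x/a)² − 1)²`, mapped linearly to descriptor space) provides
fully controlled systems whose mutants are parameter perturbations — most
usefully the well separation *a*, which raises both λ and the escape time.

## Worked example

```python
import numpy as np
from hldakin import (default_toy_spec, make_mutant, biased_escape_records,
                     fit_hlda_from_basins)
from hldakin.importance import residue_importance, rank_hotspots, screen_mutants
from hldakin.kinetics import fit_mfpt

wt = default_toy_spec(focus_residue=3)          # 10 "residues", hot spot planted at 3
model = fit_hlda_from_basins(wt, seed=42)       # sample both basins, prune, fit the CV
print(f"lambda_WT = {model.eigenvalue:.1f} over {len(model.pairs)} descriptors")

profile = residue_importance(model)
print("top hot spots:", rank_hotspots(profile, top_k=3))

mutant = make_mutant(wt, well_separation=0.4)   # wider basin separation
mut_model = fit_hlda_from_basins(mutant, seed=43)
report = screen_mutants(model, {"wide": mut_model})
print(report.rows[["mutant", "eigenvalue", "direction"]].to_string(index=False))

records, _ = biased_escape_records(wt, model.weights, n_runs=60, seed=44)
est = fit_mfpt(records)
print(f"MFPT = {est.mfpt:.1f} (R2 = {est.r_squared:.3f}, m = {est.m_selected}/{est.n_crossed})")
```

prints

```
lambda_WT = 57.3 over 36 descriptors
top hot spots: [3, 8, 7]
mutant  eigenvalue direction
  wide   92.861325    slower
MFPT = 23.3 (R2 = 0.988, m = 33/60)
```

Reading: the planted hot-spot residue 3 tops the importance ranking; the
wider-separation mutant has a larger λ and is classified *slower* (higher
barrier); the survival fit over the 33 fastest of 60 rescaled escapes gives
the wild-type MFPT in reduced time units.

A thin CLI mirrors the library (`hldakin simulate`, `label`, `fpt`,
`descriptors`, `prune`, `hlda`, `importance`, `screen`, `mfpt`, `scan`,
`correlate`); every subcommand exchanges plain TSV/JSON.

## Layout

| module | contents |
|---|---|
| `hldakin.synthetic` | double-well Langevin generator, descriptor map, mutants, hill-biased escapes |
| `hldakin.structure` | Kabsch RMSD, folded/unfolded labeling with exclusion band, first-passage detection |
| `hldakin.descriptors` | pairwise-distance matrices, Spearman-correlation pruning |
| `hldakin.hlda` | state statistics, scatter matrices, the HLDA eigenpair, CV projection |
| `hldakin.importance` | per-residue importance, hot-spot ranking, mutant screening |
| `hldakin.kinetics` | FPT rescaling, survival fits, exponentiality tests, FES, parabolic barriers, threshold scans |
| `hldakin.workflow` | end-to-end basin-sampling → pruning → CV recipes |
| `hldakin.io`, `hldakin.cli` | plain-text formats (TSV/JSON/PDB/XYZ) and the command line |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
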