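# Methods

## The model

A plastic cell is a gene regulatory network of `Ng` genes with
continuous, strictly non-negative concentrations `g_i ≥ 0` and signed
interaction strengths `B_ij ∈ [−1, 1]` (`B_ij` is the effect of gene
`j` on the transcription of gene `i`). Development integrates

    dg_i/dt = R(h_i) / (K_M + R(h_i)) − μ g_i,

with `R(x) = max(x, 0)` (the Ramp function; inhibition cannot produce
negative concentrations) and saturating Michaelis–Menten production.
The regulatory input is

    classical:     h_i = Σ_j B_ij g_j + EF_i·[i < Ne]
    second-order:  h_i = Σ_j g_j Σ_k B_ijk (g_k + EF_k·[k < Ne])

Each of the `Ne` binary environmental factors (`EF = +1` present, `−1`
absent) targets exactly one *environmentally sensitive* gene (genes
`0..Ne−1`); in the second-order (tensor) model the factors instead
modulate interaction strengths, so network topology is effectively
dynamic over developmental time. The cell phenotype is read from a
designated *gene of interest* (never one of the sensitive genes):
`+1` if its final concentration is at least the readout threshold,
`−1` otherwise. The ordered phenotypes over all `2^Ne` environments
form the cell's reaction norm — a Boolean function, stored as a truth
table whose row `r` encodes the environment with `EF_i` present iff
bit `i` of `r` is set.

### Parameter defaults (all overridable)

| parameter | default | meaning |
| --- | --- | --- |
| μ | 0.1 | decay rate, per time unit |
| K_M | 1 | Michaelis–Menten coefficient |
| δt | 10⁻² | Euler step |
| max_steps | 10⁶ | integration cap (Euler steps) |
| stability_window | 1000 | steps between compared snapshots |
| stability_tol | 0.01 | relative change defining a steady state |
| stability_floor | 10⁻² | scale floor of the per-gene stability test |
| g_i(0) | 0.1 ± U(−10⁻², 10⁻²) | noisy initial condition |
| phenotype threshold | 10⁻² | `g_goi` at/above ⇒ phenotype +1 |
| ν half-width | 0.1 | mutation step `B_ij → B_ij + U(−0.1, 0.1)` |
| p (mutation) | 1/Ng | per-entry probability (1/Ng² for tensors) |

The tensor mutation probability keeps the expected number of mutated
entries equal to `Ng` for both genome kinds, so mutational pressure is
comparable across the two implementations.

### Steady-state detection

Every `stability_window` steps the current concentrations are compared
with the previous snapshot; the state is steady when **every** gene
satisfies

    |Δg_i| ≤ stability_tol · max(g_i, stability_floor).

Two numerical choices matter here and are deliberate:

* The comparison is per gene rather than normalised by the largest
  concentration in the snapshot. Normalising by `max g` lets a gene
  that is still drifting slowly through the readout region freeze
  prematurely whenever another gene is large, which corrupts the
  binary phenotype; the per-gene test does not.
* The floor equals the phenotype threshold, so a decaying gene is only
  considered settled once it is far below the region where its exact
  value could flip the phenotype. A fully decayed network (the empty
  ancestor `B = 0` in the all-absent environment) therefore reads out
  `−1`, as it must.

A network that fails to settle within `max_steps` is *unstable*
(empirically cyclic or chaotic) and treated as lethal: during
evolution the mutation is discarded and redrawn (up to a redraw cap),
and in random scans the genome is resampled and counted.

## Complexity of a reaction norm

With outputs `P` uniform over the `2^Ne` table rows,

    Ω = 1 − max_i I(P, EF_i) / H(P),

with Shannon entropies in bits. Ω = 0 for single-input identity
functions, 1 for XOR/XNOR, 0.6163 for AND-like functions. Constant
(non-plastic) tables have `H(P) = 0` and Ω undefined; a `zero` policy
is available for analyses that pool non-plastic networks with Ω = 0.
Function classes: `non_plastic` (constant), `single_input`
(`±EF_i`), `linear_other` (otherwise linearly separable),
`non_linear` (not separable). Separability is decided exactly for
`Ne ≤ 4` by membership in the enumerated set of threshold functions
(integer-weight grid from Muroga's bound; the enumeration reproduces
the known counts 4/14/104/1882) and by a capped perceptron iteration
above that, where convergence is guaranteed iff separable.

## Evolutionary protocol

Hill climbing with viability selection: one resident genome, one
mutant per generation, fitness `W` = fraction of (training) truth-table
rows whose expressed phenotype matches the target, fixation iff
`W_m ≥ W`. Ties are accepted, so neutral drift along equal-fitness
ridges is permitted. With connection costs the selected quantity is
`W_t = W − λ·CC` with `CC` the mean absolute (L1) or mean squared (L2)
interaction strength; the *stopping* rule always watches raw `W`, so
regularisation shapes the path, not the goal.

Initial concentrations are drawn once per evolutionary run and reused
for every environment, generation and the post-training expression:
genomes are the only heritable, varying state. (Stand-alone
`develop`/`express_function` calls draw fresh noise per development;
that mode backs the noise-robustness checks and the random scans.)

`drift_generations` keeps the run going for a fixed number of
generations after the fitness target is first hit. This matters for
the generalisation experiments: the first training-consistent genome
the climber stumbles on is an arbitrary minimal perturbation of the
ancestor and carries essentially no inductive bias, whereas continued
neutral drift on the training-fitness plateau lets the lineage settle
into the bulk of the training-consistent region of genome space —
which the random-scan experiment shows is overwhelmingly occupied by
simple functions. The generalisation drivers default to a 1000-
generation drift phase; setting it to 0 recovers the stop-at-first-hit
protocol (and, measurably, chance-level completion of unseen rows).

## Experiments

* **Evolvability** (`exp1_evolvability`): generations to reach
  `W ≥ 0.9` and `W = 1` from the empty network, per
  (Ne, Ng, Ω-constraint) cell, for classical and tensor genomes.
* **GRN-space scan** (`exp2_scan`): random genomes with per-genome
  density `p ~ U(0,1)` and entry values `N(U(−1,1), 0.1)` clamped to
  `[−1,1]` (drawing the mean per genome spreads networks across the
  whole density × strength plane instead of collapsing the mean
  strength to 0.5); each stable genome is classified by the function
  it expresses. Gene count is uniform on 4..23.
* **Transitions** (`exp3_transitions`): networks trained to `W = 1` on
  a class-`a` target are cloned and re-evolved to a class-`b` target;
  the likelihood estimate of `a → b` is the mean of
  `1/max(generations, 1)` (failed replicates contribute 0; the
  `max(·,1)` keeps a zero-generation transition finite). The long-term
  class distribution iterates `x ← x + dt·P x` with renormalisation
  each step until convergence; the fixed point is the dominant
  eigenvector of `P`, hence invariant to uniform rescaling of the
  matrix. The three default classes are single_input (Ω = 0),
  linear_other (0 < Ω < 1) and non_linear (Ω = 1).
* **Generalisation** (`exp4a_generalise`): train on `TS` random rows
  (with plateau drift), then score all `2^Ne` rows. The chance
  baseline for unseen rows is `(2^Ne − TS)/2`;
  `random_completion_matches` provides the bias-free control that
  realises exactly that baseline.
* **Morphogen patterning** (`build_morphogen_field`, `exp4b_pattern`):
  a 50×25 field (1250 cells) with three gradients — stripes
  `sin(x·k)` with a 10-cell period, a radial gradient from the
  anterior-left corner, and lateral distance from the mid-row —
  thresholded at field-wise quantiles into 5 binary inputs (1 bit from
  the stripe, 2 each from the other two; quantile thresholds guarantee
  every bit is informative). The target pattern applies
  `AND(OR(AND(EF1,EF2), AND(EF2,EF3)), EF1)` to one designated bit per
  morphogen, yielding a 32-row plasticity table. Cells are
  independent (no cell–cell signalling), so each distinct 5-bit
  environment is developed once and mapped to its cells. How three
  continuous gradients are discretised into five bits is a
  configuration choice, recorded in the field object, not an inference
  about any particular embryo.

## What the synthetic data does and does not emulate

All inputs are generated internally: random genomes, random targets of
prescribed complexity, and closed-form morphogen gradients. The model
captures saturating activation, decay, environmental sensing and
viability selection, but has no space (outside the morphogen
demonstration's read-only gradients), no cell–cell communication, no
transcriptional noise during development (noise enters only through
initial conditions), and no population-genetic structure (no
polymorphism, drift at fixed fitness only). Passing tests therefore
support claims about the inductive biases of this model class, not
quantitative rates in any real regulatory system.

## Scaling choices in the shipped tests

The package defaults mirror the full-scale protocol (`max_steps = 10⁶`).
The test suite and experiment defaults use desk-scale sizes chosen once:
integration cap 10⁵ steps (slow non-convergent dynamics are flagged
unstable sooner; such genomes are resampled/redrawn either way), 10⁴
genomes for the scan, 12–30 replicates and generation caps of
8000–15000 for the evolutionary comparisons. Medians are compared where
distributions are heavy-tailed. The full-scale quantities (e.g. exact
steady-state class frequencies from high-replicate transition
matrices) are represented in the suite by their invariant properties
and by rank-level agreement at reduced scale rather than by their
published point values.

## Known limitations

* The hill climber models strong-selection/weak-mutation dynamics;
  no recombination, population structure or explicit selection
  coefficients.
* Stability detection at a 1000-step window can in principle alias a
  limit cycle whose period divides the window exactly; the redundancy
  of repeated developments across environments makes a systematic
  misclassification unlikely, but the window is configurable.
* Ω compares only single-input informativeness; it does not
  distinguish among non-separable functions beyond Ω = 1, and
  constant functions need an explicit policy.
* For `Ne > 4` the function-sampling pool falls back to rejection
  sampling, which is slow for rare classes at large `Ne`.
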