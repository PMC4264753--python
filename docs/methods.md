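# Methods

## The model

A constraint-based metabolic model is the tuple `(S, lb, ub, c)`: the
stoichiometric matrix `S` (metabolites × reactions), per-reaction flux bounds
in mmol gDW⁻¹ hr⁻¹, and a biomass objective vector `c` with a single nonzero
entry. Flux balance analysis (FBA) solves

    maximize  c·v   subject to   S v = 0,   lb ≤ v ≤ ub,

a linear program whose optimum is the steady-state flux distribution
maximizing growth. We solve it with scipy's HiGHS backend. FBA optima are
generally degenerate (many vertices share the optimal biomass); HiGHS is
deterministic for a fixed model, so within this package all
replicate-to-replicate variation comes from impurity sampling, never from the
solver. The alternative-optimum ambiguity can additionally be canonicalized by
`minimize_total_flux`, a second LP that minimizes `Σ|vᵢ|` at fixed optimal
biomass (split positive/negative flux variables; biomass pinned by an equality
row, which makes the minimization idempotent — a two-sided tolerance band
would let the solver drain the slack on every call).

Reactions are partitioned into four classes. *Exchange* reactions touch
exactly one metabolite (boundary pseudo-reactions); *transport* reactions
carry a "transport" subsystem annotation or move the same chemical species
between compartments (BiGG suffix convention `_c`/`_e`/`_p`, regex
configurable); the *biomass* reaction is the unique objective column
(ambiguity is an error, never a guess); everything else is *internal*. Only
internal fluxes enter the classifier — exchange and transport fluxes encode
the environment directly and would make the inverse problem trivial.

## Growth environments

An environment is a primary carbon and a primary nitrogen source opened at
−20 mmol gDW⁻¹ hr⁻¹ (the conventional maximum uptake), `k` carbon and `k`
nitrogen *impurities* sampled uniformly without replacement from the substrate
pool and opened at −0.2 (1/100 of the primary rate), and oxygen at −18.5 when
the model has an oxygen exchange. All other pool exchanges are closed; bounds
outside the pool (ions, ATP maintenance) are left as the model encodes them.
Impurities are resampled per replicate and never coincide with a primary
source (a duplicate would silently raise the primary's uptake; this exclusion
is configurable). Excess-nutrient scenarios override one primary's uptake
(e.g. −1000 for excess carbon). Only-carbon or only-nitrogen impurity
scenarios are expressed as `k_N = 0` or `k_C = 0`.

Observations with biomass at or below the viability threshold are discarded.
The threshold is `mean − 3·SD` of the biomass values of a reference
simulation; the SD is the sample standard deviation (ddof = 1) and the
multiplier is configurable. The filter is applied before the train/test
split, so both halves draw from the same viable population.

## Classification

The classifier is L1-penalized multinomial logistic regression — the LASSO,
mixing parameter fixed at `α = 1` — following the GLMNET recipe: features are
standardized (zero mean, unit variance; constant columns pass through
unscaled) and coefficients are reported on the standardized scale; the penalty
path has 100 values by default, log-spaced from `λ_max` (the smallest penalty
zeroing every coefficient, `max_j,k |xⱼᵀ(1[y=k] − p̄_k)|/n`) down by a factor
10⁻⁴; `λ` is selected by stratified 3-fold cross-validated misclassification,
ties resolved toward the sparser model, with no one-standard-error rule. The
penalized fits themselves use scikit-learn's saga solver (tolerance 1e-3,
warm-started along the path), seeded so the whole fit is deterministic given
the configuration. Standardization and the penalty path are computed once on
the training data passed to `fit` and shared across CV folds. Requesting
`n_folds = n` switches to leave-one-out.

Before fitting, flux magnitudes below 1e-6 are set to exactly zero: LP
solutions carry numerical noise at that scale which would otherwise act as
spurious features and slow LASSO convergence.

Two prediction modes are compared. *Joint* prediction trains one classifier
whose classes are all carbon × nitrogen pairs. *Separate* prediction trains
one classifier per axis and pairs the predictions; an observation counts as
correct only when both axes are correct, and the combined misclassification
rate is counted at the observation level, so overlapping per-axis errors are
never double-counted. Hard labels (argmax of the per-class linear scores, ties
broken by class order) are used throughout; the class with fewer than
`n_folds` training observations is reported by name as untrainable — with one
observation per joint class, the 49-class model cannot be fit at all, which is
the motivating failure mode for separate prediction.

Reactions with nonzero coefficients at the selected penalty are the
*predictive reactions*. Ablation retrains both separate models with one
reaction column removed, using the identical seed and penalty-selection
procedure, so the reported delta reflects the feature removal alone.

## The toy generator

`generate_toy_model` emulates the topology that makes inverse prediction
informative in a real network: each substrate enters through its own exchange
and transport reaction, flows down a private internal pathway
(`pathway_length` reactions, default 3), and merges into a shared per-role
core that produces the carbon and nitrogen precursors consumed by biomass
(one unit of each per unit of growth). The `overlap` fraction moves pathway
reactions from private to shared: at 0 every substrate has a unique internal
signature with a closed-form optimal flux (`toy_ground_truth`, the oracle for
the LP solver — all stoichiometric coefficients are ±1 so the optimum is an
exact min-flow); at 1 all same-role substrates are indistinguishable from
internal fluxes and no classifier can beat the `1 − 1/k` chance rate on that
axis. The reference study uses 7 + 7 substrates, overlap 0.2, and 20
replicates per condition — small enough that the full pipeline (≈1000 LP
solves plus classifier training) runs in well under a minute.

What the toy establishes: the pipeline's plumbing end to end; that accuracy
degrades monotonically as impurity uptake approaches the primary rate
(collapsing to the two-axis chance rate when they are equal and the primary
and impurity become symmetric); that separate prediction dominates joint
prediction when training data are scarce; and that the selected predictive
reactions recover each substrate's private entry pathway. What it does not
establish: behaviour under the redundancy, cofactor coupling, and reversible
loops of a genome-scale reconstruction, where alternate optima and correlated
pathways make feature selection less clean. Genome-scale runs use the same
code paths via `load_model` and a substrate-pool TSV, and are exercised
through the CLI when a model file (e.g. iAF1260 BiGG JSON) is supplied.

## Numerical choices and edge cases

- Mass-balance residual on optimal solutions is bounded by 1e-6 (asserted in
  tests); bound violations by 1e-9.
- Infeasible or non-optimal replicates are recorded with biomass 0 and fall
  to the viability filter; they never abort a batch.
- The train/test split is stratified by (carbon, nitrogen) condition — the
  natural unit of replication — with `ceil(n/2)` observations in the test
  set; training subsets of a given size are stratified subsamples of the
  training half.
- k-means substrate selection (`select_distinct_substrates`) uses 10
  restarts at a fixed seed and returns the profile closest to each centroid.
- An all-zero flux vector standardizes to `−mean/scale` and is classified by
  the resulting affine score, i.e. effectively by intercepts.
- Test and acceptance runs shorten the penalty path (20 values down to
  10⁻² of `λ_max`) — on near-separable toy data the CV curve is flat over the
  tail of the default path, so the shorter grid selects equivalent models.

## Known limitations

- Transport detection relies on annotation or compartment suffixes; models
  with non-BiGG metabolite ids need a custom `compartment_regex`.
- The toy generator produces irreversible unit-stoichiometry chains only; it
  is deliberately not a miniature E. coli.
- Separate prediction's advantage is demonstrated on seeded scenarios, not
  proven; with abundant data and strong signal both modes saturate at zero
  error and the comparison is uninformative.
- SBML reading requires python-libsbml through cobrapy; BiGG JSON has no such
  dependency and is the format the package writes.
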