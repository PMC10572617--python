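# Methods

## Model

A pathway is a signed directed graph whose nodes carry one or more genes
(families or complexes) and whose edges are activations (+1) or inhibitions
(−1). Terminal *function* nodes are annotation labels of cellular outcomes;
signal is never propagated through them. An **effector** is a node whose
outgoing edges lead only to function nodes or nowhere, and its **circuit**
is the set of all nodes with a directed path to it, together with the
induced signed edges. Circuits from sibling effector branches deliberately
overlap: they share their upstream receptor sub-tree, and each is scored
independently.

Node values `v_n` are unit-interval summaries of the node's gene expression
(arithmetic mean by default; median or a percentile are selectable). The
signal at node *n* is

    S_n = v_n · (1 − ∏_{a∈A}(1 − s_a)) · ∏_{i∈I}(1 − s_i)

with the convention that an empty activation set contributes a factor of 1
(receptors emit their own value — the literal empty product would silence
every receptor) and an empty inhibition product is 1. Since all `v ∈ [0,1]`,
all signals stay in [0,1] at every step. The rule is monotone: raising a
node connected to the effector purely through activation edges can never
decrease the effector signal, and raising a node whose every path crosses
an odd number of inhibitions can never increase it. `graphs.
positive_influence_nodes` computes the unambiguously positive set by
parity-labelled reachability.

Acyclic circuits are solved exactly in one topological sweep. Cyclic
circuits are solved by Jacobi iteration from `S⁰ = v` with a fixed sweep
order (sorted node ids), stopping when `max |ΔS| < tol` (default 1e-6) or
after `max_iter` (default 1000) sweeps; circuits that hit the cap are
flagged `converged = False` in the output, never silently accepted. On
random cyclic topologies convergence exceeds 99% of seeded trials; the rare
non-convergent cases are antagonistic inhibition loops that oscillate with
period two. Self-loops are rejected at parse time because the rule has no
convention for them.

Raw effector signals shrink geometrically with circuit depth (a chain of
k nodes at value 0.5 yields 0.5^k), so activities are divided by a
per-circuit constant. The default (`length_norm=geometric`) divides by
0.5^L, L being the node count of the longest activation-only receptor→
effector path (strongly connected components are condensed, each
contributing its size, which keeps L well defined under cycles). The
alternative (`reference`) divides by the saturation signal obtained with
all values at 1 and purely inhibitory branches at 0, guarded at 1e-12; it
is identically 1 for activation-only chains, which is why it is not the
default. Because either normalization is a positive per-circuit constant,
sample orderings and scale-free statistics are unaffected; the choice is
cosmetic for inference. One caveat: the *moderated* t couples features
through the variance prior, so per-circuit rescaling perturbs moderated
statistics very slightly — exact invariance holds for the unmoderated
(d0 = 0) t and for Cox z-statistics, which is how the property is tested.

## Preprocessing

TMM scaling factors follow the published defaults of the method: the
reference sample minimizes the distance of its upper-quartile/library ratio
from the mean of that ratio; per sample, M and A values (on library-
normalized abundances, genes with a zero in either member of the pair
excluded) are doubly trimmed (30% on M, 5% on A, rank-based two-sided) and
the factor is 2 to the variance-weighted mean of the surviving M values
(weights: inverse delta-method binomial variances), finally rescaled to
geometric mean 1. The implementation is validated against
`edgeR::calcNormFactors` on a random fixture (rtol 1e-6).

Normalized values are `log2((count + 0.5) / (libsize·factor + 1) · 1e6)` —
strictly monotone in the count. Precision weights for the mean–variance
trend are *not* computed: activities are derived from the normalized
values themselves, and the differential fits below use unweighted least
squares on activities (which are not counts) and on log-CPM.

Per-gene rescaling to [0,1] clips each gene above its 0.99 quantile
(tempering single-sample outliers; configurable) and min–max maps;
constant genes map to 0.5. Pathway genes missing from the assay are
imputed as constant rows at the grand mean of all scaled entries ("average
expression of the dataset" admits several readings — grand mean was chosen;
`--impute-value` overrides).

## Differential analysis

Per feature, ordinary least squares on an intercept + condition (control
level as reference, so the contrast coefficient is case − control) + batch
dummies; rank-deficient designs (batch confounded with condition) abort
with the aliased columns named. Residual variances are shrunk toward a
scaled inverse-chi-square prior whose hyperparameters (d0, s0²) are fitted
by method of moments on log s², using the digamma/trigamma moments of log
chi-square variables and a Newton trigamma inverse. The moderated t uses
the posterior variance (d0·s0² + d·s²)/(d0 + d) on d0 + d df. The fit is
validated against `limma::squeezeVar` (rtol 1e-4) and pinned at both limits
(d0 = 0 reproduces the classical t to 1e-10; d0 = ∞ pins every variance to
s0²). With fewer than 10 positive-variance features the prior is not
estimable and the code falls back to the classical t. BH adjustment is the
standard step-up procedure (via statsmodels). Circuits significant with the
same direction in every contrast are intersected with effect sizes and FDRs
averaged across contrasts.

## Survival

Overall-survival records take `time = max(days_to_death,
days_to_last_follow_up)` with vital status as the event indicator; rows
without a usable positive time are dropped and counted. Each circuit gets a
univariate Cox fit (lifelines; Efron tie handling), reporting HR with 95%
CI, Harrell's concordance, Wald p, BH FDR across all tested circuits, and a
PH-assumption p from the score test of scaled Schoenfeld residuals against
Kaplan–Meier-transformed time. Constant-activity or non-converging circuits
are *kept* with p = 1 and NaN estimates so the BH denominator is
reproducible. `--standardize-activity` fits on z-scores: raw activities of
deep circuits live on tiny scales where per-unit HRs become astronomically
large or small, which is a display problem, not an inference problem
(Wald z is scale-invariant). KM groups cut at activity z-score ±0.5 — under
normality that includes Φ(−0.5) ≈ 30.9% of samples per tail (the stated
z-rule is implemented, not its occasional "quartile" gloss) — with a
log-rank test between high and low.

## TFTEA

Genes are ranked by the moderated t (configurable: any column of the
differential table) to a normalized rank r ∈ [0,1], ties broken by gene id;
the rank rather than the raw statistic is used for robustness to heavy
tails, and the fixed [0,1] support makes slopes comparable across gene
universes. Each regulon (grades A–E; default filter keeps A–C, minimum 5
targets) is tested by logistic regression of membership on r; the slope is
the log-odds ratio and p is the Wald test (indistinguishable from the LR
test at these sizes; pinned against a from-scratch IRLS fit to 1e-8).
Complete separation reports |lor| capped at 50 with p = 0 and a flag.
Reversing the ranking negates the slope exactly. BH runs across TFs per
contrast; the cross-contrast summary reports, per TF, the number of
significant contrasts and the average lor/FDR over them.

## Hallmarks

Effector genes carry association scores to the ten canonical hallmarks of
cancer; scores ≥ 0.15 (inclusive — the cutoff "selects", so ties pass) are
retained. A circuit counts once toward every hallmark that any of its
effector genes passes; multi-hallmark effectors therefore make counts sum
above the number of annotated circuits. Circuits with no passing effector
are tallied "unannotated". Counts and fractions (denominator: significant
circuits per condition) are both emitted since either may be plotted.

## Synthetic data

The generator emulates the statistical shape of a tumor-vs-normal RNA-seq
cohort, not any particular dataset. Defaults (one place, `SimulationSpec`):
5 pathways of 6–12 nodes, back-edge (cycle) probability 0.15, inhibition
probability 0.2, 1–3 genes per node; 30 cases vs 30 controls; negative-
binomial counts (dispersion 0.1) over log-normal abundances (log2 mean
≈ log2 150, sd 1.2), library sizes uniform in [0.8M, 1.2M]; two batches
assigned round-robin within each arm (orthogonal to condition by
construction; `--confound` makes batch equal condition to exercise the
aliasing guard) with gene-wise log-scale batch shifts of sd 0.1; three
planted circuits at ±1.5 log2; survival from an exponential baseline
(1/1000 events per day, i.e. median ≈ 2 years) with slope 1.0 per sd of one
circuit's activity and uniform censoring calibrated by bisection to 30%;
20 regulons of 30 targets, two of them sampled with weight e^(−tilt·r)
toward the top of the true effect ranking (tilt 40).

Planting is done carefully so the recorded truth is actually true: one
circuit per randomly chosen pathway (pathways share no genes, so effects
never collide); within the pathway, the *most responsive* circuit — the one
whose effector signal moves most when its positive-influence nodes swing —
because inhibitory cycles can pin a circuit at zero regardless of input;
and only genes of positive-influence nodes are shifted, so by monotonicity
the activity provably moves in the recorded direction. Pathways with no
responsive circuit are skipped.

What the generator does not emulate: gene–gene correlation beyond shared
circuit membership, length/GC biases, sample quality gradients, non-
mesenchymal contamination, or real pathway topologies. Passing recovery
tests therefore demonstrates the estimators' statistical correctness under
the model's own assumptions, not performance on any real cohort.

## Problem sizes

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: 500 circuits for solver-oracle agreement, 1000 propagation
property trials, 200 (tests) / 100 (script) replicates for moderated-t
calibration and Cox recovery at n = 300, 100/50 replicates of the planted
differential design (20/500 features, n = 30/30), 60 replicates for the PH
diagnostic's power and size, and 20 replicates of planted TFTEA enrichment.
These were chosen as the smallest designs whose Monte-Carlo error is well
below the margins being asserted.

## Known limitations

- The Jacobi solver's rare non-convergence (antagonistic inhibition loops)
  is flagged but not resolved; a damped or Gauss–Seidel scheme would change
  the documented solver contract.
- The exact depth-normalization constant used by other implementations of
  this model family is not published; both options here are explicit, and
  downstream inference is invariant to the choice.
- Moderated-t results depend (weakly) on per-feature scaling; see above.
- Degenerate regulons (covering the whole universe, or separated
  completely) are reported with flags rather than dropped, which keeps BH
  denominators stable but means flagged rows need attention before
  biological interpretation.
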