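# Methods

## Data model

The unit of analysis is a patient × variable binary matrix: 12
perioperative complications plus a single terminal outcome (30-day death),
each coded 1 if the event occurred. Ingestion is strict — every cell must
parse as 0/1 (or true/false); patients with missing complication
information are rejected rather than imputed, because a missing indicator
is indistinguishable from an absent complication and would bias every
count downstream. Variable order comes from the file header; a default
13-name catalog is provided for the simulator and reports. The analysis
cohort is, by default, the subset of patients with at least one
complication (death alone does not qualify); the full cohort is available
via a flag, since frequency denominators and parameter-learning cohorts
are both legitimate choices and the package does not force one.

## Descriptive layer

* Frequency/mortality: carrier count, percentage (denominator either the
  with-complication subset or all patients), deaths among carriers and
  mortality among carriers. Percentages are kept at full precision and
  rounded half-up to one decimal only for display, the convention of
  clinical frequency tables; a complication with zero carriers reports an
  explicit undefined sentinel, never a division by zero.
* Co-occurrence: the multiplicity histogram (patients with exactly k
  complications), the co-occurrence rate of each complication (fraction
  of its carriers with at least one other complication) and exact
  pattern counts.
* Phi coefficients: $\phi = (n_{11}n_{00} - n_{10}n_{01}) /
  \sqrt{n_{1\cdot}n_{0\cdot}n_{\cdot 1}n_{\cdot 0}}$, computed from
  contingency counts rather than a correlation routine; the algebraic
  identity with Pearson correlation on 0/1 data is exploited as an
  independent test oracle. Pairs involving a constant column are flagged
  undefined instead of silently propagating NaN.
* Collinearity: eigenvalues of the Pearson correlation matrix and the
  condition number, defined as sqrt(largest/smallest eigenvalue) — the
  convention under which values above 30 conventionally indicate severe
  multicollinearity. The plain eigenvalue ratio is available as an option
  because the convention is not universal; the mode used is recorded in
  the report.

## Structure learning

Score-based greedy hill-climbing over single-arc moves (add, delete,
reverse), accepting the best strictly improving move until a local
optimum. The default score is BIC — log-likelihood of each node given its
parents minus (log N)/2 per free parameter, 2^k free parameters for a
binary node with k parents; pure log-likelihood is available for testing.
The score decomposes over node families, so move evaluation touches only
the families it changes and family scores are cached. A blacklist forbids
arcs out of death (death cannot cause a complication); constraint and
acyclicity are checked per move. Equal-scoring moves are resolved toward
the lexicographically smallest (source, target, move-kind), making every
search fully deterministic.

Determinism has a cost: when the first arc between two variables is
added, both orientations score identically, and the tie-break picks one
systematically. Later arcs can make that early choice wrong (only
v-structures pin orientations), and single reversal moves cannot repair
several coupled misorientations, so a lone greedy pass can end in a local
optimum containing proxy arcs — measured on 20,000-patient synthetic
cohorts, such optima sat tens of nats below the generating structure and
carried spurious arcs. Random restarts therefore re-climb from seeded
random initial DAGs (about one random arc per node) and keep the best
optimum. Restarting from random graphs, rather than perturbing the
current optimum with extra arcs, is what allows different orientation
basins to be explored; perturbation by additions alone was tested and
left the misorientations intact. `hill_climb` defaults to zero restarts
(a plain greedy ascent); bootstrap averaging uses four restarts per
replicate by default, because averaging inherits any systematic search
artifact — if every replicate falls into the same wrong basin, its proxy
arcs masquerade as high-strength arcs.

Bootstrap model averaging draws N patients with replacement per
replicate (default 1000 replicates; replicate seeds are master seed +
replicate index so any replicate reproduces in isolation), learns a
network, and tallies arc presence and orientation. Arc strength is the
fraction of replicates containing the pair in either direction; direction
probability is conditional on presence, so the two orientations sum
to one. The averaged network keeps pairs with strength strictly above
0.75, orients them by majority direction when that direction's
probability is at least 0.5, and — should the kept arcs contain a cycle,
possible since replicates disagree — repeatedly drops the lowest-strength
arc on a cycle, preserving the strongest evidence.

## Parameter learning and inference

CPTs are maximum-likelihood: P(node=1 | parent config) =
(n(node=1, config) + α) / (n(config) + 2α), α = 0 by default. Parent
configurations never observed at α = 0 are assigned 0.5 and flagged
unsupported, keeping inference total while making extrapolation visible;
support counts are stored and exported so reports can annotate
low-evidence probabilities. Smoothing (α > 0) is offered because 0.5%
prevalence complications make empty parent configurations likely at
realistic cohort sizes.

Inference is exact — with 13 binary nodes approximate methods have no
place. The production path is variable elimination with a greedy
smallest-intermediate-factor ordering (the result is order-independent);
the oracle path enumerates the full 2^13 joint, and the two are compared
to 1e-10 in the test suite. Evidence with probability zero raises an
explicit impossible-evidence error. Evidence on death itself requires an
explicit diagnostic-query flag. The canonical reports are the
single-evidence posterior matrix (every target given each single
complication present; self-conditioning cells rendered as a dash) and the
death-probability table for 1–3 complication evidence combinations; the
critical complications are operationalized as the Markov blanket of
death.

## Synthetic cohort generator

The registry underlying the published analysis is not publicly available,
so the package ships a fully specified generating network. The default
13-node instance anchors each marginal prevalence to the published
frequency table (exact marginals verified by joint enumeration: the three
primary complications at 46–50%, rare severe complications at 0.5–3%;
largest deviation 0.007) and encodes the qualitative published structure:
the primary complications (chest tube drainage → prolonged ICU stay →
prolonged ventilation) as the chain at the root, mild complications
hanging off them, reoperation driven by tamponade, renal failure and
secondary intubation as intermediate severe nodes, MODS as a v-structure
child of renal failure and intubation, stroke as a near-isolated root
(clinically, stroke is driven by pre/intra-operative factors), and death
as a noisy-OR child of the four severe complications with leak 0.016 and
contributions 0.30/0.33/0.40/0.86 — monotone in every parent, giving
P(death | MODS = 1) ≈ 0.90. Thirteen of the 18 arcs have exact pairwise
phi ≥ 0.1 (up to 0.50); the complication–complication maximum is 0.37.
Rare-node prevalences stay at or above 0.005 so 20,000-patient samples
contain enough positives for CPT estimation.

Sampling is ancestral in a deterministic (lexicographic-tie-break)
topological order from one seeded generator, so cohorts are
bit-reproducible across runs and platforms.

What the generator does not emulate: continuous severity, event timing
(no complication sequences — the generating DAG is a modelling statement,
not observed temporal order), demographics, and inter-hospital
heterogeneity. Passing recovery tests therefore shows the estimators work
when the model class is correct; it says nothing about misspecification
on real registry data. One subtlety the simulator does expose: filtering
to patients with at least one complication conditions on a function of
all complication indicators and induces genuine selection dependence, so
networks learned on the filtered subset legitimately contain arcs absent
from the generating DAG. Structure-recovery evaluations accordingly use
unfiltered samples, for which the generating network is the true
distribution.

## Evaluation sizes and numerical choices

Evaluations use 20,000-patient cohorts with 200 bootstrap replicates for
structure recovery, 50,000 patients for parameter recovery, 100 random
13-node models for the inference oracle, and 50 replicates of the
three-node exhaustive-search comparison; together they run in about a
minute. Score improvements below 1e-9 are treated as ties; joint
normalization is checked to 1e-9; oracle agreement to 1e-10.

Two tolerance notes. Parameter recovery is asserted at ±0.02 with a
4-binomial-SE floor: at support 200–1000 and mid-range probabilities, a
flat 0.02 band is below one standard error and would fail by pure
sampling noise; the floor makes the check a statement about estimator
correctness rather than about luck. The same floor applies per evidence
column when comparing fitted-model posteriors to generating-model
posteriors, since columns conditioned on 0.5%-prevalence evidence rest on
a few hundred patients.

## Known limitations

* Arcs are statistical dependencies; no causal claim is made (the data
  cannot sequence complications, and selection into the analysis cohort
  adds non-causal dependence).
* Bootstrap strength measures stability under resampling of one cohort,
  not replication across cohorts: a chance dependence present in the
  drawn cohort (e.g. a structurally zero overlap between two rare
  complications where several co-occurrences were expected) is faithfully
  stable under the bootstrap and can be retained at high strength. Such
  arcs are properties of the data, not search failures; no averaging
  scheme removes them.
* BIC's parameter count (2^k per family) makes nodes with many parents
  expensive quickly; with 13 variables this is intended regularization,
  not a scalability feature.
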