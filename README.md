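# compnet

Bayesian-network analysis of perioperative complication co-occurrence.

Patients undergoing heart-valve surgery frequently develop several
perioperative complications in sequence — a mild event such as increased
chest tube drainage or prolonged mechanical ventilation can cascade into
renal failure, multiple organ dysfunction syndrome (MODS) and death.
`compnet` models a cohort of binary complication indicators (12
complications plus 30-day death) as a discrete Bayesian network, so that
the dependence structure among complications can be learned from registry
data and the probability of any complication — or of death — can be
updated exactly as evidence about a patient accumulates. It is written for
clinical-outcomes researchers who have (or can simulate) a patient × 
complication 0/1 matrix.

## Method

For binary variables $X_1,\dots,X_V$ the network is a DAG $G$ plus one
conditional probability table per node, defining the joint

$$P(x_1,\dots,x_V)=\prod_{i=1}^{V} P\!\left(x_i \mid \mathrm{pa}_G(x_i)\right).$$

The pipeline stages are:

1. **Descriptives** — per-complication frequency and mortality,
   complication-multiplicity counts, co-occurrence rates, the phi
   coefficient between every pair ($\phi$ is the Pearson correlation of
   two 0/1 variables, computed from the 2×2 contingency table), and an
   eigenvalue/condition-number multicollinearity diagnostic.
2. **Structure learning** — greedy hill-climbing over add/delete/reverse
   arc moves maximizing the BIC score
   $\sum_i \big[\log L(x_i\mid \mathrm{pa}(x_i)) - \tfrac{\log N}{2}\,2^{|\mathrm{pa}(x_i)|}\big]$,
   under a blacklist forbidding arcs out of death, followed by
   nonparametric bootstrap model averaging: arcs kept when their bootstrap
   strength exceeds 0.75 and oriented by majority direction (≥ 0.5).
3. **Parameter learning** — maximum-likelihood CPTs (optional Laplace
   smoothing), with explicit flags for parent configurations never
   observed.
4. **Inference** — exact P(target | evidence) by variable elimination,
   the single-evidence posterior matrix, the death-probability table for
   multi-complication evidence, and the Markov blanket of death (the
   "critical complications").
5. **Synthetic cohorts** — ancestral sampling from a configurable
   ground-truth network whose default instance matches the published
   marginal prevalences (0.5%–50% per complication), so the whole pipeline
   is testable without registry access.

## Worked example

```python
from compnet import (default_ground_truth, sample_cohort, filter_any_complication,
                     bootstrap_arcs, averaged_network, ArcBlacklist, fit_cpts,
                     query, critical_nodes, marginal_summary)

spec = default_ground_truth()
cohort = filter_any_complication(sample_cohort(spec, n=20_000, seed=7))
print(f"analyzed patients: {cohort.n_patients}")

row = marginal_summary(cohort, denominator="all").row("mods")
print(f"MODS: {row['count_with']} carriers ({row['pct_with']:.1f}%), "
      f"mortality {row['pct_death']:.1f}%")

blacklist = ArcBlacklist.default_for(cohort.catalog)
conf = bootstrap_arcs(cohort, blacklist=blacklist, replicates=100, seed=7)
dag = averaged_network(conf, strength_min=0.75, direction_min=0.5, blacklist=blacklist)
print(f"averaged network: {len(dag.arcs)} arcs, "
      f"min strength {min(conf.strength(u, v) for u, v in dag.arcs):.2f}")
print(f"critical complications: {sorted(critical_nodes(dag, 'death'))}")

bn = fit_cpts(dag, cohort, alpha=0.0)
for ev in ({"mods": 1}, {"postoperative_rf": 1},
           {"postoperative_rf": 1, "secondary_tracheal_intubation": 1}):
    label = ", ".join(f"{k}=1" for k in ev)
    print(f"P(death | {label}) = {100 * query(bn, 'death', ev):.1f}%")
```

Output:

```
analyzed patients: 16002
MODS: 260 carriers (1.6%), mortality 90.0%
averaged network: 20 arcs, min strength 0.87
critical complications: ['mods', 'postoperative_rf', 'secondary_tracheal_intubation', 'stroke']
P(death | mods=1) = 89.7%
P(death | postoperative_rf=1) = 54.8%
P(death | postoperative_rf=1, secondary_tracheal_intubation=1) = 81.9%
```

Reading: of 20,000 simulated patients, 16,002 had at least one
complication; MODS struck 1.6% of them and killed 90%. Bootstrap averaging
kept 20 arcs, all with strength ≥ 0.87, and the Markov blanket of death
identifies the four severe complications as critical. Conditioning the
fitted network on renal failure raises the death probability to 55%, and
adding secondary tracheal intubation to 82% — the cascade the network is
built to quantify.

The same pipeline runs from the shell:

```bash
compnet simulate --n 20000 --seed 7 --out cohort.csv
compnet run --in cohort.csv --out-dir results/ --replicates 1000 --seed 7
compnet infer --model results/model.json --target death --evidence mods=1
```

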