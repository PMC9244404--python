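# medinet

Mutual-information food networks, eating hubs and disability models for
Mediterranean-diet questionnaire cohorts.

Epidemiological studies of diet in multiple sclerosis (MS) increasingly ask
not just *how much* of each food people eat, but *which foods are eaten
together* — the dependence structure of the diet. `medinet` implements that
analysis end to end for two-group questionnaire cohorts (an MS group and
matched healthy controls, HC): it scores a nine-item Mediterranean-Diet
(MeDi) adequacy questionnaire together with lifestyle and anthropometric
indicators, builds categorical **mutual-information networks** over age
class, sex and the nine intake items, identifies **eating hubs**, compares
the two groups' matrices against a **reshuffle null**, and relates hubs and
lifestyle to disability (EDSS) and fatigue (FSS). Since participant-level
data of this kind are rarely distributable, the package also ships a
**synthetic cohort generator** (Gaussian-copula ordinal items with planted
Spearman correlations, plus calibrated outcome models) so the whole
pipeline is reproducible and testable from a single seed.

It is aimed at biostatisticians and epidemiologists who want a tested
reference implementation of this network methodology, or a simulation
sandbox for planning similar questionnaire studies.

## The method in brief

* **Dependence.** For categorical variables X, Y the plug-in mutual
  information `I(X;Y) = Σᵢⱼ p̂ᵢⱼ ln(p̂ᵢⱼ / p̂ᵢ· p̂·ⱼ)` (nats) measures
  association with no linearity assumption.
* **Network.** Nodes are age class, sex and the nine items; a pair is an
  edge when its MI is significant under a permutation test (default
  α = 0.05, 1000 permutations; a mean-MI threshold rule is also available).
* **Hubs.** Nodes whose degree strictly exceeds mean(degree) + SD(degree).
* **Group comparison.** Pool the two matrices' 110 upper-triangle entries,
  re-partition them 1000 times into random matrix pairs, difference each
  pair, and Z-score the observed MS−HC difference per cell against that
  null; |z| > 1.96 flags a cell.
* **Outcomes.** EDSS dichotomized at ≤1.5 vs ≥2, FSS at the cohort median;
  Spearman collinearity screen among hubs; per-hub bivariate logistic
  models (IRLS); hierarchical OLS with standardized betas for lifestyle
  models; a Wald-based sensitivity analysis for the minimum detectable
  logistic slope.

See `docs/methods.md` for formulas, defaults, calibration details and
limitations.

## Worked example

Run the full pipeline on a simulated default cohort (424 MS, 165 HC):

```bash
medinet run --seed 1 --out demo
```

This writes the scored table, per-group MI matrices and edge lists, the hub
report, the group comparison and the outcome models into `demo/`, plus a
`manifest.json` with the configuration and a SHA-256 hash of every output
(identical seeds give identical hashes). With seed 1 the hub report reads

```
MS degrees: age 0, sex 2, fruit 5, vegetables 5, legumes 0, cereals 3,
            fish 3, meat 1, dairy 1, olive_oil 2, alcohol 2
MS hubs:    fruit, vegetables     (threshold 3.90)
HC hubs:    vegetables, fish
```

i.e. the most inter-connected items in the MS diet are positive foods —
the four planted clique items (fruit, vegetables, cereals, fish) top the
degree list, and the two whose degrees exceed mean + SD are declared hubs.
The models report (`demo/models.json`) contains, among others:

```
sensitivity:        min detectable |beta| = 0.3195  (n=424, alpha=0.05, power=0.90)
disability ~ vegetables:  slope = -0.48, p = 0.0006
edss ~ pack_years + ipaq_met + negative_score:
                    R² = 0.050; std betas +0.182 / -0.085 / +0.103
fss ~ pack_years + ipaq_met:
                    R² = 0.033; std betas +0.178 / -0.048
```

Read: at this sample size no logistic slope smaller than |0.32| is
detectable at 90% power; higher vegetable intake is associated with lower
odds of disability; smoking loads positively and exercise negatively on
both disability and fatigue, with the lifestyle-plus-diet model explaining
about 5% of the EDSS variance — all consistent with the signals the
generator plants (slopes −0.36/−0.34, EDSS variance share 6%).

Each stage is also available separately (`medinet simulate | score |
network | compare | models`) or as library functions:

```python
from medinet import CohortConfig, generate_cohort, score_cohort
from medinet import encode_cohort, build_network, identify_hubs

cohort = score_cohort(generate_cohort(CohortConfig(seed=1)))
net = build_network(encode_cohort(cohort[cohort.group == "MS"]), seed=1)
print(identify_hubs(net).hubs)
```

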