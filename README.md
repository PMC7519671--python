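# trpml

Model-guided engineering of tryptophan metabolism in *Saccharomyces
cerevisiae*: a pipeline combining constraint-based metabolic modeling,
combinatorial promoter-library design, biosensor growth-curve phenotyping
and Bayesian-ensemble machine learning to recommend strain designs that
increase tryptophan productivity.

The package is aimed at metabolic engineers and computational biologists
running design–build–test–learn cycles: it covers the dry-lab side of one
full cycle, from picking gene targets off a stoichiometric model to ranking
the next round of promoter combinations to build.

## What it computes

**1. Target scoring (`trpml.gsm`).** Parsimonious flux balance analysis
(pFBA) solves, for a stoichiometric model with growth objective and a
tryptophan sink, the flux distribution at each growth fraction
f ∈ {0.30, 0.35, …, 0.80} of μ_max with all remaining capacity pushed into
tryptophan. Each reaction gets a score

&nbsp;&nbsp;&nbsp;&nbsp;s_r = mean_f (|v_f| + δ) / (|v_ref| + δ),

the average flux fold change against the max-growth reference (pseudo-flux
δ = 1e-4 guards zero references), and each gene the unweighted mean of its
reactions' scores: s_g > 1 → overexpression candidate, s_g < 1 →
downregulation candidate. Pathway overrepresentation among the classified
targets uses a two-sided Fisher exact test.

**2. Library design (`trpml.library`).** The combinatorial space of one
promoter (from a bin of six) per gene for PCK1, TAL1, TKL1, CDC19 and PFK1
— 6⁵ = 7776 designs, assembled in one pot from 13 DNA parts drawn from a
pool of 38. A Monte Carlo simulation over assembly success and promoter
pick probabilities estimates how many unique genotypes a colony sample
contains (the uniform-pick case has the occupancy closed form
G·(1 − (1 − 1/G)^{np}) as an oracle).

**3. Phenotyping (`trpml.phenotyping`).** Plate-reader OD600/GFP time
series → per-strain GFP synthesis rates (MFI/h), the biosensor proxy for
tryptophan productivity: per-plate media background subtraction, rate =
ΔGFP/Δt inside the OD600 window [0.075, 0.150] (endpoint or regression
slope estimator), five-criteria strain QC, replicate aggregation
(mean ± SEM, CV of the mean) and two outlier-removal schemes (global
percentile rule and per-strain median ± 3·scaled-MAD rule).

**4. Genotype→rate model (`trpml.ensemble`).** A scikit-learn-style
estimator, `BayesianEnsembleRegressor`: rates are modeled as
y ~ N(Σ_m w_m g_m(x), σ²) where g_1…g_8 are diverse base regressors on the
30-dimensional one-hot genotype encoding and the weight vector w lives on
the simplex with a flat Dirichlet prior. The weight posterior is sampled by
random-walk Metropolis on stick-breaking coordinates, with the likelihood
evaluated on out-of-fold base-learner predictions (stacking). Accuracy is
quantified by k-fold cross-validated MAE and learning curves.

**5. Recommendation (`trpml.recommend`).** The full design space is
enumerated, seen designs excluded, and candidates ranked either by
predictive mean (exploit) or by expected improvement
EI = (μ−f\*)Φ(z) + σφ(z) (explore), yielding the 30 designs to build next.

**6. Synthetic study (`trpml.synthetic`).** A generator that emulates the
study's statistical structure — a calibrated log-additive-plus-interactions
response surface spanning ≈40–260 MFI/h with the all-native reference
design at ≈145 MFI/h, triplicate noise at CV ≈ 4.3%, library defect rates,
and rendered 82-point/15-min plate time series — so every stage above is
testable end to end without any external dataset.

## Worked example

```python
from trpml.library import default_catalog, parts_accounting, simulate_coverage
from trpml.encoding import GenotypeOneHotEncoder
from trpml.ensemble import BayesianEnsembleRegressor, cross_validate
from trpml.synthetic import make_ground_truth, sample_training_set
from trpml.recommend import recommend

cat = default_catalog()
print(cat.n_designs, parts_accounting(cat))
# 7776 (13, 38)

cov = simulate_coverage(cat, n_colonies=10_000, p_correct=0.82, n_reps=1000, seed=7)
print(f"{cov.mean_unique:.0f} ± {cov.sd_unique:.0f} unique ({100*cov.coverage:.0f}%)")
# 5069 ± 30 unique (65%)

truth = make_ground_truth(cat, seed=7)                  # hidden response surface
tr = sample_training_set(truth, n_strains=250, n_reps=3, cv=0.043, seed=8)
enc = GenotypeOneHotEncoder(cat).fit()
X = enc.transform(tr.genotypes[list(cat.genes)])
y = tr.replicates.groupby("strain")["rate"].mean().reindex(tr.genotypes["strain"]).to_numpy()

est = BayesianEnsembleRegressor(random_state=0).fit(X, y)
print(cross_validate(est, X, y, k=10, seed=0).mae)
# 9.8  (MFI/h, 10-fold test MAE on rates spanning 65–212)

recs = recommend(est, cat, mode="exploit", n=30,
                 exclude=set(tr.genotypes["key"]), f_best=float(y.max()), encoder=enc)
print(recs.table.iloc[0]["key"])
# PCK1=pREV1|TAL1=pPSP2|TKL1=pPOP6|CDC19=pTEF2|PFK1=pPFK1   (238 ± 12 MFI/h predicted)
```

The interpretation: with 250 measured genotypes (~3% of the space) the
ensemble predicts held-out rates to ~10 MFI/h on a ~150 MFI/h range, and
the exploit recommendations concentrate on designs whose *true* (generator)
rates sit at or above the best design seen in training.

A command-line interface mirrors the stages
(`trpml score-targets | design-library | simulate-coverage | generate |
phenotype | fit | recommend | run`); `trpml run --synthetic --seed 7`
executes the whole pipeline and writes a manifest with content hashes so
reruns are verifiably identical.

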