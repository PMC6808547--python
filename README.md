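# vocalaccom

Quantitative analysis of vocal dialect accommodation in common marmosets
(*Callithrix jacchus*) — or any species with discrete, repeatedly recorded
call types. The package implements the full analysis chain used in captive
translocation designs, where animals are moved to a new physical environment
(to test environmental accommodation) or placed in acoustic contact with a
population that has a different dialect (to test social accommodation /
crowd vocal learning), and their calls are recorded weekly.

It is written for bioacousticians and behavioural biologists who have
per-call audio (or a per-call feature table) plus caller/colony/sex/
condition/week metadata, and want the complete statistical pipeline rather
than ad-hoc scripts.

## What it computes

1. **Acoustic parameterization** (`vocalaccom.acoustics`): 15 per-call
   parameters for phee and food calls, 17 for trills — F0 start/end/mean/
   min/max from an autocorrelation pitch tracker, % duration at maximal F0,
   |F0 slope|, mean F0 variation per second, spectral energy quartiles
   (Q25/Q50/Q75), peak frequency and % time at peak, local jitter, duration,
   and (trills) FM rate and peak-to-trough FM extent. Includes the study's
   inclusion rules: first-k call selection per session (5 trill / 10 phee /
   20 food) and the ≥5-calls-per-animal-per-week filter.

2. **Dimensionality reduction** (`vocalaccom.dimred`):
   `ParallelAnalysisPCA`, a scikit-learn transformer that z-scores each
   parameter, runs correlation-matrix PCA, and retains the leading
   components whose eigenvalues exceed the 95% quantile of eigenvalues from
   10,000 random datasets of the same shape (Horn's parallel analysis).

3. **Crossed permuted discriminant function analysis**
   (`vocalaccom.pdfa`): `CrossedPDFA` tests whether calls differ between
   conditions while controlling for caller identity. The statistic is the
   mean % of held-out calls correctly classified by a Fisher LDA trained on
   balanced (individual × condition) subsets; the null distribution
   permutes condition labels of whole blocks *within* each individual, so
   pseudo-replication never inflates significance.

4. **Vocal distance** (`vocalaccom.distance`): each call's distance from a
   population's average vocalization,

   `d = sqrt( Σ_k [ p_k · (s_k − c_k) ]² )`,

   where `s_k` are the call's retained-PC scores, `p_k` the proportion of
   total variance explained by component k, and `c` the population centroid
   — the across-animal average of each baseline animal's 10% trimmed mean
   per axis, computed once and frozen.

5. **Accommodation models** (`vocalaccom.accommodation`): linear mixed
   model `ln d ~ sex + week + sex:week` with a random intercept per animal
   (ML), dropping a non-significant interaction; likelihood-ratio test
   against the intercept-only null; Nakagawa marginal/conditional R²; an
   OLS comparison of the last pre-translocation weeks vs 5+ weeks after;
   and per-animal weekly means with percentile-bootstrap 95% CIs.

6. **Synthetic worlds** (`vocalaccom.synth`): a generator with known
   dialect offsets, latent-factor call structure, per-animal effects,
   weekly schedules and exponential convergence/divergence dynamics — plus
   tonal/FM waveform synthesis for validating the tracker. Every stage of
   the pipeline is tested against this ground truth.

## Worked example

Simulate the social-translocation design (4 animals moved next to a colony
with a different dialect, 4 baseline animals, 16 weeks) and run the full
analysis:

```python
import vocalaccom as va
from vocalaccom.pipeline import run_experiment2

table, truth = va.simulate_features(va.default_scenario(), seed=123)
report = run_experiment2(table, seed=123)
print(report.to_text())
```

Output for the trill call type (abridged):

```
trill (n_obs=360 from 4 individuals)
  retained PCs: 4 (75.6% of total variance)
  Intercept          B=   1.000 SE= 0.196 t=   5.104 P=5.404e-07
  sex_male           B=   0.331 SE= 0.277 t=   1.197 P=0.2321
  week               B=  -0.048 SE= 0.001 t= -37.896 P=3.597e-127
  R2_m=0.487 R2_c=0.917 chi2_MLT=576.597 (df=2, p=6.215e-126)
  pre vs 5+ weeks: effect=-0.523 (p=4.241e-06; n=20 pre, 240 post)
```

Reading this: parallel analysis kept 4 components covering 75.6% of the
parameter variance; ln vocal distance to the target-colony centroid falls
by about 0.048 per week of passive acoustic exposure (the generator's true
slope is −0.050), the mixed model beats the null decisively, and calls are
significantly closer to the new population after 5+ weeks than immediately
before the translocation. In the same run food calls show a small positive
week effect (divergence), mirroring the opposite-direction pattern such
designs can produce.

The same steps are available from a shell:

```bash
vocalaccom simulate --preset social --seed 123 --out features.csv
vocalaccom run-exp2 --features features.csv --seed 123 --out-dir results/
```

## Reproducible end-to-end run

`scripts/acceptance.py` re-runs both designs from scratch — simulating the
environmental (Before/After pDFA) and social (vocal-distance convergence)
experiments from their default scenarios — prints both reports, and writes
its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The statistical validation lives in `tests/test_acceptance.py`: pDFA
type-I calibration and power, parallel-analysis rank recovery, tracker
round-trips, brute-force oracles for the distance primitives, end-to-end
convergence-slope recovery, qualitative reproduction of both experiments'
patterns, and LRT/R² calibration.
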