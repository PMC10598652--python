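# svsurv

Structural-variant gene burden and survival analysis for two-arm clinical
trials.

In many neurological diseases (ALS, Charcot-Marie-Tooth, Alzheimer,
Parkinson, ...) specific genes are implicated in the disease mechanism, and a
recurring clinical question is whether structural variants (SVs — deletions,
duplications, insertions, inversions, translocations ≥50 bp) in such a gene
modulate a patient's response to treatment. `svsurv` answers this
quantitatively: it reads a gene-annotated multi-sample VCF of SV calls and a
trial metadata sheet, tallies each participant's SV burden in a chosen target
gene, stratifies the cohort by treatment arm and SV-carrier status, and
compares survival between the strata. It is aimed at statistical geneticists
and trial analysts who want a scriptable, reproducible pipeline rather than a
point-and-click dashboard.

## Statistical core

For each stratum the survival function is estimated by the Kaplan-Meier
product-limit estimator over the distinct event times t₍ᵢ₎,

    Ŝ(t) = ∏_{tᵢ ≤ t} (1 − dᵢ/nᵢ),       Var[Ŝ(t)] = Ŝ(t)² ∑_{tᵢ ≤ t} dᵢ / (nᵢ(nᵢ−dᵢ)),

with Greenwood's variance and complementary-log-log confidence bands.
Strata are compared with the two-group log-rank test (tie-corrected
hypergeometric variance). Covariate effects are estimated under the Cox
proportional-hazards model

    h(t | x) = h₀(t) · exp(xᵀβ),

by Newton-Raphson maximization of the partial likelihood with the Efron
(default) or Breslow treatment of tied event times; hazard ratios exp(β̂)
with Wald intervals are reported. Two configurations mirror common trial
practice: a *Standard* model on all patients (arm + carrier status +
covariates) and a *Multiple* model fitted separately inside the carrier and
non-carrier subsets. A built-in simulator generates matched metadata + VCF
for a trial with known treatment/carrier/age effects, which backs all
statistical validation.

## Worked example

Simulate a 100-patient trial in which carriers of ≥3 SVs in *SETX*
(ENSG00000107290) are concentrated in the treatment arm, then analyze it:

```sh
svsurv simulate --seed 3 --out-dir demo
svsurv tally --vcf demo/cohort.vcf --out demo/tally.tsv
svsurv cohort --tally demo/tally.tsv --meta demo/meta.csv \
       --gene ENSG00000107290 --min-sv 3
```

prints the arm × carrier tally:

```
           non_carrier  carrier  carrier_fraction   n
arm
placebo             43        7              0.14  50
treatment           12       38              0.76  50
```

i.e. 7 placebo and 38 treatment participants carry ≥3 SVs in the target
gene. The Cox stage

```sh
svsurv cox --tally demo/tally.tsv --meta demo/meta.csv \
       --gene ENSG00000107290 --min-sv 3 --covariates age_at_onset \
       --out-dir demo/report
```

writes `hazard_ratios.tsv`:

```
model               term          HR   CI_low  CI_high  p       percent_effect
standard            arm           0.55 0.33    0.92     0.023   -45%
standard            carrier       1.62 0.97    2.71     0.063   +62%
standard            age_at_onset  1.02 0.99    1.04     0.168   +2%
multiple:carrier    arm           0.82 0.36    1.87     0.633   -18%
multiple:carrier    age_at_onset  1.02 0.98    1.06     0.367   +2%
multiple:noncarrier arm           0.39 0.18    0.85     0.019   -61%
multiple:noncarrier age_at_onset  1.02 0.99    1.05     0.260   +2%
```

Read: treatment roughly halves the hazard of death overall (HR 0.55), SV
carriers fare worse (HR 1.62), and each additional year of age at onset
raises the risk of death by two percent (HR 1.02). The treatment benefit is
strong among non-carriers (HR 0.39) but attenuated among carriers (HR 0.82)
— the genotype-treatment interaction the tool exists to surface. `svsurv km`
emits the matching four-stratum survival curves, two-panel life table and
risk table; `svsurv select` the per-gene carrier summary for a disease panel.

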