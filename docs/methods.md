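# Methods

## Input contracts

**Variants.** A multi-sample VCF v4.2+ (plain or bgzipped) of structural
variants, each record annotated with Ensembl gene identifiers in an INFO
field. Two annotation styles are auto-detected per record, in order: a
plain `GENE` key with `|`- or `,`-separated identifiers, then SnpEff/VEP
style `ANN` entries (gene-ID subfield). The key order can be overridden
(`--annotation-key`). Records without any recognized annotation are
retained but contribute to no tally cell; their number is logged.
Annotations are trusted as given — the package performs no interval
arithmetic, liftover or re-annotation, and coordinates stay 1-based
throughout. BND records participate through their annotations with END
taken as POS.

**Metadata.** A CSV/TSV with at least patient id, trial arm, survival
status and time-to-event columns, mapped to roles by name. Arm and status
must be two-level; any encoding is coerced to 0/1, by default mapping the
lexicographically larger level to 1 (so `treatment` > `placebo`, `1` > `0`)
with the chosen map echoed to the log; an explicit level map can be given.
Columns already coded 0/1 are accepted even if only one level is observed.
The time unit (days/weeks/months/years) is a label used in reports and for
interpreting per-unit hazard ratios; no unit conversion is performed.

## The SV burden tally

For sample s and gene g, the tally counts VCF records annotated with g in
which s carries ≥1 alternate allele. One record increments a (sample, gene)
cell at most once — a homozygous-alternate genotype counts once, and a
record annotated with k genes increments k cells. This "number of variant
records" reading is the least surprising notion of per-gene SV burden;
counting allele copies instead would double-weight homozygotes and is not
supported. Missing genotypes (`./.`, `.`) are non-carriers. The tally is
deterministic: gene columns sort lexicographically and record order is
irrelevant.

## Carrier stratification

A carrier window [min_sv, max_sv] (default [1, ∞)) defines carrier status.
Patients with sv_count = 0 are always non-carriers. Patients with a
nonzero count *outside* the window (e.g. 1–2 SVs when min_sv = 3) are
excluded from stratified analyses rather than pooled with the SV-free
group: relabeling a 2-SV patient as SV-free would contaminate the
reference stratum, and exclusion keeps both groups interpretable. The
disposition counts are logged, and a window that excludes everyone is an
error.

## Estimators

**Kaplan-Meier.** Product-limit estimate over distinct event times with the
standard tie convention that events precede censorings (a subject censored
at t is still at risk at t). Variance by Greenwood's formula; confidence
bands on the complementary log-log scale by default (plain linear
selectable), clamped to [0, 1]; where Ŝ = 0 the variance is undefined and
reported as NaN. The life table reproduces the curve exactly row by row and
is emitted in two panels (patients with vs without SVs in the target gene).

**Log-rank.** Two-group test over pooled distinct event times; at a time
with d events among n at risk (n₁ in group 1), E₁ += d·n₁/n and the
variance accumulates the hypergeometric term d(n₁/n)(1−n₁/n)(n−d)/(n−1).
With a single binary covariate and no tied event times this chi-square
equals the Cox score test under the Breslow tie approximation — an identity
the test suite checks on random tie-free instances. (With ties the two
differ by design: the hypergeometric correction factor (n−d)/(n−1) has no
Breslow counterpart; the tie-corrected form matches the mainstream survival
implementations.)

**Cox regression.** Efron's approximation for ties is the default (more
accurate than Breslow when ties are common; Breslow selectable). Estimation
is Newton-Raphson from β = 0, tolerance 1e−9 on the score norm, at most 25
iterations, with step-halving whenever a step would decrease the log
partial likelihood — the acceptance threshold for that comparison is
relative to |loglik| because near the optimum the surface is flat at
floating-point precision. There is no randomness anywhere in estimation.
Standard errors come from the inverse observed information; Wald z, two-
sided p and exp-scale CIs follow. A monotone partial likelihood (complete
separation: a coefficient passing |β| = 10 while the score stays above
tolerance) yields a flagged, non-converged result with a separation marker
in the report — not an exception. Constant covariate columns are rejected
up front; a singular information matrix raises an error naming the
(near-)collinear columns. Hazard ratios for continuous covariates are
per-unit effects in the covariate's declared unit, also rendered as a
percent change 100·(HR−1).

**Standard vs Multiple configurations.** The Standard model fits all
analyzed patients with arm, carrier status and any user covariates. The
Multiple model refits within the carrier and non-carrier subsets
separately, keeping arm as a covariate inside each subset (the alternative
— stratifying by arm as well — would leave no treatment contrast to
report). Subsets with no patients or no events are reported "not estimable"
rather than raised. Carrier status enters as a binary covariate, not as a
continuous SV count; the count-based alternative is deliberately out of
scope because the carrier window already encodes the burden threshold of
interest.

## Trial simulator

The simulator emulates a two-arm trial with a genotype-dependent treatment
response: per-patient exponential event times with hazard
λ₀·exp(β_t·arm + β_c·carrier + β_a·(age − mean age)) and administrative
censoring at a fixed study end. Defaults encode the exemplary study this
package ships as its demonstration: 50 patients per arm, carrier fractions
0.14 (placebo) and 0.72 (treatment), every carrier bearing at least 3 SVs
(3 + Poisson(1.5) records) in the target gene *SETX*, λ₀ = 0.25/year,
β_t = −0.7 (a successful treatment, HR ≈ 0.50), β_c = +0.5 (deleterious
carrier effect, HR ≈ 1.65), β_a = ln 1.02 per year, age ~ N(55, 10²)
truncated at 18, censoring at 10 years. All draws come from one seeded
generator in patient-index order, so outputs are byte-identical per seed.
The emitted VCF gives each carrier exactly sv_count private records
(genotype 0/1 for that sample alone) in the target gene plus shared
background SVs in decoy genes, which makes the tally round trip exact by
construction and testable on every seed.

What the simulator does *not* emulate: realistic SV breakpoints or
sequence context, linkage between variants, shared records among carriers,
non-exponential baselines (a Weibull hook would be the natural extension),
informative censoring, or covariate-dependent carrier probability. Tests
passing on simulated data therefore validate the estimators and the
pipeline plumbing, not the biological realism of any particular cohort.

## Numerical and design choices

- The exponential baseline was chosen over Weibull so that closed-form
  survival exp(−λt) is available as an independent oracle in tests.
- KM confidence level defaults to 95%; the log-log transform guarantees
  bands inside [0, 1] without truncation artifacts.
- Ties in the tally and registry are resolved lexicographically; all file
  outputs are UTF-8 with LF endings for byte-stable reproduction.
- The disease→gene registry is a static TSV shipped with the package
  (illustrative neurodegenerative panels only, not a clinical resource);
  disease lookup is case- and dash-variant-insensitive. No network access
  anywhere.
- No multiple-testing adjustment is applied across genes or covariates;
  raw Wald/log-rank p-values are reported and downstream correction is the
  analyst's choice.
- Validation scale: oracle-agreement tests run 200 random instances at
  n ≤ 50 against statsmodels (agreement ≤1e−6); parameter-recovery and
  coverage checks use 100–200 replicates at n = 2000/arm; type-I error
  uses 200 replicates at n = 100/arm.

## Known limitations

Two-arm trials only (no >2 groups, no competing risks or interval
censoring); no time-varying covariates, frailty terms or proportional-
hazards diagnostics; no imputation of missing clinical values; gene
symbol/ID synonym resolution is limited to the registry file. The carrier
definition is record-based and inherits whatever overlap rule the upstream
annotator used.
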