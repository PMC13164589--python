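# Methods

`karyodelim` implements the quantitative half of an integrative
species-delimitation study of two closely related wild tulips: the
rediscovered Greek population of *Tulipa scardica* (one population,
Vytoumá) against *T. undulatifolia* (four populations: Fana, Emporiós,
Dídima, Agios Stefanos). Three independent evidence streams are analysed —
karyotype structure, quantitative plant morphology, and seed morphometry —
and condensed into one side-by-side evidence table. DNA barcoding,
SEM micromorphology and soil chemistry are out of scope (the soil table is
carried through as a verbatim report block only).

## Karyomorphometry

The atom is a homologous chromosome pair with long arm `l` and short arm
`s` in μm (`l ≥ s > 0`), measured on a squashed mitotic metaphase plate; a
complement is 12 pairs (2n = 2x = 24, the stable base number of the genus).
Per chromosome:

- total length `l + s`
- arm ratio (r-index) `r = l/s`
- centromeric index `ci = l/(l + s)`
- arm difference ratio `adr = (l − s)/(l + s)`
- relative length `(l + s)/TCL`, `TCL = 2 Σ(l + s)` over the 12 pairs.

The **long-arm convention** for the centromeric index follows the source
tables (`ci ∈ [0.5, 1)`), although `s/(l + s)` is more common elsewhere.
Two algebraic identities structure the test suite: `adr = 2·ci − 1` is
linear and survives any averaging of chromosomes, while `r = ci/(1 − ci)`
is nonlinear and holds per chromosome only. This matters in practice:
published per-pair ratio columns are typically means of per-plate ratios,
which are *not* the ratios of mean arm lengths. The package therefore never
tries to reproduce ratio columns from mean arms, and `classify_r_values`
accepts published ratio means directly.

Aggregates per complement: min/max chromosome length, TCL, average length
`ACL = TCL/2n`, total haploid length `THL = TCL/2`, interchromosomal
asymmetry `CV_CL = 100·sd/mean` of lengths, intrachromosomal asymmetry
`M_CA = 100·mean(adr)`, and `CV_CI = 100·sd/mean` of centromeric indices.
CVs use the sample (n − 1) denominator, configurable, and are computed over
the 12 pair-level values (one measurement per homologous pair). With
multiple plates, every index is also reported as across-plate mean ± SD.

Morphology categories follow Levan-derived arm-ratio intervals —
m: r ∈ [1, 1.7), sm: [1.7, 3), st: [3, 7), t: ≥ 7 — with a configurable
borderline band (default |r − 3| ≤ 0.05) reported as the mixed class
"sm/st", since published tulip karyotypes contain sm/st chromosomes without
a printed rule. Satellite (SAT) status is an annotation: satellite length
is excluded from arm lengths (satellites are small and inconsistently
visible under squash preparation), and which pairs carry satellites must be
supplied, as it is not derivable from arm lengths. Karyotype formulas count
chromosomes (two per pair) in the canonical order m, sm, sm-SAT, sm/st,
sm/st-SAT, st, st-SAT; terms always sum to 2n. With the default band the
*T. scardica* complement yields `8 sm + 4 sm-SAT + 2 sm/st-SAT + 10 st`,
matching the published formula; for *T. undulatifolia* the band assigns
8 sm/st chromosomes where the published formula splits them
6 sm/st + 2 st-SAT — the same sm vs st-side totals, an irreducible
ambiguity of the unpublished borderline rule.

## Karyotype statistics

Indices are compared between taxa with Welch's unequal-variance t-test
(Welch–Satterthwaite df, two-sided p) and Cohen's d on the pooled SD,
labelled small/medium/large at 0.2/0.5/0.8 and "very large" above 1.2.
Both raw per-plate and summary-statistic (mean, sd, n) entry points exist.
The summary path is the reproducible one when only published mean ± SD
values are available; it gives t ≈ −4.75 and d ≈ 1.53 for CV_CL
(n = 10 vs 36 plates), close to but not identical with values computed from
raw plate data, which are unavailable. No multiple-testing correction is
applied across the eight index comparisons by default (matching the
reporting convention); a BH option exists. Stars follow the table footnote
convention (* p < 0.05, *** p < 0.001).

## Morphometrics

26 quantitative traits (mixed cm/mm; units are declared in a sidecar map,
never inferred) over 140 individuals in five populations. Per trait:
Kruskal–Wallis (midranks, tie-corrected; scipy) and, where significant,
Dunn's post hoc z tests on mean ranks with tie-corrected variance and
Benjamini–Hochberg adjustment over the pairs *within one trait*; results
condense into compact letter displays via the duplicate-and-absorb
algorithm (groups sharing a letter do not differ).

Discrimination uses Fisher LDA on 11 standardized traits (plant length,
stem width, and nine shape/proportion ratios computed per individual before
standardization), solved as the generalized eigenproblem of between-group
vs pooled within-group covariance; axes are ordered by eigenvalue and
sign-fixed (first nonzero loading positive). Classification uses the
Gaussian pooled-covariance rule with priors proportional to group size
(configurable to uniform). The jackknifed confusion matrix refits the model
without each held-out individual; percentages are tabulated by actual group
so columns sum to 100. Individuals missing any discriminant trait are
excluded and logged. A minimal one-way MANOVA (Wilks' Λ with Rao's F
approximation) is exposed. 95% confidence ellipses use 2.45·sd radii of the
per-group score covariance.

## Seed morphometry

Seven linear measurements per seed (TL, TW, EL, SL, SW, WW, CPL, all mm)
with geometric invariants SL ≤ TL, SW ≤ TW, EL ≤ SL, and five derived
ratios (EL/SL, TL/TW, SW/WW, SL/SW, TL/CPL). Because the mean of per-seed
ratios differs from the ratio of group means — and published tables mix the
conventions — the report prints both. Two-group comparisons run behind an
explicit policy: Shapiro–Wilk screen per group at α = 0.05 with an
{identity, log} transform ladder, Welch's t where the screen passes,
Wilcoxon rank-sum otherwise; the chosen path is recorded per trait.
Per-seed mass is batch mass / count at 4 significant digits.

## Synthetic data

The generators define the study conditions for everything stochastic:

- **Plates**: a 12-pair arm template (the published mean complements by
  default) times one mean-one lognormal plate factor (scale CV 0.10) and
  independent mean-one lognormal per-arm noise (CV 0.03), 10 plates per
  population by default. Multiplicative plate effects mirror chromosome
  condensation, which scales all arms together and leaves the ratio-based
  indices invariant — consistent with the stability of those indices
  across published plates. Arm noise is multiplicative because additive
  noise could violate positivity.
- **Traits**: a Gaussian copula with exchangeable latent correlation
  ρ = 0.5 (the true trait correlations are unpublished; ρ is a free
  parameter and all correlation-sensitive checks are property-based) and
  zero-truncated-normal marginals whose underlying (μ, σ) are
  moment-matched so the *truncated* distribution hits the published
  mean ± SD; at the study's largest relative spread (plant length,
  5.41/13.00) naive truncation would bias the mean by several percent,
  moment matching keeps it within 1%. Population layout defaults to the
  field campaign (25 + 38 + 16 + 44 + 17 = 140). Only species-level
  moments were published, so populations of the same species share
  parameters — simulated data therefore show *no* within-species
  population structure, and population-level classification success is
  expected to be lower than in the field data for the *T. undulatifolia*
  populations while the species split itself reproduces.
- **Seeds**: same copula per species with the published seed summaries;
  ordering invariants enforced by rejection (an acceptance rate below 1%
  flags an infeasible spec).

All randomness flows from one explicit integer seed; per-population and
per-plate sub-streams are spawned deterministically, and identical
config + seed reproduce every output byte-for-byte.

Passing tests on these data show the machinery is correct under the stated
distributional assumptions; they cannot show robustness to features real
measurements have and the generator lacks (population structure within
species, measurement rounding, non-exchangeable trait correlation,
plate-level arm-ratio drift).

## Numerical and reporting choices

- Report rounding: 2 decimals for μm quantities, 3 for dimensionless
  ratios, 1 for confusion percentages.
- Degenerate cases: identical chromosome lengths give CV_CL = 0 (not an
  error); a single chromosome has no CV; equal groups give t = 0, p = 1;
  zero pooled SD with equal means gives d = 0, with different means an
  error; both-variances-zero Welch with different means returns ±∞ flagged
  with p = 0.
- The one-cell misprint in the published per-pair table (*T. undulatifolia*
  pair 4 centromeric index) is documented in the acceptance suite; the
  arm-difference column, which agrees with the printed arms, is taken as
  authoritative for that pair.
- Problem sizes in tests and drivers (50 plates for recovery checks, 500
  replicates for power checks, 12 replicates for LDA-separation checks,
  n ≈ 20 for brute-force jackknife oracles) were chosen to make sampling
  error comfortably smaller than the tested margins.

## Known limitations

- Published raw per-plate and per-individual data are unavailable, so the
  printed raw-data statistics (e.g. CV_CL Welch t = −4.807, jackknife
  percentages 93.2/92.0/86.8/31.2/35.3) are benchmarks for structure, not
  exact targets; the summary-statistic and simulation-based routes are the
  reproducible substitutes.
- The sm/st borderline band is a modelling choice; published formulas do
  not define the underlying rule.
- The copula correlation is exchangeable; real morphometric correlation
  matrices are typically block-structured.
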