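# Methods

This note records the statistical model behind each stage of the
package, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical and
design decisions a maintainer should know about.

## Variant identity and filtering

A variant is identified by (chromosome, 1-based position, reference
base, alternate base); only single-nucleotide substitutions are
handled.  All filtering is exact set algebra over these keys: the
known-variant filter subtracts dbSNP-style lists, the panel filter
subtracts the union of all external exomes, and refinement subtracts
the patient's matched normal.  Strict four-field matching is the most
conservative choice — it can never silently remove a true somatic call
that merely shares a position with a known variant.  Coordinates are
1-based inclusive throughout, including domain intervals, which are
measured in CDS bases (amino-acid annotations are converted on ingest,
residue r → bases 3(r−1)+1 … 3r).  Whether domain tests should use
nucleotide or amino-acid lengths is genuinely ambiguous in this kind
of analysis; nucleotide lengths keep one unit everywhere (the gene
test's coding space N is in bases) and only rescale the hypergeometric
population, not the counts, so the ingest flag `domain_unit="aa"` is
the only switch needed.

## Panel detection sensitivity

For a panel of n external exomes, the sensitivity of a k-subset is the
fraction of a patient's germline variants present in the union of the
subset, averaged over patients.  `estimate_detection_sensitivity`
averages over all C(n, k) subsets when that count is at most
`max_combos` (default 10,000) and otherwise over `max_combos` distinct
subsets drawn uniformly without replacement; patients with empty truth
sets are excluded, and variants carried by no panel member count as
misses (they are exactly the variants the approach cannot remove).

The average over *all* subsets also has a closed form: a variant
carried by c of the n exomes is missed by a uniform k-subset with
probability C(n−c, k)/C(n, k).  `mean_sensitivity_exact` evaluates
this directly and is used wherever only the mean is needed (the
pipeline's curve, the acceptance script), because subset-sampling
noise would otherwise dominate downstream fits.  The subsampling
estimator is retained as the reference implementation and the two
routes are checked against each other in the test suite.

## Saturation extrapolation

Two models extrapolate sensitivity beyond the available panel:

* **Exponential**: S(k) = s_max(1 − e^(−k/τ)), fitted by bounded
  least squares (s_max ∈ [0, 1], τ > 0).  This is the single-class
  limit of the mixture below and is adequate for interpolation, but
  inverting it for a target close to s_max is ill-conditioned: small
  errors in ŝ_max move the required panel size enormously.  The
  required-size helper therefore raises an explicit "target exceeds
  asymptote" error rather than extrapolating past the fitted ceiling.
* **Carrier-spectrum deconvolution** (`fit_carrier_spectrum`): each
  germline variant's panel carrier count c follows Binomial(n, q) for
  carrier probability q; non-negative least squares against binomial
  profiles on a 40-point log-spaced q grid (1e-4.3 … 0.6) recovers
  spectrum weights from the instance-weighted carrier-count histogram,
  and S(k) = Σ w_j (1 − (1 − q_j)^k) then predicts any panel size.
  Because it estimates the frequency spectrum itself rather than
  fitting the k-curve, this route extrapolates an order of magnitude
  beyond the observed panel size with ~10% accuracy, where curve-based
  mixture fits (also available via `fit_saturation_curve(...,
  model="mixture")`) are unstable under realistic noise.

## Enrichment statistics

All three screens are one-sided upper tails P(X ≥ observed) — the
analysis looks for enrichment only — and no multiple-testing
correction is applied by default (a Benjamini–Hochberg column is
available via `add_bh_column`).  Conventional reporting thresholds are
P < 0.02 for genes and domains and P < 0.05 for pathways.

* **Gene**: P(m, t, n) = 1 − (1 − m/N)^n is the probability that a
  patient with m coding SNVs hits gene t of length n bases, under
  uniform placement over the N-base coding space (defaults
  N = 30,800,000 over 17,175 genes).  Expected mutated cancers =
  Σ_patients P; observed = patients with ≥1 SNV in the gene; p is a
  Poisson upper tail at the expected mean.  Since the observed count
  is a sum of independent Bernoullis with that mean, the Poisson tail
  is slightly conservative (its variance is larger), which the
  type-I-error simulations confirm.  P is evaluated as
  −expm1(n·log1p(−m/N)) to survive m/N ~ 1e-6.
* **Domain**: within genes pooling ≥5 SNVs across patients, a domain
  of d bases with ≥3 SNVs is tested with a hypergeometric upper tail
  (population = gene bases, successes = domain bases, draws = pooled
  gene SNVs), by default restricted to COSMIC-flagged domains.
  Pooling across patients (with per-patient multiplicity at recurrent
  positions) matches the convention of reporting cohort-total SNV
  counts per gene and domain.
* **Pathway**: M = (mean distinct mutated genes per patient) /
  total genes; λ(t, n) = (1 − (1 − M)^n) × cohort size for a pathway
  of n member genes; observed = patients with ≥1 SNV in any member;
  Poisson upper tail.  λ is bounded by the cohort size and strictly
  increasing in both n and M.  The test ignores gene-length
  composition within a pathway — a pathway of unusually long genes is
  tested slightly anti-conservatively — but the Poisson slack more
  than absorbs this at the calibration sizes used in the tests.

## Survival screening

Kaplan–Meier product-limit curves and the standard one-degree-of-
freedom log-rank test (simultaneous events processed in a single
risk-set update; two-sided p from the χ² upper tail; statistic 0 and
p = 1 when no events occur).  The implementation is cross-checked
against lifelines and against permutation nulls in the test suite.
The screen tests every gene with at least `min_carriers` (default 3)
mutated patients and at least one non-carrier, reports the direction
of the effect (carriers "worse" when observed > expected events) and
the KM median of each arm, and runs on the crude call set by default —
the point of the design being that panel-filtered calls suffice,
artifacts rarely change carrier status.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
not reads or coverage:

* **Germline pool**: `n_germline_sites` (default 100,000) sites placed
  uniformly (without collision) over the coding space, each assigned
  an allele frequency class.  An individual carries a site with the
  Hardy–Weinberg probability q = 1 − (1 − f)²; presence/absence is all
  that downstream filtering sees.  The default classes
  (f, site weight) = (0.25, 0.001268), (0.01, 0.032341),
  (0.001, 0.2727), (0.0004, 0.693691) were calibrated once, by
  non-negative least squares, so that a same-population panel detects
  ~54% of a patient's germline variants at k = 96, ~64% at k = 217,
  and ~90%/95% near k ≈ 1350/2000 — the operating points this kind of
  panel-filter study reports.  The spectrum is rare-heavy (≈87% of
  sites below 0.1% allele frequency), as exome cohorts are after
  common-SNP exclusion.
* **Cohort**: per patient, Poisson(`somatic_per_patient`, default 150)
  true somatic SNVs; each is drawn from a shared 30-site recurrent
  hotspot pool with probability `recurrent_fraction` (default 0.03)
  and is otherwise private (global position uniqueness enforced).
  Positions fall uniformly over the coding space unless per-gene or
  per-domain rate multipliers are supplied; the default genome
  implants 11 driver genes with gene-level multipliers descending from
  50× and a further 5× concentration inside a COSMIC-flagged domain,
  mirroring a driver-gene table with a dominant kinase-domain gene at
  the top.  Artifact calls — germline variants miscalled as somatic
  because the normal would have been under-covered — are drawn from
  the patient's own germline carriers at a rate making the expected
  artifact share of candidates `artifact_fraction` (default 0.25).
  The matched-normal call set is the germline minus misses at
  `normal_miss_rate` (default 0.02): it models a *validated* normal,
  independent of the artifact mechanism, so that refinement yields a
  near-clean gold standard.
* **Survival**: exponential times with hazard = baseline (default
  0.015 per month) × the product of hazard ratios of implanted
  prognosis genes the patient's somatic calls hit (defaults: one
  hazard-increasing gene at HR 3, one protective at HR 1/3);
  administrative censoring at 60 months.

What the generator does **not** emulate: read-level error processes,
site-specific call quality, coverage variation, linkage between sites,
population substructure, indels, or copy number.  Consequences worth
knowing: under pure Hardy–Weinberg carriage, any variant occurring in
more than ~5% of a 97-patient cohort is almost certainly carried by a
73-exome panel, so the frequency-stratified sensitivities of real
data — where mid-frequency variants are missed for call-quality
reasons — are compressed toward 0/1 here; passing tests demonstrate
the correctness and calibration of the statistics, not the error modes
of real pipelines.

## Numerical and design notes

* Subset sampling is uniform over combinations without replacement;
  every stochastic routine takes an explicit seed, and the pipeline
  derives per-stage seeds from the root seed and the stage name, so
  stages are independently reproducible and reruns are bit-identical.
* Degenerate inputs are explicit errors, not silent results: empty
  truth sets (undefined sensitivity), all-equal sensitivity curves
  (unfittable), targets at or above the fitted asymptote, hazard maps
  naming unknown genes, survival tables with duplicate patients.
* An empty stratification bin reports NaN, never 0.
* The proportion-equality test is the pooled-variance χ² on the 2×2
  table with the Yates continuity correction on by default (the
  common statistical-software convention), with a flag to disable.
* The crude-vs-refined overlap report counts units significant at the
  per-kind thresholds; a Spearman rank correlation between crude and
  refined p-values over the shared unit universe is emitted as an
  extra concordance diagnostic beyond the headline counts.
* Simulation-based tests use scaled-down genomes (hundreds to a few
  thousand genes, proportionally smaller coding spaces and pools) with
  mutation rates chosen to preserve the per-gene counts that the
  filters and tests actually see; the acceptance script runs at full
  study scale (97 patients, 17,175 genes, ~30.8 Mb, 100,000 germline
  sites, 217 panel exomes).
* The noisy-saturation recovery check evaluates the median required
  panel size over independent noisy realizations: the inversion near
  the asymptote is heavy-tailed, and the median is the appropriate
  resistant summary for a quantity whose single-realization estimate
  can be arbitrarily large.

## Known limitations

* Gene assignment of variants is taken from the input (or the
  simulation); the package does not annotate variants to transcripts.
* The pathway test inherits the length-blindness of its λ formula (see
  above).
* The exponential saturation form is descriptive, not mechanistic; for
  extrapolation always prefer the carrier-spectrum route.
* Only SNVs are modeled; indels, CNVs and structural variants are out
  of scope, as are allele-balance or strand-bias filters.
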