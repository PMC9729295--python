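# Methods

This note documents the statistical models, the defaults and the judgement
calls behind each stage of the pipeline, plus what the synthetic generators
do and do not emulate.

## Data model

Spectral intensities are nonnegative reals; exactly 0 means "not detected"
and no NaN state exists. This matters because the zero → 1 substitution rules
below presuppose true zeros. Sequence windows are 15 residues (±7 around the
phosphoacceptor), padded with `_` at protein termini; `_` never satisfies a
motif constraint. Site positions are 1-based protein coordinates.

## Differential phosphopeptide screen

* **Branch selection.** A Shapiro–Wilk gate on the pooled intensity
  distribution selects the test family once per analysis; spectral
  intensities are grossly non-normal, so the nonparametric branch is the
  effective default. The gate truncates to the first 5000 values because the
  test's p-value is unreliable beyond that n.
* **Fold change.** Group medians are taken over raw intensities with zeros
  included as observations. Only when forming the ratio is a zero median
  replaced by 1 — a change of one intensity unit is negligible against
  detected peptides at 2¹⁰–2²⁰ but keeps the ratio defined. Consequence:
  peptides undetected in one group sit at exactly ±log2(other-group median),
  producing the lateral volcano clouds; this geometry is asserted in tests.
* **Test.** Two-sided Mann–Whitney–Wilcoxon, midranks for ties (zeros tie at
  the bottom; the substitution does *not* apply inside the rank test).
  The null is Monte-Carlo: labels are permuted by a seeded RNG and
  extremeness is |U − E[U]|. The add-one estimator
  p = (1 + #extreme)/(n_perm + 1) never returns 0 and gives 5-decimal
  resolution at the default 100,000 permutations. Because midranks depend
  only on the data, ranks are computed once per peptide and the whole null
  is a rank-matrix × permutation-mask product; all peptides share one
  permutation stream.
* **Multiplicity.** Benjamini–Hochberg step-up (statsmodels), validated
  in-tree against an independent hand-rolled step-up implementation.
* **Hits.** Strict inequalities throughout: |log2 FC| > 4, p < 10⁻²·⁵,
  q < 0.25. A value exactly at a threshold is not a hit.
* **Arms.** The per-arm analyses (monotherapy arm, whole trial, combination
  arm) are one code path behind a sample-filter argument.

## KSEA

* **Motif matching.** A kinase matches a peptide iff at least one of its
  patterns has every positional constraint satisfied. Patterns are
  dash-separated strings (`R-X-X-pS/pT`, bracket groups `[RK]` allowed); the
  `p`-token marks the centre. Offset-0 constraints are restricted to S/T/Y.
  Multi-kinase membership is kept in full; no down-weighting of shared
  peptides.
* **Set size.** Sets entering enrichment satisfy 5 < size < 1000 (strict).
* **Ranking.** Pooled-variance two-sample t on log2(intensity + 1)
  (responders minus nonresponders), descending; ties broken
  lexicographically by peptide id; zero-variance peptides get t = 0. The
  log transform is a switch (`log_transform=False`) for sensitivity
  analysis. In the vectorised sums-of-squares form, pooled variances below
  10⁻¹⁰ of the mean square are treated as exact zeros to absorb cancellation
  noise on constant rows.
* **Enrichment score.** The classic (unweighted) running sum: +1/n_hit at
  members, −1/(N − n_hit) at non-members; ES is the signed extremum. The
  reported extremum is the *first* position within 10⁻¹² of the maximum
  magnitude, so analytically tied extrema are resolved deterministically and
  independently of cumulative round-off. Exact agreement with a brute-force
  walk is asserted property-based.
* **Permutations.** Phenotype labels are permuted and the full ranking
  recomputed per permutation (1000 by default, one RNG stream for all sets);
  when C(n, n_responders) ≤ n_perm the label space is enumerated
  exhaustively instead, making small-cohort results permutation-noise-free.
  Member-set permutation is available as an alternative
  (`permute="members"`).
* **NES / p / FDR.** NES = ES / mean(|null ES| of the same sign, per set);
  p is the add-one same-sign tail fraction; q follows the familiar
  enrichment-framework tail ratio — the fraction of all same-sign null NES
  at least as extreme divided by the fraction of observed same-sign NES at
  least as extreme, clipped to [0, 1]. Degenerate constant data (every
  permutation reproducing the observed ES) yields |NES| = 1.

## IHC confirmation

* H-score = (3·%high + 2·%medium + 1·%low)/100, validated to 10⁻⁹ on input
  records.
* The 75th percentile uses the linear-interpolation quantile; "High" is
  *strictly above* the cutoff, so a value exactly at the cutoff is Low and
  an all-equal cohort has no High patients.
* Association: 2×2 High/Low × pCR/no-pCR; risk ratio of proportions; odds
  ratio as the cross-product (equal to the exponentiated univariate logistic
  coefficient for a binary covariate), with the 0.5 Haldane–Anscombe
  correction and a flag when any cell is zero. Both effect measures are
  emitted because "x-fold higher chance" is ambiguous between them; the risk
  ratio is the headline. Chi-square is Pearson without continuity
  correction, two-sided, df = 1. Bonferroni multiplies by m (default 5, the
  size of a marker panel); calls on the adjusted p: < 0.01 significant,
  0.01–0.1 borderline, else ns.
* The combined two-marker stratum reports the pCR proportion with its
  standard error √(p(1−p)/n) and a chi-square against all other patients;
  empty or all-inclusive strata are reported with a note, not an error.

## Pull-down enrichment

* Zero substitution (0 → 1) precedes everything and is idempotent; which
  proteins were fully undetected in IgG is recorded *before* substitution.
* Median-of-ratio normalisation is per replicate pair and implemented by
  scaling bait intensities, so the post-normalisation median ratio is 1 —
  exactly for odd protein counts, to the even-count midpoint convention
  (mean of the two central ratios) otherwise. Fewer than 3 proteins: skipped
  with a warning.
* "Average ratio" is the ratio of replicate-averaged intensities, not the
  average of per-replicate ratios — deterministic and robust to
  single-replicate dropouts.
* The candidate filter is parsed as one evidence clause OR'd
  (log2 ratio > 2, or absent in IgG) AND one abundance clause (≥3 psm
  summed in bait, or ≥1 psm in every replicate): a 1-psm IgG-absent protein
  should not be a candidate. The abundance clause is evaluated on raw psm
  values, before substitution and normalisation.
* Cross-cell-line fold changes divide normalised replicate-averaged
  bait-bound intensities; a protein absent from one table contributes 1.

## Synthetic generators

* **Phospho matrices.** Per-cell iid log-normal intensities
  (log2 mean 15, sd 2 — detected peptides spanning roughly 2¹⁰–2²⁰).
  Dropout is intensity-dependent:
  p = clip(baseline − shift · (log2 x − log2-mean), 0, 1), i.e. the
  configured shift acts on the deviation from the configured mean, so dim
  cells drop out more often; defaults baseline 0.10, shift 0.02 per log2
  unit. Kinase substrates are assigned disjointly and each kinase's motif
  constrains two window positions with a residue pair unique to that kinase,
  while non-substrate windows carry a residue no motif allows there — set
  membership is therefore unambiguous against the emitted library, which the
  truth-consistency tests exploit. Planted kinases add their log2 effect to
  responders' substrate intensities before dropout; a configured fraction of
  peptides is forced to 0 in one random group (the lateral clouds). The
  generator draws every quantity from named substreams of one seed.
* **IHC cohorts.** A latent standard normal per patient drives the first
  marker; other markers mix it with fresh noise at the configured
  correlation. With u = Φ(z), the stained area is 100u, of which a fraction
  u is high-intensity and the rest splits evenly between medium and low,
  giving the continuous monotone H-score 1.5·u·(1+u) ∈ (0, 3). pCR is
  Bernoulli at the upper rate for patients above the cohort 75th percentile
  on every *driver* marker (default: the first marker; the tests of the
  combined stratum use both) and at the low rate otherwise. Defaults — 400
  patients, rates 0.90 vs 0.30, correlation 0.6 for two-marker cohorts —
  are the conditions under which the confirmation stage is validated.
* **Pull-down tables.** Background proteins share a log-normal base
  intensity (log2 mean 17, sd 2) with independent replicate noise
  (log2 sd 0.5) in bait and IgG, so their expected log2 ratio is 0; planted
  interactors add their enrichment to bait, and a configurable fraction of
  them is zeroed in all IgG replicates.
* **What they do not emulate.** Chromatographic artifacts, peptide-spectrum
  matching, protein inference, correlated peptide intensities within a
  protein, batch/site effects, or informative (outcome-dependent) missing
  structure beyond the planted exclusives. Passing tests therefore show the
  statistics are implemented and calibrated correctly under the assumed
  generative structure, not that the biological conclusions of any
  particular study transfer to new data.

## Problem sizes and numerical choices

Validation runs use 20 vs 20 samples with 2000 peptides (250 eight-substrate
kinase sets for null calibration; 40 thirty-substrate sets for recovery),
100,000 Mann–Whitney permutations, 1000 KSEA permutations, 20 recovery
replicates, 400-patient IHC cohorts and 1000-protein pull-down tables —
sizes chosen to match the sampling regimes of a clinical phosphoproteomic
study while keeping a full validation run in the low tens of seconds on one
CPU. Permutation-count comparisons use the 3-sigma binomial bound plus the
add-one estimator bias (≤ 2/n_perm). Floating-point guards: ES tie tolerance
10⁻¹², rank-sum comparisons at 10⁻⁹ (rank sums are multiples of ½, so this
is exact), zero-variance floor 10⁻¹⁰ of the mean square.

## Known limitations

* The Monte-Carlo MWW p-value is conservative for heavily tied rows (many
  zeros), as any discrete permutation p is.
* The KSEA FDR is the enrichment-framework tail-ratio estimate; it is not
  monotone in |NES| by construction and can be anti-conservative for very
  small set collections.
* IHC subtype stratification is carried on the records but the association
  machinery treats one cohort at a time; stratified tests are the caller's
  composition.
* `compare_cell_lines` assumes the two tables were normalised independently;
  cross-table batch effects are out of scope.
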