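# Methods

## The analysis model

PhIP-seq (phage immunoprecipitation sequencing) profiles serum antibodies
against a programmed phage-display peptide library: antibody-bound phage are
immunoprecipitated, amplified, and sequenced, and a peptide's read count is a
proxy for antibody reactivity. `phipkit` implements the post-sequencing
statistics, starting from peptide-level count matrices (alignment of reads to
peptides is upstream and out of scope).

The stage sequence, and its exact conventions:

1. **Gene aggregation.** All peptide counts mapping to the same gene are
   summed (integer-exact). Peptides without a gene mapping are a hard error
   unless explicitly dropped, because silent loss distorts the downstream
   read percentages. Feature ids are case-sensitive opaque strings; gene
   symbol curation is upstream of this package.
2. **Normalization.** A pseudocount of 0.5 reads is added to every gene, and
   each sample column is converted to percentage of total reads. The
   pseudocount is included in the denominator, so columns sum to exactly 100
   and every entry is strictly positive (the composition stays closed). This
   also bounds the fold change attainable by genes with near-zero mock-IP
   counts, which is the desired behavior: a gene never observed in the
   background cannot support an unbounded enrichment estimate.
3. **Fold change (FC).** Each serum sample's gene read-percentage is divided
   by the mean read-percentage of that gene across the mock-IP (protein A/G
   bead-only, no serum) samples. Mock columns are then dropped.
4. **Z-scores.** FC values are standardized against the healthy-control
   cohort: cases against all controls, each control against all *other*
   controls (leave-one-out), so a control's own reactivity never inflates
   its reference. The sample SD (n−1) is used — the conservative estimator
   for small references. If a reference SD is exactly 0, the Z-score is 0
   when the value equals the reference mean and ±inf otherwise; infinities
   are flagged and compare as exceeding any finite threshold downstream.
   The leave-one-out statistics are computed from centered sufficient
   statistics, which are exact (0, not epsilon) for all-equal references;
   references that are *near*-degenerate can yield large finite rather than
   infinite Z-scores.
5. **Shared-hit calling.** A gene is a disease-specific hit when (i) it is
   positive (Z ≥ 10 by default) in ≥ 10% of cases, (ii) positive controls
   stay under the control limit, (iii) at least one positive case reaches
   FC ≥ 50 over mock-IP, and (iv) no control exceeds the highest case signal
   (dominance). Two control-limit modes exist because both appear in
   practice: a fractional mode (default; pass when
   `n_positive_controls < ceil(0.02 × n_controls)`) and an absolute mode
   (pass when `n_positive_controls < k`, strict). Positivity defaults to `≥`
   with a flag for strict `>`; the dominance comparison allows ties.
6. **Control downsampling.** Hits are re-called against random control
   subsets of increasing size (default 5/10/25/50/100/150, 10 replicates
   each, drawn without replacement, one seeded RNG). Z-scores are
   *recomputed* against each subset — slicing the full-cohort Z-scores would
   leak held-out controls into the reference and understate the effect.
   Note a structural property of the fractional control limit: the allowed
   positive-control count `ceil(0.02·k)` steps from 1 to 2 between k = 50
   and k = 100, so the expected apparent-hit curve can tick *up* at that
   boundary (a gene with exactly one reactive control is excluded at 50
   but tolerated at 100). Under the absolute `< 2` mode the limit is
   constant and the curve is monotone; the downsampling experiment in
   `scripts/acceptance.py` therefore uses the absolute mode. Both modes are
   exposed.
7. **Classifier.** Disease status is predicted from log10 reads-per-100k
   (pseudocounted; a gene at 1% of a sample's reads maps to 3.0) with an
   L1-penalized logistic regression (liblinear coordinate descent, inverse
   regularization C = 1 by default, exposed). Evaluation is stratified
   5-fold cross-validation — stratified because a 128-vs-186 imbalance makes
   unstratified splits unstable — with one ROC/AUC from the pooled
   out-of-fold probabilities (not a mean of per-fold AUCs). Reported
   coefficients come from a final full-data fit at the same penalty. The
   feature transform uses only per-sample totals, so it leaks no information
   across folds. The scale/pseudocount/log-base knobs are recorded in the
   FeatureMatrix and configurable.
8. **RLBA antibody index.** For the orthogonal whole-protein radioligand
   binding assay, index = (sample − mean blank)/(positive control − mean
   blank); multiple blank or positive-control wells are averaged first. A
   sample is positive when its index strictly exceeds mean(healthy) +
   3 × SD(healthy) (sample SD); a tie at the cutoff is negative. The index
   is invariant under common rescaling of all plate readings, so the
   cpm units are treated as opaque.

## The synthetic-data generator

The generator emulates the statistical structure the analysis relies on, not
sequencing mechanics. Per dataset, one seeded `numpy` Generator is consumed
in a fixed order (background → common-gene selection → depths → per-sample
effects → per-sample counts), so identical configs are bit-identical.

* **Background:** per-gene bead-binding propensities are
  LogNormal(0, σ = 2.0) — a heavy-tailed library occupancy spanning ~4
  orders of magnitude — split equally across each gene's peptides
  (2 per gene by default; peptide structure is immediately re-aggregated
  downstream, so finer peptide detail buys nothing at desk scale).
* **Counts:** Dirichlet-multinomial with concentration 1e5 × proportions at
  a LogNormal sequencing depth (mean 1M reads, log-SD 0.3). This makes
  column totals exact, represents compositional competition (a strongly
  enriched clone suppresses everything else's read share), and gives rare
  genes the heavy-tailed replicate noise seen in IP-and-amplify data while
  abundant genes stay comparatively stable.
* **Reactivities:** every serum — case or control — carries 5 *private*
  autoreactivities on random genes and samples a pool of 40 *commonly
  targeted* genes each with 10% reactivity probability; effects are
  log-uniform on (10, 1000), matching heavy-tailed per-sample enrichment
  spectra in which every serum shows some strong reactivities regardless of
  disease status. The common (public) tier is what makes small control
  cohorts fail: 5 controls usually miss a 10%-prevalence background
  reactivity that 150 controls reliably expose. *Disease* antigens are
  spiked into cases only, each carried with the configured penetrance at a
  fixed multiplicative effect.
* **Spike detectability:** disease-gene background propensities are censored
  below at the library median. A "spike" on a gene the library effectively
  does not display has a pseudocount-limited fold change — unmeasurable by
  construction — which contradicts the semantics of a spike-in experiment;
  validated autoantigens are, by selection, adequately displayed.
* **Mock-IP samples** draw from the background alone, so mock replicates are
  exchangeable by construction.

Named fixtures: `tiny` (8 genes, 6 samples, hand-checkable), `aps1_like`
(128 cases / 186 controls / 8 mock-IP, ~20k genes, 10 disease antigens at
35% penetrance and 100× effect — cohort sizes mirroring a large monogenic
autoimmunity screen), and `null` (same cohort, no disease antigens).

**What the generator does not model:** sequencing reads and PCR duplication,
epitope-level overlap between peptides of a gene, batch/plate effects, IVIG
contamination of treated patients, and cross-reactivity structure between
genes. Passing tests therefore demonstrate correctness of the statistics
under the stated generative model, not performance on any real cohort —
in real data, effect sizes are smaller, backgrounds are batch-structured,
and public reactivities have a prevalence continuum rather than one tier.

## Numerical and design choices

* SD convention everywhere: sample SD (n−1). Leave-one-out variance via
  centered sufficient statistics, clipped at 0 against rounding.
* Zero-total sample columns are flagged (warning), not errors.
* Counts I/O: TSV canonical, CSV accepted; header row and a leading
  feature-id column required; duplicate ids, negative, missing or
  non-integral cells are hard errors with coordinates.
* Gene order after aggregation is first-appearance order of the peptides;
  all outputs have a stable column order; reruns of the pipeline with the
  same config and seed are byte-identical (gzip outputs pin mtime = 0).
* Downsampled control subsets are drawn per replicate (not per gene).
* Problem sizes: desk-scale checks run the full ~20k-gene, 322-sample
  fixture; unit-level constructions use 50–500 genes, which is enough to
  exercise every criterion and keeps the default suite fast.

## Known limitations

* The Dirichlet-multinomial concentration is a single scalar; real PhIP-seq
  overdispersion varies per clone.
* Near-degenerate (but not exactly equal) leave-one-out references produce
  large finite Z-scores rather than flagged infinities.
* The fractional control-limit mode is intentionally non-monotone in cohort
  size at ceil boundaries (see above); comparisons across control-set sizes
  should use the absolute mode.
* `cross_cohort_overlap` compares hit tables built with comparable criteria;
  it does not re-harmonize thresholds across cohorts.
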