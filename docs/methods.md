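# Methods

This note records the models, conventions and numerical choices behind
`zegselect`, in the spirit of a package methods appendix. Everything stated
here is computed by the test suite or `scripts/acceptance.py`; nothing is
asserted from memory.

## Coordinate and marker conventions

All positions are 0-based with half-open intervals. The blunt Cas9 cut
falls between `cut_index − 1` and `cut_index` (3 bp 5′ of the PAM). Marker
offsets are signed distances from the cut; **distance 1 means the
nucleotide immediately adjacent to the cut**, and positive offsets lie on
the PAM-distal side. Published distance-to-cut figures rarely state
whether they count from the cut or the PAM; this package fixes the
cut-anchored convention and keeps it consistent between the locus
configuration, the simulator and the classifier, which is what matters for
the incorporation-by-distance analysis.

Indels are stored left-aligned (VCF-style): deletions and insertions are
shifted left through repeats, and insertions are rotated accordingly. Both
the simulator and the aligner canonicalize the same way, so an allele key
such as `del3@108` is stable across the whole pipeline.

The packaged toy loci are synthetic 220-bp sequences that copy the marker
geometry of the two cardiac-channel sites this workflow was developed on:
`toyLQTS` (synonymous markers at 1/3/6 bp, KI at 5 bp, PAM right of the
cut) and `toyBrS` (synonymous markers at 1/12 bp, KI at 8 bp, PAM left).

## Read processing

* **Demultiplexing** uses the inline sample barcode at the start of mate 1.
  A read is assigned to the unique barcode within `max_mismatch` (default
  1) Hamming distance. The barcode table must have pairwise distance
  `> 2·max_mismatch`; otherwise assignment could be ambiguous and the run
  is refused up front rather than silently mis-binned.
* **Mate merging** reverse-complements mate 2 and scans overlaps of at
  least 20 bp, accepting the best overlap with ≤10% mismatches.
  Conflicting bases take the higher base quality; quality ties become `N`.
  Merging precedes consensus (merge-then-collapse) so each UMI family
  votes on full-length inserts.
* **UMI consensus** is a per-column majority vote; ties are `N`; singleton
  families pass through. Length-discordant families (rare — an error
  inside an indel) are projected onto the longest member by pairwise
  alignment before voting. With per-base error 1% and family size 5, the
  post-consensus per-base error is below 0.1% (tested empirically; a
  binomial majority-vote bound predicts ≪0.1%).
* **Alignment** is global with affine gaps (match +1, mismatch −2, gap
  open −5, extend −1), computed by Biopython's pairwise aligner and then
  normalized: indels are left-shifted through repeats, and a deletion is
  emitted before an insertion at the same junction. Scores were verified
  against an independent Gotoh dynamic program on short strings.
* **Classification** ignores primer regions. Any indel overlapping
  `cut_index ± 20 bp` makes the read INDEL, or IMPERFECT_HDR when the KI
  marker base is also present (imperfect repair junctions). Without an
  indel, any marker substitution yields HDR with the observed
  incorporation vector — the KI bit may be false for partial conversion
  tracts, which is exactly what the distance analysis consumes. Reads with
  neither indel nor marker edits tolerate 1 stray mismatch (consensus
  residual error) before falling into OTHER_SUB, which stays in the SEF
  denominator but in no editing numerator.

Two classification conventions are deliberate and configurable in
reporting: IMPERFECT_HDR counts toward "all indels", not "KI"
(conservative reading of a correct knock-in), and the SEF denominator
includes OTHER_SUB reads.

A caveat established while validating the classifier: when an indel lies
directly adjacent to substituted marker bases, an optimal alignment may
absorb the marker mismatch into the gap, so the (indel, substitution)
decomposition of such a read is not unique. This is a property of
alignment itself, not of this implementation; the classifier fidelity
check therefore draws imperfect-HDR alleles whose indels keep a margin of
(indel length + 4) bp from the markers, and reaches 100% round-trip
accuracy there.

## Synthetic experiment

The generator's defaults are the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `zeg_cells` | 21 | cells shed by the embryo genotyper |
| `we_cells` | 2000 | cells in a whole-embryo lysate |
| `read_depth` | 1000 | reads per sample (2×150 bp, ~220 bp amplicon) |
| `umi_length`, `barcode_length` | 8, 8 | inline prefix on mate 1 |
| `pcr_duplication` | 3.0 | geometric mean UMI-family size |
| `seq_error_rate` | 0.001 | per-base substitution probability |
| `mean_indel_fraction` | 0.5 | across-embryo mean indel cell fraction |
| `mean_ki_fraction` | 0.03 | across-embryo mean HDR cell fraction |
| `dirichlet_concentration` | 4.0 | mosaicism: small = clumpy clones |
| `tract_p_max`, `tract_decay_bp` | 0.95, 10 | marker incorporation `p_max·e^(−d/λ)` |

Editing levels follow what Cas9-protein injections produce at loci like
these: indel fractions around 50% and HDR around a few percent, with
strong embryo-to-embryo mosaicism (a Dirichlet with concentration 4 gives
many near-zero embryos and occasional high-KI outliers, matching observed
founder distributions). Each embryo is one Dirichlet draw over an allele
spectrum (WT + ten indel alleles spanning the <1%/1–5%/>5% frequency
classes + all marker-incorporation patterns weighted by the tract model);
the spectrum weights are the across-embryo means. ZEG and WE samples are
multinomial cell draws from the same profile — the paired design used to
validate the genotyper. Each sequenced template founds a UMI family with a
geometric size (no published duplication distribution exists; geometric is
the maximum-entropy choice on {1,2,…} given a mean). UMIs are drawn unique
within a sample: with an 8-bp UMI and ~300 families, raw birthday
collisions would merge unrelated families at a rate the real protocol's
UMI-plus-fragment diversity does not exhibit.

What the generator does **not** model: cycle-dependent quality profiles,
PCR chimeras and polymerase errors (which would create recurrent artifact
alleles), index hopping, the LQTS-style pre-amplification step, and
ZEG-to-ZEG variation in DNA yield. Passing tests therefore demonstrate
correctness of the analysis given clean library chemistry, not robustness
to every real-world artifact; the simulated ZEG↔WE concordance
(r ≈ 0.9) accordingly sits at the top of, but inside, the 0.6–0.95 band
asserted in tests, whereas real screens with those unmodeled noise
sources report r in the 0.6–0.85 range.

## Fragment-analysis (capillary) model

Each allele contributes a peak at its amplicon length with intensity
proportional to its frequency. Finite sizing resolution is modeled as peak
merging: two Gaussian peaks of width σ separated by d bp overlap by
`erfc(d / (2σ√2))` (their Gaussian overlap coefficient), and that
unresolvable share of a non-WT peak is credited to the WT bin. This makes
the indel estimate (non-WT intensity over total) exact at σ = 0,
monotonically decreasing in σ, and strongly biased against 1–2 bp indels —
the known failure mode of fragment-length assays. An earlier literal
"re-bin the blurred trace" formulation was rejected because it also bleeds
WT mass out of the WT bin and thus *overestimates* editing, which is not
how peak-calling software behaves.

## Count models

`fit_nb_glm` fits NB2 regression (variance μ + μ²/θ) with log link and a
log-total offset. Coefficients come from IRLS (statsmodels GLM with a
fixed-dispersion negative binomial family); the dispersion is estimated by
maximizing the profile likelihood over α = 1/θ with a bounded 1-d search
(log-α ∈ [−12, 5], tolerance 1e-8). Wald p-values are reported; standard
errors condition on the profiled dispersion, as in common glm.nb-style
implementations. Fixing α ≈ 0 reproduces a Poisson GLM to 1e-6, and
multiplying all totals by c shifts only the intercept by −log c (both
tested as identities).

`fit_nb_random_intercept` adds a per-allele intercept b ~ N(0, σ²) and
maximizes the exact marginal likelihood by Gauss–Hermite quadrature
(25 nodes; the likelihood factorizes over alleles, so quadrature is
one-dimensional). Optimization is BFGS over (β₀, β₁, log θ, log σ) started
from the fixed-effect fit; standard errors come from the inverse of a
central-finite-difference Hessian. A variance estimate on the boundary
(σ ≤ 1e-3) triggers a refit as the fixed model, flagged on the result.
With one allele the function delegates outright. Null simulations (six
alleles, 40 embryos) put the Wald test's type-I error at ≈0.04–0.05,
within the 3–8% band asserted in tests.

Tukey's HSD uses the studentized range over all pairwise contrasts of
fitted group means, `q = |mᵢ − mⱼ| / √((seᵢ² + seⱼ²)/2)`; with two groups
this reduces exactly to the unadjusted t-test (verified numerically).
Bonferroni caps at 1. Stars follow the conventional mapping (*** <0.001,
** <0.01, * <0.05, NS).

## Selection conventions

Thresholding is strict (`SEF > t`): the frequency-class labels "<1%" and
">5%" are strict inequalities, so boundary values (exactly 1% or 5%) fall
into the middle class, and the same reading is applied to selection
thresholds. Embryos failing the 100-read filter are neither selected nor
excluded; they are reported separately, since a failed sample says nothing
about the embryo. The count-based ZEG↔WE correlation normalizes WE counts
to ZEG totals per embryo (scale only; within-embryo ratios unchanged) and
square-root-transforms both sides; an SEF-based correlation is available
via `sef_series`.

On noiseless data both the selected-group and excluded-group averages are
non-decreasing in the threshold — the embryos that move at a higher
threshold are simultaneously the lowest of the old selected set and the
highest of the new excluded set.

## Problem sizes

Simulation-backed checks use 50 embryos × 1000 reads (frequency recovery),
24 paired embryos (concordance and enrichment), 500 random alleles per
locus (classifier fidelity), and 500 replicates (mixed-model calibration);
these sizes give stable Monte-Carlo estimates for the quantities asserted
while keeping a full test run around a minute.

## Known limitations

* Alignment-based classification cannot uniquely decompose indels fused to
  marker substitutions (see above); such reads are classified
  deterministically but their key may differ from the generating event.
* The mixed model fits a single random-intercept variance; crossed or
  nested random effects (e.g. embryo within allele) are out of scope.
* The fragment-peak model treats indel–indel co-migration as irrelevant
  because the estimator only separates WT from non-WT.
* Germline transmission is summarized arithmetically
  (`transmission_fraction`); no attempt is made to model the
  soma-to-germline relationship.
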