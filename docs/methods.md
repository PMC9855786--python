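# Methods

## The quantification model

`tdgfquant` estimates the *activity* of gut-microbiome functional groups —
butyrate producers, acetogens, sulfate reducers, mucin degraders — from
metatranscriptomic data, without assigning transcripts to taxa. Each group
`Fg` is represented by a single trait-determining genetic feature (TDGF): a
marker protein `M` for a key enzyme of the trait's pathway (butyryl-CoA
dehydrogenase for butyrate production, CO dehydrogenase for acetogenesis,
dissimilatory sulfite reductase for sulfate reduction,
alpha-N-acetylgalactosaminidase for mucin degradation). The default catalog
also carries four further acetogenesis/mucin markers for multi-marker
experiments, but the analysis default is one marker per group.

The pipeline, in execution order:

1. **Verification** (optional, `catalog.verify_tdgf_presence`). Each marker
   is aligned against labeled reference genomes of the community members; a
   marker is *specific* when present (score ≥ threshold) in every in-group
   genome and absent from all out-group genomes.
2. **Search** (`align.search_tdgfs`). Every marker protein is aligned
   against every assembled contig by six-frame translated local alignment.
   The best score over frames is the contig's score for that marker.
3. **Filter** (`align.filter_hits`). Contigs with best score strictly below
   the threshold (default raw score 250) are discarded; a contig scoring
   exactly 250 is retained. The threshold is exposed because it must be
   re-tuned for natural (non-synthetic) communities.
4. **Aggregate** (`aggregate`). Per sample `E_j`, a group's abundance is the
   sum of quantifier TPM values over its marker's retained contigs `C_i`
   (RNA-seq route), or the sum of 16S relative abundances over its member
   taxa `B_i` (taxonomic route). Per diet `D` with `k` mice, the
   *whole-community* estimate is the arithmetic mean `1/k Σ_j Σ_i value`.
   The *distinguished-groups* estimate first forms, within each mouse, each
   group's share of the four groups' summed abundance (ignoring the
   unclassified remainder), then averages the `k` shares.
5. **Compare** (`compare`). The two routes are cross-validated by Pearson
   correlation of per-group patterns (over the 3 diet means, or over
   mouse-matched values) and by Welch's unequal-variance t test between
   diets.

## Numerical and statistical choices

- **Scoring.** Raw Smith–Waterman score, BLOSUM62, affine gaps with open 11
  and extend 1; a gap of length L costs `11 + (L−1)·1`. The alignment
  engine is Biopython's `PairwiseAligner` in local mode; the test suite
  checks it against an independently written quadratic-space Gotoh DP,
  exactly, on hundreds of random pairs.
- **Translation.** Bacterial/archaeal code (table 11); trailing partial
  codons dropped; codons containing N translate to X. Frames +1..+3 read
  the forward strand at offsets 0..2, −1..−3 the reverse complement.
- **Stop codons.** Intact marker ORFs contain no internal stops, so an
  alignment is never allowed to span one: translated frames are segmented
  at stop codons and each stop-free segment is aligned independently. (A
  "non-matching sentinel" substitution score alone would not achieve this:
  an affine gap could still bridge the stop at a cost of ~12.)
- **Ties.** When two frames or segments reach the same best score, the
  earlier one in the order +1, +2, +3, −1, −2, −3 (and left-to-right within
  a frame) is reported, for determinism.
- **Summation order.** All abundance sums run sequentially over ids in
  lexicographic order, so results are bit-reproducible across platforms,
  row orders, and re-runs; the test suite asserts exact (not approximate)
  agreement with naive recomputation.
- **Share normalization.** As a per-diet quantity, the distinguished-groups
  share is computed per mouse and then averaged over the diet's `k` mice.
  This respects the per-mouse pairing and makes the four shares sum to
  exactly 1 both per mouse and per diet mean. The alternative — dividing
  the diet-summed numerator by the diet-summed denominator — is available
  as `pooled_ratio=True` (CLI `--pooled-ratio`).
- **Confidence intervals.** Two-sided 95% Student-t intervals,
  `mean ± t_{0.975,k−1}·sd/√k`; with `k = 1` the interval degenerates to
  the point (with a warning). A seeded percentile bootstrap is available.
- **Welch's test.** Computed from the explicit statistic and
  Welch–Satterthwaite degrees of freedom; two-sided. Degenerate zero-
  variance inputs return p = 1 (equal means) or p = 0 with a warning.
  No multiplicity correction is applied by default (the workflow runs a
  single small contrast family); `diet_contrasts` results can be fed to any
  external correction.
- **Correlations.** Pearson by default (the compared values share a scale);
  Spearman by flag. With only three diets, diet-mean correlations rest on
  n = 3 and are flagged `descriptive_only`; they support qualitative
  pattern statements, not inference.
- **Units.** TPM columns must sum to 1e6 (relative tolerance 1e−4, warning
  on drift). 16S tables are proportions in [0, 1]; percent-scaled input is
  accepted only with an explicit `percent=True` — never auto-guessed.

## The synthetic-data generator

`synthetic` emulates the defined-community experiment the method was
designed around: 14 named gut species, of which 4 are butyrate producers,
2 acetogens, 1 a sulfate reducer, 4 mucin degraders, and 3 unclassified
(this partition is an illustrative simulation default, not a curated
annotation of the real strains). Thirteen mice (3 fiber-free F, 4
fiber-rich R, 6 alternating FR) receive 16S profiles; three mice per diet,
chosen at random, additionally receive RNA-seq abundance tables.

Generation works as follows. For each species and each group it belongs
to, the group's marker protein is diverged to a target amino-acid identity
(default 0.85 — exactly `round((1−identity)·L)` positions substituted with
BLOSUM62-positive neighbors), reverse-translated with one fixed codon per
amino acid, framed by random UTRs on a random strand. Each species also
contributes 3 decoy contigs of uniform random nucleotides (their alignment
scores against ~200-aa markers sit around 40–60, far below 250, so ground
truth is unambiguous). Per mouse, species abundances are a symmetric
Dirichlet(α = 10) draw — moderate inter-mouse compositional variation, as
expected in a gnotobiotic cohort; the 16S table reports these abundances
exactly. A contig's expected expression is species abundance × contig base
rate × a per-(group, diet) multiplier (marker contigs only), perturbed by
lognormal noise with σ = 0.2; TPM follows from expression shares and read
counts are derived through effective lengths (fragment length 150). The
default multipliers encode the qualitative diet response the method is
meant to recover: mucin degraders (0.3) and sulfate reducers (0.4)
suppressed under R, the butyrate marker reduced (0.5), acetogens most
active under R (1.0 vs 0.5 under F).

The ground-truth object records realized species abundances, per-contig
provenance, and the noise-free expected group activities and shares, so
recovery can be scored without re-deriving anything.

What the generator does **not** model: read-level error, de novo assembly
artefacts (fragmented or chimeric contigs), non-uniform codon usage,
paralogs or non-homologous isofunctional enzymes, and 16S copy-number
bias. Passing recovery tests therefore demonstrate correctness of the
quantification machinery under clean, well-separated conditions — not
robustness of the method on natural communities, where the score threshold
in particular must be re-tuned.

## Problem sizes used in tests

The shipped validation runs use the default community (53 contigs, 13
mice) per simulation; recovery rates are measured over 100 independent
simulations; alignment-oracle agreement over 200 random pairs (queries ≤
60 aa, contigs ≤ 200 nt); formula agreement over 50 fixtures of 100
contigs × 12 samples; Welch-null uniformity over 2,000 draws of two
size-3 samples.

## Known limitations

- The shipped marker sequences are synthetic placeholders; quantitative
  results on real data require the real enzyme sequences in a user catalog.
- A raw-score threshold is length-dependent: short genuine marker fragments
  can be lost at 250, and very long spurious alignments could cross it.
- TPM and 16S proportions are both compositional; the distinguished-groups
  normalization mitigates but does not remove closure effects, and no
  log-ratio transform is applied.
- With k = 3 mice per diet, between-diet tests have little power; the
  pipeline reports them but flags small-n correlations as descriptive.
- In the generator, community composition is drawn independently of diet
  (only marker *expression* responds to diet), so on synthetic data the
  16S route shows no systematic diet pattern and cross-method diet-mean
  correlations are dominated by compositional noise. They exercise the
  comparison machinery, not the biological agreement one would expect on
  real data, where composition itself shifts with diet.
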