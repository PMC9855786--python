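# tdgfquant

Trait-based quantification of functional-group activity in the gut
microbiome from metatranscriptomic data.

## The problem

Microbial ecology questions about the gut — who is producing butyrate, is
sulfate reduction suppressed by a fiber-rich diet, how active are the
mucin degraders — are questions about *functional groups*, not individual
taxa. Mapping transcripts back to species is unreliable (incomplete
references, horizontal gene transfer), and whole-metatranscriptome
functional profilers return far more than these questions need.
`tdgfquant` takes the trait-based shortcut: each functional group `Fg` is
represented by one *trait-determining genetic feature* (TDGF) — a marker
protein `M` for a key enzyme of the trait's pathway (e.g. butyryl-CoA
dehydrogenase for butyrate production, dissimilatory sulfite reductase for
sulfate reduction) — and the group's activity is read off the summed
abundance of the transcripts carrying that marker.

## The method

Given assembled transcriptome contigs and per-contig TPM values from a
pseudo-alignment quantifier (TSV: `target_id, length, eff_length,
est_counts, tpm`):

1. each marker protein is aligned against every contig by six-frame
   translated Smith–Waterman (BLOSUM62, gap open 11 / extend 1; frames
   split at stop codons);
2. contigs with best raw score < 250 are excluded (a contig scoring
   exactly 250 is kept); the threshold is configurable;
3. per mouse `E_j`, the group abundance is `Σ_i TPM(M, D, C_i, E_j)` over
   the retained contigs `C_i`; per diet `D` with `k` mice the estimate is
   the mean `(1/k) Σ_j Σ_i TPM(M, D, C_i, E_j)`. The parallel 16S route
   sums member-taxon relative abundances `16SrRNA(Fg, D, B_i, E_j)`
   instead. A second normalization expresses each group as its share of
   the four modeled groups' total within each mouse;
4. the two routes are cross-validated by Pearson correlation across diets
   and Welch's t test between diets.

A ground-truthed synthetic-community simulator (14 gut species, three
diets F/R/FR, 13 mice with 16S profiles, RNA-seq for 3 mice per diet)
makes the whole pipeline testable without any sequencing data. See
`docs/methods.md` for the model, parameter choices, and limitations.

## Worked example

Run the full pipeline on a simulated experiment:

```sh
printf 'synthetic: {}\n' > config.yaml
tdgfquant run --config config.yaml --out demo --seed 1
```

`demo/results.tsv` then contains, among the 48 group × diet × method ×
normalization rows, the distinguished-groups shares estimated from the
simulated transcriptomes (rounded):

```
          group_id  diet  n   mean  ci_low  ci_high
   mucin_degraders     F  3  0.382   0.265    0.499
   mucin_degraders    FR  3  0.400   0.283    0.517
   mucin_degraders     R  3  0.212   0.178    0.245
  sulfate_reducers     F  3  0.089   0.009    0.169
  sulfate_reducers     R  3  0.064   0.034    0.095
```

The simulation suppresses the mucin-degradation marker under the
fiber-rich diet (expression multiplier 0.3 vs 1.0), and the pipeline
recovers exactly that: the mucin-degrader share falls from 0.38 (F) to
0.21 (R), with `demo/contrasts.tsv` reporting the Welch test for the F vs
R contrast (t = 6.02, Welch df = 2.33, p = 0.018 on the whole-community
values). Shares of the four groups sum to exactly 1 in every diet.
`demo/correlations.tsv` holds the per-group correlations between the
RNA-seq and 16S routes (n = 3 diet means, flagged descriptive), and
`demo/manifest.json` records every parameter and input digest needed to
reproduce the run bit-for-bit.

The stages are also available individually (`tdgfquant simulate | verify |
search | aggregate | compare`) and as a plain Python API
(`tdgfquant.search_tdgfs`, `tdgfquant.filter_hits`,
`tdgfquant.group_abundance_rnaseq`, ...).

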