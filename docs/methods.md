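# Methods

## Pipeline model and assumptions

The package infers a competing-endogenous-RNA network from a
multi-condition bulk transcriptome. Its inferential chain makes three
assumptions explicit:

* **Repression leaves a correlation footprint.** A miRNA that represses a
  transcript should anti-correlate with it across samples; the screen
  keeps pairs with Pearson `r < −0.7` and `p < 0.05` (both strict). The p
  comes from `t = r√((n−2)/(1−r²))` on n−2 degrees of freedom. With the
  nine samples of a 3×3 design these gates are jointly satisfiable
  (p ≈ 0.036 at r = −0.7); restricted to the six samples of a single
  comparison they are not (p ≈ 0.121), so the default correlation scope
  is all samples and the scope is configurable and recorded in the run
  log.
* **Targeting requires a seed match.** Target evidence is canonical seed
  pairing: a transcript match to the reverse complement of miRNA
  positions 2–7 (optionally 2–8), graded 6mer / 7mer-A1 / 7mer-m8 / 8mer
  by position-8 pairing and the A opposite position 1. Each seed6 hit
  yields exactly one class. The pipeline's default evidence threshold is
  7mer-A1 or better, since bare 6mers are weak and noisy. Scoring-based
  engines are deliberately out of scope; instead, an n-way intersection
  operator applies the consensus rule over any externally supplied
  prediction tables.
* **Competition means a shared element.** A (miRNA, mRNA, lncRNA)
  triplet is reported when both partners are consensus targets of the
  same miRNA and both edges pass the correlation screen. Identity of the
  site coordinates across partners is not required — the shared element
  is the miRNA's seed. The development-annotation gate applies to mRNA
  partners only; lncRNAs are gated by differential expression and target
  evidence. Edges without a completing partner stay in the exported
  graph.

Differential expression uses Welch's *t* on log₂(x+1)-transformed
FPKM/TPM with a pseudocount of 1, the simplest defensible test for
three-versus-three normalized abundances; count-model alternatives (NB
GLMs) are a non-goal. The fold-change gate `|log₂FC| > 1` reads the
"absolute fold-change > 1" threshold on the log₂ scale (a linear reading
would flag any nonzero change); significance is gated on p, with BH
q-values reported alongside. Gene-set enrichment is the inclusive
hypergeometric upper tail with BH q-values over the collection and rich
factor x/K; the background is all features tested for DE in that class.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `q_threshold` / `max_low_quality` | 20 / 1 | reject reads with ≥ 2 bases at Q ≤ 20 (inclusive, "more than one") |
| `min_insert_len` | 18 nt | minimum insert after adapter removal |
| `p_thr`, `lfc_thr` | 0.05, 1.0 | DE gates (strict inequalities) |
| `r_thr`, `coexpr_p_thr` | −0.7, 0.05 | negative co-expression gates (strict) |
| `q_thr` | 0.05 | enrichment significance |
| `min_site_type` | 7mer-A1 | weakest admissible seed class |
| `sample_scope` | all | samples used for correlation |

Adapter matching is exact substring (5′ adapter as prefix, then the first
occurrence of the 3′ adapter); no mismatch tolerance, which keeps the
filter's behavior fully checkable. Library size for FPKM/TPM is the
within-matrix column sum. miRNA TPM is per-million-tags (length-free),
the small-RNA convention; the length-normalized form exists and is
feature-wise proportional to FPKM within a sample.

## The synthetic-data generator

The generator emulates the target study design: 3 time points
(30d/60d/90d) × 3 replicates, with mRNA/lncRNA/miRNA count matrices,
transcript and miRNA sequences, GMT gene sets, and an adapter-flanked
small-RNA FASTQ. Defaults: 200 mRNAs, 50 lncRNAs, 30 miRNAs, 10 planted
triplets, `repression_r = −0.9`, `de_lfc = 3`, NB dispersion 0.05
(biological triplicate of controlled, same-age farm animals), 500-nt
transcript sequences, 400 reads with 10% planted QC failures.

Counts are negative-binomial around log-normal means: background features
draw a constant log₂ baseline ~ N(6, 2²); planted features draw
~ N(9, 0.5²) so NB sampling noise does not dominate their log-scale
coupling. Each planted triplet gets a per-sample signal: a linear group
trend spanning `de_lfc` log₂ units plus a latent per-sample factor
(sd 0.35) shared by the triplet's members — positive on the miRNA,
negated on its two targets, with the trend's sign alternating across
triplets so per-million normalization is not systematically distorted by
planted features moving together. Independent Gaussian log-noise is then
added per planted feature, its variance calibrated analytically from
`repression_r`: the required total noise is
`v·(1+r)/(−r)` for signal variance `v`, minus the expected NB
contribution `ln(1 + 1/μ + φ)/ln²2`. The latent sd of 0.35 is the value
at which the defaults jointly deliver planted-pair correlations tracking
`repression_r`, ≥ 80% of planted pairs below −0.7 at r = −0.9, and ≥ 90%
Welch sensitivity for planted effects at `de_lfc = 3` with three
replicates; a larger latent share buys no extra correlation (the noise
budget is recalibrated) but erodes DE power.

Sequence truth is exact by rejection sampling (1,000 retries, exhaustion
is an error): each planted target embeds one 8mer site for its partner
miRNA; background transcripts, and planted targets with respect to
non-partner planted miRNAs, contain no seed match for any planted miRNA.
miRNA seeds are sampled pairwise-distinct and non-nested (no miRNA's
seed match may sit inside another's 8mer site string, which would make
clean planted targets unsatisfiable). The FASTQ plants each QC violation
in isolation — 2 bases at exactly Q20, an N in the insert, a missing
adapter, an empty insert, a 17-nt insert — so per-rule rejection counts
are exact; good inserts are 21–23 nt, mostly copies of the simulated
mature miRNAs.

What the generator does **not** emulate: genomic alignment and mapping
ambiguity, isoforms, GC/length biases, sequencing-error profiles beyond
the planted violations, batch effects, or within-animal pairing of
samples (the 9 samples are treated as group-labeled replicates). Passing
tests therefore demonstrate the pipeline's correctness and its power
under an idealized generative model, not performance on real libraries.

## Numerical choices

* BH q-values via the standard step-up procedure (statsmodels), validated
  against a from-definition implementation.
* Zero-variance features in the DE test get p = 1 rather than NaN.
* Pearson r is clipped to [−1, 1]; collinearity within 1e−14 of |r| = 1
  reports p = 0 exactly.
* Hypergeometric tails use the survival function at x−1 (inclusive upper
  tail); x = 0 returns p = 1.
* Enrichment ties sort by ascending q, then descending rich factor, then
  term id; the top-20 report is a prefix of that order.
* Tag collapsing sorts by descending count, then sequence.
* Site coordinates are 0-based half-open on the transcript, 5′→3′; U and
  T are interchangeable on input and DNA is the internal alphabet.

## Problem sizes

The test suite and the acceptance script use the default bundle
(200/50/30 features, 10 triplets) for end-to-end checks, a
60/20/15-feature bundle for unit-level properties, 20 seeds × 1,000
features for the null calibration, 1,000 random vectors for the
correlation and BH oracles, 500 random miRNA–transcript pairs for the
seed-match oracle, and every valid configuration with N ≤ 12 for the
hypergeometric enumeration. These sizes give stable statistics while
keeping a full run in seconds.

## Known limitations

* The Welch test on three replicates is mildly conservative on NB counts
  (null rejection ≈ 3–4% at the 5% level) and underpowered for small
  effects; planted effects at `de_lfc = 3` are detected reliably,
  subtler ones are not.
* Exact-substring adapter matching will not strip adapters with
  sequencing errors; real libraries need an error-tolerant trimmer
  upstream.
* The seed-match engine carries no hybridization energetics,
  conservation, or 3′-supplementary pairing; it is a transparent stand-in
  for scoring predictors, to be combined with them via the intersection
  operator when their outputs are available.
* Correlation screening across all nine samples conflates within- and
  between-group co-variation; the per-comparison scope is available but
  cannot jointly satisfy the printed r and p gates at n = 6.
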