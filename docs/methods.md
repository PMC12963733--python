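# Methods

`ceranet` re-implements, as a tested library, the post-quantification
analysis used in bird reproductive-state transcriptomics: nominate long
non-coding RNAs from an assembled transcriptome, call differential
expression between two physiological states (laying vs brooding) across
the hypothalamus–pituitary–gonadal (HPG) axis, assign cis/trans target
genes, test term over-representation, and screen lncRNA–miRNA–mRNA
(ceRNA) triples into an interaction network.  Because such screens are
usually published as one-off scripts, every stage here is specified,
deterministic, and validated against a simulator with planted ground
truth.

## lncRNA identification

A transcript is nominated as a lncRNA when it has **≥ 2 exons**, a mature
length (sum of exon lengths) **> 200 bp** (strict), and **all four**
coding-potential tools — CNCI, CPC2, CPAT, PFAM — call it noncoding.
Tool scores are consumed as verdict tables; the tools themselves are out
of scope.  Choices worth knowing:

* "Length" is mature transcript length, not genomic span; this is how
  assembly tools report lncRNA length, and it changes which transcripts
  survive the 200 bp rule.  Users comparing against span-based filters
  should be aware of the difference.
* A PFAM domain hit is treated as a "coding" verdict, symmetrically with
  the other three tools.
* ORF length is carried descriptively (for the characteristics summary)
  and never used as a filter.
* Known vs novel is pure id membership against a reference list.

## Differential expression

Counts are the tested unit; FPKM is computed descriptively
(`counts · 10⁹ / (length · library size)`).  The screen applies the
published thresholds — raw p < 0.05 and |log2FC| ≥ 0.26 — with the
boundary configurable because the source criteria are printed both as
`≥` and `>` in different places.  No multiple-testing correction is
applied, again matching the stated criteria; a pseudocount of 1
normalized count guards fold changes of zeros.

The p-value comes from a self-contained **conditional NB exact test**:

1. Samples are brought to equal effective depth.  The default factors
   are DESeq-style *median of ratios* (each sample's median ratio to the
   per-feature geometric mean over features expressed everywhere).
   Plain total-count scaling is available as an option but is knowingly
   biased when a large fraction of counts shifts asymmetrically — in the
   simulator's strong-signal regime it hands every null feature a
   spurious fold change, which is why it is not the default.
2. A single **common dispersion** φ is estimated by the method of
   moments: per feature and group, `(s² − m)/m²`, pooled by degrees of
   freedom, averaged over features, floored at 0.  No tagwise shrinkage
   is attempted; with a handful of replicates per group, a common φ is
   the honest granularity.
3. Conditional on the total `t = sum_a + sum_b`, the split follows
   `P(Y_a = a | t) ∝ f_NB(a; n_a μ, φ/n_a) · f_NB(t−a; n_b μ, φ/n_b)`
   with `μ = t/(n_a+n_b)` (a sum of n i.i.d. NB(μ, φ) is NB(nμ, φ/n)).
   The two-sided p is the **minimum-likelihood** sum — all splits no more
   likely than the observed one — computed by full enumeration of
   `0..t` in log space.  The doubling-the-tail rule would give different
   values; minlike is stated explicitly for reproducibility.  `t = 0`
   returns p = 1, and at φ = 0 the test reduces exactly to the
   conditional binomial exact test.

Under an NB null (2 000 features, 3 vs 3, mean 100, φ = 0.1) the
empirical rejection rate at 0.05 is ≈ 0.045 — mildly conservative, as
expected of a discrete exact test.

The 2^−ΔΔCt utility implements relative qPCR quantification against a
reference gene and calibrator sample.

## Target assignment

* **Cis**: a coding gene is a cis target when its span lies within
  100 kb (inclusive) of the DE lncRNA's span on the same chromosome;
  overlapping spans get distance 0; strand is ignored.  Span-to-span
  distance was chosen over TSS-to-TSS as the natural reading of "within
  100 kb upstream and downstream"; the boundary is inclusive.
* **Trans**: Pearson |r| strictly above 0.95 *and* p < 0.05 (t transform
  with n−2 df), treated as a conjunction.  The pipeline computes these
  correlations on log1p depth-normalized counts across the samples of
  the contrast (both conditions pooled).  A caveat the simulator makes
  visible: near the count-noise floor, zero-inflation attenuates sample
  correlations, so the strict 0.95 screen is only well powered for
  adequately expressed genes.

The Pearson/Spearman primitives (average ranks for ties; p via
`t = r·√((n−2)/(1−r²))`) live here and are reused verbatim by the ceRNA
screen, so recorded statistics always reproduce by calling one function.

## Enrichment

Exact upper-tail hypergeometric probability, accumulated in log space
(`gammaln` + `logsumexp`), never through a normal approximation.  The
background defaults to all genes in the supplied term map; terms without
study hits are suppressed; tiers are raw p < 0.05 ("significant") and
p < 0.01 ("highly significant"), with Bonferroni available but off by
default to match the stated criteria.

## ceRNA screen

A triple (lncRNA, miRNA, mRNA) is accepted iff (i) the miRNA targets
both the lncRNA and the mRNA in the interaction tables, (ii) all three
are DE in the comparison, (iii) Spearman(miRNA, lncRNA) ≤ −0.7 **and**
Spearman(miRNA, mRNA) ≤ −0.7 — the negative-regulation requirement is
applied to both pairs, the stricter of the two possible readings,
(iv) Pearson(lncRNA, mRNA) > 0.9 (strict), and (v) the overlap of the
full miRNA sets targeting the lncRNA and the mRNA is hypergeometrically
significant (p < 0.05) against the universe of all miRNAs appearing in
either interaction table.  Edges carry no weights; correlation values
live on the triad table.  Hubs are reported as all maximal-degree nodes
per class, since "central node" has no published criterion.  Export is
Cytoscape-friendly (edge + node attribute TSVs, SIF), and reading the
TSVs back reproduces the graph exactly.

## The simulator

The generator emulates the statistical structure the screen assumes —
not sequences, reads, or alignment:

* **Design**: 3 tissues × 2 conditions × `n_replicates_per_condition`
  samples; features are mRNAs, lncRNAs and miRNAs with GTF-compatible
  annotations for the two transcribed classes.
* **Counts**: NB(mean, φ) with variance `mean + φ·mean²` (φ = 0 ⇒
  Poisson), baseline log-means uniform on a configurable range.
* **Planted triads**: one latent factor per triad, `z_s ~ N(0,1)` per
  sample, entering the lncRNA/mRNA log-mean with loading +β and the
  miRNA with −β.  This forces exactly the sign structure the screen
  tests and is analytically transparent; a feature belongs to at most
  one triad.
* **Condition effect**: ±δ/2 log2 units on every triad member (lncRNA
  and mRNA together, miRNA opposite) and on a random background
  fraction of each class, applied to the log-mean so DE truth and
  coupling truth stay orthogonal knobs.
* **Interactions**: every planted link, plus — per planted pair — links
  from `n_support_mirnas` miRNAs drawn from a reserved pool, emulating
  the multiple shared miRNA response elements that real ceRNA pairs
  exhibit and that the shared-miRNA hypergeometric test is designed to
  detect.  (With a single shared miRNA and a 2 % background rate, no
  overlap of k = 1 can reach p < 0.05 against a ~80-miRNA universe, so
  the test would be structurally untestable.)  Reserved-pool miRNAs
  never receive a condition effect, so they can never seed false
  triads.  All remaining (miRNA, target) pairs appear independently at
  `background_interaction_rate`.
* **Votes and references**: coding/noncoding verdicts flip independently
  at `coding_call_flip_rate`; a configurable fraction of lncRNAs forms
  the "known" reference; a random term→gene map over the mRNAs feeds
  the enrichment stage.
* **Randomness**: one root seed, split into fixed per-stage child
  streams (`numpy.random.SeedSequence` spawn keys), so any stage is
  independently reproducible and whole runs are byte-identical.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `n_planted_triads` | 50 | enough triads for stable sensitivity estimates |
| `coupling_beta` | 1.5 | strong but imperfect coupling; log-scale correlations ≈ 0.95 |
| `nb_dispersion_phi` | 0.1 | typical bulk RNA-seq biological CV ≈ 0.32 |
| `n_replicates_per_condition` | 15 | benchmark replication at which the full screen should succeed |
| `condition_shift_delta` | 4.0 log2 | unambiguous planted DE ("clear signal" regime) |
| `background_interaction_rate` | 0.02 | sparse predicted-targeting tables |
| `n_support_mirnas` | 3 | shared-set overlap detectable at p < 0.05 |
| `baseline_log_mean_range` | (3.0, 5.5) ln | per-sample means ≈ 20–250 counts |
| `coding_call_flip_rate` | 0.0 | noiseless votes by default; noise is a test knob |

`SimConfig.study_scale()` switches to 3 replicates per tissue and
condition — the sequenced design of the motivating studies — where the
same screen's sensitivity degrades; at that scale only the internal
consistency of reported triads is guaranteed, not recovery.

### What the simulator does not emulate

No tissue-specific baselines (tissue is pure replication structure
here), no sequence-level biology (no binding sites, no seed matches), no
isoform structure shared between genes, no batch effects, no
library-preparation biases beyond a scalar depth factor.  Passing the
planted-recovery benchmark therefore shows the *screen logic* is sound
under the assumed statistical model — it does not certify performance on
real data, where normalization, annotation quality and targeting-tool
precision dominate.

## Numerical choices

* Hypergeometric and NB pmfs in log space; minlike outcome collection
  uses a 1e−7 relative slack so floating-point ties do not flip
  p-values.
* Correlation r is clamped to [−1, 1]; |r| = 1 returns p = 0; constant
  vectors raise rather than return NaN (matrix screening drops them).
* Normalized group sums are rounded to the nearest integer before the
  exact test (its support is integral).
* Ties in enrichment output are broken by term id; exported networks
  sort nodes and edges lexicographically — both purely for byte-stable
  output.
* Degenerate inputs: all-zero matrices, empty universes, zero totals and
  missing tool verdicts raise typed errors (`ceranet.errors`) instead of
  propagating NaNs.

## Known limitations

* A single common dispersion under-serves datasets with strong
  mean-dispersion trends; the exact test is conservative at small
  totals.
* Raw-p thresholds (no FDR) replicate the published criteria but are not
  a recommendation.
* The cis rule knows nothing of regulatory topology; 100 kb span
  distance is a heuristic.
* The trans and ceRNA correlation screens assume expression well above
  the count-noise floor; low-abundance features are effectively
  invisible to strict |r| thresholds.
* Full enumeration of the conditional support is O(t) per feature;
  extremely deep libraries (t in the many millions) would warrant a
  saddlepoint or normal approximation that is deliberately not
  implemented.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the benchmark
configuration (480 features, 90 samples, 50 triads, seeds 1–5), a
2 000-feature null calibration, 2 000-transcript identification checks,
an exhaustive hypergeometric sweep (universe ≤ 25), and 1 000 random
correlation vectors — sizes chosen so every guarantee is checked from
scratch in well under a minute each on one core.
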