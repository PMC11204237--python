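# Methods

## The colocalization statistic

Given two interval tracks A (genes) and B (lincRNA loci), each A record is
paired with the same-chromosome B record whose center is nearest to its own
(distance ties resolved toward the smaller start coordinate, so output is
deterministic; B records may serve several A records). Pairs with center
distance L above `max_pair_size` (default 100 kb) are dropped — beyond that
scale "nearest neighbor" no longer reflects a local spatial relationship.

Each pair k carries the index of overlapping

    IO_k = (L_k − s_k/2) / (L_k + s_k/2),      s_k = a_k + b_k,

with a_k, b_k the two stretch lengths. IO_k = −1 exactly when the centers
coincide, crosses 0 when L equals the mean combined half-length, and tends
to +1 for remote stretches. Negative mean IO therefore means B centers lie
inside their paired A stretches.

The null model is the *complete pairwise permutation*: for every unordered
pair of pairs (k, k′) the combined lengths are exchanged while the center
distances stay in place,

    IO_kk′ = ½ [ (L_k − s_k′/2)/(L_k + s_k′/2) + (L_k′ − s_k/2)/(L_k′ + s_k/2) ],

and the observed mean I̅O̅ is compared with the mean ⟨IO⟩_p of IO_kk′ over
all K(K−1)/2 swaps: ΔI = I̅O̅ − ⟨IO⟩_p. Enumerating all swaps (rather than
sampling permutations) removes Monte-Carlo uncertainty from the null at
O(K²) cost — a 500×500 matrix at the gene-track scale, negligible in
practice (memory becomes the binding constraint only above K ≈ 20,000).

## The effective variance of ΔI

ΔI is a U-statistic with kernel h(k,k′) = (IO_k + IO_k′)/2 − IO_kk′ (the
observed-mean term enters through the kernel average). Its first-order
(Hájek projection) variance is

    Var(ΔI) ≈ (4/K) · Var( h̄₁(k) ),    h̄₁(k) = mean over k′≠k of h(k,k′),

estimated with the sample variance of h̄₁ (ddof = 1). This is the σ_eff²
that normalises ζ = ΔI / σ_eff.

An additive approximation, σ²(I)/K + 2σ²(I_kk′)/K − 2Cov with Cov an
empirical observed/permuted covariance term, is also computed and reported
(`sigma_eff_approx`). It replaces the projected kernel variance with the
*total* kernel variance, and the excess (the law of total variance applied
to IO_kk′ in its two arguments) makes it systematically too large: under
null simulations ζ normalised this way has standard deviation ≈ 0.67
instead of 1. The projection variance is therefore the one used for
inference; calibration simulations (1,000 replicates, ~500 pairs each,
both tracks uniform) give mean(ζ) ≈ −0.02, sd(ζ) ≈ 1.01 and an
|ζ| ≥ 1.96 rejection rate of ≈ 0.05, i.e. ζ is standard Gaussian to within
sampling error, which is what the two-sided normal p-value assumes.

Degenerate inputs are surfaced, not papered over: K < 2 is an error (the
null needs two pairs), and a non-positive effective variance — identical
pairs, constant tracks — raises a dedicated diagnostic rather than
returning an infinite or clipped ζ.

A track pair is called colocalized when the two-sided p is at or below α
(default 0.05) *and* the mean IO is negative; a significantly *positive*
ΔI would indicate avoidance, not colocalization.

## Contact quantification

Stages run in a fixed order: replicate intersection → low-complexity
exclusion → extension → gene projection → filter. Intersection keeps the
merged regions covered by both replicates and sums the read counts of every
contributing record, preserving total evidence. Exclusion removes contacts
*fully contained* in a single annotated low-complexity region (partial
overlap survives) — containment, not overlap, because a read entirely
inside a repeat is unmappable evidence while a boundary-spanning read is
not. Extension replaces each shorter contact by
[center − 2500, center + 2500) (a 6-cutter assay resolves contacts to
±2.5 kb), truncated at coordinate 0 and, when a chromosome-sizes map is
given, at the chromosome end; already-long contacts are untouched. A
contact overlapping several gene bodies credits each in full (no unique
assignment is attempted; a `direction`-style unique-best mode was
considered and rejected as under-determined). The filter is strictly
greater-than: a gene at exactly the threshold (default 100 reads) is
dropped.

## Enrichment and expression comparisons

Term enrichment is the one-sided Fisher exact test — the hypergeometric
upper tail P(X ≥ k) for overlap k between an n-gene query and an m-gene
term in a background of N genes (default N = 20,000, roughly the
protein-coding universe; configurable because absolute p-values scale with
it). Benjamini–Hochberg adjustment runs across all terms of a library.
Symbols are uppercased and stripped; no alias resolution is attempted
(that would require an external identifier database and would silently
change counts).

Expression comparisons use the two-sided Mann–Whitney U test: exact
enumeration of the U distribution for untied samples with n+m ≤ 12,
otherwise the tie-corrected normal approximation with continuity
correction (the default behavior of the standard R pairwise test).
Families of pairwise comparisons are Holm-adjusted (step-down FWER
control). Summaries report medians, quartiles and each group's median as a
ratio to a reference group; a zero reference median flags the ratio as
undefined instead of emitting infinities. Violin plots are deliberately
not part of the tested surface — graphics are not testable claims.

## The synthetic-data generator

Defaults describe a 4 × 25 Mb genome with 500 genes (lognormal lengths,
median 20 kb, σ_log = 0.5, placed uniformly without overlap with a ≥6 kb
gap) and 2,000 lincRNA loci. A fraction ρ of lincRNAs (default 0.5; 0 for
null calibration, 1 for planted-recovery experiments) is planted with its
center at gene_center ± f·gene_length inside a uniformly chosen host gene;
the rest are uniform. The offset fraction f defaults to 1/6, for which a
point-like lincRNA gives per-pair IO = (f − ½)/(f + ½) = −0.5 — the
magnitude regime of genuinely colocalized tracks. An independent
Monte-Carlo oracle (`expected_io_oracle`, 10 replicate simulations at the
test's sample size) provides the recovery target without reusing the
analytic shortcut.

Contact totals per contacted gene are negative binomial (mean 120,
dispersion 4 — overdispersed, as deep-sequencing counts are), split
binomially between replicates, with one gene pinned at exactly the filter
threshold to exercise the strict inequality. Decoy contacts inside
low-complexity regions and single-replicate noise contacts exercise the
exclusion and intersection stages; the generator constrains their placement
so the ground-truth pass list is exact, not approximate. TPMs are lognormal
with the lincRNA log-mean shifted by log(1/15), planting a ~15× median gap.
Library terms have 100 members; planted terms draw 55 from the query set
(the "55/100 overlap" regime), decoys draw uniformly from the background.

What the generator does *not* emulate: chromatin-domain structure or
distance decay in contacts, gene clustering/strand structure, expression
correlation between neighboring genes, multi-transcript gene models, and
mapping artifacts beyond the low-complexity decoys. Passing tests
demonstrate the statistical machinery is correct and calibrated under
these idealised conditions, not that any particular biological dataset
will show colocalization.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GTF is converted at
  ingest. Interval centers are kept real-valued ((start+end)/2, possibly
  x.5) — rounding would bias every center distance by up to 0.5 bp.
- Chromosome names match by exact string equality. A `chr1`/`1` mismatch
  yields zero pairs and a loud error, never silent aliasing.
- Strand is parsed and carried but ignored by all distance and overlap
  computations.
- All interval set arithmetic is delegated to pyranges; the permutation
  statistic is vectorised numpy checked against a literal double-loop
  oracle to 1e-12 in the test suite.
- Every generator and pipeline stage is a pure function of (inputs, seed);
  stage randomness comes from named substreams of one seed, and reruns are
  byte-identical.

## Limitations

- The O(K²) complete permutation is quadratic in pair count; for tracks
  with >~20,000 surviving pairs a sampled null would be needed.
- The projection variance is a first-order approximation; residual
  dependence between pairs that share a nearest B record is ignored (the
  calibration simulations bound its effect at the percent level).
- Enrichment p-values depend on the chosen background size, so absolute
  values are comparable only within a fixed background.
- With very small K (≲ 10) the Gaussian approximation for ζ is unreliable;
  the degenerate-variance diagnostic catches the extreme cases but modest-K
  p-values should be treated as descriptive.
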