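# lincoloc

Do long intergenic non-coding RNA (lincRNA) loci colocalize with the genes
that physically contact ribosomal DNA? rDNA clusters organise the nucleolus,
and genes found in 4C contact with the rDNA intergenic spacer form a
distinctive, expression-linked gene set. `lincoloc` implements the
computational chain needed to ask whether lincRNA loci sit *inside* those
genes more often than chance allows:

1. **Contact quantification** — two replicates of mapped 4C contacts are
   intersected (read support summed), contacts lying entirely within
   low-complexity regions are discarded, survivors are extended to 5 kb
   (the resolution of a 6-cutter 4C assay) and projected onto gene bodies;
   genes with more than 100 supporting reads are called rDNA-contacting.
2. **Colocalization** — every gene is paired with its nearest lincRNA by
   center distance (pairs capped at 100 kb). Each pair gets the index of
   overlapping

   IO_k = (L_k − (a_k + b_k)/2) / (L_k + (a_k + b_k)/2),

   where L_k is the center distance and a_k, b_k the stretch lengths:
   −1 when centers coincide, → +1 for remote stretches. The observed mean
   I̅O̅ is compared with the mean of the *complete* pairwise permutation
   null (lengths swapped between every pair of pairs, distances kept), and
   the difference ΔI is normalised to a z-like statistic
   ζ = ΔI / σ_eff(ΔI) with a covariance-corrected effective standard
   deviation, so two-sided Gaussian tails give the significance.
3. **Co-expression enrichment** — the contact genes are scored against a
   GMT library of lincRNA co-expression terms with the one-sided Fisher
   exact test, Benjamini–Hochberg adjusted, plus Venn/shared-fraction
   arithmetic for comparing gene sets between conditions.
4. **Expression comparison** — TPM distributions of gene groups are
   compared with two-sided Mann–Whitney U tests under Holm correction.

A seeded synthetic-data generator (`lincoloc.simulate`) produces every
input with planted, known structure — colocalized lincRNAs at a chosen
offset, contact read counts straddling the filter threshold, a ~15× planted
gene/lincRNA expression gap, enriched library terms — so the whole pipeline
can be validated end to end without external data. Real data in standard
formats (GTF, BED, TSV, GMT) drop into the same entry points.

## Worked example

The numbered scripts under `analysis/` run the full chain on synthetic
inputs with full planted colocalization (seed 17):

```
python analysis/01_simulate_inputs.py
python analysis/02_quantify_contacts.py
python analysis/03_colocalize.py
```

which prints

```
113 genes pass the >100-read filter (ground truth: 113; exact match: True)
planted: IO=-0.4896  zeta=-9.27  p=1.89e-20  pairs=111  -> colocalized
null   : IO=0.1577  zeta=0.17   p=0.866     pairs=496  -> not colocalized
```

The planted tracks put every lincRNA center inside a gene at 1/6 of the
gene length from its center, for which the per-pair index is
(1/6 − 1/2)/(1/6 + 1/2) = −0.5; the pipeline recovers IO ≈ −0.49 with a
strongly negative ζ, while the unstructured null track pair is correctly
not called. `04_enrichment.py` ranks the planted co-expression terms first
(overlap 55/100, p_adj ≈ 10⁻¹⁰¹ vs ≈ 0.6 for decoys) and
`05_compare_expression.py` reports the planted ~15× lincRNA/gene median
expression gap with Holm-adjusted Mann–Whitney p < 10⁻⁵⁹.

The same stages are available as a CLI (`lincoloc simulate / quantify /
colocalize / enrich / compare-expression / run-all`) for use on real
annotation and contact files.

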