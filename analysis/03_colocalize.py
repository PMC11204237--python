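#!/usr/bin/env python
"""Do lincRNA loci colocalize with the rDNA-contacting genes?

Runs the index-of-overlapping statistic with its complete pairwise length-
swap permutation null on (filter-passing genes) × (lincRNA loci), and — for
contrast — on a freshly simulated null track pair with no planted
structure. Writes results/colocalization.tsv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from lincoloc.colocalization import ColocalizationParams, colocalize
from lincoloc.intervals import genes_to_track, read_bed, read_gtf_genes
from lincoloc.simulate import SyntheticConfig, simulate_tracks

INPUTS = Path("results/inputs")
OUT = Path("results/colocalization.tsv")
SEED = 17


def main() -> None:
    genes = read_gtf_genes(INPUTS / "genes.gtf")
    contacts = pd.read_csv(Path("results/gene_contacts.tsv"), sep="\t")
    passing = set(contacts.gene_id[contacts.passes_filter])
    gene_track = genes_to_track([g for g in genes if g.gene_id in passing])
    lincs = read_bed(INPUTS / "lincs.bed")

    params = ColocalizationParams(max_pair_size=100_000, alpha=0.05)
    res = colocalize(gene_track, lincs, params)

    null_cfg = SyntheticConfig(seed=SEED + 1, coloc_fraction=0.0)
    ng, _, nl = simulate_tracks(null_cfg)
    null_res = colocalize(ng, nl, params)

    rows = [
        {"comparison": "rDNA-contacting genes vs lincRNAs", **res.to_row()},
        {"comparison": "null (uniform tracks)", **null_res.to_row()},
    ]
    pd.DataFrame(rows).to_csv(OUT, sep="\t", index=False)
    print(f"planted: IO={res.io_mean:.4f}  zeta={res.zeta:.2f}  "
          f"p={res.p_two_sided:.3g}  pairs={res.K}  -> "
          f"{'colocalized' if res.colocalized else 'not colocalized'}")
    print(f"null   : IO={null_res.io_mean:.4f}  zeta={null_res.zeta:.2f}  "
          f"p={null_res.p_two_sided:.3g}  pairs={null_res.K}  -> "
          f"{'colocalized' if null_res.colocalized else 'not colocalized'}")


if __name__ == "__main__":
    main()
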