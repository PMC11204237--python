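"""Synthetic inputs with planted, known structure for every pipeline stage.

The generator emulates the qualitative features the analysis depends on:

* a gene track (non-overlapping, uniformly placed, lognormal lengths) and a
  lincRNA track in which a tunable fraction of lincRNA centers is planted
  *inside* genes at a fixed offset from the gene center — the signal the
  colocalization statistic is built to detect. With point-like lincRNAs and
  an offset of 1/6 of the gene length, each planted pair has
  IO = (g/6 − g/2)/(g/6 + g/2) = −0.5 exactly;
* two replicates of 4C contact records whose per-gene read totals are
  overdispersed (negative binomial) and straddle the 100-read filter
  threshold, plus low-complexity decoys and single-replicate noise, with the
  ground-truth pass/fail list emitted alongside;
* lognormal TPM tables in which the lincRNA median is planted well below
  the gene median (default 1/15);
* a GMT gene-set library of fixed-size co-expression terms, some of which
  are planted to overlap a designated query set far above chance.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs. Stage randomness is drawn from named substreams of
the single config seed so stages stay independent of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactRecord
from .enrichment import GeneSetLibrary
from .intervals import GeneAnnotation, GenomicInterval, Track

__all__ = [
    "SyntheticConfig",
    "simulate_tracks",
    "expected_io_oracle",
    "simulate_repeats",
    "simulate_contacts",
    "simulate_expression",
    "simulate_gene_set_library",
    "write_synthetic_inputs",
]

_STREAMS = {"tracks": 0, "repeats": 1, "contacts": 2, "expression": 3, "library": 4, "oracle": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic genome, with study-scale defaults.

    Defaults give a 4×25 Mb genome carrying 500 genes (median 20 kb,
    lognormal) and 2000 lincRNA loci, of which ``coloc_fraction`` are
    planted inside genes at ``offset_fraction`` of the gene length from the
    gene center (1/6 ⇒ per-pair IO of −0.5 for point lincRNAs). Contact
    read totals are negative binomial with mean 120 and dispersion 4, so
    roughly half the contacted genes clear the 100-read filter.
    """

    seed: int
    n_chroms: int = 4
    chrom_length: int = 25_000_000
    n_genes: int = 500
    gene_median_length: float = 20_000.0
    gene_length_sigma: float = 0.5
    min_gene_length: int = 500
    min_gene_gap: int = 6_000
    n_lincs: int = 2_000
    coloc_fraction: float = 0.5
    offset_fraction: float = 1.0 / 6.0
    linc_length: int = 1_000
    # 4C contacts
    n_contact_genes: int = 200
    contact_read_mean: float = 120.0
    contact_read_dispersion: float = 4.0
    contact_region_half: int = 100
    contact_threshold: int = 100
    plant_boundary_total: Optional[int] = 100
    n_noise_contacts: int = 200
    n_repeat_regions: int = 300
    repeat_length: int = 400
    n_decoy_contacts: int = 100
    # expression
    tpm_gene_log_mu: float = math.log(20.0)
    tpm_log_sigma: float = 1.2
    linc_tpm_ratio: float = 1.0 / 15.0
    # gene-set library
    n_terms: int = 50
    term_size: int = 100
    planted_terms: int = 3
    planted_overlap: int = 55
    background_size: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_lincs", "linc_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.term_size > self.background_size:
            raise ValueError("term_size cannot exceed background_size")


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _place_nonoverlapping(
    rng: np.random.Generator, lengths: np.ndarray, chrom_length: int, gap: int
) -> np.ndarray:
    """Uniformly place non-overlapping intervals with a minimum gap.

    Uses the spacing construction: draw sorted uniforms over the free space
    left after reserving every interval plus its gap, then lay intervals
    down cumulatively. The result is the uniform distribution over all
    admissible non-overlapping configurations (in sorted order).
    """
    n = len(lengths)
    reserved = lengths.sum() + gap * max(n - 1, 0)
    free = chrom_length - reserved
    if free <= 0:
        raise ValueError(
            f"genome too small: need > {reserved} bp for {n} genes on a "
            f"{chrom_length} bp chromosome"
        )
    u = np.sort(rng.uniform(0.0, free, size=n))
    offsets = np.concatenate([[0.0], np.cumsum(lengths[:-1] + gap)])
    return np.floor(u + offsets).astype(np.int64)


def simulate_tracks(config: SyntheticConfig) -> tuple[Track, list[GeneAnnotation], Track]:
    """Generate the gene and lincRNA tracks.

    Returns (gene track, gene annotations, lincRNA track). Planted lincRNAs
    pick a host gene uniformly and sit at
    ``gene_center ± offset_fraction·gene_length``; the remainder are placed
    uniformly over the genome.
    """
    rng = _rng(config.seed, "tracks")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom_genes = _split_counts(config.n_genes, config.n_chroms)

    gene_ivs: list[GenomicInterval] = []
    annotations: list[GeneAnnotation] = []
    gidx = 0
    for chrom, n_c in zip(chroms, per_chrom_genes):
        if n_c == 0:
            continue
        lengths = rng.lognormal(math.log(config.gene_median_length), config.gene_length_sigma, n_c)
        lengths = np.maximum(np.round(lengths), config.min_gene_length).astype(np.int64)
        starts = _place_nonoverlapping(rng, lengths, config.chrom_length, config.min_gene_gap)
        for s, ln in zip(starts, lengths):
            gid = f"g{gidx:05d}"
            iv = GenomicInterval(chrom, int(s), int(s + ln), gid)
            gene_ivs.append(iv)
            annotations.append(GeneAnnotation(gid, f"GENE{gidx:05d}", iv))
            gidx += 1

    n_planted = int(round(config.coloc_fraction * config.n_lincs))
    linc_ivs: list[GenomicInterval] = []
    ll = config.linc_length
    if n_planted:
        hosts = rng.integers(0, len(gene_ivs), size=n_planted)
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        for i, (h, sgn) in enumerate(zip(hosts, signs)):
            g = gene_ivs[h]
            center = g.center + sgn * config.offset_fraction * g.length
            start = int(math.floor(center - ll / 2.0))
            start = max(start, 0)
            linc_ivs.append(GenomicInterval(g.chrom, start, start + ll, f"linc{i:05d}"))
    for i in range(n_planted, config.n_lincs):
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - ll))
        linc_ivs.append(GenomicInterval(chrom, start, start + ll, f"linc{i:05d}"))

    genes_track = Track(name="genes", intervals=gene_ivs)
    lincs_track = Track(name="lincRNAs", intervals=linc_ivs)
    return genes_track, annotations, lincs_track


def expected_io_oracle(config: SyntheticConfig, n_replicates: int = 10) -> float:
    """Monte-Carlo expectation of the mean IO under the planted model.

    Simulates ``n_replicates`` independent track pairs (10× the sample size
    of a single run) with seeds derived from the config seed, runs the
    nearest-neighbor pairing and averages the per-run mean IO. Serves as
    the recovery target for planted-signal tests; independent of the
    analytic shortcut ``IO = (f − 1/2)/(f + 1/2)`` that holds for point
    lincRNAs at offset fraction ``f``.
    """
    from .colocalization import ColocalizationParams, pair_nearest_neighbors

    rng = _rng(config.seed, "oracle")
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    means = []
    for s in seeds:
        genes, _, lincs = simulate_tracks(replace(config, seed=int(s)))
        pairs = pair_nearest_neighbors(genes, lincs, ColocalizationParams())
        means.append(float(np.mean([p.io for p in pairs])))
    return float(np.mean(means))


def simulate_repeats(config: SyntheticConfig, annotations: Sequence[GeneAnnotation]) -> Track:
    """Uniformly placed low-complexity regions, kept clear of the gene
    bodies designated to receive contacts (so decoy exclusion cannot
    perturb the planted contact ground truth)."""
    rng = _rng(config.seed, "repeats")
    contact_bodies = _contact_gene_set(config, annotations)
    ivs: list[GenomicInterval] = []
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    attempts = 0
    while len(ivs) < config.n_repeat_regions and attempts < config.n_repeat_regions * 20:
        attempts += 1
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - config.repeat_length))
        iv = GenomicInterval(chrom, start, start + config.repeat_length, f"rep{len(ivs):05d}")
        if any(
            iv.chrom == g.interval.chrom
            and iv.start < g.interval.end
            and g.interval.start < iv.end
            for g in contact_bodies
        ):
            continue
        ivs.append(iv)
    return Track(name="low_complexity", intervals=ivs)


def _contact_gene_set(
    config: SyntheticConfig, annotations: Sequence[GeneAnnotation]
) -> list[GeneAnnotation]:
    """The designated contact-receiving genes (deterministic substream)."""
    rng = _rng(config.seed, "contacts")
    idx = rng.choice(len(annotations), size=min(config.n_contact_genes, len(annotations)),
                     replace=False)
    return [annotations[i] for i in sorted(idx)]


def simulate_contacts(
    config: SyntheticConfig,
    annotations: Sequence[GeneAnnotation],
    repeats: Optional[Track] = None,
) -> tuple[list[ContactRecord], list[ContactRecord], pd.DataFrame]:
    """Two replicates of contact records plus the ground-truth gene table.

    Per contacted gene a total read count T ~ NegBin(mean, dispersion) is
    split binomially between the replicates; a gene's contact region is a
    short window at its center, identical in replicate 1 and expanded by a
    few bp in replicate 2 (replicate intersection recovers the window and
    sums the reads). The first contacted gene can be pinned to an exact
    boundary total (default 100) to exercise the strict > threshold. Decoy
    contacts sit wholly inside low-complexity regions; noise contacts occur
    in a single replicate only. Ground truth: total T with both replicate
    shares >= 1 read, zero otherwise; passes ⇔ total > threshold.
    """
    rng = _rng(config.seed, "contacts")
    idx = rng.choice(len(annotations), size=min(config.n_contact_genes, len(annotations)),
                     replace=False)
    chosen = [annotations[i] for i in sorted(idx)]

    r = config.contact_read_dispersion
    p_nb = r / (r + config.contact_read_mean)
    totals = rng.negative_binomial(r, p_nb, size=len(chosen)).astype(np.int64)
    if config.plant_boundary_total is not None and len(chosen) > 0:
        totals[0] = config.plant_boundary_total
    shares = rng.binomial(totals, 0.5)

    rep1: list[ContactRecord] = []
    rep2: list[ContactRecord] = []
    truth_rows = []
    half = config.contact_region_half
    for gene, total, r1 in zip(chosen, totals, shares):
        r2 = int(total - r1)
        r1 = int(r1)
        c = int(gene.interval.center)
        base = GenomicInterval(gene.interval.chrom, c - half, c + half, f"ct_{gene.gene_id}")
        jitter = int(rng.integers(0, 26))
        wide = GenomicInterval(base.chrom, max(base.start - jitter, 0), base.end + jitter, base.id)
        if r1 >= 1:
            rep1.append(ContactRecord(base, r1))
        if r2 >= 1:
            rep2.append(ContactRecord(wide, r2))
        observed = int(total) if (r1 >= 1 and r2 >= 1) else 0
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "gene_name": gene.gene_name,
                "true_reads": observed,
                "passes": observed > config.contact_threshold,
            }
        )

    if repeats is not None and len(repeats) > 0 and config.n_decoy_contacts > 0:
        pool = repeats.intervals
        picks = rng.integers(0, len(pool), size=config.n_decoy_contacts)
        for i, j in enumerate(picks):
            reg = pool[int(j)]
            mid = int(reg.center)
            iv = GenomicInterval(reg.chrom, mid - 25, mid + 25, f"decoy{i:04d}")
            reads = int(rng.integers(60, 200))
            rep1.append(ContactRecord(iv, reads))
            rep2.append(ContactRecord(iv, reads))

    noise1 = _noise_contacts(rng, config, "n1")
    noise2 = _noise_contacts(rng, config, "n2")
    noise1 = [c for c in noise1 if not _overlaps_any(c.interval, rep2 + noise2)]
    noise2 = [c for c in noise2 if not _overlaps_any(c.interval, rep1 + noise1)]
    rep1 += noise1
    rep2 += noise2

    rep1.sort(key=lambda cr: cr.interval)
    rep2.sort(key=lambda cr: cr.interval)
    truth = pd.DataFrame(truth_rows).sort_values("gene_id").reset_index(drop=True)
    return rep1, rep2, truth


def _noise_contacts(
    rng: np.random.Generator, config: SyntheticConfig, tag: str
) -> list[ContactRecord]:
    out = []
    for i in range(config.n_noise_contacts):
        chrom = f"chr{int(rng.integers(0, config.n_chroms)) + 1}"
        start = int(rng.integers(0, config.chrom_length - 200))
        out.append(
            ContactRecord(
                GenomicInterval(chrom, start, start + 200, f"{tag}_{i:04d}"),
                int(rng.integers(1, 6)),
            )
        )
    return out


def _overlaps_any(iv: GenomicInterval, records: Sequence[ContactRecord]) -> bool:
    return any(
        iv.chrom == c.interval.chrom and iv.start < c.interval.end and c.interval.start < iv.end
        for c in records
    )


def simulate_expression(
    config: SyntheticConfig,
    annotations: Sequence[GeneAnnotation],
    lincs: Track,
) -> pd.DataFrame:
    """Replicate-averaged TPM table over genes and lincRNA loci.

    Both groups are lognormal with a common log-scale sigma; the lincRNA
    log-mean is shifted down by ``log(linc_tpm_ratio)`` so the planted
    median ratio is ``linc_tpm_ratio`` (default 1/15, i.e. lincRNAs are
    expressed ~15× lower). Sigma 0 collapses each group to a constant.
    """
    rng = _rng(config.seed, "expression")
    gene_ids = [g.gene_id for g in annotations]
    linc_ids = [iv.id or f"linc{i:05d}" for i, iv in enumerate(lincs)]
    g_tpm = rng.lognormal(config.tpm_gene_log_mu, config.tpm_log_sigma, len(gene_ids))
    l_tpm = rng.lognormal(
        config.tpm_gene_log_mu + math.log(config.linc_tpm_ratio),
        config.tpm_log_sigma,
        len(linc_ids),
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids + linc_ids,
            "tpm": np.concatenate([g_tpm, l_tpm]),
            "biotype": ["gene"] * len(gene_ids) + ["lincRNA"] * len(linc_ids),
        }
    )


def simulate_gene_set_library(
    config: SyntheticConfig, query_genes: Sequence[str]
) -> tuple[GeneSetLibrary, list[str]]:
    """A co-expression term library with planted enrichment.

    ``planted_terms`` terms draw ``planted_overlap`` of their members from
    the query set (far above the hypergeometric expectation); the remaining
    decoy terms are uniform draws from the background universe. Returns the
    library and the planted term names.
    """
    rng = _rng(config.seed, "library")
    query = sorted({q.strip().upper() for q in query_genes if q.strip()})
    if not query:
        raise ValueError("query_genes is empty")
    n_bg_extra = config.background_size - len(query)
    if n_bg_extra < 0:
        raise ValueError("query larger than background_size")
    universe = query + [f"BG{i:05d}" for i in range(n_bg_extra)]
    universe_arr = np.array(universe)
    nonquery = np.array(universe[len(query):]) if n_bg_extra else np.array([])

    overlap = min(config.planted_overlap, len(query), config.term_size)
    terms: dict[str, frozenset[str]] = {}
    planted_names = []
    for i in range(config.planted_terms):
        name = f"LINC-PLANTED-{i + 1:02d}"
        planted_names.append(name)
        from_query = rng.choice(len(query), size=overlap, replace=False)
        n_rest = config.term_size - overlap
        rest = (
            rng.choice(len(nonquery), size=n_rest, replace=False) if n_rest else np.array([], int)
        )
        members = [query[j] for j in from_query] + [str(nonquery[j]) for j in rest]
        terms[name] = frozenset(members)
    for i in range(config.n_terms - config.planted_terms):
        name = f"LINC-DECOY-{i + 1:03d}"
        members = universe_arr[rng.choice(len(universe_arr), size=config.term_size, replace=False)]
        terms[name] = frozenset(str(m) for m in members)
    return GeneSetLibrary(terms, background_size=config.background_size), planted_names


def write_synthetic_inputs(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise every synthetic input as standard-format files.

    Writes genes.gtf, lincs.bed, repeats.bed, contacts_rep1/2.bed,
    expression.tsv, library.gmt and the contact ground truth, and returns
    the path map. Byte-identical across reruns with the same config.
    """
    from .contacts import write_contacts_bed
    from .intervals import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_track, annotations, lincs = simulate_tracks(config)
    repeats = simulate_repeats(config, annotations)
    rep1, rep2, truth = simulate_contacts(config, annotations, repeats)
    expr = simulate_expression(config, annotations, lincs)
    # plant enrichment against the genes the contact filter will recover, so
    # the downstream enrichment stage has a true signal to find
    query = list(truth.gene_name[truth.passes])
    if len(query) < config.planted_overlap:
        query = list(truth.gene_name)
    library, planted = simulate_gene_set_library(config, query)

    paths = {
        "genes_gtf": outdir / "genes.gtf",
        "lincs_bed": outdir / "lincs.bed",
        "repeats_bed": outdir / "repeats.bed",
        "contacts_rep1": outdir / "contacts_rep1.bed",
        "contacts_rep2": outdir / "contacts_rep2.bed",
        "expression_tsv": outdir / "expression.tsv",
        "library_gmt": outdir / "library.gmt",
        "contact_truth": outdir / "contact_truth.tsv",
        "planted_terms": outdir / "planted_terms.txt",
    }
    _write_gtf(annotations, paths["genes_gtf"])
    write_bed(lincs, paths["lincs_bed"])
    write_bed(repeats, paths["repeats_bed"])
    write_contacts_bed(rep1, paths["contacts_rep1"])
    write_contacts_bed(rep2, paths["contacts_rep2"])
    expr.to_csv(paths["expression_tsv"], sep="\t", index=False)
    library.to_gmt(paths["library_gmt"])
    truth.to_csv(paths["contact_truth"], sep="\t", index=False)
    paths["planted_terms"].write_text("".join(f"{t}\n" for t in planted))
    return paths


def _write_gtf(annotations: Sequence[GeneAnnotation], path: Path) -> None:
    """Write gene-level GTF records (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in sorted(annotations, key=lambda a: a.interval):
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{iv.chrom}\tlincoloc\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand or '.'}\t.\t{attrs}\n"
            )
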