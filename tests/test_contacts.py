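"""Contact quantification: replicate intersection, containment exclusion,
extension, gene assignment and the strict read-count filter."""

import numpy as np
import pytest

from lincoloc.contacts import (
    ContactRecord,
    GeneContactTable,
    assign_contacts_to_genes,
    exclude_low_complexity,
    extend_contacts,
    filter_contact_genes,
    intersect_replicates,
    quantify_contacts,
)
from lincoloc.intervals import GeneAnnotation, GenomicInterval, Track


def contact(chrom, start, end, reads, cid=None):
    return ContactRecord(GenomicInterval(chrom, start, end, cid), reads)


def gene(gid, chrom, start, end):
    return GeneAnnotation(gid, gid.upper(), GenomicInterval(chrom, start, end, gid))


class TestIntersectReplicates:
    def test_identical_records_sum(self):
        out = intersect_replicates([contact("chr1", 0, 100, 10)], [contact("chr1", 0, 100, 10)])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end, out[0].reads) == (0, 100, 20)

    def test_disjoint_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            out = intersect_replicates(
                [contact("chr1", 0, 10, 3)], [contact("chr1", 50, 60, 4)]
            )
        assert out == []

    def test_partial_overlap_region_and_counts(self):
        out = intersect_replicates(
            [contact("chr1", 0, 100, 5)], [contact("chr1", 50, 150, 7)]
        )
        assert [(c.interval.start, c.interval.end, c.reads) for c in out] == [(50, 100, 12)]

    def test_multiple_contributors_sum(self):
        rep1 = [contact("chr1", 0, 100, 5), contact("chr1", 60, 120, 2)]
        rep2 = [contact("chr1", 50, 150, 7)]
        out = intersect_replicates(rep1, rep2)
        # covered-by-both region is [50,120); all three overlapping records contribute
        assert [(c.interval.start, c.interval.end, c.reads) for c in out] == [(50, 120, 14)]


class TestExcludeLowComplexity:
    def test_full_containment_removed(self):
        regions = Track(intervals=[GenomicInterval("chr1", 0, 100)])
        out = exclude_low_complexity([contact("chr1", 10, 20, 5)], regions)
        assert out == []

    def test_partial_overlap_kept(self):
        regions = Track(intervals=[GenomicInterval("chr1", 0, 100)])
        c = contact("chr1", 90, 110, 5)
        assert exclude_low_complexity([c], regions) == [c]

    def test_empty_regions_identity(self):
        c = contact("chr1", 10, 20, 5)
        assert exclude_low_complexity([c], Track()) == [c]


class TestExtendContacts:
    def test_symmetric_extension(self):
        (out,) = extend_contacts([contact("chr1", 100_000, 100_010, 1)])
        assert (out.interval.start, out.interval.end) == (97_505, 102_505)

    def test_clamped_at_zero(self):
        (out,) = extend_contacts([contact("chr1", 1000, 1010, 1)])
        assert (out.interval.start, out.interval.end) == (0, 3505)

    def test_long_contact_untouched(self):
        c = contact("chr1", 0, 6000, 1)
        assert extend_contacts([c]) == [c]

    def test_chrom_sizes_clamp_right(self):
        (out,) = extend_contacts(
            [contact("chr1", 9000, 9010, 1)], chrom_sizes={"chr1": 10_000}
        )
        assert out.interval.end == 10_000


class TestAssignAndFilter:
    GENES = [gene("g1", "chr1", 0, 1000), gene("g2", "chr1", 1000, 2000)]

    def test_contact_spanning_two_genes_credits_both(self):
        table = assign_contacts_to_genes([contact("chr1", 900, 1100, 120)], self.GENES)
        assert dict(zip(table.table.gene_id, table.table.contact_reads)) == {
            "g1": 120,
            "g2": 120,
        }

    def test_uncontacted_gene_zero(self):
        table = assign_contacts_to_genes([contact("chr1", 100, 200, 60)], self.GENES)
        assert dict(zip(table.table.gene_id, table.table.contact_reads)) == {"g1": 60, "g2": 0}

    def test_counts_additive(self):
        table = assign_contacts_to_genes(
            [contact("chr1", 100, 200, 60), contact("chr1", 300, 400, 50)], self.GENES
        )
        assert table.table.set_index("gene_id").contact_reads["g1"] == 110

    @pytest.mark.parametrize("reads,passes", [(101, True), (100, False), (99, False)])
    def test_strict_threshold(self, reads, passes):
        table = assign_contacts_to_genes([contact("chr1", 100, 200, reads)], self.GENES)
        assert bool(table.table.set_index("gene_id").passes_filter["g1"]) is passes

    def test_refilter(self):
        table = assign_contacts_to_genes([contact("chr1", 100, 200, 60)], self.GENES)
        relaxed = filter_contact_genes(table, threshold=50)
        assert relaxed.passing_gene_ids == ["g1"]


class TestPipelineOrder:
    """The canonical order matters: excluding after extension would spare
    contacts whose extension escapes the repeat region."""

    def test_exclude_before_extend(self):
        genes = [gene("g1", "chr1", 0, 20_000)]
        repeat = Track(intervals=[GenomicInterval("chr1", 9_000, 9_400)])
        inside = [contact("chr1", 9_100, 9_200, 500)]
        canonical = assign_contacts_to_genes(
            extend_contacts(exclude_low_complexity(inside, repeat)), genes
        )
        wrong = assign_contacts_to_genes(
            exclude_low_complexity(extend_contacts(inside), repeat), genes
        )
        assert canonical.table.contact_reads.sum() == 0
        assert wrong.table.contact_reads.sum() == 500

    def test_synthetic_recount(self, small_config, rng):
        """Filter-passing genes from the full chain equal a brute-force
        recount on the generator's ground truth."""
        from lincoloc.simulate import simulate_contacts, simulate_repeats, simulate_tracks

        _, ann, _ = simulate_tracks(small_config)
        repeats = simulate_repeats(small_config, ann)
        rep1, rep2, truth = simulate_contacts(small_config, ann, repeats)
        table = quantify_contacts(rep1, rep2, ann, exclude_regions=repeats)
        got = set(table.passing_gene_ids)
        want = set(truth.gene_id[truth.passes])
        assert got == want
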