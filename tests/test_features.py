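import numpy as np
import pandas as pd
import pytest

from retroscope.features import (
    assign_genomic_context,
    at_fraction,
    cfs_overlap_summary,
    context_summary,
    exon_proximity,
    flanking_composition,
    gene_length_strata,
    gene_list_intersection,
    gene_patient_table,
    percent,
    recurrent_gene_report,
    tsd_length_histogram,
)
from retroscope.model import GeneSet, PatientClass, TEFamily

from conftest import mk_cons, mk_gene


class TestTSDHistogram:
    def test_single_observation(self):
        calls = [mk_cons(100, tsd_sequence="AAGAAAGTAAAGGA")]
        hist, mode, n_missing = tsd_length_histogram(calls)
        assert hist.to_dict() == {14: 1}
        assert mode == 14 and n_missing == 0

    def test_no_tsd_reported_as_absent(self):
        hist, mode, n_missing = tsd_length_histogram([mk_cons(100), mk_cons(200)])
        assert hist.empty and mode is None and n_missing == 2

    def test_mode_tie_breaks_to_smallest_length(self):
        calls = [
            mk_cons(100, tsd_sequence="AAAA"),
            mk_cons(200, tsd_sequence="CCCCCC"),
        ]
        _, mode, _ = tsd_length_histogram(calls)
        assert mode == 4


class TestFlankingComposition:
    def test_all_a_contig(self):
        genome = {"chr1": "A" * 201}
        table, n_used, n_excl = flanking_composition(genome, [mk_cons(101)], 50)
        assert n_used == 1 and n_excl == 0
        assert (table["A"] == 1.0).all()

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": "".join(rng.choice(list("ACGTN"), size=2000))}
        calls = [mk_cons(int(p)) for p in rng.integers(100, 1900, size=20)]
        table, _, _ = flanking_composition(genome, calls, 50)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_edge_truncated_sites_excluded_and_counted(self):
        genome = {"chr1": "A" * 200}
        table, n_used, n_excl = flanking_composition(
            genome, [mk_cons(10), mk_cons(100)], 50
        )
        assert n_used == 1 and n_excl == 1

    def test_absent_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chr9"):
            flanking_composition({"chr1": "A" * 200}, [mk_cons(100, chrom="chr9")], 50)


def _gene_fixture():
    # g1: exons (1000,1200) and (5000,5200), CDS inside both
    g1 = mk_gene(
        "g1", "chr1", 1000, 5200,
        exons=[(1000, 1200), (5000, 5200)],
        cds=[(1100, 1200), (5000, 5100)],
    )
    g2 = mk_gene("g2", "chr1", 4000, 9000, exons=[(4000, 4100), (8900, 9000)])
    return GeneSet([g1, g2])


class TestGenomicContext:
    def test_intron_between_exons(self):
        labels = assign_genomic_context([mk_cons(3001)], _gene_fixture())
        assert labels[0].label == "intron"
        assert labels[0].gene_ids_overlapped == ("g1",)

    def test_intergenic_outside_every_span(self):
        labels = assign_genomic_context([mk_cons(20_000)], _gene_fixture())
        assert labels[0].label == "intergenic"
        assert labels[0].gene_ids_overlapped == ()

    def test_cds_and_utr_precedence(self):
        genes = _gene_fixture()
        cds = assign_genomic_context([mk_cons(1151)], genes)[0]
        assert cds.label == "CDS"
        utr5 = assign_genomic_context([mk_cons(1051)], genes)[0]
        assert utr5.label == "UTR5"  # exonic, upstream of CDS on '+' strand
        utr3 = assign_genomic_context([mk_cons(5151)], genes)[0]
        assert utr3.label == "UTR3"

    def test_two_gene_overlap_flagged_once(self):
        labels = assign_genomic_context([mk_cons(4501)], _gene_fixture())
        assert labels[0].overlapping_flag
        assert set(labels[0].gene_ids_overlapped) == {"g1", "g2"}
        table = context_summary(labels)
        assert table["count"].sum() == 1
        assert table.attrs["n_overlapping"] == 1


class TestContextSummary:
    def test_percentages_half_up(self):
        assert percent(19_809, 39_574) == 50.06
        assert percent(1, 3) == 33.33

    def test_single_insertion_is_100_percent(self):
        labels = assign_genomic_context([mk_cons(3001)], _gene_fixture())
        table = context_summary(labels)
        assert table.loc[table.label == "intron", "pct"].iloc[0] == 100.00

    def test_counts_sum_and_pct_within_rounding(self, default_results):
        table = default_results["tables"]["genomic_context"]
        n_labels = table["count"].sum()
        assert n_labels > 0
        assert abs(table["pct"].sum() - 100.0) <= 0.05


class TestGeneLength:
    def test_all_genes_inserted_leaves_empty_complement(self):
        genes = _gene_fixture()
        labels = assign_genomic_context([mk_cons(3001), mk_cons(8001)], genes)
        strata = gene_length_strata(genes, labels)
        assert strata["n_inserted"] == 2
        assert len(strata["non_inserted_lengths"]) == 0
        assert strata["median_non_inserted"] is None
        assert strata["inserted_fraction_pct"] == 100.00


class TestCFS:
    def test_membership_half_open(self):
        cfs = {"chr1": [(100, 200)]}
        inside = cfs_overlap_summary([mk_cons(101), mk_cons(201)], cfs)
        # 1-based 101 is 0-based 100 (inside); 1-based 201 is 0-based 200,
        # the half-open end, hence outside
        assert inside["n_in_cfs"] == 1
        assert inside["n_cfs_hit"] == 1

    def test_no_intervals_flagged_undefined(self):
        out = cfs_overlap_summary([mk_cons(100)], {})
        assert not out["defined"]
        assert out["n_in_cfs"] == 0 and np.isnan(out["frac_in_cfs"])


class TestRecurrence:
    def _cohort(self):
        from retroscope.model import ClassifiedInsertion

        def rec(pid, pos, cls=PatientClass.GERMLINE):
            return ClassifiedInsertion(
                patient_id=pid, chrom="chr1", final_pos=pos,
                te_family=TEFamily.ALU, subfamily=None, tsd_sequence=None,
                patient_class=cls,
            )

        # g1 span 1000..5200: hit by P1 (x5), P2, P3; g2 by P1 only
        cohort = [rec("P1", 3000 + i) for i in range(5)]
        cohort += [rec("P2", 3001), rec("P3", 3002), rec("P1", 8001)]
        return cohort

    def test_threshold_and_per_patient_collapse(self):
        genes = _gene_fixture()
        table = recurrent_gene_report(self._cohort(), genes, min_patients=3)
        assert list(table["gene_id"]) == ["g1"]
        assert table.loc[0, "n_patients"] == 3  # P1's five insertions count once
        none = recurrent_gene_report(self._cohort()[:6], genes, min_patients=3)
        assert "g2" not in set(none["gene_id"])

    def test_gene_list_intersection_case_insensitive(self):
        genes = _gene_fixture()
        affected = gene_patient_table(self._cohort(), genes)
        out = gene_list_intersection(affected, ["G1", "tp53"])
        assert list(out["name"]) == ["g1"]
        assert out.loc[0, "matched_symbol"] == "G1"
        empty = gene_list_intersection(affected, [])
        assert empty.empty


class TestExonProximity:
    def test_inclusive_bound_and_distance_one(self):
        genes = _gene_fixture()
        # exon1 of g1 ends at 1200 (0-based); 0-based 1200 is 1 bp past it
        calls = [mk_cons(1201), mk_cons(1300), mk_cons(1301), mk_cons(3000)]
        labels = assign_genomic_context(calls, genes)
        out = exon_proximity(labels, genes, max_dist_bp=100)
        by_pos = dict(zip(out["pos"], out["distance_bp"]))
        assert by_pos[1201] == 1
        assert by_pos[1300] == 100  # exactly at the bound: included
        assert 1301 not in by_pos  # 101 bp: excluded
        assert 3000 not in by_pos
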