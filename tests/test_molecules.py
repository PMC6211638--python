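"""UMI collapse, allele-count aggregation, DNA proportions, testability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import allelic as al
from allelic.errors import FormatError
from allelic.molecules import count_reads, dedup_umi


def mol_table(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "orientation", "allele", "umi", "replicate", "fraction"],
    )


class TestDedup:
    def test_identical_umis_count_once(self):
        records = mol_table(
            [("s1", "forward", "ref", "AAA", 1, "RNA")] * 3
        )
        out = dedup_umi(records)
        assert out["ref_count"].tolist() == [1]

    def test_distinct_umi_set_size(self):
        records = mol_table(
            [
                ("s1", "forward", "ref", "AAA", 1, "RNA"),
                ("s1", "forward", "ref", "AAT", 1, "RNA"),
                ("s1", "forward", "ref", "AAA", 1, "RNA"),
            ]
        )
        assert dedup_umi(records)["ref_count"].tolist() == [2]

    def test_groups_do_not_share_umis(self):
        # same UMI in different replicates/alleles counts separately
        records = mol_table(
            [
                ("s1", "forward", "ref", "AAA", 1, "RNA"),
                ("s1", "forward", "alt", "AAA", 1, "RNA"),
                ("s1", "forward", "ref", "AAA", 2, "RNA"),
            ]
        )
        out = dedup_umi(records)
        assert out.set_index("replicate")["ref_count"].to_dict() == {1: 1, 2: 1}
        assert out.loc[out["replicate"] == 1, "alt_count"].tolist() == [1]

    def test_inconsistent_umi_lengths_rejected(self):
        records = mol_table(
            [
                ("s1", "forward", "ref", "AAA", 1, "RNA"),
                ("s1", "forward", "ref", "AAAA", 1, "RNA"),
            ]
        )
        with pytest.raises(FormatError, match="UMI length"):
            dedup_umi(records)

    def test_recovers_molecule_table_from_duplicated_reads(self):
        # seeded fixture with mu_dup = 2 and no UMI collisions: dedup must
        # reproduce the pre-duplication molecule counts exactly
        cfg = al.SimConfig(n_snps=200, mu_dup=2.0, n_rna_reps=2, seed=13)
        designs, truth = al.simulate_design(cfg)
        counts = al.simulate_rna_counts(designs, truth, cfg)
        mols = al.simulate_rna_molecules(designs, truth, cfg)
        dd = dedup_umi(mols)
        key = ["snp_id", "orientation", "replicate", "fraction"]
        merged = counts.merge(dd, on=key, how="left", suffixes=("", "_dedup")).fillna(0)
        assert (merged["ref_count"] == merged["ref_count_dedup"]).all()
        assert (merged["alt_count"] == merged["alt_count_dedup"]).all()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2"]),
                st.sampled_from(["forward", "reverse"]),
                st.sampled_from(["ref", "alt"]),
                st.text(alphabet="ACGT", min_size=3, max_size=3),
                st.integers(1, 2),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_idempotent_and_never_increasing(self, rows):
        records = mol_table([(*r, "RNA") for r in rows])
        dd = dedup_umi(records)
        raw = count_reads(records)
        key = ["snp_id", "orientation", "replicate", "fraction"]
        m = raw.merge(dd, on=key, suffixes=("_raw", "_dedup"))
        # dedup never increases counts
        assert (m["ref_count_dedup"] <= m["ref_count_raw"]).all()
        assert (m["alt_count_dedup"] <= m["alt_count_raw"]).all()
        # idempotence at the count level: each retained molecule has a
        # distinct UMI, so a second collapse over unique reads is a no-op
        unique_reads = records.drop_duplicates()
        pd.testing.assert_frame_equal(dedup_umi(unique_reads), dd)

    def test_equals_raw_counts_when_all_umis_distinct(self):
        from allelic.io import encode_umis

        umis = encode_umis(np.arange(20, dtype=np.uint64), umi_length=4)
        records = mol_table(
            [("s1", "forward", "ref", u, 1, "RNA") for u in umis]
        )
        assert dedup_umi(records)["ref_count"].sum() == 20
        assert count_reads(records)["ref_count"].sum() == 20


class TestBamAdapter:
    def test_reads_alleles_and_umis_from_alignments(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        from allelic.molecules import molecules_from_bam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        # SNP at 1-based position 101 (0-based 100), ref A / alt G
        reads = [  # coordinate-sorted for indexing
            ("r3_AAAA", 90, "A"),   # duplicate UMI of r1
            ("r1_AAAA", 95, "A"),   # ref allele
            ("r2_CCCC", 98, "G"),   # alt allele
            ("r4_GGGG", 99, "T"),   # matches neither allele -> skipped
        ]
        bam_path = tmp_path / "toy.bam"
        with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
            for name, start, base in reads:
                a = pysam.AlignedSegment()
                a.query_name = name
                offset = 100 - start
                a.query_sequence = "C" * offset + base + "C" * (19 - offset)
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "20M"
                a.mapping_quality = 60
                a.flag = 0
                bam.write(a)
        pysam.index(str(bam_path))

        snps = pd.DataFrame(
            {"snp_id": ["s1"], "chrom": ["chr1"], "pos": [101],
             "ref_allele": ["A"], "alt_allele": ["G"]}
        )
        mols = molecules_from_bam(str(bam_path), snps, replicate=1, fraction="RNA")
        assert len(mols) == 3  # mismatching base dropped
        counts = dedup_umi(mols)
        assert counts["ref_count"].tolist() == [1]  # r1/r3 share a UMI
        assert counts["alt_count"].tolist() == [1]


class TestDnaProportions:
    def test_symmetric_counts_give_half(self):
        dna = pd.DataFrame(
            {"snp_id": ["s1"], "ref_count": [50], "alt_count": [50]}
        )
        out = al.estimate_dna_proportions(dna)
        assert out["p0"].iloc[0] == pytest.approx(0.5)

    def test_zero_total_flagged_untestable(self):
        dna = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "ref_count": [0, 10], "alt_count": [0, 10]}
        )
        out = al.estimate_dna_proportions(dna).set_index("snp_id")
        assert not out.loc["s1", "testable"]
        assert np.isnan(out.loc["s1", "p0"])
        assert out.loc["s2", "testable"]

    def test_pseudocount_arithmetic(self):
        dna = pd.DataFrame({"snp_id": ["s1"], "ref_count": [99], "alt_count": [1]})
        out = al.estimate_dna_proportions(dna, pseudocount=0.5)
        assert out["p0"].iloc[0] == pytest.approx(99.5 / 101)
        p0 = 99.5 / 101
        assert out["var0"].iloc[0] == pytest.approx(p0 * (1 - p0) / 101)

    def test_pools_across_replicates(self):
        dna = pd.DataFrame(
            {
                "snp_id": ["s1", "s1", "s1"],
                "ref_count": [10, 20, 30],
                "alt_count": [30, 20, 10],
            }
        )
        out = al.estimate_dna_proportions(dna, pseudocount=0.5)
        assert out["d_total"].iloc[0] == 120
        assert out["p0"].iloc[0] == pytest.approx(60.5 / 121)


class TestFilterTestable:
    @pytest.fixture()
    def toy(self):
        counts = pd.DataFrame(
            {
                "snp_id": list("abcde"),
                "replicate": 1,
                "fraction": "RNA",
                "ref_count": [0, 2, 3, 6, 12],
                "alt_count": [0, 2, 2, 4, 8],
            }
        )
        dna = pd.DataFrame(
            {
                "snp_id": list("abcde"),
                "p0": 0.5,
                "var0": 0.001,
                "d_total": [100] * 5,
                "testable": True,
            }
        )
        return counts, dna

    def test_threshold_five_keeps_three(self, toy):
        counts, dna = toy
        kept, summary = al.filter_testable(counts, dna, min_rna_total=5, min_dna_total=0)
        assert summary["n_kept"] == 3
        assert set(kept["snp_id"]) == {"c", "d", "e"}

    def test_threshold_one_drops_only_zero_rna(self, toy):
        counts, dna = toy
        kept, summary = al.filter_testable(counts, dna, min_rna_total=1, min_dna_total=0)
        assert summary["dropped_low_rna"] == 1
        assert set(kept["snp_id"]) == {"b", "c", "d", "e"}

    def test_zero_thresholds_identity(self, toy):
        counts, dna = toy
        kept, summary = al.filter_testable(counts, dna, min_rna_total=0, min_dna_total=0)
        assert summary["n_kept"] == 5
        pd.testing.assert_frame_equal(kept, counts)

    def test_dna_filter_counts_reason(self, toy):
        counts, dna = toy
        dna.loc[dna["snp_id"] == "e", "d_total"] = 3
        kept, summary = al.filter_testable(counts, dna, min_rna_total=0, min_dna_total=10)
        assert summary["dropped_low_dna"] == 1
        assert "e" not in set(kept["snp_id"])
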