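import numpy as np
import pandas as pd
import pytest

from isomir_prognosis import annotation as ann
from isomir_prognosis import simulate
from isomir_prognosis.core import IsomiRKey, reverse_complement, to_rna

GFF_FIXTURE = """##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI0000001;Name=hsa-mir-t1
chr1\t.\tmiRNA\t105\t126\t.\t+\t.\tID=MIMAT0000001;Name=hsa-miR-t1-5p;Derives_from=MI0000001
chr1\t.\tmiRNA\t150\t171\t.\t+\t.\tID=MIMAT0000002;Name=hsa-miR-t1-3p;Derives_from=MI0000001
chr2\t.\tmiRNA_primary_transcript\t500\t580\t.\t-\t.\tID=MI0000002;Name=hsa-mir-t2
chr2\t.\tmiRNA\t520\t541\t.\t-\t.\tID=MIMAT0000003;Name=hsa-miR-t2-3p;Derives_from=MI0000002
"""


class TestParseGFF3:
    def test_three_mature_rows(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_FIXTURE)
        recs = ann.parse_gff3(p)
        assert len(recs) == 3
        assert [r.strand for r in recs] == ["+", "+", "-"]
        assert recs[0].accession == "MIMAT0000001"
        assert recs[0].hairpin_id == "MI0000001"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("")
        assert ann.parse_gff3(p) == []

    def test_malformed_column_count_reports_line(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tmiRNA\t1\t2\n")
        with pytest.raises(ann.GFF3ParseError, match=":1:"):
            ann.parse_gff3(p)

    def test_round_trip_with_generator(self, tmp_path, small_annotation):
        p = tmp_path / "sim.gff3"
        p.write_text(small_annotation.gff3_text())
        recs = ann.parse_gff3(p)
        assert {r.accession for r in recs} == {m.accession for m in small_annotation.matures}
        by_acc = {r.accession: r for r in recs}
        for m in small_annotation.matures:
            r = by_acc[m.accession]
            assert (r.chrom, r.start, r.end, r.strand) == (m.chrom, m.start, m.end, m.strand)


def _row(acc, chrom, start, end, strand, count=1, rpm=1.0):
    return ann.IsoformRow(acc, chrom, start, end, strand, count, rpm)


class TestComputeShift:
    def test_plus_strand_upstream_two(self):
        arch = ann.MatureRecord("MIMAT0000062", "m", "chr1", 100, 121, "+")
        assert ann.compute_shift(arch, _row("MIMAT0000062", "chr1", 98, 121, "+")) == -2

    def test_plus_strand_downstream_four(self):
        arch = ann.MatureRecord("MIMAT0000062", "m", "chr1", 100, 121, "+")
        assert ann.compute_shift(arch, _row("MIMAT0000062", "chr1", 104, 121, "+")) == 4

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_identity_zero(self, strand):
        arch = ann.MatureRecord("A", "m", "chr1", 100, 121, strand)
        assert ann.compute_shift(arch, _row("A", "chr1", 100, 121, strand)) == 0

    def test_minus_strand_end_shift(self):
        arch = ann.MatureRecord("A", "m", "chr1", 179, 200, "-")
        assert ann.compute_shift(arch, _row("A", "chr1", 175, 196, "-")) == 4

    def test_minus_strand_sequence_oracle(self, rng):
        # the 5' end of a minus-strand isomiR with shift +4 must sit 4 nt
        # inside the archetype 5' end in mature orientation
        chrom_seq = "".join(rng.choice(list("ACGT"), size=300))
        arch = ann.MatureRecord("A", "m", "chr1", 179, 200, "-")
        row = _row("A", "chr1", 175, 196, "-")
        shift = ann.compute_shift(arch, row)
        assert shift == 4
        arch_seq = reverse_complement(chrom_seq[arch.start - 1 : arch.end])
        row_seq = reverse_complement(chrom_seq[row.start - 1 : row.end])
        assert arch_seq[shift:] == row_seq[: len(arch_seq) - shift]

    def test_strand_mismatch_raises(self):
        arch = ann.MatureRecord("A", "m", "chr1", 100, 121, "+")
        with pytest.raises(ann.ShiftAssignmentError):
            ann.compute_shift(arch, _row("A", "chr1", 100, 121, "-"))

    def test_chrom_mismatch_raises(self):
        arch = ann.MatureRecord("A", "m", "chr1", 100, 121, "+")
        with pytest.raises(ann.ShiftAssignmentError):
            ann.compute_shift(arch, _row("A", "chr2", 100, 121, "+"))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_shift_reconstructs_five_prime(self, strand, rng):
        # self-inverse: applying the shift to the archetype 5' coordinate
        # reproduces the observed isoform 5' coordinate on both strands
        for _ in range(200):
            start = int(rng.integers(1000, 2000))
            end = start + 21
            arch = ann.MatureRecord("A", "m", "chr1", start, end, strand)
            k = int(rng.integers(-5, 6))
            if strand == "+":
                row = _row("A", "chr1", start + k, end + int(rng.integers(0, 3)), strand)
                observed_5p = row.start
                reconstructed = arch.start + ann.compute_shift(arch, row)
            else:
                row = _row("A", "chr1", start - int(rng.integers(0, 3)), end - k, strand)
                observed_5p = row.end
                reconstructed = arch.end - ann.compute_shift(arch, row)
            assert reconstructed == observed_5p


class TestBuildMatrix:
    ARCH = [ann.MatureRecord("A", "m", "chr1", 100, 121, "+")]

    def test_same_key_counts_sum(self):
        rows = {"s1": [_row("A", "chr1", 100, 121, "+", 5, 10.0),
                       _row("A", "chr1", 100, 123, "+", 7, 14.0)]}
        m = ann.build_matrix(rows, self.ARCH)
        assert m.counts.loc["A|0", "s1"] == 12
        assert m.rpm.loc["A|0", "s1"] == pytest.approx(24.0)

    def test_mass_conservation(self, rng):
        rows = {
            f"s{i}": [
                _row("A", "chr1", 100 + int(rng.integers(-2, 3)), 121, "+",
                     int(rng.integers(1, 50)), 1.0)
                for _ in range(10)
            ]
            for i in range(4)
        }
        total_in = sum(r.read_count for rs in rows.values() for r in rs)
        m = ann.build_matrix(rows, self.ARCH)
        assert m.counts.to_numpy().sum() == total_in

    def test_unknown_accession_skipped_and_reported(self):
        rows = {"s1": [_row("ZZZ", "chr1", 100, 121, "+", 5, 1.0)]}
        m = ann.build_matrix(rows, self.ARCH)
        assert m.counts.empty
        assert len(m.skip_report) == 1
        assert m.skip_report.iloc[0]["reason"] == "unknown_accession"

    def test_cross_mapped_row_dropped(self):
        rows = {"s1": [_row("A", "chr9", 100, 121, "+", 5, 1.0)]}
        m = ann.build_matrix(rows, self.ARCH)
        assert len(m.skip_report) == 1
        assert m.skip_report.iloc[0]["reason"] == "locus_mismatch"

    def test_round_trip_recovers_planted_keys(self, small_sim, small_annotation, tmp_path):
        tables = {}
        for sample, df in small_sim.tables.items():
            p = tmp_path / f"{sample}.txt"
            df.to_csv(p, sep="\t", index=False)
            tables[sample] = ann.read_isoform_table(p)
        m = ann.build_matrix(tables, small_annotation.matures)
        planted = {
            ann.IsomiRKey(acc, s).label
            for acc, shifts in small_sim.truth.planted_shifts.items()
            for s in shifts
        }
        recovered = set(m.counts.index)
        assert recovered <= planted
        # every planted key with at least one nonzero simulated count is found
        expressed = set(small_sim.counts.index[(small_sim.counts > 0).any(axis=1)])
        assert recovered == expressed

    def test_rpm_columns_sum_to_million(self, small_sim, small_annotation, tmp_path):
        tables = {}
        for sample, df in list(small_sim.tables.items())[:3]:
            p = tmp_path / f"{sample}.txt"
            df.to_csv(p, sep="\t", index=False)
            tables[sample] = ann.read_isoform_table(p)
        m = ann.build_matrix(tables, small_annotation.matures)
        assert np.allclose(m.rpm.sum(axis=0), 1e6, rtol=1e-4)


class TestIsomirSequence:
    @pytest.fixture()
    def setup(self, rng):
        chrom = "".join(rng.choice(list("ACGT"), size=400))
        arch_plus = ann.MatureRecord("P", "p", "chr1", 101, 122, "+")
        arch_minus = ann.MatureRecord("M", "m", "chr1", 201, 222, "-")
        return {"chr1": chrom}, arch_plus, arch_minus

    def test_shift_zero_is_archetype(self, setup):
        seqs, arch, _ = setup
        out = ann.isomir_sequence(IsomiRKey("P", 0), [arch], seqs, {"P|0": arch.end})
        assert out == to_rna(seqs["chr1"][arch.start - 1 : arch.end])

    def test_shift_plus_two_drops_two_nt(self, setup):
        seqs, arch, _ = setup
        full = ann.isomir_sequence(IsomiRKey("P", 0), [arch], seqs, {"P|0": arch.end})
        shifted = ann.isomir_sequence(IsomiRKey("P", 2), [arch], seqs, {"P|2": arch.end})
        assert shifted == full[2:]

    def test_minus_strand_reverse_complement_oracle(self, setup):
        seqs, _, arch = setup
        out = ann.isomir_sequence(IsomiRKey("M", 0), [arch], seqs, {"M|0": arch.start})
        assert out == reverse_complement(seqs["chr1"][arch.start - 1 : arch.end])

    def test_unobserved_key_raises(self, setup):
        seqs, arch, _ = setup
        with pytest.raises(KeyError):
            ann.isomir_sequence(IsomiRKey("P", 1), [arch], seqs, {})

    def test_seed_invariant_for_archetype(self, small_annotation):
        # seed of the shift-0 sequence equals the archetype seed
        seqs = small_annotation.sequences
        for m in small_annotation.matures[:4]:
            s0 = ann.isomir_sequence(
                IsomiRKey(m.accession, 0), [m], seqs,
                {f"{m.accession}|0": m.end if m.strand == "+" else m.start},
            )
            arch_seq = (
                to_rna(seqs[m.chrom][m.start - 1 : m.end])
                if m.strand == "+"
                else reverse_complement(seqs[m.chrom][m.start - 1 : m.end])
            )
            assert ann.seed_of(s0) == ann.seed_of(arch_seq)


class TestSeedOf:
    def test_definition(self):
        assert ann.seed_of("UAGCUUAUCAGACUGAUGUUGA") == "AGCUUAU"

    def test_shifted_seed_moves(self):
        seq = "UAGCUUAUCAGACUGAUGUUGA"
        assert ann.seed_of(seq[1:]) == seq[2:9]

    def test_slice_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=22))
        assert ann.seed_of(seq) == seq[1:8]

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            ann.seed_of("ACGUACG")


class TestParseRegion:
    def test_with_assembly(self):
        assert ann.parse_region("hg38:chr1:100-121:+") == ("chr1", 100, 121, "+")

    def test_without_assembly(self):
        assert ann.parse_region("chr2:5-9:-") == ("chr2", 5, 9, "-")

    def test_malformed(self):
        with pytest.raises(ValueError):
            ann.parse_region("chr2:5..9")


class TestFilterSamples:
    @staticmethod
    def manifest(rows):
        return pd.DataFrame(rows, columns=["file_id", "participant", "sample_type", "has_annotation"])

    def test_annotation_rule(self):
        rows = [(f"f{i}", f"p{i}", "Primary Tumor", i < 2) for i in range(10)]
        kept, report = ann.filter_samples(self.manifest(rows))
        assert len(kept) == 8
        assert report["annotation"] == 2

    def test_duplicate_participant_keeps_first(self):
        rows = [("f3", "TCGA-44-6775", "Primary Tumor", False),
                ("f1", "TCGA-44-6775", "Primary Tumor", False),
                ("f2", "TCGA-44-6775", "Primary Tumor", False)]
        kept, report = ann.filter_samples(self.manifest(rows))
        assert len(kept) == 1
        assert kept.iloc[0]["file_id"] == "f1"
        assert report["duplicate_participant"] == 2

    def test_recurrent_dropped(self):
        rows = [("f1", "p1", "Primary Tumor", False),
                ("f2", "p2", "Recurrent Solid Tumor", False)]
        kept, report = ann.filter_samples(self.manifest(rows))
        assert list(kept["participant"]) == ["p1"]
        assert report["recurrent_tumor"] == 1

    def test_no_exclusions_identity(self):
        rows = [(f"f{i}", f"p{i}", "Primary Tumor", False) for i in range(5)]
        m = self.manifest(rows)
        kept, report = ann.filter_samples(m)
        pd.testing.assert_frame_equal(kept, m)
        assert sum(report.values()) == 0
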