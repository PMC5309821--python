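import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhins.core_io import (
    CatalogueEntry,
    FormatError,
    GenomeSequence,
    Loop,
    Peak,
    Read,
    VariantKey,
    left_normalize,
    read_bed,
    read_bedpe,
    read_catalogue,
    read_fasta,
    read_fastq,
    read_key_file,
    read_vcf_insertion_keys,
    write_bed,
    write_bedpe,
    write_catalogue,
    write_fastq,
    write_key_file,
    write_vcf,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        genome = read_fasta(p)
        assert genome.lengths == {"chr1": 4}
        assert genome["chr1"] == "ACGT"

    def test_lowercase_folded(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgt\n")
        assert read_fasta(p)["chr1"] == "ACGT"

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_multiline_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\nACGT\n")
        assert read_fasta(p)["chr1"] == "ACGTACGT"

    def test_bad_alphabet(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACXT\n")
        with pytest.raises(FormatError):
            read_fasta(p)


class TestReadFastq:
    def _write(self, path, records):
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def test_count_conserved(self, tmp_path):
        p = tmp_path / "r.fq"
        self._write(p, [(f"r{i}", "ACGT" * 10) for i in range(3)])
        assert len(list(read_fastq(p))) == 3

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("")
        assert list(read_fastq(p)) == []

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\n" + "ACGT" * 10 + "\n+\nIII\n")
        with pytest.raises(FormatError):
            list(read_fastq(p))

    def test_truncated_record_rejected(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\n" + "ACGT" * 10 + "\n")
        with pytest.raises(FormatError):
            list(read_fastq(p))

    def test_round_trip(self, tmp_path):
        reads = [Read(f"r{i}", "ACGTACGTACGTACGTACGTA") for i in range(5)]
        p = tmp_path / "r.fq"
        write_fastq(reads, p)
        assert list(read_fastq(p)) == reads


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


class TestBed:
    def test_format_semantics(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t200\n")
        assert read_bed(p) == [Peak("chr1", 100, 200)]

    def test_round_trip(self, tmp_path):
        peaks = [Peak("chr1", 0, 10), Peak("chr2", 5, 500)]
        p = tmp_path / "p.bed"
        write_bed(peaks, p)
        assert read_bed(p) == peaks

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t-5\t200\n")
        with pytest.raises(FormatError):
            read_bed(p)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t300\t200\n")
        with pytest.raises(FormatError):
            read_bed(p)


class TestBedpe:
    def test_format_semantics(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t100\t200\tchr1\t900\t1000\t0.15\t1,1\n")
        [loop] = read_bedpe(p)
        assert loop.fdr == 0.15
        assert loop.ctcf_both
        assert loop.span == (100, 1000)

    def test_round_trip(self, tmp_path):
        loops = [
            Loop("chr1", (0, 50), (900, 1000), 0.05, True, True),
            Loop("chr2", (10, 20), (30, 40), 0.5, False, True),
        ]
        p = tmp_path / "l.bedpe"
        write_bedpe(loops, p)
        assert read_bedpe(p) == loops

    def test_overlapping_anchors_rejected(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t100\t300\tchr1\t200\t400\t0.1\t1,1\n")
        with pytest.raises(FormatError):
            read_bedpe(p)

    def test_single_anchor_ctcf_not_both(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t100\t200\tchr1\t900\t1000\t0.1\t1,0\n")
        [loop] = read_bedpe(p)
        assert not loop.ctcf_both


# ---------------------------------------------------------------------------
# catalogue + keys + VCF
# ---------------------------------------------------------------------------


def _entries():
    return [
        CatalogueEntry(VariantKey("chr1", 10, "A"), {"s1"}, 3, {"read"}, set()),
        CatalogueEntry(VariantKey("chr1", 10, "AG"), {"s1", "s2"}, 2, {"read", "contig"}, {"dbsnp"}),
        CatalogueEntry(VariantKey("chr1", 99, "TTT"), {"s3"}, 1, {"contig"}, {"dbsnp", "recurrent"}),
        CatalogueEntry(VariantKey("chr2", 5, "C"), {"s1", "s2", "s3"}, 9, {"read"}, {"recurrent"}),
        CatalogueEntry(VariantKey("chr2", 500, "GATTACA"), {"s2"}, 4, {"read"}, set()),
    ]


class TestCatalogue:
    def test_round_trip_identity(self, tmp_path):
        p = tmp_path / "cat.tsv"
        entries = _entries()
        write_catalogue(entries, p)
        assert read_catalogue(p) == sorted(entries, key=lambda e: e.key)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("wrong\theader\n")
        with pytest.raises(FormatError):
            read_catalogue(p)

    def test_key_file_round_trip(self, tmp_path):
        keys = {e.key for e in _entries()}
        p = tmp_path / "keys.tsv"
        write_key_file(keys, p)
        assert read_key_file(p) == keys


class TestVcf:
    def test_export_and_reimport(self, tmp_path, genome2k):
        entries = [
            CatalogueEntry(VariantKey("chr1", 50, "TT"), {"s1"}, 1),
            CatalogueEntry(VariantKey("chr1", 500, "ACG"), {"s1"}, 2),
        ]
        # use keys already left-normalized w.r.t. the genome
        from enhins.core_io import left_normalize

        normed = []
        for e in entries:
            pos, seq = left_normalize(genome2k["chr1"], e.key.position, e.key.sequence)
            normed.append(CatalogueEntry(VariantKey("chr1", pos, seq), e.samples, e.support))
        p = tmp_path / "out.vcf"
        write_vcf(normed, genome2k, p)
        keys = read_vcf_insertion_keys(p, genome2k)
        assert keys == {e.key for e in normed}


# ---------------------------------------------------------------------------
# domain-type invariants
# ---------------------------------------------------------------------------


class TestVariantKey:
    def test_serialize(self):
        assert VariantKey("chr1", 500, "AC").serialize() == "chr1:500:AC"

    def test_parse_round_trip(self):
        key = VariantKey("chr10", 1234, "GATTACA")
        assert VariantKey.parse(key.serialize()) == key

    def test_size_bounds(self):
        with pytest.raises(ValueError):
            VariantKey("chr1", 0, "")
        with pytest.raises(ValueError):
            VariantKey("chr1", 0, "A" * 32)
        VariantKey("chr1", 0, "A" * 31)  # boundary OK

    @given(
        chrom=st.sampled_from(["chr1", "chr2", "chrX"]),
        pos=st.integers(min_value=0, max_value=10**9),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=31),
        chrom2=st.sampled_from(["chr1", "chr2", "chrX"]),
        pos2=st.integers(min_value=0, max_value=10**9),
        seq2=st.text(alphabet="ACGT", min_size=1, max_size=31),
    )
    @settings(max_examples=200, deadline=None)
    def test_equality_is_serialized_string_equality(self, chrom, pos, seq, chrom2, pos2, seq2):
        a, b = VariantKey(chrom, pos, seq), VariantKey(chrom2, pos2, seq2)
        assert (a == b) == (a.serialize() == b.serialize())


class TestLeftNormalize:
    def test_homopolymer_run(self):
        #           0123456
        ref = "GCAAAATC"
        anchor, seq = left_normalize(ref, 5, "A")  # insert A after the run
        assert (anchor, seq) == (1, "A")  # shifted before the first A (after C at 1)

    def test_no_shift_when_context_differs(self):
        ref = "GCATGCAT"
        assert left_normalize(ref, 3, "C") == (3, "C")

    def test_dinucleotide_rotation(self):
        ref = "TTACACACGG"
        anchor, seq = left_normalize(ref, 7, "AC")
        assert (anchor, seq) == (1, "AC")

    def test_equivalent_haplotypes(self):
        ref = "GGGTTTAAACCC"
        for anchor in range(3, 9):
            a, s = left_normalize(ref, anchor, ref[anchor])
            hap_orig = ref[: anchor + 1] + ref[anchor] + ref[anchor + 1:]
            hap_norm = ref[: a + 1] + s + ref[a + 1:]
            assert hap_orig == hap_norm

    @given(
        data=st.data(),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization_preserves_haplotype(self, data, seq):
        import numpy as np

        rng = np.random.default_rng(data.draw(st.integers(0, 2**31)))
        ref = "".join(rng.choice(list("ACGT"), size=50))
        anchor = data.draw(st.integers(min_value=0, max_value=49))
        a, s = left_normalize(ref, anchor, seq)
        assert ref[: anchor + 1] + seq + ref[anchor + 1:] == ref[: a + 1] + s + ref[a + 1:]


class TestDomainInvariants:
    def test_read_too_short(self):
        with pytest.raises(ValueError):
            Read("r", "ACGT")

    def test_genome_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            GenomeSequence({"chr1": "ACGU"})

    def test_genome_rejects_empty_sequence(self):
        with pytest.raises(ValueError):
            GenomeSequence({"chr1": ""})

    def test_peak_half_open_membership(self):
        peak = Peak("chr1", 100, 200)
        assert ("chr1", 100) in peak
        assert ("chr1", 199) in peak
        assert ("chr1", 200) not in peak

    def test_entry_requires_samples(self):
        with pytest.raises(ValueError):
            CatalogueEntry(VariantKey("chr1", 1, "A"), set(), 1)

    def test_loop_fdr_range(self):
        with pytest.raises(ValueError):
            Loop("chr1", (0, 10), (20, 30), 1.5, True, True)
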