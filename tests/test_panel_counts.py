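"""k-mer construction, alignment-free counting, and ALT-ratio profiles."""

import numpy as np
import pytest

from ddcfdna import (
    AlleleCountTable,
    SnpLocus,
    SnpPanel,
    alt_ratio_profile,
    build_allele_kmers,
    count_alleles,
    reverse_complement,
    simulate_fastq,
)
from ddcfdna.panel import FastqError, PanelError


def _locus(snp_id, context, alt, **kw):
    center = len(context) // 2
    return SnpLocus(id=snp_id, chrom="chr1", pos=100, ref=context[center],
                    alt=alt, context=context, **kw)


class TestBuildAlleleKmers:
    def test_center_substitution(self):
        panel = SnpPanel([_locus("s1", "AACTGAC", "G")], k=7)
        (pair,) = build_allele_kmers(panel, k=7).pairs
        assert pair.ref_kmer == "AACTGAC"
        assert pair.alt_kmer == "AACGGAC"

    def test_shared_window_collides(self):
        ctx = "ACGTACGTACGTACGTACGTACGTACGTACG"  # 31 bp
        panel = SnpPanel([_locus("s1", ctx, "A"), _locus("s2", ctx, "C")], k=31)
        result = build_allele_kmers(panel)
        assert [p.snp_id for p in result.pairs] == ["s1"]
        assert "s2" in result.excluded and "collision" in result.excluded["s2"]

    def test_random_panel_pairs_hamming_one(self, small_panel, small_kmers):
        assert len(small_kmers.pairs) == len(small_panel)
        for pair in small_kmers:
            dist = sum(a != b for a, b in zip(pair.ref_kmer, pair.alt_kmer))
            assert dist == 1
            assert len(pair.ref_kmer) == small_panel.k

    def test_context_too_short(self):
        panel = SnpPanel([_locus("s1", "ACTGA", "C")], k=31)
        result = build_allele_kmers(panel)
        assert not result.pairs
        assert "too short" in result.excluded["s1"]

    def test_non_acgt_context_excluded(self):
        panel = SnpPanel([_locus("s1", "ACNTGAC", "C")], k=7)
        result = build_allele_kmers(panel, k=7)
        assert "non-ACGT" in result.excluded["s1"]

    def test_even_k_rejected(self, small_panel):
        with pytest.raises(PanelError, match="odd"):
            build_allele_kmers(small_panel, k=30)


class TestPanelInvariants:
    def test_duplicate_ids_rejected(self):
        loci = [_locus("s1", "AACTGAC", "G"), _locus("s1", "CCCTGGG", "A")]
        with pytest.raises(PanelError, match="duplicate"):
            SnpPanel(loci)

    def test_ref_must_match_context(self):
        with pytest.raises(PanelError, match="does not match ref"):
            SnpLocus(id="s1", chrom="chr1", pos=1, ref="G", alt="A", context="AACTGAC")

    def test_identical_alleles_rejected(self):
        with pytest.raises(PanelError):
            _locus("s1", "AACTGAC", "T")


class TestCountAlleles:
    def test_planted_kmers(self, small_kmers):
        pair = small_kmers.pairs[0]
        reads = ["CC" + pair.ref_kmer + "TT"] * 90 + ["GG" + pair.alt_kmer + "AA"] * 10
        table = count_alleles(reads, small_kmers)
        assert table.rows[pair.snp_id] == (90, 10)
        assert all(table.rows[p.snp_id] == (0, 0) for p in small_kmers.pairs[1:])

    def test_reverse_complement_counts_as_ref(self, small_kmers):
        pair = small_kmers.pairs[0]
        table = count_alleles([reverse_complement("AA" + pair.ref_kmer + "GG")], small_kmers)
        assert table.rows[pair.snp_id] == (1, 0)

    def test_reverse_complement_matching_can_be_disabled(self, small_kmers):
        pair = small_kmers.pairs[0]
        rc_read = reverse_complement("AA" + pair.ref_kmer + "GG")
        table = count_alleles([rc_read], small_kmers, match_reverse_complement=False)
        assert table.rows[pair.snp_id] == (0, 0)

    def test_chimeric_read_is_ambiguous(self, small_kmers):
        pair = small_kmers.pairs[0]
        table = count_alleles([pair.ref_kmer + pair.alt_kmer], small_kmers)
        assert table.rows[pair.snp_id] == (0, 0)
        assert table.ambiguous == 1

    def test_strand_invariance(self, small_kmers, rng):
        source = AlleleCountTable(
            "s", {p.snp_id: (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                  for p in small_kmers.pairs}
        )
        reads = [seq for _, seq, _ in simulate_fastq(source, small_kmers.pairs, seed=rng)]
        fwd = count_alleles(reads, small_kmers)
        rev = count_alleles([reverse_complement(r) for r in reads], small_kmers)
        assert fwd.rows == rev.rows

    def test_count_conservation_under_concatenation(self, small_kmers, rng):
        t1 = AlleleCountTable("a", {p.snp_id: (3, 1) for p in small_kmers.pairs})
        t2 = AlleleCountTable("b", {p.snp_id: (0, 2) for p in small_kmers.pairs})
        r1 = [s for _, s, _ in simulate_fastq(t1, small_kmers.pairs, seed=1)]
        r2 = [s for _, s, _ in simulate_fastq(t2, small_kmers.pairs, seed=2)]
        separate = count_alleles(r1, small_kmers) + count_alleles(r2, small_kmers)
        together = count_alleles(r1 + r2, small_kmers)
        assert separate.rows == together.rows

    def test_fastq_roundtrip_exact(self, small_kmers, rng, tmp_path):
        source = AlleleCountTable(
            "s", {p.snp_id: (int(rng.integers(0, 50)), int(rng.integers(0, 50)))
                  for p in small_kmers.pairs}
        )
        from ddcfdna import write_fastq

        path = tmp_path / "reads.fastq"
        write_fastq(simulate_fastq(source, small_kmers.pairs, seed=9), path)
        recovered = count_alleles(path, small_kmers)
        assert recovered.rows == source.rows

    def test_empty_stream_gives_zero_table(self, small_kmers):
        table = count_alleles([], small_kmers)
        assert table.total_reads() == 0
        assert set(table.rows) == {p.snp_id for p in small_kmers.pairs}

    def test_malformed_fastq_reports_record(self, small_kmers, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\nnot_a_header\nACGT\n+\nIIII\n")
        with pytest.raises(FastqError, match="record index 1"):
            count_alleles(path, small_kmers)


class TestAltRatioProfile:
    @pytest.mark.parametrize(
        "ref,alt,min_depth,expected_ratio,expected_depth",
        [
            (90, 10, 1, 0.1, 100),
            (0, 0, 1, None, 0),
            (0, 57, 1, 1.0, 57),
            (3, 1, 10, None, 4),
        ],
    )
    def test_ratio_and_depth(self, ref, alt, min_depth, expected_ratio, expected_depth):
        table = AlleleCountTable("s", {"snp": (ref, alt)})
        profile = alt_ratio_profile(table, min_depth=min_depth)
        ratio, depth = profile.rows["snp"]
        assert depth == expected_depth
        if expected_ratio is None:
            assert ratio is None
        else:
            assert ratio == pytest.approx(expected_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AlleleCountTable("s", {"snp": (10, -1)})
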