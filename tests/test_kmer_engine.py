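import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uniqmap import (
    Genome,
    merge_k_range,
    oracle_unique_start_mask,
    read_mask,
    read_merged,
    reverse_complement,
    unique_start_mask,
    write_mask,
    write_merged,
)
from uniqmap.kmer_engine import MaskError, UniquenessMask

from conftest import assert_masks_equal, random_genome_factory


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"),
        ("AACG", "CGTT"),
        ("AN", "NT"),
        ("", ""),
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_rejects_other_characters(self):
        with pytest.raises(MaskError):
            reverse_complement("ACGU")

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGTN", max_size=100))
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s


class TestUniqueStartMask:
    @pytest.mark.parametrize("seq,k,expected", [
        # AAA and AAC occur once forward, revcomps TTT/GTT never
        ("AAAC", 3, [1, 1, 0, 0]),
        # ACGT is its own reverse complement: hits = 2, never unique
        ("ACGT", 4, [0, 0, 0, 0]),
        # AACG repeats at starts 0 and 4; the three interior 4-mers unique
        ("AACGAACG", 4, [0, 1, 1, 1, 0, 0, 0, 0]),
    ])
    def test_known_masks(self, seq, k, expected):
        g = Genome.from_dict({"c": seq})
        mask = unique_start_mask(g, k)
        np.testing.assert_array_equal(mask.chroms["c"], expected)
        assert_masks_equal(mask, oracle_unique_start_mask(g, k))

    def test_cross_chromosome_hits(self):
        # "TTGCA" present on chr1 and chr2: no unique start may use it
        g = Genome.from_dict({"chr1": "ATTGCAG", "chr2": "CTTGCAT"})
        mask = unique_start_mask(g, 5)
        assert_masks_equal(mask, oracle_unique_start_mask(g, 5))
        assert mask.chroms["chr1"][1] == 0  # TTGCA shared across chroms

    def test_n_kmers_never_unique(self):
        g = Genome.from_dict({"c": "ACGTNACGTT"})
        mask = unique_start_mask(g, 3)
        # any start whose 3-mer covers the N at index 4 stays 0
        assert mask.chroms["c"][2] == 0
        assert mask.chroms["c"][3] == 0
        assert mask.chroms["c"][4] == 0
        assert_masks_equal(mask, oracle_unique_start_mask(g, 3))

    def test_k_exceeding_all_chromosomes_warns_all_zero(self):
        g = Genome.from_dict({"c": "ACGTT"})
        with pytest.warns(UserWarning):
            mask = unique_start_mask(g, 10)
        assert mask.chroms["c"].sum() == 0
        assert len(mask.chroms["c"]) == 5

    def test_tail_positions_structurally_zero(self):
        g = Genome.from_dict({"c": "ACGGTTCAAG"})
        mask = unique_start_mask(g, 4)
        assert mask.chroms["c"][-3:].sum() == 0

    @pytest.mark.parametrize("k", [3, 12, 33, 40, 64, 65])
    def test_oracle_equivalence_across_chunk_boundaries(self, k):
        """Engine equals brute force for k below/at/above uint64 packing."""
        g = random_genome_factory(seed=100 + k, length=800, n_chrom=2)
        assert_masks_equal(unique_start_mask(g, k),
                           oracle_unique_start_mask(g, k))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seqs=st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=120),
                      min_size=1, max_size=3),
        k=st.integers(min_value=1, max_value=12),
    )
    def test_oracle_equivalence_property(self, seqs, k):
        g = Genome(tuple((f"c{i}", s) for i, s in enumerate(seqs)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert_masks_equal(unique_start_mask(g, k),
                               oracle_unique_start_mask(g, k))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotonicity_in_k(self, seed):
        """A superstring of a unique exact match is itself unique."""
        g = random_genome_factory(seed=seed, length=600, n_chrom=1)
        small = unique_start_mask(g, 8)
        for k2 in (9, 14):
            big = unique_start_mask(g, k2)
            L = len(g["chr1"])
            for name in small.chroms:
                s, b = small.chroms[name], big.chroms[name]
                in_bounds = np.arange(L) + k2 <= L
                assert np.all(b[(s == 1) & in_bounds] == 1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the genome mirrors the mask: i -> L-k-i."""
        k = 10
        g = random_genome_factory(seed=seed, length=500, n_chrom=1)
        rc = Genome(tuple(
            (n, reverse_complement(s)) for n, s in g.items()
        ))
        fwd = unique_start_mask(g, k)
        rev = unique_start_mask(rc, k)
        for name in fwd.chroms:
            L = len(g[name])
            f = fwd.chroms[name][: L - k + 1]
            r = rev.chroms[name][: L - k + 1]
            np.testing.assert_array_equal(f, r[::-1])


class TestMergeKRange:
    def _mask(self, k, vec, mode="unmodified"):
        return UniquenessMask(k=k, mode=mode,
                              chroms={"c": np.asarray(vec, dtype=np.uint8)})

    def test_smallest_k_wins(self):
        m24 = self._mask(24, [1, 0, 0, 1] + [0] * 46)
        m36 = self._mask(36, [1, 1, 0, 0] + [0] * 46)
        merged = merge_k_range([m24, m36])
        assert merged.k_range == (24, 36)
        assert merged.chroms["c"][0] == 24   # unique at both: smallest wins
        assert merged.chroms["c"][1] == 36   # only at 36
        assert merged.chroms["c"][2] == 0    # never unique
        assert merged.chroms["c"][3] == 24

    def test_all_zero(self):
        merged = merge_k_range([self._mask(5, [0] * 10),
                                self._mask(8, [0] * 10)])
        assert merged.chroms["c"].sum() == 0

    def test_merged_consistency_on_real_masks(self):
        g = random_genome_factory(seed=3, length=900, n_chrom=1)
        ks = [6, 9, 14]
        masks = {k: unique_start_mask(g, k) for k in ks}
        merged = merge_k_range(list(masks.values()))
        vec = merged.chroms["chr1"]
        for i, v in enumerate(vec):
            if v == 0:
                assert all(masks[k].chroms["chr1"][i] == 0 for k in ks)
            else:
                assert masks[v].chroms["chr1"][i] == 1
                assert all(masks[k].chroms["chr1"][i] == 0
                           for k in ks if k < v)

    def test_mixed_modes_and_frames_rejected(self):
        with pytest.raises(MaskError):
            merge_k_range([self._mask(4, [0] * 6),
                           self._mask(5, [0] * 6, mode="bisulfite_plus")])
        with pytest.raises(MaskError):
            merge_k_range([self._mask(4, [0] * 6), self._mask(5, [0] * 7)])
        with pytest.raises(MaskError):
            merge_k_range([])


class TestContainers:
    def test_mask_round_trip(self, tmp_path):
        g = random_genome_factory(seed=11, length=400, n_chrom=2)
        mask = unique_start_mask(g, 7)
        path = tmp_path / "m.mask"
        write_mask(mask, path)
        back = read_mask(path)
        assert back.mode == mask.mode
        assert_masks_equal(mask, back)

    def test_merged_round_trip(self, tmp_path):
        g = random_genome_factory(seed=12, length=300, n_chrom=1)
        merged = merge_k_range([unique_start_mask(g, k) for k in (5, 9)])
        path = tmp_path / "m.merged"
        write_merged(merged, path)
        back = read_merged(path)
        assert back.k_range == merged.k_range
        for name in merged.chroms:
            np.testing.assert_array_equal(back.chroms[name],
                                          merged.chroms[name])

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "junk.mask"
        p.write_bytes(b"NOTMAGIC" + b"\x00" * 16)
        with pytest.raises(MaskError):
            read_mask(p)
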