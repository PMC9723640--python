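"""Length/library filtering, translation, AAV and OTU construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bficomm.sequence_units import (
    FilterConfig,
    InternalStopError,
    TranslationError,
    build_aav_matrix,
    cluster_otus,
    filter_by_length,
    filter_by_library_size,
    pairwise_identity,
    translate,
)

from .conftest import make_sequence_set

# codons grouped for property tests
_SYN_CODONS = {"L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
               "P": ["CCT", "CCC", "CCA", "CCG"],
               "K": ["AAA", "AAG"]}


class TestFilters:
    def test_hzo_length_window(self):
        # hzo reads must satisfy 160 <= length <= 190
        seqs = make_sequence_set(
            [("s1", f"r{n}", "A" * n) for n in (150, 170, 200)]
        )
        out = filter_by_length(seqs, FilterConfig(min_len=160, max_len=190))
        assert list(out.records["nt"].str.len()) == [170]

    def test_no_bounds_is_identity(self):
        seqs = make_sequence_set([("s1", "r1", "ACGT"), ("s2", "r2", "AC")])
        out = filter_by_length(seqs, FilterConfig())
        assert len(out) == 2

    def test_archaeal_amoa_minimum_is_inclusive(self):
        seqs = make_sequence_set(
            [("s1", "short", "A" * 279), ("s1", "ok", "A" * 280)]
        )
        out = filter_by_length(seqs, FilterConfig(min_len=280))
        assert list(out.records["seq_id"]) == ["ok"]

    def test_library_filter_is_strictly_fewer_than(self):
        # 1,700 reads < 1,800 threshold drops the sample; exactly 1,800 stays
        records = [("low", f"r{i}", "ACG") for i in range(1700)]
        records += [("exact", f"r{i}", "ACG") for i in range(1800)]
        seqs = make_sequence_set(records)
        out = filter_by_library_size(seqs, FilterConfig(min_library=1800))
        assert out.samples == ["exact"]

    def test_threshold_zero_is_identity(self):
        seqs = make_sequence_set([("s1", "r1", "ACG")])
        out = filter_by_library_size(seqs, FilterConfig(min_library=0))
        assert len(out) == 1

    def test_removing_every_sample_raises(self):
        seqs = make_sequence_set([("s1", "r1", "ACG")])
        with pytest.raises(ValueError, match="every sample"):
            filter_by_library_size(seqs, FilterConfig(min_library=5))

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_len=100, max_len=50)


class TestTranslate:
    def test_standard_code(self):
        assert translate("ATGAAA") == "MK"

    def test_terminal_stop_stripped(self):
        assert translate("ATGAAATAA") == "MK"

    def test_internal_stop_raises(self):
        with pytest.raises(InternalStopError):
            translate("ATGTAAAAA")

    @pytest.mark.parametrize("bad", ["ATGAA", "ATGNAA"])
    def test_bad_frame_or_alphabet(self, bad):
        with pytest.raises(TranslationError):
            translate(bad)


class TestAavMatrix:
    def test_synonymous_sequences_collapse(self):
        # CTT and CTC both encode leucine
        seqs = make_sequence_set(
            [("s1", "r1", "ATGCTT"), ("s1", "r2", "ATGCTC")]
        )
        clusters, m = build_aav_matrix(seqs)
        assert len(clusters) == 1
        assert clusters[0].member_nt == {"ATGCTT", "ATGCTC"}
        assert m.loc[clusters[0].aav_id, "s1"] == 2

    def test_nonsynonymous_sequences_split(self):
        seqs = make_sequence_set(
            [("s1", "r1", "ATGCTT"), ("s1", "r2", "ATGAAA")]
        )
        clusters, _ = build_aav_matrix(seqs)
        assert sorted(c.protein for c in clusters) == ["MK", "ML"]

    def test_counts_conserved_and_stop_records_excluded(self):
        seqs = make_sequence_set(
            [("s1", "r1", "ATGCTT"), ("s2", "r1", "ATGCTT"),
             ("s2", "r2", "ATGAAA"), ("s2", "r3", "TAAAAA")]
        )
        _, m = build_aav_matrix(seqs)
        assert m.to_numpy().sum() == 3  # internal-stop record dropped

    def test_empty_input(self):
        seqs = make_sequence_set([])
        clusters, m = build_aav_matrix(seqs)
        assert clusters == [] and m.empty

    def test_cluster_count_equals_distinct_proteins(self, rng):
        aas = "ACDEFG"
        records = []
        for i in range(60):
            protein_codons = [
                _SYN_CODONS["L"][rng.integers(6)],
                _SYN_CODONS["P"][rng.integers(4)],
                _SYN_CODONS["K"][rng.integers(2)] if rng.random() < 0.5 else "GGG",
            ]
            records.append((f"s{rng.integers(3)}", f"r{i}", "".join(protein_codons)))
        seqs = make_sequence_set(records)
        clusters, m = build_aav_matrix(seqs)
        proteins = {translate(nt) for _, _, nt in records}
        assert len(clusters) == len(proteins) == m.shape[0]
        assert m.to_numpy().sum() == len(records)


class TestPairwiseIdentity:
    def test_substitution_arithmetic(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        two = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        two = two[:70] + ("G" if two[70] != "G" else "T") + two[71:]
        assert pairwise_identity(base, two) == pytest.approx(0.98)

    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0


def brute_force_clusters(seq_totals, threshold):
    """Independent naive clustering: all-pairs identity matrix first, then
    sequential assignment by the same ordering rule."""
    order = sorted(seq_totals, key=lambda s: (-seq_totals[s], s))
    ident = {
        (a, b): pairwise_identity(a, b) for a in order for b in order
    }
    assignment = {}
    centroids = []
    for s in order:
        for c in centroids:
            if ident[(s, c)] >= threshold:
                assignment[s] = c
                break
        else:
            centroids.append(s)
            assignment[s] = s
    return assignment


class TestOtuClustering:
    def test_identical_sequences_one_otu(self):
        seqs = make_sequence_set(
            [("s1", "r1", "ACGTACGT"), ("s2", "r1", "ACGTACGT")]
        )
        clusters, m = cluster_otus(seqs)
        assert len(clusters) == 1
        assert m.to_numpy().sum() == 2

    def test_threshold_boundary_merging(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))

        def mutate(s, positions):
            out = list(s)
            for p in positions:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        near = mutate(base, [10, 60])  # identity 0.98 -> merges at 0.97
        far = mutate(base, [5, 25, 45, 85])  # identity 0.96 -> splits
        seqs = make_sequence_set(
            [("s1", "r1", base), ("s1", "r2", base), ("s1", "r3", near)]
        )
        clusters, _ = cluster_otus(seqs, threshold=0.97)
        assert len(clusters) == 1
        seqs = make_sequence_set(
            [("s1", "r1", base), ("s1", "r2", base), ("s1", "r3", far)]
        )
        clusters, _ = cluster_otus(seqs, threshold=0.97)
        assert len(clusters) == 2

    def test_centroid_is_most_abundant_member(self, rng):
        base = "".join(rng.choice(list("ACGT"), 60))
        variant = "T" + base[1:] if base[0] != "T" else "A" + base[1:]
        seqs = make_sequence_set(
            [("s1", "r1", variant), ("s1", "r2", variant),
             ("s1", "r3", variant), ("s2", "r1", base)]
        )
        clusters, _ = cluster_otus(seqs, threshold=0.9)
        assert len(clusters) == 1
        assert clusters[0].centroid_nt == variant

    def test_matches_brute_force_on_random_inputs(self, rng):
        for trial in range(10):
            n = int(rng.integers(5, 20))
            pool = []
            base = "".join(rng.choice(list("ACGT"), 50))
            for _ in range(n):
                seq = list(base)
                for p in rng.choice(50, rng.integers(0, 6), replace=False):
                    seq[p] = "ACGT"[rng.integers(4)]
                pool.append("".join(seq))
            records = [
                (f"s{rng.integers(3)}", f"r{i}", s) for i, s in enumerate(pool)
            ]
            seqs = make_sequence_set(records)
            clusters, m = cluster_otus(seqs, threshold=0.95)
            totals = {}
            for s in pool:
                totals[s] = totals.get(s, 0) + 1
            expected = brute_force_clusters(totals, 0.95)
            got = {}
            for cl in clusters:
                for member in cl.member_nt:
                    got[member] = cl.centroid_nt
            assert got == expected
            assert m.to_numpy().sum() == len(records)
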