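import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siroclass.alignment import (
    MultiAlignment,
    ScoringScheme,
    center_star_msa,
    global_align,
    sp_score,
    trim_columns,
)
from siroclass.errors import AlignmentError
from siroclass.seq_io import ProteinRecord

from conftest import brute_force_global_score

seq4 = st.text(alphabet="ACDE", min_size=1, max_size=8)


class TestGlobalAlign:
    def test_self_alignment_identity_mapping(self, identity):
        aln = global_align("CLSTER", "CLSTER", identity)
        assert aln.score == 6.0
        assert aln.ref_to_query == (1, 2, 3, 4, 5, 6)

    def test_single_gap_example_matches_enumeration(self, identity):
        aln = global_align("ACGC", "AGC", identity)
        assert aln.score == brute_force_global_score("ACGC", "AGC", identity)
        assert aln.aligned_ref.replace("-", "") == "ACGC"
        assert aln.aligned_query.replace("-", "") == "AGC"

    def test_empty_sequence_rejected(self, identity):
        with pytest.raises(AlignmentError):
            global_align("", "AC", identity)

    @settings(max_examples=150, deadline=None)
    @given(a=seq4, b=seq4)
    def test_score_equals_exhaustive_enumeration(self, identity, a, b):
        """The DP optimum equals the brute-force optimum over all global
        alignments, for short sequences over a reduced alphabet."""
        aln = global_align(a, b, identity)
        assert aln.score == pytest.approx(brute_force_global_score(a, b, identity))
        assert aln.aligned_ref.replace("-", "") == a
        assert aln.aligned_query.replace("-", "") == b

    def test_score_symmetric_under_role_swap(self, identity):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = "".join(rng.choice(list("ACDE"), rng.integers(1, 9)))
            b = "".join(rng.choice(list("ACDE"), rng.integers(1, 9)))
            assert global_align(a, b, identity).score == pytest.approx(
                global_align(b, a, identity).score
            )

    def test_mapping_strictly_increasing(self, blosum):
        aln = global_align("MKAACDEFWY", "MKCDEFHHWY", blosum)
        mapped = [q for q in aln.ref_to_query if q is not None]
        assert mapped == sorted(set(mapped))

    def test_matches_biopython_pairwise_aligner(self, blosum):
        """Independent cross-check of affine scoring against Bio.Align."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, rng.integers(5, 40)))
            b = "".join(rng.choice(aas, rng.integers(5, 40)))
            assert global_align(a, b, blosum).score == pytest.approx(aligner.score(a, b))

    def test_free_end_gaps_fit_domain_without_terminal_penalty(self, blosum):
        aln = global_align("WWWHHH", "AAAAWWWHHHDDDD", blosum, free_end_gaps=True)
        assert aln.ref_to_query == (5, 6, 7, 8, 9, 10)
        assert aln.aligned_query.replace("-", "") == "AAAAWWWHHHDDDD"


def recs(*seqs):
    return [ProteinRecord(f"S{i}", s) for i, s in enumerate(seqs)]


class TestCenterStar:
    def test_identical_sequences_align_without_gaps(self, blosum):
        msa = center_star_msa(recs("MKLVF", "MKLVF", "MKLVF"), blosum)
        assert all("-" not in row for row in msa.rows)

    def test_degapping_recovers_inputs(self, blosum):
        seqs = ("MKLVFAAA", "MKLFAAA", "MKLVFAAAWW")
        msa = center_star_msa(recs(*seqs), blosum)
        assert tuple(msa.degapped(i) for i in range(3)) == seqs

    def test_fewer_than_two_records_rejected(self, blosum):
        with pytest.raises(AlignmentError):
            center_star_msa(recs("MK"), blosum)

    def test_center_choice_maximizes_sp_score_over_alternatives(self, identity):
        """The chosen star is at least as good (SP score) as forcing any
        other record to act as the center — checked by enumerating all
        three center choices on short sequences."""
        from siroclass.alignment import global_align as ga

        seqs = ("ACDEAC", "ACDAC", "CDEACC")
        records = recs(*seqs)
        chosen = sp_score(center_star_msa(records, identity), identity)

        def star_around(c):
            n = len(records[c].sequence)
            others = [i for i in range(3) if i != c]
            # re-run the merge with a forced center by reordering so the
            # forced center has maximal summed score via direct construction
            import siroclass.alignment as al

            center = records[c]
            gaps = np.zeros(n + 1, dtype=int)
            pairs = []
            for i in others:
                aln = ga(center, records[i], identity)
                ins = np.zeros(n + 1, dtype=int)
                blocks = [[] for _ in range(n + 1)]
                chars = []
                p = 0
                for ca, cq in zip(aln.aligned_ref, aln.aligned_query):
                    if ca == "-":
                        ins[p] += 1
                        blocks[p].append(cq)
                    else:
                        p += 1
                        chars.append(cq)
                pairs.append((i, ins, blocks, chars))
                gaps = np.maximum(gaps, ins)

            def build(ins, blocks, chars):
                parts = []
                for p in range(n + 1):
                    parts.append("".join(blocks[p]) + "-" * (gaps[p] - ins[p]))
                    if p < n:
                        parts.append(chars[p])
                return "".join(parts)

            rows = [None] * 3
            rows[c] = build(np.zeros(n + 1, dtype=int), [[] for _ in range(n + 1)], list(center.sequence))
            for i, ins, blocks, chars in pairs:
                rows[i] = build(ins, blocks, chars)
            return sp_score(MultiAlignment(tuple(r.id for r in records), tuple(rows)), identity)

        assert chosen >= max(star_around(c) for c in range(3)) - 1e-9

    def test_deterministic(self, blosum):
        seqs = ("MKLVFAAA", "MKLFAAA", "MKLVFAAAWW", "MKKVFAAA")
        a = center_star_msa(recs(*seqs), blosum)
        b = center_star_msa(recs(*seqs), blosum)
        assert a.rows == b.rows


class TestTrimColumns:
    def msa(self, *rows):
        return MultiAlignment(tuple(f"S{i}" for i in range(len(rows))), tuple(rows))

    def test_gapless_msa_unchanged(self):
        m = self.msa("MKLV", "MKLV", "MKIV")
        out, kept = trim_columns(m, 0.5)
        assert out.rows == m.rows
        assert kept == [1, 2, 3, 4]

    def test_column_with_three_quarters_gaps_removed_at_half_threshold(self):
        m = self.msa("M-LV", "M-LV", "M-IV", "MKIV")
        out, kept = trim_columns(m, 0.5)
        assert kept == [1, 3, 4]
        assert out.rows == ("MLV", "MLV", "MIV", "MIV")

    def test_kept_columns_are_ordered_subset(self):
        m = self.msa("M--V", "MK-V", "MKIV")
        _, kept = trim_columns(m, 0.34)
        assert kept == sorted(kept)
        assert set(kept) <= {1, 2, 3, 4}

    def test_idempotent_at_fixed_threshold(self):
        m = self.msa("M--VWW", "MK-VW-", "MKIV-W")
        once, _ = trim_columns(m, 0.5)
        twice, kept = trim_columns(once, 0.5)
        assert twice.rows == once.rows
        assert kept == list(range(1, once.n_cols + 1))

    def test_may_return_zero_columns(self):
        m = self.msa("M-", "-M", "--")
        out, kept = trim_columns(m, 0.1)
        assert kept == []
        assert out.n_cols == 0
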