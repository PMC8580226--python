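import math

import numpy as np
import pytest

from helpers_oracles import enum_forward_bits, enum_viterbi_bits, random_tiny_model
from skincomet import phmm
from skincomet.msa import Msa
from skincomet.seqio import AA20, ProteinRecord, ValidationError


class TestSelectMatchColumns:
    def test_gapless_all_match(self):
        msa = Msa(["a", "b"], ["ACD", "ACD"])
        assert phmm.select_match_columns(msa) == [True, True, True]

    def test_gap_dominated_column_is_insert(self):
        msa = Msa(list("abcd"), ["A-", "A-", "A-", "AC"])
        assert phmm.select_match_columns(msa, 0.5) == [True, False]

    def test_exact_threshold_is_insert(self):
        msa = Msa(["a", "b"], ["A-", "AC"])
        assert phmm.select_match_columns(msa, 0.5) == [True, False]

    def test_all_insert_rejected(self):
        msa = Msa(["a", "b", "c"], ["A", "-", "-"])
        with pytest.raises(ValidationError, match="no match columns"):
            phmm.select_match_columns(msa, 0.5)


class TestBuildProfile:
    def test_laplace_emission_estimate(self):
        m = phmm.build_profile(Msa(["a", "b"], ["AC", "AC"]), pseudocount=1.0)
        assert m.match_emissions[0, 0] == pytest.approx(3 / 22)
        assert m.match_emissions[1, AA20.index("C")] == pytest.approx(3 / 22)

    def test_no_pseudocount_limit(self):
        m = phmm.build_profile(Msa(list("abcd"), ["A"] * 4), pseudocount=0.0)
        assert m.match_emissions[0, 0] == 1.0
        assert m.match_emissions[0, 1:].sum() == 0.0

    def test_gapless_transition_estimate(self):
        n = 2
        m = phmm.build_profile(Msa(["a", "b"], ["ACD", "ACD"]))
        assert m.t_mm[1] == pytest.approx((n + 1) / (n + 3))

    def test_probability_rows_sum_to_one(self, rng):
        for _ in range(10):
            m = random_tiny_model(rng)
            if m is None:
                continue
            assert np.allclose(m.match_emissions.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(m.t_mm + m.t_mi + m.t_md, 1.0, atol=1e-9)
            assert np.allclose(m.t_im + m.t_ii, 1.0, atol=1e-9)
            assert np.allclose(m.t_dm[1:] + m.t_dd[1:], 1.0, atol=1e-9)


class TestScoring:
    def test_all_x_scores_transition_only(self):
        m = phmm.build_profile(Msa(["a", "b"], ["ACD", "ACD"]))
        got = phmm.score_forward(m, "XXXX")
        assert got == pytest.approx(enum_forward_bits(m, "XXXX"), abs=1e-9)

    def test_forward_matches_enumeration_on_tiny_models(self, rng):
        checked = 0
        while checked < 40:
            m = random_tiny_model(rng, max_rows=4, max_cols=3)
            if m is None:
                continue
            L = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list(AA20 + "X"), L))
            assert phmm.score_forward(m, seq) == pytest.approx(
                enum_forward_bits(m, seq), abs=1e-9)
            checked += 1

    def test_viterbi_matches_enumeration_and_bounds_forward(self, rng):
        checked = 0
        while checked < 40:
            m = random_tiny_model(rng, max_rows=4, max_cols=3)
            if m is None:
                continue
            L = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list(AA20), L))
            v, path = phmm.score_viterbi(m, seq)
            f = phmm.score_forward(m, seq)
            assert v == pytest.approx(enum_viterbi_bits(m, seq), abs=1e-9)
            assert v <= f + 1e-9
            assert path and all(s in "MID" for s, _ in path)
            checked += 1

    def test_single_path_model_viterbi_equals_forward(self):
        # one match state emitting A with certainty: only one local path
        # per (start, length-1 alignment); compare on a length-1 sequence
        m = phmm.build_profile(Msa(list("abcd"), ["A"] * 4), pseudocount=0.0)
        f = phmm.score_forward(m, "A")
        v, _ = phmm.score_viterbi(m, "A")
        assert v == pytest.approx(f, abs=1e-12)

    def test_member_outscores_shuffled_sequence(self, small_models, rng):
        m = small_models.models[0]
        member = m.members[0]
        # the member's own sequence vs a composition-preserving shuffle
        aln = small_models.alignments[small_models.group_of_model[m.name]]
        seq = aln.ungapped(member)
        shuffled = "".join(rng.permutation(list(seq)))
        assert phmm.score_forward(m, seq) > phmm.score_forward(m, shuffled) + 10


class TestCalibrateGa:
    def _toy(self):
        return phmm.build_profile(Msa(["a", "b"], ["ACD", "ACD"]))

    def test_midpoint_rule(self):
        m = self._toy()
        pos = [ProteinRecord("p1", "g", "ACD"), ProteinRecord("p2", "g", "ACD")]
        neg = [ProteinRecord("n1", "g", "WWW")]
        ga = phmm.calibrate_ga(m, pos, neg,
                               pos_scores=np.array([41.9, 55.0]),
                               neg_scores=np.array([12.3, 30.1]))
        assert ga == pytest.approx(36.0)
        assert not m.ga_overlap

    def test_boundary_overlap_flagged(self):
        m = self._toy()
        ga = phmm.calibrate_ga(m, [ProteinRecord("p", "g", "ACD")],
                               [ProteinRecord("n", "g", "WWW")],
                               pos_scores=np.array([10.0]),
                               neg_scores=np.array([10.0]))
        assert ga == 10.0
        assert m.ga_overlap

    def test_monotonicity(self, rng):
        m = self._toy()
        pos = np.sort(rng.normal(50, 5, 5))
        neg = np.sort(rng.normal(10, 5, 8))
        p = [ProteinRecord(f"p{i}", "g", "ACD") for i in range(5)]
        n = [ProteinRecord(f"n{i}", "g", "WWW") for i in range(8)]
        ga = phmm.calibrate_ga(m, p, n, pos_scores=pos, neg_scores=neg)
        # a higher-scoring negative never lowers GA
        ga_hi = phmm.calibrate_ga(m, p, n + [n[0]],
                                  pos_scores=pos,
                                  neg_scores=np.append(neg, neg.max() + 3))
        assert ga_hi >= ga
        # a lower-scoring positive never raises GA
        ga_lo = phmm.calibrate_ga(m, p + [p[0]], n,
                                  pos_scores=np.append(pos, pos.min() - 3),
                                  neg_scores=neg)
        assert ga_lo <= ga

    def test_empty_positives_rejected(self):
        with pytest.raises(ValidationError):
            phmm.calibrate_ga(self._toy(), [], [ProteinRecord("n", "g", "W")])

    def test_empty_negatives_fallback(self):
        m = self._toy()
        ga = phmm.calibrate_ga(m, [ProteinRecord("p", "g", "ACD")], [],
                               pos_scores=np.array([20.0]))
        assert ga == pytest.approx(19.5)
        assert m.ga_overlap


class TestModelFile:
    def test_roundtrip_preserves_scores_and_ga(self, small_models, tmp_path, rng):
        models = small_models.models
        path = tmp_path / "models.hmm"
        phmm.write_model_file(models, path)
        back = phmm.read_model_file(path)
        assert [m.name for m in back] == [m.name for m in models]
        seqs = ["".join(rng.choice(list(AA20), 40)) for _ in range(20)]
        for m1, m2 in zip(models, back):
            assert m2.ga_bits == m1.ga_bits  # exact
            s1 = phmm.score_forward_many(m1, seqs)
            s2 = phmm.score_forward_many(m2, seqs)
            np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_missing_ga_loads_unset_and_blocks_scan(self, tmp_path):
        m = phmm.build_profile(Msa(["a", "b"], ["ACD", "ACD"]), name="m1")
        path = tmp_path / "m.hmm"
        phmm.write_model_file([m], path)
        back = phmm.read_model_file(path)
        assert back[0].ga_bits is None
        from skincomet.scan import scan_proteome
        with pytest.raises(ValidationError, match="gathering threshold"):
            scan_proteome(back, [ProteinRecord("p", "g", "ACD")])

    def test_truncated_file_rejected(self, tmp_path):
        m = phmm.build_profile(Msa(["a", "b"], ["ACDEF", "ACDEF"]), name="m1")
        path = tmp_path / "m.hmm"
        phmm.write_model_file([m], path)
        text = path.read_text().splitlines()
        (tmp_path / "trunc.hmm").write_text("\n".join(text[:-4]) + "\n")
        with pytest.raises(ValidationError):
            phmm.read_model_file(tmp_path / "trunc.hmm")
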