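import math

import numpy as np
import pytest
from scipy import stats

from ompfam.io import AMINO_ACIDS, SequenceRecord
from ompfam.profiles import (GumbelParams, Hit, build_profile, calibrate,
                             default_background, fit_gumbel, merge_hits,
                             score_to_evalue, search)


def _uniform_bg():
    return np.full(20, 1.0 / 20.0)


class TestBuildProfile:
    def test_single_sequence_seed_columns(self):
        profile = build_profile([("s1", "ACD")])
        assert profile.n_columns == 3

    def test_self_match_is_maximal_over_equal_length_targets(self):
        profile = build_profile([("s1", "ACD")])
        calibrate(profile, seed=1)
        rng = np.random.default_rng(2)

        def score_of(seq):
            hits = search(profile, [SequenceRecord("t", seq)],
                          inclusion_evalue=math.inf, db_size=1)
            return hits[0].score if hits else 0.0

        self_score = score_of("ACD")
        for _ in range(300):
            other = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 3))
            assert score_of(other) <= self_score

    def test_majority_gap_column_excluded(self):
        # middle column is 60% gaps -> not a match column
        rows = [("a", "A-D"), ("b", "A-D"), ("c", "AC-"),
                ("d", "A-D"), ("e", "ACD")]
        profile = build_profile(rows)
        assert profile.n_columns == 2

    def test_emission_log_odds_formula(self):
        """Column {A, A}: score(A) = log2(((2 + a*p_A)/(2 + a)) / p_A)."""
        alpha = 1.5
        bg = _uniform_bg()
        profile = build_profile([("x", "AC"), ("y", "AC")],
                                pseudocount_weight=alpha, background=bg)
        p_a = bg[AMINO_ACIDS.index("A")]
        expected = math.log2(((2 + alpha * p_a) / (2 + alpha)) / p_a)
        assert profile.match_scores[0, AMINO_ACIDS.index("A")] == \
            pytest.approx(expected)

    def test_zero_match_columns_rejected(self):
        with pytest.raises(ValueError, match="zero match columns"):
            build_profile([("a", "--"), ("b", "--"), ("c", "AC")])

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_profile([])

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            build_profile([("a", "ACD"), ("b", "AC")])


class TestCalibration:
    def test_same_seed_reproducible(self, potra_profile):
        a = calibrate(potra_profile, n_random=250, length=200, seed=9)
        b = calibrate(potra_profile, n_random=250, length=200, seed=9)
        assert (a.lam, a.mu) == (b.lam, b.mu)

    def test_lambda_positive(self, potra_profile):
        params = calibrate(potra_profile, n_random=250, length=200, seed=3)
        assert params.lam > 0

    def test_too_few_samples_rejected(self, potra_profile):
        with pytest.raises(ValueError, match="at least 200"):
            calibrate(potra_profile, n_random=50)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.full(300, 5.0))

    def test_gumbel_params_require_positive_lambda(self):
        with pytest.raises(ValueError):
            GumbelParams(lam=-1.0, mu=0.0, n_calibration=200,
                         calibration_length=100, seed=0)


class TestSearch:
    def test_seed_sequence_envelope_covers_full_target(self):
        seed_seq = "MKLVANWGRTEDSYHQCFIP" * 3
        profile = build_profile([("s1", seed_seq)])
        calibrate(profile, seed=5)
        hits = search(profile, [SequenceRecord("t", seed_seq)],
                      inclusion_evalue=1.0, db_size=1)
        assert len(hits) == 1
        assert (hits[0].env_start, hits[0].env_end) == (1, len(seed_seq))

    def test_unrelated_target_not_reported(self):
        seed_seq = "MKLVANWGRTEDSYHQCFIP" * 3
        profile = build_profile([("s1", seed_seq)])
        calibrate(profile, seed=5)
        rng = np.random.default_rng(6)
        target = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 60))
        assert search(profile, [SequenceRecord("t", target)],
                      inclusion_evalue=1e-5, db_size=1) == []

    def test_uncalibrated_profile_rejected(self):
        profile = build_profile([("s1", "ACDEFGH")])
        with pytest.raises(ValueError, match="not calibrated"):
            search(profile, [SequenceRecord("t", "ACDEFGH")])

    def test_evalue_monotone_in_score(self):
        cal = GumbelParams(lam=0.6, mu=12.0, n_calibration=500,
                           calibration_length=350, seed=0)
        # strictly monotone above the saturation region (E ~ db for s << mu)
        es = [score_to_evalue(s, cal, 100) for s in np.linspace(14, 80, 30)]
        assert all(x > y for x, y in zip(es, es[1:]))
        assert score_to_evalue(0.0, cal, 100) >= score_to_evalue(14.0, cal, 100)

    def test_envelope_containment(self, omp85_profile, small_dataset):
        """Restricting a target to the hit envelope preserves the score."""
        rec = small_dataset.records[0]
        hits = search(omp85_profile, [rec], inclusion_evalue=10.0, db_size=1)
        assert hits
        h = hits[0]
        sub = SequenceRecord("sub", rec.residues[h.env_start - 1:h.env_end])
        sub_hits = search(omp85_profile, [sub], inclusion_evalue=math.inf,
                          db_size=1)
        assert sub_hits[0].score == pytest.approx(h.score)


class TestMergeHits:
    def _hit(self, target, profile, score, e):
        return Hit(query_profile=profile, target_id=target, score=score,
                   evalue=e, env_start=1, env_end=10)

    def test_single_sided_target_kept(self):
        merged = merge_hits([self._hit("t1", "omp85", 50, 1e-9)], [])
        assert merged["t1"].query_profile == "omp85"

    def test_higher_scoring_profile_wins(self):
        merged = merge_hits([self._hit("t1", "omp85", 60, 1e-11)],
                            [self._hit("t1", "tpsb", 50, 1e-9)])
        assert merged["t1"].score == 60

    def test_union_semantics(self):
        a = [self._hit(f"a{i}", "omp85", 40, 1e-6) for i in range(5)]
        b = [self._hit(f"b{i}", "tpsb", 40, 1e-6) for i in range(3)]
        b.append(self._hit("a0", "tpsb", 30, 1e-4))
        merged = merge_hits(a, b)
        assert set(merged) == {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(3)}

    def test_score_tie_broken_by_evalue_then_name(self):
        merged = merge_hits([self._hit("t", "omp85", 50, 1e-8)],
                            [self._hit("t", "tpsb", 50, 1e-9)])
        assert merged["t"].query_profile == "tpsb"
        merged = merge_hits([self._hit("t", "omp85", 50, 1e-8)],
                            [self._hit("t", "tpsb", 50, 1e-8)])
        assert merged["t"].query_profile == "omp85"
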