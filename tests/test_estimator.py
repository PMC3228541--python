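"""k-mer profiles, the overlap statistic and the linear timing model."""

import random

import numpy as np
import pytest

from elastiseq import (CalibrationRun, KmerProfile, RuntimeModel,
                       SequenceRecord, SyntheticSpec, ValidationError,
                       compute_profile, fit_model, generate_synthetic,
                       overlap_statistic, predict_cpu_hours,
                       reference_weights, reverse_complement)
from elastiseq.estimator import load_model, load_profile, save_model, save_profile

from conftest import brute_force_profile


class TestComputeProfile:
    def test_empty_record_set(self):
        p = compute_profile([], 11)
        assert p.counts == {} and p.total == 0

    def test_hand_enumerated_homopolymer(self):
        p = compute_profile([SequenceRecord("a", "AAAA")], 2)
        assert p.counts == {"AA": 3, "TT": 3}
        assert p.total == 6

    def test_window_count_and_oracle_for_one_sequence(self):
        (rec,) = generate_synthetic(SyntheticSpec(1, 200, 200, seed=21))
        p = compute_profile([rec], 11)
        assert p.total == 2 * (200 - 11 + 1)
        assert p.counts == brute_force_profile([rec.seq], 11)

    @pytest.mark.parametrize("k", [2, 3, 11])
    @pytest.mark.parametrize("alphabet", ["dna", "protein"])
    def test_oracle_equivalence_100_sequences(self, k, alphabet):
        records = generate_synthetic(
            SyntheticSpec(100, 20, 120, alphabet=alphabet, seed=k))
        revcomp = alphabet == "dna"
        p = compute_profile(records, k, alphabet, include_revcomp=revcomp)
        oracle = brute_force_profile([r.seq for r in records], k, alphabet,
                                     include_revcomp=revcomp)
        assert p.counts == oracle

    def test_ambiguity_windows_are_skipped(self):
        p = compute_profile([SequenceRecord("a", "ACNGT")], 2,
                            include_revcomp=False)
        assert p.counts == {"AC": 1, "GT": 1}

    def test_short_sequences_contribute_nothing(self):
        p = compute_profile([SequenceRecord("a", "ACG")], 11)
        assert p.total == 0

    def test_strand_symmetry(self):
        for seed in range(5):
            (rec,) = generate_synthetic(SyntheticSpec(1, 80, 150, seed=seed))
            rc = SequenceRecord(rec.id, reverse_complement(rec.seq))
            assert compute_profile([rec], 11).counts == \
                compute_profile([rc], 11).counts

    def test_revcomp_rejected_for_protein(self):
        with pytest.raises(ValidationError):
            compute_profile([], 3, "protein", include_revcomp=True)

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            compute_profile([], 0)


class TestOverlapStatistic:
    def test_empty_query_is_zero(self):
        assert overlap_statistic(KmerProfile(3, "dna", {}), {"AAA": 2.0}) == 0.0

    def test_hand_computed_dot_product(self):
        q = KmerProfile(2, "dna", {"AA": 3, "AC": 1, "GG": 5})
        w = {"AA": 0.5, "GG": 0.1, "TT": 9.0}
        assert overlap_statistic(q, w) == pytest.approx(3 * 0.5 + 5 * 0.1)

    def test_linearity_in_counts(self):
        q = KmerProfile(2, "dna", {"AA": 3, "CG": 7})
        w = {"AA": 1.25, "CG": 0.5}
        assert overlap_statistic(q.scaled(2), w) == \
            pytest.approx(2 * overlap_statistic(q, w))


class TestFitAndPredict:
    def test_noiseless_fit_recovers_exactly(self):
        runs = [CalibrationRun(x, 0.5 + 2.0 * x) for x in (0.0, 1.0, 4.0, 9.0)]
        m = fit_model(runs, 2, {"AA": 1.0})
        assert m.alpha == pytest.approx(0.5, abs=1e-9)
        assert m.beta == pytest.approx(2.0, abs=1e-9)

    def test_noisy_parameter_recovery(self):
        rng = random.Random(123)
        runs = [
            CalibrationRun(x, max(0.0, 0.5 + 2.0 * x + rng.gauss(0, 0.05)))
            for x in (rng.uniform(0, 10) for _ in range(50))
        ]
        m = fit_model(runs, 2, {})
        assert abs(m.alpha - 0.5) < 0.1
        assert abs(m.beta - 2.0) < 0.05

    def test_negative_intercept_is_clamped(self):
        # every observation slightly below beta*x forces alpha < 0 unconstrained
        runs = [CalibrationRun(x, max(0.0, 2.0 * x - 0.2)) for x in (1, 2, 5, 8)]
        m = fit_model(runs, 2, {})
        assert m.alpha == 0.0
        assert m.beta > 0

    def test_too_few_or_degenerate_runs(self):
        with pytest.raises(ValidationError):
            fit_model([CalibrationRun(1, 1)], 2, {})
        with pytest.raises(ValidationError):
            fit_model([CalibrationRun(1, 1), CalibrationRun(1, 2)], 2, {})

    def test_empty_query_predicts_alpha(self):
        m = RuntimeModel(2, "dna", {"AA": 1.0}, alpha=0.7, beta=3.0)
        assert predict_cpu_hours(m, KmerProfile(2, "dna", {})) == 0.7

    def test_prediction_is_alpha_plus_beta_x(self):
        m = RuntimeModel(2, "dna", {"AA": 1.0}, alpha=0.0, beta=1.0)
        q = KmerProfile(2, "dna", {"AA": 7, "CC": 100})
        assert predict_cpu_hours(m, q) == pytest.approx(7.0)

    def test_k_mismatch_rejected(self):
        m = RuntimeModel(3, "dna", {})
        with pytest.raises(ValidationError):
            predict_cpu_hours(m, KmerProfile(2, "dna", {}))

    def test_monotone_in_query_counts(self):
        m = RuntimeModel(2, "dna", {"AA": 0.4, "CC": 0.0}, alpha=0.1, beta=2.0)
        base = KmerProfile(2, "dna", {"AA": 3, "CC": 5})
        t0 = predict_cpu_hours(m, base)
        for w in base.counts:
            bumped = dict(base.counts)
            bumped[w] += 1
            assert predict_cpu_hours(m, KmerProfile(2, "dna", bumped)) >= t0

    def test_held_out_prediction_under_known_law(self):
        """Calibrate on noisy timings from a linear law, predict held out."""
        rng = random.Random(7)
        alpha0, beta0 = 0.5, 2.0
        runs = [
            CalibrationRun(x, max(0.0, alpha0 + beta0 * x + rng.gauss(0, 0.05)))
            for x in (rng.uniform(0, 10) for _ in range(50))
        ]
        m = fit_model(runs, 2, {"AA": 1.0})
        for count in (3, 12, 40):  # x == count under the unit weight on AA
            q = KmerProfile(2, "dna", {"AA": count})
            truth = alpha0 + beta0 * count
            assert abs(predict_cpu_hours(m, q) - truth) / truth < 0.05


class TestSerialization:
    def test_profile_round_trip(self, tmp_path):
        records = generate_synthetic(SyntheticSpec(10, 30, 60, seed=2))
        p = compute_profile(records, 5)
        back = load_profile(save_profile(p, tmp_path / "p.profile"))
        assert back.k == p.k and back.alphabet == p.alphabet
        assert back.counts == p.counts

    def test_model_round_trip(self, tmp_path):
        ref = compute_profile(
            generate_synthetic(SyntheticSpec(5, 50, 80, seed=3)), 4)
        m = RuntimeModel(4, "dna", reference_weights(ref), alpha=0.25, beta=1.5)
        back = load_model(save_model(m, tmp_path / "m.model"))
        assert back.alpha == m.alpha and back.beta == m.beta
        assert back.reference_weights == pytest.approx(m.reference_weights)
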