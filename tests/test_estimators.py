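import numpy as np
import pytest

from uspiorelax.estimators import (
    DegenerateInputError,
    Despot1HifiEstimator,
    FitConfig,
    IrseEstimator,
    R2StarEstimator,
    VfaEstimator,
    _scalar_predictor,
    fit_despot1_hifi,
    fit_irse,
    fit_r2star,
    fit_vfa,
)
from uspiorelax.phantom import add_noise
from uspiorelax.sequences import SequenceKind, SequenceParams, get_preset
from uspiorelax.signal_models import (
    VoxelParams,
    irse_signal,
    irsgre_signal,
    sgre_signal,
)


def forward_hifi(seqs, s0, r1, k, model="deichmann"):
    out = []
    for s in seqs:
        p = VoxelParams(s0=s0, r1=r1, k=k)
        if s.kind is SequenceKind.SGRE:
            out.append(float(sgre_signal(p, s)))
        else:
            out.append(float(irsgre_signal(p, s, model=model)))
    return np.array(out)


class TestScalarPredictors:
    @pytest.mark.parametrize("model", ["simplified", "deichmann", "brix"])
    def test_match_canonical_array_models(self, protocol, model):
        """The fast solver-side closures implement the same formulas as the
        reference array models."""
        for seq in protocol:
            f = _scalar_predictor(seq, model)
            for r1 in (0.1, 0.7, 1.3, 3.0, 6.0):
                for k in (0.8, 1.0, 1.25):
                    p = VoxelParams(s0=123.4, r1=r1, k=k)
                    ref = (
                        sgre_signal(p, seq)
                        if seq.kind is SequenceKind.SGRE
                        else irsgre_signal(p, seq, model=model)
                    )
                    assert f(123.4, r1, k) == pytest.approx(float(ref), abs=1e-10)


class TestDespot1Hifi:
    @pytest.mark.parametrize("model", ["simplified", "deichmann", "brix"])
    def test_self_consistent_recovery(self, protocol, model):
        """Noiseless data generated by a model are recovered exactly by the
        same model's fit."""
        y = forward_hifi(protocol, 1000.0, 0.9, 1.1, model=model)
        res = fit_despot1_hifi(y, protocol, FitConfig(model=model))
        assert res.converged
        assert res.params.s0 == pytest.approx(1000.0, rel=1e-4)
        assert res.params.r1 == pytest.approx(0.9, rel=1e-4)
        assert res.params.k == pytest.approx(1.1, rel=1e-4)

    def test_recovery_grid(self, protocol):
        for r1 in (0.5, 1.0, 2.0, 4.5):
            for k in (0.8, 1.0, 1.2):
                y = forward_hifi(protocol, 800.0, r1, k)
                res = fit_despot1_hifi(y, protocol, FitConfig(model="deichmann"))
                assert res.params.r1 == pytest.approx(r1, rel=1e-4)
                assert res.params.k == pytest.approx(k, rel=1e-4)

    def test_positivity_constraint_holds_under_noise(self, protocol, rng):
        y = forward_hifi(protocol, 50.0, 0.4, 0.9)
        est = Despot1HifiEstimator(sequences=protocol)
        est.fit(y + rng.normal(0, 2.0, (20, len(y))))
        assert np.all(est.s0_[est.converged_] > 0)
        assert np.all(est.r1_[est.converged_] > 0)
        assert np.all(est.k_[est.converged_] > 0)

    def test_model_mismatch_bias_grows_with_r1(self, protocol):
        """Fitting pulse-train data with the simplified model is acceptably
        wrong at tissue r1 but badly wrong at post-contrast blood r1."""
        biases = {}
        for r1 in (1.0, 4.5):
            y = forward_hifi(protocol, 1000.0, r1, 1.0, model="brix")
            res = fit_despot1_hifi(y, protocol, FitConfig(model="simplified"))
            biases[r1] = abs(res.params.r1 - r1)
        assert biases[4.5] > biases[1.0]
        assert biases[4.5] > 0.05

    def test_all_zero_signals_raise(self, protocol):
        with pytest.raises(DegenerateInputError):
            fit_despot1_hifi(np.zeros(5), protocol)

    def test_deterministic(self, protocol):
        y = forward_hifi(protocol, 120.0, 1.7, 0.95)
        r1 = fit_despot1_hifi(y, protocol).params.r1
        r2 = fit_despot1_hifi(y, protocol).params.r1
        assert r1 == r2


class TestVfa:
    def sgre_seqs(self):
        return [get_preset(f"sgre_fa{f}") for f in (12, 5, 3)]

    def test_exact_recovery_when_k_is_one(self):
        seqs = self.sgre_seqs()
        y = np.array([float(sgre_signal(VoxelParams(s0=500, r1=1.2, k=1.0), s)) for s in seqs])
        res = fit_vfa(y, seqs)
        assert res.params.r1 == pytest.approx(1.2, rel=1e-6)
        assert res.params.k == 1.0

    def test_two_point_linear_solution_equals_nonlinear(self):
        seqs = self.sgre_seqs()[:2]
        y = np.array([float(sgre_signal(VoxelParams(s0=500, r1=0.8, k=1.0), s)) for s in seqs])
        lin = VfaEstimator(sequences=seqs, refine=False).fit(y)
        nl = VfaEstimator(sequences=seqs, refine=True).fit(y)
        assert lin.r1_[0] == pytest.approx(nl.r1_[0], rel=1e-8)
        assert lin.s0_[0] == pytest.approx(nl.s0_[0], rel=1e-8)

    def test_flip_angle_miscalibration_biases_r1(self, protocol):
        """With true k=1.15 the k-fixed fit misses r1, while the joint fit on
        the augmented data recovers it."""
        seqs = self.sgre_seqs()
        y5 = forward_hifi(protocol, 1000.0, 1.0, 1.15)
        res_vfa = fit_vfa(y5[:3], seqs)
        res_hifi = fit_despot1_hifi(y5, protocol)
        assert abs(res_vfa.params.r1 - 1.0) > 0.1
        assert res_hifi.params.r1 == pytest.approx(1.0, abs=1e-4)

    def test_identical_flip_angles_rejected(self):
        seqs = [get_preset("sgre_fa5"), get_preset("sgre_fa5")]
        with pytest.raises(np.linalg.LinAlgError):
            VfaEstimator(sequences=seqs).fit(np.array([1.0, 1.0]))


class TestR2Star:
    def test_two_point_exact(self):
        seq = SequenceParams(kind="ME-sGRE", tr=0.1, te_list=(5e-3, 55e-3), flip_deg=15)
        res = fit_r2star(np.array([90.484, 33.287]), seq)
        assert res.params.r2star == pytest.approx(20.0, abs=1e-3)
        assert res.params.s_te0 == pytest.approx(100.0, abs=1e-2)

    def test_constant_signal_gives_zero_rate(self, me_seq):
        res = fit_r2star(np.full(8, 42.0), me_seq)
        assert res.params.r2star == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_fit_exact_regardless_of_exclusion(self, me_seq):
        te = np.array(me_seq.te_list)
        y = 100 * np.exp(-25.0 * te)
        for factor in (0.0, 3.0):
            cfg = FitConfig(noise_sigma=0.05, noise_floor_factor=factor)
            res = fit_r2star(y, me_seq, cfg)
            assert res.params.r2star == pytest.approx(25.0, rel=1e-8)
            assert res.n_points_used == 8

    def test_insufficient_points_flagged_not_fit(self, me_seq):
        y = np.full(8, 1.0)
        cfg = FitConfig(noise_sigma=10.0, noise_floor_factor=3.0, min_echoes=2)
        res = fit_r2star(y, me_seq, cfg)
        assert not res.converged
        assert np.isnan(res.params.r2star)
        assert res.n_points_used == 0

    def test_negative_rate_allowed(self, me_seq):
        te = np.array(me_seq.te_list)
        y = 10 * np.exp(5.0 * te)
        res = fit_r2star(y, me_seq)
        assert res.params.r2star == pytest.approx(-5.0, rel=1e-6)

    def test_floor_exclusion_reduces_bias_in_strong_decay_regime(self, me_seq, rng):
        """Monte-Carlo: with several echoes in the Rician floor, excluding
        points below 3 sigma shrinks the mean r2* bias magnitude."""
        te = np.array(me_seq.te_list)
        r2s = 150.0
        sig = 100 * np.exp(-r2s * te)
        sigma = sig[0] / 30.0
        noisy = add_noise(np.tile(sig, (400, 1)), sigma, "rician", rng)
        with_excl = R2StarEstimator(
            sequence=me_seq, noise_sigma=sigma, noise_floor_factor=3.0
        ).fit(noisy)
        without = R2StarEstimator(
            sequence=me_seq, noise_sigma=sigma, noise_floor_factor=0.0
        ).fit(noisy)
        b_with = abs(np.nanmean(with_excl.r2star_) - r2s)
        b_without = abs(np.nanmean(without.r2star_) - r2s)
        assert b_with < b_without
        assert np.nanmean(with_excl.n_points_used_) < 8

    def test_loglinear_mode_matches_nonlinear_noiseless(self, me_seq):
        te = np.array(me_seq.te_list)
        y = 80 * np.exp(-40.0 * te)
        a = R2StarEstimator(sequence=me_seq, method="loglinear").fit(y)
        b = R2StarEstimator(sequence=me_seq, method="nonlinear").fit(y)
        assert a.r2star_[0] == pytest.approx(b.r2star_[0], rel=1e-8)


class TestIrse:
    def signals(self, irse_seqs, r1, s0=100.0):
        return np.array(
            [float(irse_signal(VoxelParams(s0=s0, r1=r1), s)) for s in irse_seqs]
        )

    @pytest.mark.parametrize("r1", [0.3, 0.6, 1.0, 4.5])
    def test_signed_round_trip(self, irse_seqs, r1):
        res = fit_irse(self.signals(irse_seqs, r1), irse_seqs)
        assert res.params.r1 == pytest.approx(r1, rel=1e-8)
        assert res.converged

    def test_no_zero_crossing_high_r1_still_exact(self, irse_seqs):
        y = self.signals(irse_seqs, 30.0)
        assert np.all(y > 0)  # recovery complete before the shortest TI
        res = fit_irse(y, irse_seqs)
        assert res.params.r1 == pytest.approx(30.0, rel=1e-6)

    @pytest.mark.parametrize("r1", [0.4, 1.0, 2.5])
    def test_polarity_restoration_matches_signed_fit(self, irse_seqs, r1):
        """Magnitude data recover the same r1 as signed data via the
        exhaustive single-zero-crossing sign search."""
        y = self.signals(irse_seqs, r1)
        signed = fit_irse(y, irse_seqs)
        mag = fit_irse(np.abs(y), irse_seqs, magnitude=True)
        assert mag.params.r1 == pytest.approx(signed.params.r1, rel=1e-8)

    def test_requires_three_inversion_times(self, irse_seqs):
        with pytest.raises(ValueError, match=">=3"):
            fit_irse(np.array([1.0, 2.0]), irse_seqs[:2])
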