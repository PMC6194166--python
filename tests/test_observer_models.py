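"""Observer, explanation, and client-strategy models."""

import numpy as np
import pytest
from numpy.random import default_rng

from embryoscope.experiment_engine import build_trial
from embryoscope.observer_models import (
    ClientParams,
    ExplanationRecord,
    ObserverState,
    SerParams,
    client_decide,
    client_rate,
    exemplar_observer_decide,
    generate_explanation,
    ideal_observer_decide,
    learner_update,
    load_template_bank,
    simulate_learning_curve,
)
from embryoscope.sdt_analysis import compute_dprime, tally_sdt
from embryoscope.shape_space import mahalanobis_dprime, tune_category_pair


class TestIdealObserver:
    def test_category_center_noiseless(self, pair):
        assert ideal_observer_decide(pair.spec_p.mean, pair, 0.0, seed=0) == "P"
        assert ideal_observer_decide(pair.spec_q.mean, pair, 0.0, seed=0) == "Q"

    def test_boundary_symmetric(self, pair):
        """At the equal-likelihood midpoint, P is chosen ~50% of the time."""
        mid = (pair.spec_p.mean + pair.spec_q.mean) / 2.0
        picks = [
            ideal_observer_decide(mid, pair, 0.0, seed=s) == "P" for s in range(10_000)
        ]
        assert np.mean(picks) == pytest.approx(0.5, abs=0.02)

    def test_monte_carlo_dprime_matches_mahalanobis(self, criterion_pair):
        """Simulated noiseless ideal-observer d' recovers the closed form (1.68)."""
        rng = default_rng(99)
        records = []
        for _ in range(20_000):
            label = "P" if rng.random() < 0.5 else "Q"
            query = rng.multivariate_normal(
                criterion_pair.spec(label).mean,
                criterion_pair.spec(label).covariance,
            )
            records.append(
                (ideal_observer_decide(query, criterion_pair, 0.0, rng), label)
            )
        dp = compute_dprime(tally_sdt(records), correction="log_linear")
        assert dp == pytest.approx(mahalanobis_dprime(criterion_pair), abs=0.1)

    @pytest.mark.parametrize("target", [1.0, 1.68, 2.5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mc_dprime_within_3_se_across_pairs(self, space, target, seed):
        pair = tune_category_pair(space, target, np.eye(2), seed=17 + seed)
        rng = default_rng(seed)
        n = 8000
        records = []
        for _ in range(n):
            label = "P" if rng.random() < 0.5 else "Q"
            query = rng.multivariate_normal(
                pair.spec(label).mean, pair.spec(label).covariance
            )
            records.append((ideal_observer_decide(query, pair, 0.0, rng), label))
        tally = tally_sdt(records, correction="log_linear")
        dp = compute_dprime(tally)
        # SE of d' via the rate-variance delta method
        from scipy.stats import norm

        h, f = tally.hit_rate, tally.fa_rate
        se = np.sqrt(
            h * (1 - h) / (n / 2 * norm.pdf(norm.ppf(h)) ** 2)
            + f * (1 - f) / (n / 2 * norm.pdf(norm.ppf(f)) ** 2)
        )
        assert abs(dp - target) < 3 * se + 0.02  # small allowance for estimator bias


class TestExemplarObserver:
    def test_query_on_sample(self):
        assert (
            exemplar_observer_decide([1.0, 1.0], [1.0, 1.0], [0.0, 0.0], 0.0, seed=0)
            == "P"
        )

    def test_equidistant_symmetric(self):
        picks = [
            exemplar_observer_decide([0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], 0.0, seed=s)
            == "P"
            for s in range(10_000)
        ]
        assert np.mean(picks) == pytest.approx(0.5, abs=0.02)

    def test_above_chance_but_below_ideal(self, pair):
        """One-sample-per-category comparison helps, but less than full knowledge."""
        rng = default_rng(3)
        n = 6000
        exemplar_correct, ideal_correct = 0, 0
        for _ in range(n):
            label = "P" if rng.random() < 0.5 else "Q"
            query = rng.multivariate_normal(
                pair.spec(label).mean, pair.spec(label).covariance
            )
            sp = rng.multivariate_normal(pair.spec_p.mean, pair.spec_p.covariance)
            sq = rng.multivariate_normal(pair.spec_q.mean, pair.spec_q.covariance)
            exemplar_correct += (
                exemplar_observer_decide(query, sp, sq, 0.0, rng) == label
            )
            ideal_correct += ideal_observer_decide(query, pair, 0.0, rng) == label
        assert exemplar_correct / n > 0.55
        assert exemplar_correct < ideal_correct


class TestLearner:
    def test_zero_rate_freezes_prototypes(self):
        s0 = ObserverState(np.zeros(2), np.ones(2), learning_rate=0.0)
        s1 = learner_update(s0, [3.0, 3.0], "P")
        np.testing.assert_array_equal(s1.prototype_p, s0.prototype_p)
        assert s1.n_updates == 1

    def test_unit_rate_jumps_to_query(self):
        s0 = ObserverState(np.zeros(2), np.ones(2), learning_rate=1.0)
        s1 = learner_update(s0, [3.0, -2.0], "Q")
        np.testing.assert_array_equal(s1.prototype_q, [3.0, -2.0])
        np.testing.assert_array_equal(s1.prototype_p, s0.prototype_p)

    def test_unknown_label_rejected(self):
        s0 = ObserverState.untrained()
        with pytest.raises(ValueError):
            learner_update(s0, [0.0, 0.0], "X")

    def test_prototype_convergence_to_category_means(self, pair):
        """2000 feedback trials at rate 0.05: prototypes near the true means.

        Constant-rate delta updates reach a stationary distribution with
        per-axis sd about sigma*sqrt(rate/(2-rate)) ~ 0.16 sigma, so the
        2-D error norm hovers near 0.2 of the total within-category sd
        sqrt(trace(Sigma)).  Checked as a pooled RMS over seeds (the
        expectation-level claim) plus a hard 3-sd cap per prototype.
        """
        sigma_within = np.sqrt(np.trace(pair.spec_p.covariance))
        errors = []
        for seed in range(3):
            rng = default_rng(seed)
            state = ObserverState.untrained(learning_rate=0.05)
            for _ in range(2000):
                label = "P" if rng.random() < 0.5 else "Q"
                query = rng.multivariate_normal(
                    pair.spec(label).mean, pair.spec(label).covariance
                )
                state = learner_update(state, query, label)
            assert state.n_updates == 2000
            for proto, spec in (
                (state.prototype_p, pair.spec_p),
                (state.prototype_q, pair.spec_q),
            ):
                err = np.linalg.norm(proto - spec.mean)
                errors.append(err)
                assert err < 0.5 * sigma_within  # ~3 stationary sds
        rms = np.sqrt(np.mean(np.square(errors)))
        assert rms < 0.25 * sigma_within


class TestLearningCurve:
    def test_random_noise_floor(self, pair):
        """Overwhelming perceptual noise keeps mean d' within CI of zero."""
        state = ObserverState.untrained(perceptual_noise_sd=500.0)
        dps, _ = simulate_learning_curve(pair, state, n_blocks=20, seed=0)
        # 20 blocks x 40 trials: SE of mean block d' is about 0.4/sqrt(20)
        assert abs(np.mean(dps)) < 0.3

    def test_learning_improves_dprime(self, pair):
        """Late-block d' exceeds early-block d' in expectation (20 seeds).

        With the default learning rate most of the improvement happens inside
        the first block, so the expected late-minus-early difference is
        modest but reliably positive.
        """
        diffs = []
        for seed in range(20):
            dps, _ = simulate_learning_curve(
                pair, ObserverState.untrained(), n_blocks=10, seed=seed
            )
            diffs.append(np.mean(dps[-3:]) - np.mean(dps[:3]))
        diffs = np.asarray(diffs)
        assert diffs.mean() > 0
        # one-sided significance of the improvement across seeds
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert t > 1.73  # p < 0.05, df=19

    def test_block_size_honored(self, pair):
        dps, state = simulate_learning_curve(
            pair, ObserverState.untrained(), n_blocks=4, block_size=40, seed=1
        )
        assert len(dps) == 4
        assert state.n_updates == 4 * 40


class TestGenerateExplanation:
    def test_locality_mix_one_always_local(self):
        state = ObserverState.untrained()
        for seed in range(50):
            rec = generate_explanation(
                state, trial_id=seed, decision="P", locality_mix=1.0, seed=seed
            )
            assert rec.locality == "local"
            assert rec.cue_validity == 0.85
            assert rec.text

    def test_ser_s_uncorrelated_with_validity(self):
        """Self-ratings carry no information about explanation efficacy."""
        from embryoscope.sdt_analysis import pearson_corr

        state = ObserverState.untrained()
        rng = default_rng(4)
        recs = [
            generate_explanation(state, trial_id=i, decision="Q", seed=rng)
            for i in range(5000)
        ]
        res = pearson_corr(
            [r.ser_s for r in recs], [r.cue_validity for r in recs]
        )
        assert res.p_value > 0.01  # within CI of zero correlation

    def test_ser_s_in_range_and_mean_high(self):
        state = ObserverState.untrained()
        rng = default_rng(5)
        vals = [
            generate_explanation(state, trial_id=i, decision="P", seed=rng).ser_s
            for i in range(2000)
        ]
        assert min(vals) >= 0.0 and max(vals) <= 100.0
        assert np.mean(vals) > 70.0  # servers rate their explanations well

    def test_invalid_probability_rejected(self):
        state = ObserverState.untrained()
        with pytest.raises(ValueError):
            generate_explanation(state, 0, "P", locality_mix=1.5, seed=0)
        with pytest.raises(ValueError):
            generate_explanation(
                state, 0, "P", validity_by_locality={"local": 0.4, "global": 0.6},
                seed=0,
            )

    def test_template_bank_nonempty_both_classes(self):
        bank = load_template_bank()
        assert len(bank["local"]) >= 3
        assert len(bank["global"]) >= 3


def _mk_explanation(validity=0.85, trial_id=0):
    return ExplanationRecord(
        trial_id=trial_id,
        server_id="S1",
        text="Shading on the neck of P is darker.",
        locality="local" if validity > 0.7 else "global",
        cue_validity=validity,
        ser_s=90.0,
    )


class TestClientDecide:
    def test_full_compliance_copies_decision(self, pair, space):
        params = ClientParams(compliance_weight=1.0)
        for seed in range(30):
            trial = build_trial(pair, space, "client_eval", seed, trial_id=seed)
            out = client_decide(
                params, trial, "Q", _mk_explanation(), "expert", seed
            )
            assert out == "Q"

    def test_naive_source_ignored_entirely(self, pair, space):
        """Server data attributed to a naive source leaves accuracy at chance."""
        params = ClientParams()
        rng = default_rng(2)
        correct = 0
        n = 4000
        for i in range(n):
            trial = build_trial(pair, space, "client_eval", rng, trial_id=i)
            out = client_decide(
                params, trial, trial.true_label, _mk_explanation(), "naive", rng
            )
            correct += out == trial.true_label
        assert abs(correct / n - 0.5) < 0.025

    def test_decision_beats_explanation_beats_chance(self, pair, space, trained_server):
        """Expert-source ordering: decisions-only >= explanations-only > chance."""
        params = ClientParams()
        rng = default_rng(6)
        n = 4000
        acc = {"decision": 0, "explanation": 0}
        for i in range(n):
            trial = build_trial(pair, space, "client_eval", rng, trial_id=i)
            server_decision = trained_server.decide(trial.query, rng)
            out_d = client_decide(params, trial, server_decision, None, "expert", rng)
            out_e = client_decide(
                params, trial, None, _mk_explanation(0.85 if rng.random() < 0.5 else 0.55),
                "expert", rng,
            )
            acc["decision"] += out_d == trial.true_label
            acc["explanation"] += out_e == trial.true_label
        assert acc["decision"] >= acc["explanation"]
        assert acc["explanation"] / n > 0.55

    def test_compliance_monotonicity(self, pair, space, trained_server):
        """Expected accuracy is non-decreasing in compliance on expert data."""
        rng = default_rng(8)
        n = 3000
        trials = [
            build_trial(pair, space, "client_eval", rng, trial_id=i) for i in range(n)
        ]
        decisions = [trained_server.decide(t.query, rng) for t in trials]
        accs = []
        for w in (0.0, 0.5, 1.0):
            params = ClientParams(compliance_weight=w)
            correct = sum(
                client_decide(params, t, d, None, "expert", default_rng([j, int(w * 10)]))
                == t.true_label
                for j, (t, d) in enumerate(zip(trials, decisions))
            )
            accs.append(correct / n)
        assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02
        assert accs[2] > accs[0]


class TestClientRate:
    def test_zero_bias_equal_means(self):
        params = ClientParams(conformity_bias=0.0)
        rng = default_rng(0)
        expl = _mk_explanation()
        ours = {"expert": [], "naive": []}
        for src in ("expert", "naive"):
            for _ in range(2000):
                ours[src].append(client_rate(params, expl, src, rng).oer)
        diff = np.mean(ours["expert"]) - np.mean(ours["naive"])
        assert abs(diff) < 1.0

    def test_conformity_bias_recovery(self):
        """Injected 15-point expert-source bias is recovered to +/- 1 (n=5000)."""
        params = ClientParams(conformity_bias=15.0)
        rng = default_rng(1)
        expl = _mk_explanation()
        oer = {"expert": [], "naive": []}
        for src in ("expert", "naive"):
            for _ in range(5000):
                oer[src].append(client_rate(params, expl, src, rng).oer)
        diff = np.mean(oer["expert"]) - np.mean(oer["naive"])
        assert diff == pytest.approx(15.0, abs=1.0)

    def test_naive_our_oer_uncorrelated(self):
        from embryoscope.sdt_analysis import pearson_corr

        params = ClientParams()
        rng = default_rng(2)
        recs = [
            client_rate(params, _mk_explanation(v), "expert", rng)
            for v in np.where(default_rng(3).random(2000) < 0.5, 0.85, 0.55)
        ]
        res = pearson_corr([r.our for r in recs], [r.oer for r in recs])
        assert abs(res.statistic) < 0.06

    def test_expert_oer_tracks_validity_naive_does_not(self):
        rng = default_rng(4)
        for expertise, should_track in (("expert", True), ("naive", False)):
            params = ClientParams(expertise=expertise, conformity_bias=0.0)
            hi = np.mean(
                [client_rate(params, _mk_explanation(0.85), "expert", rng).oer
                 for _ in range(1500)]
            )
            lo = np.mean(
                [client_rate(params, _mk_explanation(0.55), "expert", rng).oer
                 for _ in range(1500)]
            )
            if should_track:
                assert hi - lo > 20.0
            else:
                assert abs(hi - lo) < 2.0

    def test_ratings_clipped_to_range(self):
        params = ClientParams(rating_noise_sd=60.0)
        rng = default_rng(5)
        for _ in range(300):
            rec = client_rate(params, _mk_explanation(), "expert", rng)
            assert 0.0 <= rec.our <= 100.0
            assert 0.0 <= rec.oer <= 100.0


class TestRecordValidation:
    def test_explanation_record_invariants(self):
        with pytest.raises(ValueError):
            _mk_explanation(validity=0.3)
        with pytest.raises(ValueError):
            ExplanationRecord(0, "S", "", "local", 0.8, 50.0)
        with pytest.raises(ValueError):
            ExplanationRecord(0, "S", "x", "local", 0.8, 120.0)

    def test_observer_state_invariants(self):
        with pytest.raises(ValueError):
            ObserverState(np.zeros(2), np.zeros(2), learning_rate=1.5)
        with pytest.raises(ValueError):
            ObserverState(np.zeros(2), np.zeros(2), perceptual_noise_sd=-1.0)

    def test_client_params_invariants(self):
        with pytest.raises(ValueError):
            ClientParams(compliance_weight=1.2)
        with pytest.raises(ValueError):
            ClientParams(expertise="guru")
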