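"""Experiment analyses: drift, ownership, skin conductance, screening."""

import numpy as np
import pandas as pd
import pytest

from rhibayes.analysis import (
    Exp1Record,
    SchemaError,
    baseline_bias,
    drift_inference,
    exclude_outliers,
    exp2_inference,
    load_exp1,
    load_exp2,
    normality_screen,
    ownership_drift_correlation,
    ownership_inference,
    proprioceptive_drift,
    scr_response,
    sign_test,
)
from rhibayes.synth import (
    Exp1GenConfig,
    Exp2GenConfig,
    generate_exp1,
    generate_exp2,
    write_exp1_csv,
    write_exp2_csv,
)


def _record(group="sync", pre=None, post=None, own=(1, 2), subject="s1", true_pos=None):
    pre = np.full(40, 300.0) if pre is None else np.asarray(pre, dtype=float)
    post = pre.copy() if post is None else np.asarray(post, dtype=float)
    return Exp1Record(
        subject=subject, group=group, pre=pre, post=post,
        pre_ownership=own[0], post_ownership=own[1], true_hand_position=true_pos,
    )


class TestDrift:
    def test_identical_pre_post_gives_zero_drift(self):
        assert proprioceptive_drift(_record()) == 0.0

    def test_uniform_shift_is_recovered_exactly(self):
        r = _record(pre=np.full(40, 300.0), post=np.full(40, 312.5))
        assert proprioceptive_drift(r) == pytest.approx(12.5)

    def test_empty_sequence_is_an_error(self):
        r = _record()
        r.pre = np.array([])
        with pytest.raises(ValueError):
            proprioceptive_drift(r)

    def test_injected_group_drift_recovered_with_nominal_ci_coverage(self):
        # per-group 95% CIs cover the injected drift at close to the
        # nominal rate over replicate cohorts
        from scipy import stats

        cfg = Exp1GenConfig()
        n_seeds = 40
        covered = {g: 0 for g in cfg.drift_means}
        for seed in range(n_seeds):
            res = drift_inference(generate_exp1(cfg, seed=seed))
            for g, injected in cfg.drift_means.items():
                grp = res.per_subject.query("group == @g")["drift_mm"]
                lo, hi = stats.t.interval(
                    0.95, len(grp) - 1, loc=grp.mean(), scale=grp.sem()
                )
                covered[g] += lo <= injected <= hi
        for g, hits in covered.items():
            assert hits / n_seeds >= 0.85, f"group {g}: coverage {hits / n_seeds}"

    def test_two_identical_groups_give_zero_pairwise_t(self):
        pre = np.linspace(280, 320, 40)
        recs = [
            _record(group=g, subject=f"{g}{i}", pre=pre, post=pre + (i % 5))
            for g in ("sync", "async") for i in range(6)
        ]
        res = drift_inference(recs)
        assert res.planned["sync_vs_async"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res.planned["sync_vs_async"]["d"] == pytest.approx(0.0, abs=1e-12)

    def test_optional_holm_adjustment_never_shrinks_p(self):
        records = generate_exp1(Exp1GenConfig(), seed=3)
        res = drift_inference(records, holm=True)
        assert len(res.planned) == 3
        for v in res.planned.values():
            assert v["p_one_tailed_holm"] >= v["p_one_tailed"] - 1e-15

    def test_row_order_invariance(self):
        records = generate_exp1(Exp1GenConfig(), seed=7)
        fwd = drift_inference(records)
        rev = drift_inference(records[::-1])
        assert fwd.anova == rev.anova
        assert fwd.per_group == rev.per_group


class TestOutliers:
    def test_identical_subjects_none_excluded(self):
        recs = [_record(subject=f"s{i}") for i in range(5)]
        kept, excluded = exclude_outliers(recs)
        assert len(kept) == 5 and not excluded

    def test_displaced_subject_is_the_one_excluded(self):
        rng = np.random.default_rng(0)
        recs = [
            _record(subject=f"s{i}", pre=rng.normal(300, 10, 40)) for i in range(20)
        ]
        recs.append(_record(subject="shifted", pre=rng.normal(300, 10, 40) + 5 * 10.5))
        kept, excluded = exclude_outliers(recs, k=3.0)
        assert [r.subject for r in excluded] == ["shifted"]

    def test_infinite_threshold_excludes_none(self):
        rng = np.random.default_rng(1)
        recs = [_record(subject=f"s{i}", pre=rng.normal(300, 50, 40)) for i in range(10)]
        kept, excluded = exclude_outliers(recs, k=np.inf)
        assert not excluded

    def test_statistics_computed_once_not_rescreened(self):
        # the huge outlier inflates the one-pass sample SD; a subject at
        # ~2 input-SDs survives, though re-screening after the removal of
        # the huge outlier would have rejected it
        base = np.full(40, 300.0)
        recs = [_record(subject=f"s{i}", pre=base + (i % 3)) for i in range(30)]
        recs.append(_record(subject="huge", pre=base + 500.0))
        means = np.array([r.pre.mean() for r in recs])
        sd = means.std(ddof=1)
        recs.append(_record(subject="edge", pre=base + 2.0 * sd))
        kept, excluded = exclude_outliers(recs, k=3.0)
        names = {r.subject for r in excluded}
        assert "huge" in names and "edge" not in names
        # the edge subject is far beyond 3 SDs of the huge-free sample
        clean = np.array([r.pre.mean() for r in recs if r.subject != "huge"])
        z_edge = abs(clean[-1] - clean.mean()) / clean.std(ddof=1)
        assert z_edge > 3.0


class TestOwnership:
    def test_unanimous_agreement_has_closed_form_sign_test(self):
        recs = [_record(subject=f"s{i}", own=(3, 3)) for i in range(8)]
        out = ownership_inference(recs)
        assert out["pooled_pre"]["fraction_positive"] == 1.0
        assert out["pooled_pre"]["sign_test"]["p"] == pytest.approx(2 * 0.5**8)

    def test_symmetric_ratings_have_null_sign_test(self):
        recs = [
            _record(subject=f"p{i}", own=(v, v))
            for i, v in enumerate([1, -1, 2, -2, 3, -3])
        ]
        out = ownership_inference(recs)
        assert out["pooled_pre"]["median"] == 0.0
        assert out["pooled_pre"]["sign_test"]["p"] == pytest.approx(1.0)

    def test_zeros_are_dropped_from_the_sign_test(self):
        res = sign_test([0, 0, 1, 2, 3])
        assert res["n"] == 3 and res["p"] == pytest.approx(2 * 0.5**3)
        with pytest.raises(ValueError):
            sign_test([0, 0, 0])

    def test_perfect_coupling_gives_unit_correlation(self):
        recs = []
        for i, own in enumerate([-2, -1, 0, 1, 2, 3]):
            pre = np.full(40, 300.0)
            recs.append(
                _record(subject=f"s{i}", own=(own, own), pre=pre, post=pre + 4.0 * own)
            )
        r, p = ownership_drift_correlation(recs, phase="post")
        assert r == pytest.approx(1.0)

    def test_correlation_requires_variance(self):
        recs = [_record(subject=f"s{i}", own=(2, 2)) for i in range(5)]
        with pytest.raises(ValueError):
            ownership_drift_correlation(recs, phase="post")


class TestSCR:
    def _trace(self, duration=30.0):
        t = np.arange(0, duration + 0.05, 0.1)
        return t, np.full_like(t, 8.0)

    def test_constant_trace_gives_zero_response(self):
        t, c = self._trace()
        res = scr_response(t, c, event_time=5.0)
        assert res["raw"] == 0.0 and res["transformed"] == 0.0

    def test_step_inside_window_gives_step_height(self):
        t, c = self._trace()
        c = c + 0.8 * (t >= 8.0)   # step at event + 3 s
        res = scr_response(t, c, event_time=5.0)
        assert res["raw"] == pytest.approx(0.8)
        assert res["transformed"] == pytest.approx(np.log10(1.8))

    def test_additive_baseline_shift_is_invariant(self):
        t, c = self._trace()
        rng = np.random.default_rng(0)
        c = c + rng.normal(0, 0.05, c.size)
        a = scr_response(t, c, event_time=5.0)
        b = scr_response(t, c + 3.7, event_time=5.0)
        assert a["raw"] == pytest.approx(b["raw"], rel=1e-12)

    def test_integer_upsampling_is_invariant(self):
        t, c = self._trace()
        c = c + 0.5 * (t >= 7.0) - 0.2 * (t >= 9.0)
        a = scr_response(t, c, event_time=5.0)
        t2 = np.arange(0, 30.0 + 0.025, 0.05)
        c2 = np.interp(t2, t, c)
        b = scr_response(t2, c2, event_time=5.0)
        assert a["raw"] == pytest.approx(b["raw"], rel=1e-12)

    def test_window_outside_trace_is_an_error(self):
        t, c = self._trace(duration=4.0)
        with pytest.raises(ValueError):
            scr_response(t, c, event_time=1.0)   # window would end at 6 s

    def test_window_endpoints_are_included(self):
        t, c = self._trace()
        c = c.copy()
        c[100] = 9.0    # the sample at exactly event + 5 s
        assert t[100] == pytest.approx(10.0)
        res = scr_response(t, c, event_time=5.0)
        assert res["raw"] == pytest.approx(1.0)


class TestExp2Inference:
    def test_identical_traces_give_null_anova(self):
        cfg = Exp2GenConfig(
            amp_eye={"plausible_arm": (0.0, 1e-9), "hanging_arm": (0.0, 1e-9),
                     "no_arm": (0.0, 1e-9)},
            noise_sd=0.01,
        )
        records = generate_exp2(cfg, seed=3)
        out = exp2_inference(records)
        assert out["eye_opening"]["anova"]["p"] > 0.05

    def test_strong_group_effect_is_detected(self):
        records = generate_exp2(Exp2GenConfig(), seed=5)
        out = exp2_inference(records)
        assert out["eye_opening"]["anova"]["p"] < 0.01
        assert out["threat"]["anova"]["p"] < 0.01
        assert out["eye_opening"]["plausible_vs_hanging_arm"]["d"] > 0
        assert out["ownership"]["plausible_arm"]["median"] >= 1.0
        assert out["ownership"]["hanging_arm"]["median"] <= -1.0

    def test_coupling_produces_positive_ownership_scr_correlation(self):
        records = generate_exp2(Exp2GenConfig(), seed=8)
        out = exp2_inference(records)
        assert out["ownership_scr_correlation"]["eye_opening"]["r"] > 0.3


class TestBiasAndNormality:
    def test_perfect_localization_has_zero_bias(self):
        recs = [
            _record(subject=f"s{i}", pre=np.full(40, 320.0), true_pos=320.0)
            for i in range(6)
        ]
        # zero spread across subjects: t is undefined, bias must still be 0
        out = baseline_bias(recs)
        assert out["available"] and out["mean_bias_mm"] == pytest.approx(0.0)

    def test_unavailable_without_true_position(self):
        out = baseline_bias([_record(subject="a"), _record(subject="b")])
        assert out["available"] is False

    def test_injected_bias_and_sd_recovered_within_ci(self):
        cfg = Exp1GenConfig()
        records = generate_exp1(cfg, seed=11)
        out = baseline_bias(records)
        se_bias = np.hypot(cfg.between_subject_sd,
                           cfg.within_subject_sd / np.sqrt(40)) / np.sqrt(len(records))
        assert out["mean_bias_mm"] == pytest.approx(cfg.baseline_bias, abs=3 * se_bias)
        # per-subject sample SD estimates c4 * sigma; compare to that expectation
        n = cfg.n_localizations
        from scipy.special import gammaln
        c4 = np.exp(gammaln(n / 2) - gammaln((n - 1) / 2)) * np.sqrt(2 / (n - 1))
        se_sd = cfg.within_subject_sd / np.sqrt(2 * (n - 1)) / np.sqrt(len(records))
        assert out["mean_within_subject_sd_mm"] == pytest.approx(
            c4 * cfg.within_subject_sd, abs=3 * se_sd
        )

    def test_gaussian_cohort_passes_normality_screen(self):
        records = generate_exp1(Exp1GenConfig(), seed=23)
        out = normality_screen(records)
        for frac in out["pass_fraction"].values():
            assert frac >= 0.90

    def test_heavy_tails_fail_shapiro_wilk(self):
        rng = np.random.default_rng(0)
        recs = [
            _record(subject=f"s{i}", pre=300 + 13 * rng.standard_t(2, size=40))
            for i in range(25)
        ]
        out = normality_screen(recs)
        assert out["pass_fraction"]["shapiro_wilk"] < 0.5

    def test_constant_sequences_are_flagged(self):
        recs = [_record(subject=f"s{i}") for i in range(3)]
        recs.append(_record(subject="ok", pre=np.random.default_rng(0).normal(300, 10, 40)))
        out = normality_screen(recs)
        assert set(out["flagged_subjects"]) == {"s0", "s1", "s2"}
        assert out["n_evaluated"] == 1


class TestIO:
    def test_exp1_csv_round_trip(self, tmp_path):
        records = generate_exp1(Exp1GenConfig(n_per_group=3), seed=2)
        path = tmp_path / "exp1.csv"
        write_exp1_csv(records, path)
        loaded = load_exp1(path)
        assert len(loaded) == len(records)
        for a, b in zip(records, loaded):
            assert a.subject == b.subject and a.group == b.group
            np.testing.assert_array_equal(a.pre, b.pre)
            np.testing.assert_array_equal(a.post, b.post)
            assert (a.pre_ownership, a.post_ownership) == (b.pre_ownership, b.post_ownership)
            assert a.true_hand_position == b.true_hand_position

    def test_exp2_csv_round_trip(self, tmp_path):
        records = generate_exp2(Exp2GenConfig(n_per_group=2, duration_s=40.0,
                                              event_times={"eye_opening": 10.0,
                                                           "threat": 25.0}), seed=4)
        write_exp2_csv(records, tmp_path)
        loaded = load_exp2(tmp_path / "subjects.csv")
        assert len(loaded) == len(records)
        for a, b in zip(records, loaded):
            assert a.subject == b.subject and a.ownership == b.ownership
            np.testing.assert_allclose(a.conductance, b.conductance, rtol=1e-12)

    def test_missing_column_names_the_column(self, tmp_path):
        df = pd.DataFrame({"subject": ["a"], "pre_1": [300.0]})
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="group"):
            load_exp1(p)

    def test_short_localization_row_warns_but_loads(self, tmp_path):
        with pytest.warns(UserWarning, match="39"):
            records = generate_exp1(Exp1GenConfig(n_per_group=2, n_localizations=39), seed=2)
        path = tmp_path / "short.csv"
        write_exp1_csv(records, path)
        with pytest.warns(UserWarning, match="39 localizations"):
            loaded = load_exp1(path)
        assert all(r.pre.size == 39 for r in loaded)

    def test_non_numeric_localization_is_a_parse_error(self, tmp_path):
        records = generate_exp1(Exp1GenConfig(n_per_group=2), seed=2)
        path = tmp_path / "exp1.csv"
        write_exp1_csv(records, path)
        df = pd.read_csv(path)
        df.loc[1, "pre_3"] = "oops"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="row 1"):
            load_exp1(path)
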