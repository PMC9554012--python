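"""Importance-performance analysis: performance means, thresholds, quadrants."""

import numpy as np
import pytest

import mcdmkit as mk
from conftest import build_panel


def test_mean_performance_simple_cases(toy_instrument):
    crits = toy_instrument.criterion_ids
    groups = toy_instrument.groups()
    chains = {gid: [0.5] * (len(m) - 1) for gid, m in groups.items()}
    panel = build_panel(
        toy_instrument,
        {r: chains for r in ("r1", "r2", "r3")},
        {
            "r1": {c: (3 if c == "D11" else 5) for c in crits},
            "r2": {c: (4 if c == "D11" else 5) for c in crits},
            "r3": {c: 5 for c in crits},
        },
    )
    perf = mk.mean_performance(panel)
    assert perf["D11"] == pytest.approx(4.0)
    assert perf["D12"] == pytest.approx(5.0)


def test_mean_performance_reverse_coding():
    inst = mk.Instrument.model_validate(
        {
            "name": "rev",
            "dimensions": [
                {"id": "D1", "criteria": [
                    {"id": "D11", "reverse_worded": True}, {"id": "D12"}]},
            ],
        }
    )
    groups = inst.groups()
    chains = {gid: [0.5] * (len(m) - 1) for gid, m in groups.items()}
    panel = build_panel(inst, {"r1": chains}, {"r1": {"D11": 2, "D12": 2}})
    raw = mk.mean_performance(panel)
    rev = mk.mean_performance(panel, reverse_code=True)
    assert raw["D11"] == 2.0 and rev["D11"] == 4.0  # 6 - x on flagged item only
    assert raw["D12"] == rev["D12"] == 2.0


def test_mean_performance_recovers_latent_mean_at_large_n():
    """Sampling check: n = 500 synthetic ratings around mu = 4.2, sigma = 0.5
    recover the discretized mean within ~2 standard errors."""
    cfg = mk.hhnjs_generator_config(seed=11, n=500, judgment_noise=0.0, rating_noise=0.5)
    cfg.true_performance = {c: 4.2 for c in cfg.instrument.criterion_ids}
    panel = mk.generate_panel(cfg)
    perf = mk.mean_performance(panel)
    # ratings are rounded to 1..5, so compare against the mean of the
    # discretized distribution rather than 4.2 itself
    from scipy.stats import norm

    edges = np.array([1.5, 2.5, 3.5, 4.5])
    cdf = norm.cdf(edges, loc=4.2, scale=0.5)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    discrete_mean = (np.arange(1, 6) * probs).sum()
    discrete_sd = np.sqrt((np.arange(1, 6) ** 2 * probs).sum() - discrete_mean**2)
    se = discrete_sd / np.sqrt(500)
    deviations = np.abs(perf.to_numpy() - discrete_mean)
    assert deviations.mean() < 2 * se
    assert deviations.max() < 4 * se  # max over 30 criteria needs headroom


class TestThresholds:
    def test_scale_midpoint(self):
        t = mk.compute_thresholds([0.1] * 30, [3.5] * 30, strategy="scale_midpoint")
        assert t.tau_performance == 3.0
        assert t.tau_importance == pytest.approx(1 / 30)

    def test_fixed_echoes_values(self):
        t = mk.compute_thresholds(
            [0.1], [3.0], strategy="fixed", tau_importance=0.0304, tau_performance=3.7688
        )
        assert (t.tau_importance, t.tau_performance) == (0.0304, 3.7688)

    def test_fixed_requires_both_values(self):
        with pytest.raises(ValueError, match="fixed strategy requires"):
            mk.compute_thresholds([0.1], [3.0], strategy="fixed", tau_importance=0.03)

    def test_grand_mean_matches_summation_oracle(self, reference_ipa):
        perf = reference_ipa["performance"].to_numpy()
        imp = reference_ipa["importance"].to_numpy()
        t = mk.compute_thresholds(imp, perf, strategy="grand_mean")
        assert t.tau_performance == pytest.approx(sum(perf) / len(perf), abs=1e-12)
        assert t.tau_importance == pytest.approx(sum(imp) / len(imp), abs=1e-12)

    def test_median_strategy(self):
        t = mk.compute_thresholds([0.1, 0.2, 0.6], [2.0, 3.0, 5.0], strategy="median")
        assert (t.tau_importance, t.tau_performance) == (0.2, 3.0)


class TestClassification:
    @pytest.mark.parametrize(
        "imp, perf, expected",
        [
            (0.0432, 3.7742, "I"),   # high importance, high performance
            (0.0147, 3.9032, "II"),  # low importance, high performance
            (0.0159, 3.0, "III"),    # low importance, low performance
            (0.0469, 3.0, "IV"),     # high importance, low performance
            (0.0304, 3.7688, "I"),   # exactly at both thresholds counts high
        ],
    )
    def test_quadrant_rules(self, imp, perf, expected):
        t = mk.Thresholds("fixed", 0.0304, 3.7688)
        out = mk.classify_quadrants(["x"], [imp], [perf], t)
        assert out.table["quadrant"].iloc[0] == expected

    def test_partition_every_criterion_in_one_quadrant(self, reference_ipa):
        t = mk.compute_thresholds(
            reference_ipa["importance"], reference_ipa["performance"], "grand_mean"
        )
        out = mk.classify_quadrants(
            reference_ipa["criterion"],
            reference_ipa["importance"],
            reference_ipa["performance"],
            t,
        )
        counts = out.quadrant_counts()
        assert sum(counts.values()) == len(reference_ipa)
        assert set(out.table["quadrant"]) <= {"I", "II", "III", "IV"}

    def test_raising_performance_threshold_only_demotes(self, reference_ipa):
        """Moving tau_performance up can push criteria I->IV and II->III,
        never the other way."""
        imp = reference_ipa["importance"]
        perf = reference_ipa["performance"]
        lo = mk.classify_quadrants(
            reference_ipa["criterion"], imp, perf, mk.Thresholds("fixed", 0.0304, 3.5)
        ).table["quadrant"]
        hi = mk.classify_quadrants(
            reference_ipa["criterion"], imp, perf, mk.Thresholds("fixed", 0.0304, 4.0)
        ).table["quadrant"]
        allowed = {("I", "I"), ("I", "IV"), ("II", "II"), ("II", "III"),
                   ("III", "III"), ("IV", "IV")}
        assert set(zip(lo, hi)) <= allowed
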