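import numpy as np
import pandas as pd
import pytest

from navkit.stats import (DesignError, interaction_anova, log10_tau_table,
                          per_voltage_tests)


def _table(rng, means, n=10, sd=1.0):
    """Balanced 2x2 data; means indexed by (genotype, temperature)."""
    rows = []
    for (g, t), mu in means.items():
        for _ in range(n):
            rows.append({"genotype": g, "temperature": t,
                         "y": mu + (sd and rng.normal(0, sd))})
    return pd.DataFrame(rows)


def _anova_oracle_additive(df):
    """From-scratch Type-II sums of squares for a balanced 2x2 design
    (effects computed from marginal means)."""
    y = df["y"].to_numpy()
    n = len(df)
    grand = y.mean()
    ss = {}
    for factor in ("genotype", "temperature"):
        levels = df[factor].unique()
        ss[factor] = sum(
            (df.loc[df[factor] == lv, "y"].mean() - grand) ** 2
            * (df[factor] == lv).sum() for lv in levels)
    cell_means = df.groupby(["genotype", "temperature"])["y"].transform("mean")
    ss_within = float(((y - cell_means) ** 2).sum())
    gm = df.groupby("genotype")["y"].transform("mean")
    tm = df.groupby("temperature")["y"].transform("mean")
    ss_inter = float(((cell_means - gm - tm + grand) ** 2).sum())
    df_resid = n - 4
    return {
        "genotype": (ss["genotype"] / 1) / ((ss_within + ss_inter) / (n - 3)),
        "temperature": (ss["temperature"] / 1) / ((ss_within + ss_inter) / (n - 3)),
    }


def _permutation_interaction_p(df, n_perm=500, seed=0):
    """Permutation oracle for the interaction: F statistic under label
    permutation of responses."""
    def inter_f(frame):
        res = interaction_anova(frame, "y", alpha=1.1)  # always full model
        return res.effect("C(genotype):C(temperature)").F

    rng = np.random.default_rng(seed)
    f_obs = inter_f(df)
    count = 0
    y = df["y"].to_numpy()
    for _ in range(n_perm):
        perm = df.copy()
        perm["y"] = rng.permutation(y)
        if inter_f(perm) >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def test_zero_variance_equal_means_all_null():
    df = _table(np.random.default_rng(0),
                {("WT", 22): 5.0, ("WT", 37): 5.0,
                 ("LQ", 22): 5.0, ("LQ", 37): 5.0}, sd=0.0)
    res = interaction_anova(df, "y")
    for e in res.effects:
        assert e.F == pytest.approx(0.0)
        assert e.p == pytest.approx(1.0)


def test_pure_interaction_detected_and_matches_permutation_oracle():
    """A pure interaction of 3 residual SDs at n=10/cell is detected at
    p < 0.001 by the F test and confirmed by a permutation test."""
    rng = np.random.default_rng(42)
    df = _table(rng, {("WT", 22): 0.0, ("WT", 37): 3.0,
                      ("LQ", 22): 3.0, ("LQ", 37): 0.0}, n=10, sd=1.0)
    res = interaction_anova(df, "y")
    assert not res.stepdown_applied
    p = res.effect("C(genotype):C(temperature)").p
    assert p < 1e-3
    assert _permutation_interaction_p(df) < 0.01


def test_stepdown_reports_main_effects():
    rng = np.random.default_rng(8)
    df = _table(rng, {("WT", 22): 0.0, ("WT", 37): 2.0,
                      ("LQ", 22): 1.0, ("LQ", 37): 3.0}, n=12, sd=1.0)
    res = interaction_anova(df, "y")
    assert res.stepdown_applied
    assert res.effect("C(genotype)").p < 0.05
    assert res.effect("C(temperature)").p < 0.05


def test_additive_f_statistics_match_sum_of_squares_oracle():
    rng = np.random.default_rng(3)
    df = _table(rng, {("WT", 22): 0.0, ("WT", 37): 1.0,
                      ("LQ", 22): 0.5, ("LQ", 37): 1.5}, n=8, sd=1.0)
    res = interaction_anova(df, "y")
    assert res.stepdown_applied
    oracle = _anova_oracle_additive(df)
    assert res.effect("C(genotype)").F == pytest.approx(
        oracle["genotype"], rel=1e-8)
    assert res.effect("C(temperature)").F == pytest.approx(
        oracle["temperature"], rel=1e-8)


def test_row_order_invariance():
    rng = np.random.default_rng(11)
    df = _table(rng, {("WT", 22): 0.0, ("WT", 37): 1.0,
                      ("LQ", 22): 0.3, ("LQ", 37): 1.6}, n=9, sd=1.0)
    shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
    a = interaction_anova(df, "y")
    b = interaction_anova(shuffled, "y")
    for ea, eb in zip(a.effects, b.effects):
        assert ea.F == pytest.approx(eb.F, rel=1e-12)


def test_empty_cell_raises():
    rng = np.random.default_rng(0)
    df = _table(rng, {("WT", 22): 0.0, ("WT", 37): 1.0,
                      ("LQ", 22): 0.5}, n=5, sd=1.0)
    with pytest.raises(DesignError):
        interaction_anova(df, "y")


def test_power_increases_with_effect_size():
    """Main-effect p-values shrink monotonically as the genotype effect
    grows, on matched noise realizations."""
    ps = []
    for effect in (0.3, 1.0, 3.0):
        rng = np.random.default_rng(100)  # same noise stream per size
        df = _table(rng, {("WT", 22): 0.0, ("WT", 37): 0.0,
                          ("LQ", 22): effect, ("LQ", 37): effect},
                    n=8, sd=1.0)
        ps.append(interaction_anova(df, "y").effect("C(genotype)").p)
    assert ps[0] > ps[1] > ps[2]


class TestPerVoltage:
    def _tau_table(self, rng, ratio=1.0, n=8, cv=0.05):
        grid = [-30.0, -20.0, -10.0, 0.0, 10.0, 20.0]
        base = {v: 0.5 - 0.005 * v for v in grid}
        rows = []
        for g, scale in (("WT", 1.0), ("LQ", 1.0 / ratio)):
            for i in range(n):
                cell_factor = np.exp(rng.normal(0, cv)) if cv else 1.0
                for v in grid:
                    rows.append({"cell_id": f"{g}{i}", "genotype": g,
                                 "voltage": v,
                                 "tau_ms": base[v] * scale * cell_factor})
        return pd.DataFrame(rows)

    def test_identical_taus_not_significant(self):
        df = self._tau_table(np.random.default_rng(0), ratio=1.0, cv=0.0)
        df = log10_tau_table(df)
        for v, p in per_voltage_tests(df, response="log10_tau_ms"):
            assert p > 0.99

    def test_rate_ratio_detected_at_every_voltage(self):
        df = self._tau_table(np.random.default_rng(8), ratio=1.485, cv=0.05)
        df = log10_tau_table(df)
        for v, p in per_voltage_tests(df, response="log10_tau_ms"):
            assert p < 0.05

    def test_single_cell_group_raises(self):
        df = self._tau_table(np.random.default_rng(0), n=1)
        df = log10_tau_table(df)
        with pytest.raises(DesignError):
            per_voltage_tests(df, response="log10_tau_ms")

    def test_non_positive_tau_rejected(self):
        df = self._tau_table(np.random.default_rng(0))
        df.loc[3, "tau_ms"] = -0.1
        with pytest.raises(DesignError):
            log10_tau_table(df)
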