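"""Group statistics for genotype x temperature electrophysiology cohorts.

The analysis plan mirrors common practice for two crossed two-level
factors: a fixed-effects two-way ANOVA including the genotype x
temperature interaction (the test of differential temperature
sensitivity); when the interaction is not significant at alpha, the
model is refit additively and the two main effects are evaluated
independently (Type-II sums of squares, which matter for the unbalanced
cohorts).  Fast-inactivation onset time constants are log10-transformed
before analysis, and genotype contrasts at each voltage on the
-30..+20 mV grid use Welch's unequal-variance t-test with no additional
multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = ["AnovaResult", "EffectResult", "DesignError",
           "interaction_anova", "per_voltage_tests", "log10_tau_table"]

ALPHA = 0.05


class DesignError(ValueError):
    """The design is too deficient to test the requested effects."""


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df: tuple  # (df_effect, df_residual)
    p: float


@dataclass
class AnovaResult:
    """Two-way ANOVA outcome.

    ``effects`` holds the reported tests: from the interaction model if
    the interaction is significant, otherwise the additive-model main
    effects plus the (non-significant) interaction test that triggered
    the stepdown.  ``stepdown_applied`` records which path was taken.
    """
    effects: List[EffectResult]
    alpha: float = ALPHA
    stepdown_applied: bool = False
    response: str = ""

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(f"no effect named {name!r}; have "
                       f"{[e.name for e in self.effects]}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"effect": e.name, "F": e.F, "df1": e.df[0], "df2": e.df[1],
                 "p": e.p, "significant": e.p < self.alpha}
                for e in self.effects]
        return pd.DataFrame(rows)


def _check_design(table: pd.DataFrame, response: str,
                  factors=("genotype", "temperature")) -> pd.DataFrame:
    for col in (*factors, response):
        if col not in table.columns:
            raise DesignError(f"table lacks column {col!r}")
    df = table.dropna(subset=[response])
    if df[response].isna().any() or len(df) < len(table):
        raise DesignError(f"missing responses in {response!r}")
    counts = df.groupby(list(factors), observed=True).size()
    if len(counts) < 4:
        raise DesignError(
            f"empty factor cell: only {len(counts)} of 4 genotype x "
            f"temperature cells populated")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DesignError(f"fewer than 2 cells per group in {bad}")
    return df


def _anova_effects(table: pd.DataFrame, formula: str, response: str):
    model = smf.ols(formula, data=table).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    df_resid = float(tab.loc["Residual", "df"])
    effects = []
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    for name in tab.index:
        if name == "Residual":
            continue
        F = float(tab.loc[name, "F"])
        p = float(tab.loc[name, "PR(>F)"])
        if not np.isfinite(F):
            # 0/0 designs (zero residual variance): an effect with zero
            # sum of squares carries no evidence, one with positive sum
            # of squares against zero residual is unambiguous.
            ss = float(tab.loc[name, "sum_sq"])
            if ss <= 1e-12 * max(ss_resid, 1.0):
                F, p = 0.0, 1.0
            else:
                F, p = float("inf"), 0.0
        effects.append(EffectResult(
            name=name,
            F=F,
            df=(int(tab.loc[name, "df"]), int(df_resid)),
            p=p,
        ))
    return effects


def interaction_anova(table: pd.DataFrame, response: str,
                      alpha: float = ALPHA) -> AnovaResult:
    """Two-way genotype x temperature ANOVA with interaction stepdown.

    Parameters
    ----------
    table : DataFrame
        Long-format measurements with columns ``genotype``,
        ``temperature`` (each a 2-level factor) and `response`.
    response : str
        Name of the numeric response column.
    alpha : float
        Significance level for the stepdown decision (default 0.05).

    Returns
    -------
    AnovaResult
        If the interaction is significant, the full interaction-model
        table.  Otherwise the additive-model main effects (Type-II)
        plus the interaction test, with ``stepdown_applied=True``.
    """
    df = _check_design(table, response).copy()
    df["_y"] = df[response].astype(float)
    if float(np.var(df["_y"])) == 0.0:
        # all responses identical: no effect carries any evidence
        n = len(df)
        effects = [EffectResult(name, 0.0, (1, n - 4), 1.0)
                   for name in ("C(genotype)", "C(temperature)",
                                "C(genotype):C(temperature)")]
        return AnovaResult(effects=effects, alpha=alpha,
                           stepdown_applied=True, response=response)
    full = _anova_effects(
        df, "_y ~ C(genotype) * C(temperature)", response)
    inter = next(e for e in full if ":" in e.name)
    # Degenerate zero-variance designs give nan F; treat as no evidence
    # of interaction.
    inter_p = inter.p if np.isfinite(inter.p) else 1.0
    if inter_p < alpha:
        return AnovaResult(effects=full, alpha=alpha,
                           stepdown_applied=False, response=response)
    additive = _anova_effects(df, "_y ~ C(genotype) + C(temperature)", response)
    return AnovaResult(effects=additive + [inter], alpha=alpha,
                       stepdown_applied=True, response=response)


def log10_tau_table(table: pd.DataFrame, response: str = "tau_ms") -> pd.DataFrame:
    """Return a copy with `response` log10-transformed into
    ``log10_<response>``.  Non-positive values raise
    :class:`DesignError` naming the offending rows."""
    bad = table.index[~(table[response] > 0)].tolist()
    if bad:
        raise DesignError(
            f"non-positive {response!r} cannot be log-transformed "
            f"(rows {bad[:10]})")
    out = table.copy()
    out[f"log10_{response}"] = np.log10(table[response].astype(float))
    return out


def per_voltage_tests(table: pd.DataFrame, response: str,
                      voltage_col: str = "voltage",
                      group_col: str = "genotype") -> List[tuple]:
    """Genotype contrast at each voltage (Welch's t-test).

    Parameters
    ----------
    table : DataFrame
        Long-format per-cell values at a single temperature, with a
        voltage column, the 2-level grouping factor, and the (already
        transformed, e.g. log10 tau) response.

    Returns
    -------
    list of (voltage, p) sorted by voltage.  No multiplicity
    correction is applied.
    """
    for col in (voltage_col, group_col, response):
        if col not in table.columns:
            raise DesignError(f"table lacks column {col!r}")
    levels = sorted(table[group_col].unique())
    if len(levels) != 2:
        raise DesignError(f"{group_col!r} must have exactly 2 levels, "
                          f"got {levels}")
    out = []
    for v in sorted(table[voltage_col].unique()):
        sub = table[table[voltage_col] == v]
        a = sub.loc[sub[group_col] == levels[0], response].dropna().to_numpy()
        b = sub.loc[sub[group_col] == levels[1], response].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise DesignError(
                f"need >= 2 cells per group at {v} mV, got {len(a)}/{len(b)}")
        if np.var(a) == 0 and np.var(b) == 0:
            # degenerate noise-free groups: identical means carry no
            # evidence, distinct constant means are unambiguous
            p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        else:
            _, p = sps.ttest_ind(a, b, equal_var=False)
        out.append((float(v), float(p)))
    return out
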