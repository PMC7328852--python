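"""Factorial statistics for the 3x2 (time x volume) study design.

The study crosses exposure time (60, 120, 300 s) with applied volume
(20, 40 uL). Analysis follows the standard SPSS-style factorial workflow:

- fixed-effects two-way ANOVA with interaction (Type III sums of squares
  with sum-to-zero contrasts, so unbalanced cells are handled the way the
  usual factorial software defaults do),
- Tukey HSD post hoc contrasts on factors with >= 3 levels, using the
  factorial residual mean square as the error term,
- simple-effects decomposition of the interaction: each factor tested
  within every level of the other, against the pooled omnibus residual.

Outcomes are analysed one at a time; no multiplicity adjustment is applied
across outcomes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "FactorialDataset",
    "two_way_anova",
    "tukey_hsd",
    "simple_effects",
    "summarize_groups",
    "table1_markdown",
    "TIME_LEVELS",
    "VOLUME_LEVELS",
]

TIME_LEVELS: tuple[int, ...] = (60, 120, 300)
VOLUME_LEVELS: tuple[int, ...] = (20, 40)

_FACTOR_A = "time_s"
_FACTOR_B = "volume_ul"


@dataclass(frozen=True)
class FactorialDataset:
    """Long-format per-sample outcomes tagged with the two factor levels.

    ``data`` needs columns ``sample_id``, ``time_s``, ``volume_ul`` plus one
    column per outcome. Factor levels outside the declared sets are
    rejected so coding mistakes surface early.
    """

    data: pd.DataFrame
    time_levels: tuple[int, ...] = TIME_LEVELS
    volume_levels: tuple[int, ...] = VOLUME_LEVELS

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        for col in ("sample_id", _FACTOR_A, _FACTOR_B):
            if col not in df.columns:
                raise ValueError(f"missing required column '{col}'")
        bad_t = set(df[_FACTOR_A].unique()) - set(self.time_levels)
        bad_v = set(df[_FACTOR_B].unique()) - set(self.volume_levels)
        if bad_t or bad_v:
            raise ValueError(
                f"factor levels outside the declared sets: time {sorted(bad_t)}, "
                f"volume {sorted(bad_v)}")
        object.__setattr__(self, "data", df)

    def outcomes(self) -> list[str]:
        reserved = {"sample_id", _FACTOR_A, _FACTOR_B}
        return [c for c in self.data.columns
                if c not in reserved and pd.api.types.is_numeric_dtype(self.data[c])]


def _check_design(df: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if outcome not in df.columns:
        raise KeyError(f"outcome '{outcome}' not in dataset")
    sub = df[[_FACTOR_A, _FACTOR_B, outcome]].dropna()
    for fac in (_FACTOR_A, _FACTOR_B):
        if sub[fac].nunique() < 2:
            raise ValueError(f"factor '{fac}' needs >= 2 occupied levels")
    cells = sub.groupby([_FACTOR_A, _FACTOR_B], observed=True)[outcome].count()
    expected = set(itertools.product(sub[_FACTOR_A].unique(),
                                     sub[_FACTOR_B].unique()))
    empty = sorted((int(a), int(b)) for a, b in expected - set(cells.index))
    if empty:
        raise ValueError(
            f"interaction is not estimable; empty design cells: {empty}")
    n = len(sub)
    df_model = sub[_FACTOR_A].nunique() * sub[_FACTOR_B].nunique()
    if n - df_model <= 0:
        raise ValueError(
            f"residual df would be {n - df_model} (<= 0); "
            "need >= 2 observations in at least one cell")
    return sub


def two_way_anova(dataset: FactorialDataset, outcome: str) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction (Type III SS).

    Returns a table indexed by ``Time``, ``Volume``, ``Time:Volume`` and
    ``Residual`` with columns ``sum_sq``, ``df``, ``mean_sq``, ``F`` and
    ``p``. Sum-to-zero contrasts make the Type III tests match the default
    factorial output of the common statistics packages; on balanced data
    they coincide with the classical decomposition.
    """
    sub = _check_design(dataset.data, outcome).rename(columns={outcome: "_y"})
    model = smf.ols(
        f"_y ~ C({_FACTOR_A}, Sum) * C({_FACTOR_B}, Sum)", data=sub
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        table = anova_lm(model, typ=3)
    rename = {
        f"C({_FACTOR_A}, Sum)": "Time",
        f"C({_FACTOR_B}, Sum)": "Volume",
        f"C({_FACTOR_A}, Sum):C({_FACTOR_B}, Sum)": "Time:Volume",
    }
    table = table.rename(index=rename).drop(index="Intercept")
    table = table.rename(columns={"PR(>F)": "p"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return table[["sum_sq", "df", "mean_sq", "F", "p"]]


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise Tukey HSD contrasts, or a notice when the test was skipped."""

    contrasts: pd.DataFrame
    notice: str | None = None

    @property
    def skipped(self) -> bool:
        return self.notice is not None


def tukey_hsd(dataset: FactorialDataset, factor: str, outcome: str) -> PosthocResult:
    """All pairwise level contrasts of ``factor`` with Tukey HSD adjustment.

    Marginal level means are compared with the studentized-range
    distribution, using the two-way ANOVA residual mean square and df as the
    error term (Tukey-Kramer standard error for unequal level sizes). A
    factor with fewer than 3 levels is skipped with a notice, since the
    omnibus factorial F already is that single contrast.
    """
    if factor not in (_FACTOR_A, _FACTOR_B):
        raise KeyError(f"unknown factor '{factor}'")
    anova = two_way_anova(dataset, outcome)
    sub = dataset.data[[factor, outcome]].dropna()
    levels = np.sort(sub[factor].unique())
    if levels.size < 3:
        return PosthocResult(
            contrasts=pd.DataFrame(
                columns=["level_a", "level_b", "mean_diff", "se", "q", "p_adj"]),
            notice=f"factor '{factor}' has {levels.size} levels; "
                   "Tukey HSD needs >= 3 (the omnibus F covers 2 levels)",
        )
    mse = float(anova.loc["Residual", "mean_sq"])
    df_resid = float(anova.loc["Residual", "df"])
    means = sub.groupby(factor)[outcome].mean()
    ns = sub.groupby(factor)[outcome].count()
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = float(means[a] - means[b])
        se = float(np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b])))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, levels.size, df_resid))
        rows.append({"level_a": a, "level_b": b, "mean_diff": diff,
                     "se": se, "q": q, "p_adj": min(max(p, 0.0), 1.0)})
    return PosthocResult(contrasts=pd.DataFrame(rows))


@dataclass(frozen=True)
class SimpleEffectsResult:
    """Conditional F-tests of each factor at each level of the other."""

    tests: pd.DataFrame
    notices: tuple[str, ...] = ()


def simple_effects(dataset: FactorialDataset, outcome: str) -> SimpleEffectsResult:
    """SPSS-syntax-style simple effects decomposition of the interaction.

    For each level ``b`` of one factor, the other factor's cell means within
    that slice are tested with ``F = (SS_slice / df_slice) / MS_resid`` where
    ``MS_resid`` is the pooled residual mean square of the omnibus two-way
    model (not a per-slice error term). Slices with a single occupied cell
    are skipped with a notice; a zero residual mean square (all-constant
    outcome) yields undefined p-values with a notice rather than an error.
    """
    anova = two_way_anova(dataset, outcome)
    mse = float(anova.loc["Residual", "mean_sq"])
    df_resid = float(anova.loc["Residual", "df"])
    sub = dataset.data[[_FACTOR_A, _FACTOR_B, outcome]].dropna()
    # an all-constant outcome leaves a residual MS of pure rounding noise
    if mse <= 1e-12 * max(1.0, float(np.mean(sub[outcome] ** 2))):
        mse = 0.0

    rows = []
    notices: list[str] = []
    for tested, within in ((_FACTOR_A, _FACTOR_B), (_FACTOR_B, _FACTOR_A)):
        for lev in np.sort(sub[within].unique()):
            slice_ = sub[sub[within] == lev]
            cells = slice_.groupby(tested)[outcome]
            k = cells.ngroups
            if k < 2:
                notices.append(
                    f"effect of {tested} at {within}={lev}: single occupied "
                    "cell, skipped")
                continue
            n_c = cells.count().to_numpy(dtype=float)
            m_c = cells.mean().to_numpy()
            grand = float(np.average(m_c, weights=n_c))
            ss = float(np.sum(n_c * (m_c - grand) ** 2))
            df_num = k - 1
            if mse > 0:
                f_val = (ss / df_num) / mse
                p = float(sps.f.sf(f_val, df_num, df_resid))
            else:
                f_val, p = np.nan, np.nan
                notices.append(
                    f"effect of {tested} at {within}={lev}: zero residual "
                    "mean square, p undefined")
            rows.append({
                "effect_of": tested, "at_factor": within, "at_level": lev,
                "sum_sq": ss, "df": df_num, "F": f_val, "p": p,
            })
    return SimpleEffectsResult(tests=pd.DataFrame(rows), notices=tuple(notices))


def summarize_groups(dataset: FactorialDataset,
                     outcomes: list[str] | None = None) -> pd.DataFrame:
    """Mean and sample SD (n-1) per factor level and per design cell.

    One row per (grouping, level(s), outcome); the SD of a single
    observation is reported as missing.
    """
    df = dataset.data
    if df.empty:
        raise ValueError("dataset is empty")
    outcomes = outcomes if outcomes is not None else dataset.outcomes()

    def _agg(group_cols: list[str], label: str) -> pd.DataFrame:
        g = df.groupby(group_cols, observed=True)
        frames = []
        for out in outcomes:
            agg = g[out].agg(["mean", "std", "count"]).reset_index()
            agg.insert(0, "grouping", label)
            agg.insert(len(group_cols) + 1, "outcome", out)
            frames.append(agg)
        return pd.concat(frames, ignore_index=True)

    by_time = _agg([_FACTOR_A], "time")
    by_volume = _agg([_FACTOR_B], "volume")
    by_cell = _agg([_FACTOR_A, _FACTOR_B], "cell")
    out = pd.concat([by_time, by_volume, by_cell], ignore_index=True)
    cols = ["grouping", _FACTOR_A, _FACTOR_B, "outcome", "mean", "std", "count"]
    for c in (_FACTOR_A, _FACTOR_B):
        if c not in out.columns:
            out[c] = np.nan
    return out[cols]


def table1_markdown(dataset: FactorialDataset,
                    outcomes: list[str] | None = None) -> str:
    """Markdown summary table in the study's per-time-level layout."""
    outcomes = outcomes if outcomes is not None else dataset.outcomes()
    summary = summarize_groups(dataset, outcomes)
    by_time = summary[summary["grouping"] == "time"]
    header = "| time (s) | " + " | ".join(
        f"{o} mean | {o} SD" for o in outcomes) + " |"
    sep = "|" + "---|" * (1 + 2 * len(outcomes))
    lines = [header, sep]
    for t in sorted(by_time[_FACTOR_A].dropna().unique()):
        cells = [f"| {int(t)} "]
        for o in outcomes:
            row = by_time[(by_time[_FACTOR_A] == t) & (by_time["outcome"] == o)]
            m = float(row["mean"].iloc[0])
            s = row["std"].iloc[0]
            s_txt = f"{float(s):.1f}" if pd.notna(s) else "--"
            cells.append(f"| {m:.1f} | {s_txt} ")
        lines.append("".join(cells) + "|")
    return "\n".join(lines)
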