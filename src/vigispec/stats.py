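"""Estimation statistics and the pooled-vs-state-resolved masking comparison.

Inference follows the estimation-statistics convention: effects are
reported as mean differences with bootstrap confidence intervals whose
level is Bonferroni-adjusted for the number of planned comparisons
(1 − α/m); an effect is "significant" when its adjusted CI excludes
zero.  Factorial fixed-effects ANOVAs (Type II sums of squares, so
unbalanced cells are handled sensibly) summarise the factor structure.

:class:`MaskingAnalysis` is the package's headline analysis: the same
subject × state exponent table is analysed twice — once with vigilance
state as a factor (state-resolved) and once after collapsing each subject
to a single occupancy-weighted exponent (pooled).  When groups differ in
state occupancy, a within-state group difference can vanish entirely from
the pooled branch; the analysis reports both so the masking is explicit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats

__all__ = [
    "EffectEstimate",
    "AnovaTable",
    "SummaryStats",
    "mean_difference_ci",
    "factorial_anova",
    "correlation_matrix",
    "age_regression",
    "MaskingAnalysis",
    "MaskingResults",
    "masking_analysis",
    "summary_stats",
]


@dataclass
class EffectEstimate:
    """Group mean difference with a multiplicity-adjusted bootstrap CI."""

    mean_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    alpha_adjusted: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("CI must bracket the mean difference")

    @property
    def significant(self) -> bool:
        """True when the adjusted CI excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0

    def __str__(self) -> str:
        star = "*" if self.significant else ""
        return (f"{self.name + ': ' if self.name else ''}"
                f"{self.mean_diff:.3g} [{self.ci_low:.3g}; {self.ci_high:.3g}]{star}")


@dataclass
class AnovaTable:
    """Per-term F statistics of a fixed-effects factorial ANOVA."""

    terms: pd.DataFrame  # columns: term, df, df_resid, F, p
    formula: str

    def p_for(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])

    def __str__(self) -> str:
        lines = [f"ANOVA: {self.formula}"]
        for _, r in self.terms.iterrows():
            lines.append(
                f"  {r['term']:<24s} F({int(r['df'])},{int(r['df_resid'])}) ="
                f" {r['F']:8.3f}   p = {r['p']:.4g}"
            )
        return "\n".join(lines)


@dataclass
class SummaryStats:
    """Group mean with coefficient of variance (SD/mean)."""

    mean: float
    cv: float
    n: int


def summary_stats(values) -> SummaryStats:
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return SummaryStats(mean=mean, cv=sd / mean if mean != 0 else np.nan, n=len(x))


def mean_difference_ci(
    group_a,
    group_b,
    n_boot: int = 5000,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    seed: int | np.random.Generator | None = None,
    name: str = "",
) -> EffectEstimate:
    """Bootstrap estimation of mean(b) − mean(a) with an adjusted percentile CI.

    Resampling is with replacement within each group; the percentile
    interval is taken at level 1 − alpha/n_comparisons (Bonferroni), so a
    larger comparison family yields a strictly wider interval.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    diffs = b[ib].mean(axis=1) - a[ia].mean(axis=1)
    adj = alpha / n_comparisons
    lo, hi = np.percentile(diffs, [100 * adj / 2.0, 100 * (1 - adj / 2.0)])
    point = float(b.mean() - a.mean())
    return EffectEstimate(
        mean_diff=point,
        ci_low=min(float(lo), point),
        ci_high=max(float(hi), point),
        n_boot=n_boot,
        alpha_adjusted=adj,
        name=name,
    )


def factorial_anova(
    table: pd.DataFrame,
    response: str = "exponent",
    factors: list[str] | None = None,
) -> AnovaTable:
    """Fixed-effects factorial ANOVA with all interactions, Type II SS.

    Factors with fewer than two observed levels are dropped with a
    warning, as are terms rendered inestimable by empty cells.  Raises on
    zero residual degrees of freedom (e.g. one observation per cell with
    the full interaction model).
    """
    factors = list(factors or ["group", "state"])
    missing = [f for f in factors if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks factor columns {missing}")
    usable = []
    for f in factors:
        if table[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has < 2 levels; dropped", stacklevel=2)
        else:
            usable.append(f)
    if not usable:
        raise ValueError("no factor has at least two levels")
    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in usable)
    model = smf.ols(formula, data=table).fit()
    if model.df_resid < 1:
        raise ValueError("zero residual degrees of freedom; design saturated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on NaN F for empty cells
        aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.drop(index="Residual", errors="ignore")
    rows = []
    for term, r in aov.iterrows():
        if not np.isfinite(r["F"]):
            warnings.warn(f"term {term!r} inestimable (empty cells); dropped",
                          stacklevel=2)
            continue
        clean = str(term).replace("C(", "").replace(")", "")
        rows.append(
            {"term": clean, "df": float(r["df"]), "df_resid": float(model.df_resid),
             "F": float(r["F"]), "p": float(r["PR(>F)"])}
        )
    return AnovaTable(terms=pd.DataFrame(rows), formula=formula.replace("C(", "").replace(")", ""))


def correlation_matrix(observations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson correlations with Bonferroni-corrected p-values.

    Returns (r, p_adjusted) frames; two-sided p-values are multiplied by
    the number of distinct pairs and capped at 1.  A zero-variance
    variable yields NaN entries and a warning rather than an error.
    """
    cols = list(observations.columns)
    n, v = observations.shape
    if n < 4 or v < 2:
        raise ValueError("need >= 4 subjects and >= 2 variables")
    m = v * (v - 1) // 2
    r = pd.DataFrame(np.eye(v), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((v, v)), index=cols, columns=cols)
    for i in range(v):
        for j in range(i + 1, v):
            xi = observations.iloc[:, i].to_numpy(float)
            xj = observations.iloc[:, j].to_numpy(float)
            if np.std(xi) == 0 or np.std(xj) == 0:
                warnings.warn(
                    f"zero-variance variable in pair ({cols[i]}, {cols[j]}); "
                    "correlation undefined", stacklevel=2,
                )
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sstats.pearsonr(xi, xj)
                pij = min(pij * m, 1.0)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def age_regression(exponents, ages, group: str = "") -> tuple[float, float, float, float]:
    """OLS of pooled exponent on age within one group.

    Returns (slope, intercept, F, p) where F/p test the age slope.
    """
    y = np.asarray(exponents, dtype=float)
    x = np.asarray(ages, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired (exponent, age) observations")
    if np.std(x) == 0:
        raise ValueError("age is constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return (
        float(res.params[1]),
        float(res.params[0]),
        float(res.fvalue),
        float(res.f_pvalue),
    )


# ---------------------------------------------------------------------------
# masking analysis


@dataclass
class MaskingResults:
    """Twin analyses of one cohort: state-resolved vs state-pooled.

    ``state_effects`` holds one adjusted :class:`EffectEstimate` per
    (state, group-pair); ``pooled_effects`` one per group pair on the
    occupancy-weighted subject exponents.
    """

    resolved_anova: AnovaTable
    pooled_anova: AnovaTable | None
    state_effects: list[EffectEstimate]
    pooled_effects: list[EffectEstimate]
    reference_group: str
    seed: int | None = None
    pooled_table: pd.DataFrame = field(default=None, repr=False)

    @property
    def state_resolved_significant(self) -> bool:
        """All within-state group comparisons exclude zero (adjusted CIs)."""
        return bool(self.state_effects) and all(e.significant for e in self.state_effects)

    @property
    def pooled_significant(self) -> bool:
        return any(e.significant for e in self.pooled_effects)

    @property
    def masking_demonstrated(self) -> bool:
        """Group effect visible within states but invisible after pooling."""
        return self.state_resolved_significant and not self.pooled_significant

    def summary(self) -> str:
        lines = ["Masking analysis", "=" * 48, "", "State-resolved branch:",
                 str(self.resolved_anova)]
        for e in self.state_effects:
            lines.append(f"  {e}")
        lines += ["", "Pooled branch (occupancy-weighted subject exponents):"]
        if self.pooled_anova is not None:
            lines.append(str(self.pooled_anova))
        for e in self.pooled_effects:
            lines.append(f"  {e}")
        lines += ["", f"group effect within states: "
                  f"{'significant' if self.state_resolved_significant else 'not significant'}",
                  f"group effect after pooling:  "
                  f"{'significant' if self.pooled_significant else 'not significant'}"]
        if self.masking_demonstrated:
            lines.append("=> pooling across vigilance states masks the group effect")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def eff(e: EffectEstimate) -> dict:
            return {"name": e.name, "mean_diff": e.mean_diff, "ci_low": e.ci_low,
                    "ci_high": e.ci_high, "n_boot": e.n_boot,
                    "alpha_adjusted": e.alpha_adjusted, "significant": e.significant}

        return {
            "seed": self.seed,
            "reference_group": self.reference_group,
            "resolved_anova": self.resolved_anova.terms.to_dict("records"),
            "pooled_anova": (self.pooled_anova.terms.to_dict("records")
                             if self.pooled_anova is not None else None),
            "state_effects": [eff(e) for e in self.state_effects],
            "pooled_effects": [eff(e) for e in self.pooled_effects],
            "state_resolved_significant": self.state_resolved_significant,
            "pooled_significant": self.pooled_significant,
            "masking_demonstrated": self.masking_demonstrated,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot(self, table: pd.DataFrame, axes=None):
        """Side-by-side view of the two branches: state-resolved exponents
        per group and the occupancy-weighted pooled exponents."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        groups = sorted(table["group"].unique())
        states = sorted(table["state"].unique())
        width = 0.8 / len(groups)
        for gi, g in enumerate(groups):
            data = [table.query("group == @g and state == @s")["exponent"]
                    for s in states]
            pos = np.arange(len(states)) + gi * width
            axes[0].boxplot(data, positions=pos, widths=width * 0.9,
                            tick_labels=states if gi == 0 else [""] * len(states))
        axes[0].set_title("state-resolved")
        axes[0].set_ylabel("aperiodic exponent")
        pooled = self.pooled_table if self.pooled_table is not None else None
        if pooled is not None:
            data = [pooled.query("group == @g")["exponent"] for g in groups]
            axes[1].boxplot(data, tick_labels=groups)
        axes[1].set_title("pooled across states")
        return axes


class MaskingAnalysis:
    """Compare state-resolved and state-pooled group inference on one cohort.

    Parameters
    ----------
    table
        Subject × state exponents: columns ``subject, group, state,
        exponent`` plus optional ``sex`` and ``n_epochs`` (epoch counts
        drive the occupancy weighting of the pooled branch; without them
        states are weighted equally).
    reference_group
        Group each other group is compared against (default: first by
        sort order).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        reference_group: str | None = None,
        n_boot: int = 5000,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> None:
        required = {"subject", "group", "state", "exponent"}
        if not required <= set(table.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        self.table = table.copy()
        groups = sorted(self.table["group"].unique())
        states = sorted(self.table["state"].unique())
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if len(states) < 2:
            warnings.warn("single-state cohort: pooled and resolved branches "
                          "coincide", stacklevel=2)
        self.groups = groups
        self.states = states
        self.reference_group = reference_group or groups[0]
        if self.reference_group not in groups:
            raise ValueError(f"unknown reference group {self.reference_group!r}")
        self.n_boot = n_boot
        self.alpha = alpha
        self.seed = seed

    def pooled_table(self) -> pd.DataFrame:
        """One occupancy-weighted exponent per subject, state ignored."""
        def agg(g: pd.DataFrame) -> pd.Series:
            w = g["n_epochs"].to_numpy(float) if "n_epochs" in g else np.ones(len(g))
            out = {"exponent": float(np.average(g["exponent"], weights=w)),
                   "group": g["group"].iloc[0]}
            if "sex" in g:
                out["sex"] = g["sex"].iloc[0]
            return pd.Series(out)

        return (self.table.groupby("subject", sort=True)
                .apply(agg, include_groups=False).reset_index())

    def fit(self) -> MaskingResults:
        rng = np.random.default_rng(self.seed)
        others = [g for g in self.groups if g != self.reference_group]
        factors = ["group", "state"]
        if "sex" in self.table.columns and self.table["sex"].nunique() > 1:
            factors.append("sex")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resolved = factorial_anova(self.table, "exponent", factors)

        m = len(self.states) * len(others)
        state_effects = []
        for g in others:
            for s in self.states:
                a = self.table.query("group == @self.reference_group and state == @s")["exponent"]
                b = self.table.query("group == @g and state == @s")["exponent"]
                if len(a) < 3 or len(b) < 3:
                    warnings.warn(
                        f"state {s!r}: fewer than 3 subjects per group for "
                        f"{g} vs {self.reference_group}; comparison skipped",
                        stacklevel=2,
                    )
                    continue
                state_effects.append(
                    mean_difference_ci(a, b, self.n_boot, self.alpha, m, rng,
                                       name=f"{g} vs {self.reference_group} in {s}")
                )

        pooled = self.pooled_table()
        pooled_factors = [f for f in factors if f != "state"]
        pooled_anova = None
        if pooled["group"].nunique() >= 2 and len(pooled) > pooled["group"].nunique():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled_anova = factorial_anova(pooled, "exponent", pooled_factors)
        pooled_effects = []
        for g in others:
            a = pooled.query("group == @self.reference_group")["exponent"]
            b = pooled.query("group == @g")["exponent"]
            pooled_effects.append(
                mean_difference_ci(a, b, self.n_boot, self.alpha, len(others), rng,
                                   name=f"{g} vs {self.reference_group} (pooled)")
            )
        return MaskingResults(
            resolved_anova=resolved,
            pooled_anova=pooled_anova,
            state_effects=state_effects,
            pooled_effects=pooled_effects,
            reference_group=self.reference_group,
            seed=self.seed,
            pooled_table=pooled,
        )


def masking_analysis(
    table: pd.DataFrame,
    reference_group: str | None = None,
    n_boot: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MaskingResults:
    """Convenience wrapper: build and fit a :class:`MaskingAnalysis`."""
    return MaskingAnalysis(table, reference_group, n_boot, alpha, seed).fit()
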