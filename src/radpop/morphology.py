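"""Factorial (population x sex) ANOVA on morphometric traits.

Cell sizes are unbalanced (museum preparations lack some measurements), so
effects are tested with Type II sums of squares: each main effect is the
reduction in residual SS when added to the model already containing the
other main effect, and the interaction is tested against the full model's
residual mean square.  Effect magnitudes are additionally summarised as the
absolute location mean difference divided by the grand mean, in percent.
Sign convention for location: mean(Hawaii) - mean(Japan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaEffect:
    F: float
    df: tuple[float, float]
    p_value: float


@dataclass
class AnovaResult:
    trait: str
    effects: dict[str, AnovaEffect]  # "location", "sex", "interaction"
    grand_mean: float
    location_difference: float  # mean(Hawaii) - mean(Japan)
    percent_effect: float
    n: int


def factorial_anova(
    table: pd.DataFrame,
    trait: str,
    location_order: tuple[str, str] = ("Hawaii", "Japan"),
) -> AnovaResult:
    """Two-way ANOVA with interaction (Type II SS) for one trait.

    Rows with a missing value of ``trait`` are dropped (per trait, not
    listwise).  Requires both factor levels present and at least two
    observations in at least three of the four cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = table[["population", "sex", trait]].dropna(subset=[trait]).copy()
    sub = sub.rename(columns={trait: "y"})
    for factor in ("population", "sex"):
        if sub[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has <2 levels after dropping NAs")
    counts = sub.groupby(["population", "sex"]).size()
    if len(counts) < 4:
        empty = {
            (p, s)
            for p in sub["population"].unique()
            for s in sub["sex"].unique()
        } - set(counts.index)
        raise ValueError(f"empty design cell(s): {sorted(empty)}")
    if (counts >= 2).sum() < 3:
        raise ValueError("need >=2 observations in at least 3 of 4 cells")

    model = smf.ols("y ~ C(population) * C(sex)", data=sub).fit()
    if model.ssr <= 1e-12 * max(float(sub["y"].abs().max()) ** 2, 1.0):
        # all-equal (or perfectly fitted) response: F is 0/0; report degenerate
        effects = {
            name: AnovaEffect(0.0, (float("nan"), float("nan")), float("nan"))
            for name in ("location", "sex", "interaction")
        }
    else:
        aov = sm.stats.anova_lm(model, typ=2)
        key = {
            "location": "C(population)",
            "sex": "C(sex)",
            "interaction": "C(population):C(sex)",
        }
        resid_df = float(aov.loc["Residual", "df"])
        effects = {
            name: AnovaEffect(
                float(aov.loc[row, "F"]),
                (float(aov.loc[row, "df"]), resid_df),
                float(aov.loc[row, "PR(>F)"]),
            )
            for name, row in key.items()
        }
    pop_means = sub.groupby("population")["y"].mean()
    loc_diff = float(pop_means[location_order[0]] - pop_means[location_order[1]])
    grand = float(sub["y"].mean())
    return AnovaResult(
        trait=trait,
        effects=effects,
        grand_mean=grand,
        location_difference=loc_diff,
        percent_effect=percent_effect(loc_diff, grand),
        n=int(len(sub)),
    )


def percent_effect(mean_difference: float, grand_mean: float) -> float:
    """|mean difference| as a percentage of the grand mean."""
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive")
    return abs(mean_difference) / grand_mean * 100.0


def assumption_checks(table: pd.DataFrame, trait: str) -> dict:
    """Shapiro-Wilk on model residuals and Levene's test across the 4 cells."""
    import statsmodels.formula.api as smf

    sub = table[["population", "sex", trait]].dropna(subset=[trait]).copy()
    sub = sub.rename(columns={trait: "y"})
    model = smf.ols("y ~ C(population) * C(sex)", data=sub).fit()
    sw_stat, sw_p = stats.shapiro(model.resid)
    cells = [grp["y"].to_numpy() for _, grp in sub.groupby(["population", "sex"])]
    lev_stat, lev_p = stats.levene(*cells)
    return {
        "shapiro_wilk": {"statistic": float(sw_stat), "p_value": float(sw_p)},
        "levene": {"statistic": float(lev_stat), "p_value": float(lev_p)},
        "n": int(len(sub)),
    }


def anova_report(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Per-trait summary table mirroring the standard presentation."""
    rows = []
    for trait in traits:
        res = factorial_anova(table, trait)
        rows.append(
            {
                "trait": trait,
                "n": res.n,
                "grand_mean_mm": res.grand_mean,
                "hawaii_minus_japan_mm": res.location_difference,
                "location_effect_pct": res.percent_effect,
                "p_location": res.effects["location"].p_value,
                "p_sex": res.effects["sex"].p_value,
                "p_interaction": res.effects["interaction"].p_value,
            }
        )
    return pd.DataFrame(rows)
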