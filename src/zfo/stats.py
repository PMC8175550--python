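"""Cohort statistics for paired-eye zebrafish measurements.

Because both eyes of a fish are measured, observations are not independent:
the model of record is a random-intercept linear mixed model

    y_ij = beta0 + beta1 * I(mutant_i) + u_i + eps_ij,
    u_i ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma^2),

with genotype as the fixed factor and fish as the random factor, fitted by
REML.  beta1 is the genotype effect of interest (e.g. µm of axial length).
Supporting procedures: wild-type controls are size-matched to within 10% of
the mean mutant body length before modelling (fish-level filtering); each
age is analyzed separately (cross-sectional); and heteroscedastic multi-group
outcomes (ERG, OKR, lens optics) use Welch's ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LmmFit",
    "WelchAnovaResult",
    "size_match_controls",
    "fit_random_intercept_lmm",
    "welch_anova",
    "crosssectional_report",
]

REQUIRED_COLUMNS = ("fish_id", "genotype", "eye", "body_length_mm", "value")


@dataclass
class LmmFit:
    beta1: float  # fixed genotype effect (mutant - WT)
    se: float
    p_value: float
    beta0: float
    sigma_u: float  # between-fish SD (random intercept)
    sigma_e: float  # residual SD
    n_wt_fish: int
    n_mut_fish: int
    converged: bool = True
    note: str = ""


@dataclass
class WelchAnovaResult:
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")


def size_match_controls(
    table: pd.DataFrame, tolerance: float = 0.10
) -> pd.DataFrame:
    """Keep WT fish whose body length is within ``tolerance`` of the mean
    mutant body length; mutants pass through unchanged.

    Filtering is at fish level: both eyes of a fish are kept or dropped
    together (body length is a per-fish property).
    """
    _check_table(table)
    mut = table[table["genotype"] == "mutant"]
    if mut.empty:
        raise ValueError("mutant group is empty; size matching undefined")
    target = mut.groupby("fish_id")["body_length_mm"].first().mean()
    lo, hi = (1 - tolerance) * target, (1 + tolerance) * target
    wt = table[table["genotype"] == "WT"]
    wt_lengths = wt.groupby("fish_id")["body_length_mm"].first()
    keep = wt_lengths[(wt_lengths >= lo) & (wt_lengths <= hi)].index
    return pd.concat([wt[wt["fish_id"].isin(keep)], mut]).sort_index()


def fit_random_intercept_lmm(
    table: pd.DataFrame, outcome: str = "value"
) -> LmmFit:
    """REML fit of ``outcome ~ genotype`` with a per-fish random intercept.

    Reports the genotype fixed effect (mutant minus WT) with its Wald
    standard error and normal-reference p-value, plus the between-fish and
    residual SDs.  Degenerate (zero-variance) data and non-convergence fall
    back to the exact group-mean difference with ``converged=False``.
    """
    _check_table(table)
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} not in table")
    sub = table.dropna(subset=[outcome]).copy()
    y = sub[outcome].to_numpy(dtype=float)
    geno = (sub["genotype"] == "mutant").to_numpy(dtype=float)
    n_wt = sub.loc[sub["genotype"] == "WT", "fish_id"].nunique()
    n_mut = sub.loc[sub["genotype"] == "mutant", "fish_id"].nunique()
    if n_wt < 2 or n_mut < 2:
        raise ValueError("need at least 2 fish per genotype")

    wt_mean = float(y[geno == 0].mean())
    mut_mean = float(y[geno == 1].mean())
    # centered residual variance after removing genotype means
    resid = y - np.where(geno == 1, mut_mean, wt_mean)
    if float(np.var(resid)) < 1e-24:
        return LmmFit(
            beta1=mut_mean - wt_mean, se=0.0, p_value=1.0, beta0=wt_mean,
            sigma_u=0.0, sigma_e=0.0, n_wt_fish=n_wt, n_mut_fish=n_mut,
            converged=False, note="zero residual variance; exact mean difference",
        )

    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                f"{outcome} ~ genotype", sub, groups=sub["fish_id"]
            )
            fit = model.fit(reml=True)
        except Exception as exc:  # singular fits on pathological input
            return LmmFit(
                beta1=mut_mean - wt_mean, se=float("nan"), p_value=float("nan"),
                beta0=wt_mean, sigma_u=float("nan"), sigma_e=float("nan"),
                n_wt_fish=n_wt, n_mut_fish=n_mut, converged=False,
                note=f"mixed model failed: {exc}",
            )

    term = next(t for t in fit.params.index if t.startswith("genotype"))
    # statsmodels codes genotype alphabetically (WT reference before mutant)
    return LmmFit(
        beta1=float(fit.params[term]),
        se=float(fit.bse[term]),
        p_value=float(fit.pvalues[term]),
        beta0=float(fit.params["Intercept"]),
        sigma_u=float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))),
        sigma_e=float(np.sqrt(fit.scale)),
        n_wt_fish=n_wt,
        n_mut_fish=n_mut,
        converged=bool(fit.converged),
    )


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    For two groups the F statistic equals the square of Welch's t.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if np.var(g, ddof=1) == 0:
            raise ValueError("a group has zero variance; Welch weights undefined")

    import pingouin as pg

    df = pd.DataFrame(
        {
            "value": np.concatenate(arrays),
            "group": np.concatenate(
                [np.full(g.size, i) for i, g in enumerate(arrays)]
            ),
        }
    )
    res = pg.welch_anova(data=df, dv="value", between="group").iloc[0]
    return WelchAnovaResult(
        f_statistic=float(res["F"]),
        df_num=float(res["ddof1"]),
        df_den=float(res["ddof2"]),
        p_value=float(res["p_unc"]),
    )


def crosssectional_report(
    table: pd.DataFrame,
    outcome: str = "value",
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Size matching plus the mixed model, independently per age label.

    Returns one tidy row per age; an age that cannot be analyzed (e.g. only
    one genotype present) is flagged in the ``error`` column and does not
    affect the other ages.
    """
    _check_table(table)
    if "age" not in table.columns:
        raise ValueError("cohort table needs an 'age' column for per-age analysis")
    rows = []
    for age, sub in table.groupby("age", sort=True):
        row: dict = {"age": age}
        try:
            matched = size_match_controls(sub, tolerance=tolerance)
            fit = fit_random_intercept_lmm(matched, outcome=outcome)
            row.update(
                beta1=fit.beta1, se=fit.se, p_value=fit.p_value, beta0=fit.beta0,
                sigma_u=fit.sigma_u, sigma_e=fit.sigma_e,
                n_wt_fish=fit.n_wt_fish, n_mut_fish=fit.n_mut_fish,
                converged=fit.converged, error="",
            )
        except Exception as exc:
            row.update(
                beta1=np.nan, se=np.nan, p_value=np.nan, beta0=np.nan,
                sigma_u=np.nan, sigma_e=np.nan, n_wt_fish=0, n_mut_fish=0,
                converged=False, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
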