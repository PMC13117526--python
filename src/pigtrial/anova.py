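"""Repeated-measures analysis for physiology, haematology and cytokine series.

The model is the classical longitudinal ANOVA: fixed effects of treatment,
time and their interaction, plus a random intercept per animal to absorb
repeated measurement of the same subject.  Treatment contrasts are reported
as differences in least-squares (model-predicted cell) means with 95%
confidence intervals; degrees of freedom for the contrasts use the
between-subject stratum (n_animals - 2), the Satterthwaite-style choice for
a between-subject factor in a random-intercept design.  With a single
timepoint the model reduces to an ordinary pooled-variance two-sample
comparison and is fitted as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["RepeatedResult", "validate_repeated", "fit_repeated", "log10_analyte"]

REQUIRED_COLS = ("animal_id", "arm", "timepoint_h", "value")


@dataclass
class RepeatedResult:
    """Per-timepoint least-squares means and treatment contrasts."""

    effects: pd.DataFrame  # timepoint_h, lsmean_vehicle, lsmean_treated, diff, ci_lo, ci_hi, p
    overall_diff: float
    overall_ci: tuple
    overall_p: float
    f_treatment: float
    df_contrast: float
    converged: bool


def validate_repeated(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"repeated table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["animal_id", "timepoint_h"])
    if dup.any():
        raise ValueError("one value per (animal, timepoint) required; duplicates found")


def _single_timepoint(df: pd.DataFrame, alpha: float) -> RepeatedResult:
    """Two arms at one timepoint: pooled-variance two-sample t."""
    g = {a: df.loc[df["arm"] == a, "value"].to_numpy() for a in ("vehicle", "treated")}
    n1, n2 = len(g["vehicle"]), len(g["treated"])
    m1, m2 = g["vehicle"].mean(), g["treated"].mean()
    s2 = (
        (n1 - 1) * g["vehicle"].var(ddof=1) + (n2 - 1) * g["treated"].var(ddof=1)
    ) / (n1 + n2 - 2)
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    df_ = n1 + n2 - 2
    diff = m2 - m1
    tcrit = stats.t.ppf(1 - alpha / 2, df_)
    p = 2 * stats.t.sf(abs(diff / se), df_)
    tp = float(df["timepoint_h"].iloc[0])
    effects = pd.DataFrame(
        [
            {
                "timepoint_h": tp,
                "lsmean_vehicle": m1,
                "lsmean_treated": m2,
                "diff": diff,
                "ci_lo": diff - tcrit * se,
                "ci_hi": diff + tcrit * se,
                "p": p,
            }
        ]
    )
    return RepeatedResult(
        effects=effects,
        overall_diff=float(diff),
        overall_ci=(float(diff - tcrit * se), float(diff + tcrit * se)),
        overall_p=float(p),
        f_treatment=float((diff / se) ** 2),
        df_contrast=float(df_),
        converged=True,
    )


def fit_repeated(table: pd.DataFrame, alpha: float = 0.05) -> RepeatedResult:
    """Mixed ANOVA of one analyte: treatment, time, treatment×time + subject.

    Returns LS means per arm×time cell, per-timepoint treatment differences
    with CIs and p-values, the time-averaged (overall) difference, and the
    Wald F for the overall treatment contrast.
    """
    validate_repeated(table)
    df = table.dropna(subset=["value"]).copy()
    arms = sorted(df["arm"].unique())
    if set(arms) != {"treated", "vehicle"}:
        raise ValueError(f"need arms {{vehicle, treated}}, got {arms}")
    times = np.sort(df["timepoint_h"].unique())
    if len(times) == 1:
        return _single_timepoint(df, alpha)
    shared = [
        t
        for t in times
        if {"vehicle", "treated"} <= set(df.loc[df["timepoint_h"] == t, "arm"])
    ]
    if len(shared) < 2:
        raise ValueError("both arms needed at >= 2 shared timepoints")

    df["arm"] = pd.Categorical(df["arm"], categories=["vehicle", "treated"])
    df["tp"] = pd.Categorical(df["timepoint_h"])
    model = smf.mixedlm("value ~ C(arm) * C(tp)", df, groups=df["animal_id"])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        last_err: Exception | None = None
        # tight gradient tolerance: balanced-design contrasts should match
        # the classical ANOVA decomposition to near machine precision
        for meth, kw in (
            ("bfgs", {"gtol": 1e-12}),
            ("lbfgs", {}),
            ("powell", {}),
            ("cg", {}),
        ):
            try:
                fit = model.fit(reml=True, method=meth, **kw)
                break
            except np.linalg.LinAlgError as e:
                last_err = e
        if fit is None:
            raise ValueError(f"singular design: {last_err}") from last_err
    fe = fit.fe_params
    cov = fit.cov_params().loc[fe.index, fe.index].to_numpy()
    names = list(fe.index)
    aliased = [n for n in names if not np.isfinite(fe[n])]
    if aliased:
        raise ValueError(f"singular design, aliased term(s): {aliased}")

    n_animals = df["animal_id"].nunique()
    dfc = float(n_animals - 2)
    tcrit = stats.t.ppf(1 - alpha / 2, dfc)

    def cell_vector(arm: str, t) -> np.ndarray:
        v = np.zeros(len(names))
        v[names.index("Intercept")] = 1.0
        a = f"C(arm)[T.treated]"
        tname = f"C(tp)[T.{t}]"
        iname = f"C(arm)[T.treated]:C(tp)[T.{t}]"
        if arm == "treated":
            v[names.index(a)] = 1.0
        if tname in names:
            v[names.index(tname)] = 1.0
            if arm == "treated" and iname in names:
                v[names.index(iname)] = 1.0
        return v

    fe_arr = fe.to_numpy()
    rows = []
    contrasts = []
    for t in times:
        cv = cell_vector("vehicle", t)
        ct = cell_vector("treated", t)
        d = ct - cv
        contrasts.append(d)
        est_v, est_t = float(cv @ fe_arr), float(ct @ fe_arr)
        diff = float(d @ fe_arr)
        se = float(np.sqrt(d @ cov @ d))
        rows.append(
            {
                "timepoint_h": float(t),
                "lsmean_vehicle": est_v,
                "lsmean_treated": est_t,
                "diff": diff,
                "ci_lo": diff - tcrit * se,
                "ci_hi": diff + tcrit * se,
                "p": 2 * stats.t.sf(abs(diff / se), dfc) if se > 0 else 1.0,
            }
        )
    effects = pd.DataFrame(rows)

    d_overall = np.mean(contrasts, axis=0)
    diff_o = float(d_overall @ fe_arr)
    se_o = float(np.sqrt(d_overall @ cov @ d_overall))
    p_o = 2 * stats.t.sf(abs(diff_o / se_o), dfc) if se_o > 0 else 1.0
    return RepeatedResult(
        effects=effects,
        overall_diff=diff_o,
        overall_ci=(diff_o - tcrit * se_o, diff_o + tcrit * se_o),
        overall_p=float(p_o),
        f_treatment=float((diff_o / se_o) ** 2) if se_o > 0 else 0.0,
        df_contrast=dfc,
        converged=bool(fit.converged),
    )


def log10_analyte(
    table: pd.DataFrame,
    analyte: str | None = None,
    detection_limit: float | None = None,
) -> pd.DataFrame:
    """log10-transform an analyte series, handling below-detection values.

    Values at or below the declared detection limit are replaced by half
    the limit before transforming, and flagged in ``below_detection``.
    Nonpositive values with no declared limit are an error, never silently
    dropped.
    """
    df = table.copy()
    if analyte is not None and "analyte" in df.columns:
        df = df[df["analyte"] == analyte].copy()
    vals = df["value"].to_numpy(dtype=float)
    below = np.zeros(len(vals), dtype=bool)
    if detection_limit is not None:
        below = vals <= detection_limit
        vals = np.where(below, detection_limit / 2.0, vals)
    if np.any(vals <= 0):
        raise ValueError(
            "nonpositive values present and no detection limit declared"
        )
    df["value"] = np.log10(vals)
    df["below_detection"] = below
    return df
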