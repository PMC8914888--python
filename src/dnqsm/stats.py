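"""VOI-level statistics: residualization, ANCOVA, post hocs, correlations, ICC.

The layer reproduces the standard morphometry workflow: dentate volumes are
residualized against total intracranial volume using the control-only
regression v(TIV), group effects are tested with ANCOVA (age as covariate)
and quantified with partial η², pairwise post hocs use the Sidak
correction, clinical correlations are age-controlled Spearman (partial
correlation on ranks), and rater reliability uses the two-way mixed-effects
ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ResidualModel",
    "AncovaResult",
    "CorrelationResult",
    "IccResult",
    "residualize",
    "ancova",
    "sidak_adjust",
    "pairwise_posthoc",
    "partial_spearman",
    "icc_two_way_mixed",
    "cohort_summary",
]


@dataclass
class ResidualModel:
    """Control-only linear fit v(TIV) with the whole-sample residual sd."""

    intercept: float
    slope: float
    resid_sd: float
    n_controls: int

    def predict(self, tiv):
        return self.intercept + self.slope * np.asarray(tiv, dtype=float)


@dataclass
class AncovaResult:
    """Per-term F tests of a linear model with partial η² effect sizes."""

    terms: dict  # term -> dict(F, df_effect, df_error, p, partial_eta_squared)

    def __getitem__(self, term):
        return self.terms[term]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    covariates: tuple = ()


@dataclass
class IccResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


# --------------------------------------------------------------------------

def residualize(volumes, tivs, is_control):
    """Head-size correction of volumes via the control-only TIV regression.

    An OLS line v(TIV) is fitted on controls only; residuals
    ``volume_i - v(TIV_i)`` are computed for every subject and standardized
    by the sample sd (ddof=1) of the whole sample's residuals.

    Returns ``(standardized_residuals, ResidualModel)``.
    """
    volumes = np.asarray(volumes, dtype=float)
    tivs = np.asarray(tivs, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    if is_control.all() or not is_control.any():
        raise ValueError("need both controls and patients")
    if is_control.sum() < 3:
        raise ValueError("need at least 3 controls for the TIV regression")
    t_c = tivs[is_control]
    if np.var(t_c) == 0:
        raise ValueError("TIV variance among controls is zero")
    slope, intercept = np.polyfit(t_c, volumes[is_control], 1)
    resid = volumes - (intercept + slope * tivs)
    sd = resid.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(volumes).max())):
        raise ValueError("all residuals are zero; cannot standardize")
    model = ResidualModel(float(intercept), float(slope), float(sd), int(is_control.sum()))
    return resid / sd, model


def ancova(dep, group, age=None, extra_covariates: Optional[dict] = None) -> AncovaResult:
    """ANCOVA of ``dep`` on group with age (and optional extra covariates).

    Fits the linear model dep ~ C(group) + age (+ extras) and reports the
    type-III F test per term together with partial η² =
    SS_effect / (SS_effect + SS_error).  With ``age=None`` the model reduces
    to a one-way ANOVA.
    """
    data = pd.DataFrame({"dep": np.asarray(dep, float), "group": np.asarray(group)})
    rhs = ["C(group)"]
    if age is not None:
        data["age"] = np.asarray(age, float)
        rhs.append("age")
    for name, vals in (extra_covariates or {}).items():
        data[name] = np.asarray(vals, dtype=float)
        rhs.append(name)
    groups = pd.unique(data["group"])
    if len(groups) < 2 or data.groupby("group").size().min() < 2:
        raise ValueError("need >=2 groups with >=2 subjects each")
    model = smf.ols("dep ~ " + " + ".join(rhs), data=data)
    mat = model.exog
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError(
            "rank-deficient design; collinear columns among: "
            + ", ".join(model.exog_names)
        )
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=3)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])
    terms = {}
    for term in table.index:
        if term in ("Residual", "Intercept"):
            continue
        ss = float(table.loc[term, "sum_sq"])
        name = "group" if term.startswith("C(group)") else term
        terms[name] = {
            "F": float(table.loc[term, "F"]),
            "df_effect": float(table.loc[term, "df"]),
            "df_error": df_err,
            "p": float(table.loc[term, "PR(>F)"]),
            "partial_eta_squared": ss / (ss + ss_err),
        }
    return AncovaResult(terms)


def sidak_adjust(p_values, m: Optional[int] = None):
    """Sidak multiple-comparison adjustment p_adj = 1 - (1 - p)^m.

    ``m`` defaults to the number of p-values supplied and must not be
    smaller than it.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n_comp = max(p.size, 1)
    if m is None:
        m = n_comp
    if m < 1 or m < n_comp:
        raise ValueError(f"m={m} is smaller than the {n_comp} comparisons supplied")
    adj = 1.0 - (1.0 - p) ** m
    return np.clip(adj, 0.0, 1.0)


def pairwise_posthoc(values, groups, covariate=None):
    """Pairwise group comparisons with Sidak-adjusted p-values.

    Each pair is tested with the same linear model as :func:`ancova`
    (covariate-adjusted if given, Welch t-test otherwise); the raw p matrix
    is Sidak-corrected for the number of pairs.  Returns a dict with
    ``labels``, ``p_raw``, ``p_adj`` and ``direction`` (sign of the first
    group's mean minus the second's).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    k = len(labels)
    m = k * (k - 1) // 2
    p_raw = np.full((k, k), np.nan)
    direction = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sel = (groups == labels[i]) | (groups == labels[j])
            if covariate is not None:
                res = ancova(values[sel], groups[sel], np.asarray(covariate, float)[sel])
                p = res["group"]["p"]
            else:
                p = sps.ttest_ind(
                    values[groups == labels[i]], values[groups == labels[j]],
                    equal_var=False,
                ).pvalue
            d = np.sign(values[groups == labels[i]].mean() - values[groups == labels[j]].mean())
            p_raw[i, j] = p_raw[j, i] = p
            direction[i, j] = d
            direction[j, i] = -d
    p_adj = np.where(np.isnan(p_raw), np.nan, 1.0 - (1.0 - np.nan_to_num(p_raw)) ** m)
    p_adj = np.clip(p_adj, 0.0, 1.0)
    return {"labels": labels, "p_raw": p_raw, "p_adj": p_adj, "direction": direction, "m": m}


def partial_spearman(x, y, covariate) -> CorrelationResult:
    """Age-controlled Spearman correlation (partial correlation on ranks).

    x, y and the covariate are rank-transformed; the partial Pearson
    correlation of the x/y ranks controlling for the covariate ranks is
    returned with a t-approximation p-value on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(cov))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rx, ry, rc = (sps.rankdata(v) for v in (x, y, cov))
    design = np.column_stack([np.ones(n), rc])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    r = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r, p, n, "partial spearman", ("covariate",))


def icc_two_way_mixed(ratings, absolute_agreement: bool = False) -> IccResult:
    """Two-way mixed-effects intraclass correlation, single-rater form.

    ``ratings`` is an (n_subjects × n_raters) matrix without missing cells.
    Consistency form ICC(3,1) = (MS_subj - MS_err)/(MS_subj + (k-1) MS_err);
    the absolute-agreement variant ICC(2,1) additionally penalizes rater
    mean offsets.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be 2D (subjects x raters)")
    n, k = r.shape
    if n < 3 or k < 2:
        raise ValueError("need >=3 subjects and >=2 raters")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing cells are not allowed")
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((r - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if absolute_agreement:
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        model = "two-way mixed, absolute agreement, single rater (ICC(2,1)-form)"
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        model = "two-way mixed, consistency, single rater (ICC(3,1))"
    return IccResult(float(icc), model, n, k)


def cohort_summary(table: pd.DataFrame, variables: Sequence[str] = ("age_years", "sara"),
                   group_col: str = "group") -> pd.DataFrame:
    """Descriptive statistics per group with Welch t-tests patients vs controls."""
    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2 or table.groupby(group_col).size().min() < 2:
        raise ValueError("need exactly 2 groups with >=2 subjects each")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    rows = []
    for var in variables:
        a, b = g1[var].to_numpy(float), g2[var].to_numpy(float)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "variable": var,
                f"mean_{groups[0]}": a.mean(),
                f"range_{groups[0]}": (a.min(), a.max()),
                f"mean_{groups[1]}": b.mean(),
                f"range_{groups[1]}": (b.min(), b.max()),
                "welch_t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
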