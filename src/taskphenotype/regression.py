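"""Hierarchical OLS prediction of PHQ-9 scores.

The assessment battery is validated by regressing PHQ-9 totals on
behavioral metrics while controlling for demographics: age and gender
enter in a first block (the null model H0), the metrics of interest in
a second block (H1).  The second block's contribution is summarized by
the R-squared change and its F-change test,

    dF = (dR2 / m) / ((1 - R2_full) / (n - k_full - 1)),

with m added predictors and k_full predictors in the full model.  Each
coefficient is reported unstandardized (B) with its standard error,
standardized (beta = B * sd(x) / sd(y)), and with a two-tailed t test.
Multicollinearity is screened with variance inflation factors,
VIF_j = 1 / (1 - R2_j) from regressing predictor j on the others.

Gender is coded male = 1, female = 0 throughout the package; missing
data are dropped listwise before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

GENDER_CODES = {"female": 0, "male": 1}


def encode_gender(values: pd.Series) -> pd.Series:
    """Indicator coding male = 1, female = 0."""
    if values.dtype == object:
        return values.map(GENDER_CODES).astype(float)
    return values.astype(float)


class RegressionBlockSpec(BaseModel):
    """Predictor blocks for a hierarchical fit."""

    block0: list[str] = Field(default_factory=lambda: ["age", "gender"])
    block1: list[str] = Field(min_length=1)
    outcome: str = "phq9_total"

    @model_validator(mode="after")
    def _no_repeats(self) -> "RegressionBlockSpec":
        all_preds = self.block0 + self.block1
        if len(set(all_preds)) != len(all_preds):
            raise ValueError("a predictor appears in more than one block")
        if self.outcome in all_preds:
            raise ValueError("outcome cannot also be a predictor")
        return self


@dataclass
class OlsFit:
    """A single OLS fit: coefficient table plus model-fit statistics.

    ``coef`` is indexed by term ("(Intercept)" first) with columns
    B, se_B, beta, t, p.
    """

    coef: pd.DataFrame
    r2: float
    f: float
    p_model: float
    n: int
    df_model: int
    df_resid: int
    ssr: float  # residual sum of squares


@dataclass
class RegressionReport:
    """Two-block hierarchical fit mirroring the published report format:
    per-coefficient B, se B, beta, t, p and per-block R2, F, p, dR2, dF."""

    spec: RegressionBlockSpec
    reduced: OlsFit
    full: OlsFit
    delta_r2: float
    delta_f: float
    p_delta: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, fit in (("H0", self.reduced), ("H1", self.full)):
            for term, row in fit.coef.iterrows():
                rows.append(
                    {
                        "model": label,
                        "term": term,
                        "B": row["B"],
                        "se_B": row["se_B"],
                        "beta": row["beta"],
                        "t": row["t"],
                        "p": row["p"],
                    }
                )
            rows[-1].update(
                {
                    "R2": fit.r2,
                    "F": fit.f,
                    "p_model": fit.p_model,
                    "dR2": fit.r2 - (0.0 if label == "H0" else self.reduced.r2),
                    "dF": fit.f if label == "H0" else self.delta_f,
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:0.3f}".format):
            return df.to_string(index=False, na_rep="")


def fit_ols(design: pd.DataFrame, outcome: pd.Series) -> OlsFit:
    """Ordinary least squares of ``outcome`` on ``design`` (an intercept
    is added), with listwise deletion of missing rows.

    Raises on rank deficiency or when n <= number of parameters.
    """
    data = pd.concat([design, outcome.rename("__y__")], axis=1).dropna()
    y = data["__y__"].astype(float)
    X = data[design.columns].astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for {k} predictors")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, Xc).fit()

    sd_y = y.std(ddof=1)
    beta = pd.Series(np.nan, index=res.params.index)
    for col in X.columns:
        beta[col] = res.params[col] * X[col].std(ddof=1) / sd_y

    coef = pd.DataFrame(
        {
            "B": res.params,
            "se_B": res.bse,
            "beta": beta,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    ).rename(index={"const": "(Intercept)"})
    return OlsFit(
        coef=coef,
        r2=float(res.rsquared),
        f=float(res.fvalue),
        p_model=float(res.f_pvalue),
        n=n,
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        ssr=float(res.ssr),
    )


def model_f(r2: float, k: int, n: int) -> tuple[float, float]:
    """Whole-model F statistic and p-value recomputed from R-squared
    alone: F = (R2/k) / ((1-R2)/(n-k-1))."""
    if not 0 <= r2 < 1:
        raise ValueError("R2 must be in [0, 1)")
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    p = float(sps.f.sf(f, k, n - k - 1))
    return f, p


def delta_f_from_r2(
    r2_reduced: float, r2_full: float, n: int, m: int, k_full: int
) -> tuple[float, float]:
    """F-change statistic and p-value recomputed from the two blocks'
    R-squared values: dF = (dR2/m) / ((1-R2_full)/(n-k_full-1))."""
    if r2_full < r2_reduced:
        raise ValueError("R2 cannot decrease when predictors are added")
    d = r2_full - r2_reduced
    df2 = n - k_full - 1
    f = (d / m) / ((1.0 - r2_full) / df2)
    p = float(sps.f.sf(f, m, df2))
    return f, p


def hierarchical_fit(spec: RegressionBlockSpec, data: pd.DataFrame) -> RegressionReport:
    """Fit the reduced (block 0) then full (block 0 + block 1) model and
    report the block comparison.  ``data`` may carry gender as strings;
    it is indicator-coded before fitting."""
    df = data.copy()
    if "gender" in df.columns:
        df["gender"] = encode_gender(df["gender"])
    cols = spec.block0 + spec.block1 + [spec.outcome]
    df = df[cols].dropna()

    y = df[spec.outcome]
    reduced = fit_ols(df[spec.block0], y)
    full = fit_ols(df[spec.block0 + spec.block1], y)
    delta_f, p_delta = delta_f_from_r2(
        reduced.r2, full.r2, n=full.n, m=len(spec.block1), k_full=len(spec.block0) + len(spec.block1)
    )
    return RegressionReport(
        spec=spec,
        reduced=reduced,
        full=full,
        delta_r2=full.r2 - reduced.r2,
        delta_f=delta_f,
        p_delta=p_delta,
        n=full.n,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R2_j) per predictor, from
    regressing each predictor on the remaining ones."""
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in X.columns:
        others = X.drop(columns=col)
        r2 = fit_ols(others, X[col]).r2
        if r2 >= 1.0 - 1e-12:
            raise ValueError(f"predictor {col!r} is collinear with the others")
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def effect_size_f2(delta_r2: float, r2_full: float) -> dict[str, float]:
    """Local effect size of an added block.

    Returns both conventions: ``cohen`` = dR2/(1-R2_full) and
    ``variant`` = dR2/(1-dR2).
    """
    if not 0 <= delta_r2 <= r2_full:
        raise ValueError("need 0 <= delta_r2 <= r2_full")
    if r2_full >= 1:
        raise ValueError("R2_full must be < 1")
    return {
        "cohen": delta_r2 / (1.0 - r2_full),
        "variant": delta_r2 / (1.0 - delta_r2),
    }
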