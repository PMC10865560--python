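"""Normative lifespan modeling of peri-sinus structure volumes.

Volumes (optionally expressed as percent of intracranial volume) are
modeled across age with restricted quadratic splines — piecewise
quadratic, C^1-continuous, and exactly linear beyond the last knot —
with a sex main effect, spline(age) x sex interaction, and a random
intercept per source dataset:

    y ~ spline(age) + sex + spline(age):sex + (1 | source)

fit by (restricted) maximum likelihood through
``statsmodels.MixedLM``.  Goodness of fit is summarized by AIC and an
adjusted R^2 computed on the marginal (fixed-effects) predictions.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SplineBasis",
    "LifespanModelFit",
    "icv_normalize",
    "build_spline_basis",
    "fit_lifespan_model",
    "predict_curve",
]

log = logging.getLogger(__name__)

DEFAULT_KNOT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)


def icv_normalize(volume, icv):
    """Express a structure volume as a percentage of intracranial volume.

    Both arguments must share units (cm^3 against cm^3, or mm^3 against
    mm^3).
    """
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0):
        raise ValueError("ICV must be positive")
    return 100.0 * np.asarray(volume, dtype=float) / icv


@dataclass
class SplineBasis:
    """Restricted quadratic spline basis on ``knots`` (ages, years).

    Basis functions: intercept, linear age, and for j = 1..K-1
    ``b_j(a) = (a - k_j)_+^2 - (a - k_K)_+^2``, which is continuous with
    continuous first derivative and exactly linear for a >= k_K.
    """

    knots: tuple

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 2 or np.any(np.diff(k) <= 0):
            raise ValueError("knots must be >= 2 strictly increasing values")
        self.knots = tuple(float(x) for x in k)

    @property
    def column_names(self):
        return ["intercept", "age"] + [f"rq{j + 1}"
                                       for j in range(len(self.knots) - 1)]

    def design(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        kK = self.knots[-1]
        cols = [np.ones_like(a), a]
        tail = np.clip(a - kK, 0, None) ** 2
        for kj in self.knots[:-1]:
            cols.append(np.clip(a - kj, 0, None) ** 2 - tail)
        return np.column_stack(cols)


def build_spline_basis(ages, knots) -> pd.DataFrame:
    """Evaluate the restricted quadratic spline design at ``ages``."""
    basis = SplineBasis(tuple(knots))
    return pd.DataFrame(basis.design(ages), columns=basis.column_names)


@dataclass
class LifespanModelFit:
    response: str
    basis: SplineBasis
    params: pd.Series             # fixed effects
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    source_var: float
    resid_var: float
    adjusted_r2: float
    aic: float
    converged: bool
    mixed: bool                   # False when degraded to OLS
    n_obs: int
    age_range: tuple
    normalized_icv: bool = False
    interaction_wald_p: float = np.nan

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "p": self.pvalues})


def _design(df: pd.DataFrame, basis: SplineBasis):
    X_age = basis.design(df["age"].to_numpy())
    male = (df["sex"].astype(str).str.lower()
            .map({"male": 1, "m": 1, "female": 0, "f": 0}))
    if male.isna().any():
        raise ValueError("sex column must be male/female")
    male = male.to_numpy(dtype=float)
    names = basis.column_names
    cols = {n: X_age[:, i] for i, n in enumerate(names)}
    cols["sex_male"] = male
    for i, n in enumerate(names[1:], start=1):
        cols[f"{n}:sex_male"] = X_age[:, i] * male
    X = pd.DataFrame(cols, index=df.index)
    inter_cols = [c for c in X.columns if c.endswith(":sex_male")]
    return X, inter_cols


def fit_lifespan_model(records: pd.DataFrame, response: str,
                       normalize_icv: bool = False,
                       knots: Optional[Sequence[float]] = None,
                       reml: bool = False) -> LifespanModelFit:
    """Fit the normative mixed model for one peri-sinus metric.

    ``records`` needs columns ``age``, ``sex``, ``source``, the response,
    and ``icv_cm3`` when ``normalize_icv`` is requested.  Knots default
    to the 5th/35th/65th/95th age percentiles.  With fewer than two
    source levels the model degrades to fixed-effects OLS with a
    warning; the same fallback is used on a singular mixed fit.
    """
    required = {"age", "sex", "source", response}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.dropna(subset=sorted(required)).copy()
    y = df[response].to_numpy(dtype=float)
    if normalize_icv:
        icv = df["icv_cm3"].to_numpy(dtype=float)
        scale = 1e-3 if response.endswith("_mm3") else 1.0
        y = icv_normalize(y * scale, icv)

    ages = df["age"].to_numpy(dtype=float)
    if knots is None:
        knots = np.percentile(ages, DEFAULT_KNOT_PERCENTILES)
    basis = SplineBasis(tuple(knots))
    X, inter_cols = _design(df, basis)

    n_sources = df["source"].nunique()
    mixed = n_sources >= 2
    result = None
    if mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(y, X, groups=df["source"].to_numpy())
                result = model.fit(reml=reml)
                if not result.converged or not np.all(np.isfinite(result.bse_fe)):
                    raise np.linalg.LinAlgError("singular mixed fit")
            except (np.linalg.LinAlgError, ValueError) as exc:
                log.warning("mixed fit failed (%s); falling back to OLS", exc)
                mixed = False
                result = None
    if not mixed and result is None:
        if n_sources < 2:
            warnings.warn("fewer than 2 sources: fitting fixed-effects OLS",
                          stacklevel=2)
        result = sm.OLS(y, X).fit()

    if mixed:
        fe = result.fe_params
        bse = result.bse_fe
        pv = result.pvalues[: len(fe)]
        cov = pd.DataFrame(np.asarray(result.cov_params())[: len(fe), : len(fe)],
                           index=X.columns, columns=X.columns)
        source_var = float(np.asarray(result.cov_re).ravel()[0])
        resid_var = float(result.scale)
        aic = float(-2 * result.llf + 2 * (len(fe) + 2))
        converged = bool(result.converged)
    else:
        fe = result.params
        bse = result.bse
        pv = result.pvalues
        cov = pd.DataFrame(np.asarray(result.cov_params()),
                           index=X.columns, columns=X.columns)
        source_var = 0.0
        resid_var = float(result.mse_resid)
        aic = float(result.aic)
        converged = True

    fe = pd.Series(np.asarray(fe), index=X.columns)
    yhat = X.to_numpy() @ fe.to_numpy()
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = len(y), X.shape[1]
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)

    # joint Wald test of the age x sex interaction block
    try:
        R = np.zeros((len(inter_cols), p))
        for r_i, c in enumerate(inter_cols):
            R[r_i, X.columns.get_loc(c)] = 1.0
        if mixed:
            R_full = np.pad(R, ((0, 0), (0, 1)))
            wald = result.wald_test(R_full, scalar=True)
        else:
            wald = result.wald_test(R, scalar=True)
        inter_p = float(np.asarray(wald.pvalue))
    except Exception:   # pragma: no cover - diagnostic only
        inter_p = np.nan

    return LifespanModelFit(
        response=response, basis=basis,
        params=fe,
        bse=pd.Series(np.asarray(bse)[: len(fe)], index=X.columns),
        pvalues=pd.Series(np.asarray(pv)[: len(fe)], index=X.columns),
        cov_params=cov, source_var=source_var, resid_var=resid_var,
        adjusted_r2=float(adj_r2), aic=aic, converged=converged, mixed=mixed,
        n_obs=n, age_range=(float(ages.min()), float(ages.max())),
        normalized_icv=normalize_icv, interaction_wald_p=inter_p,
    )


def predict_curve(fit: LifespanModelFit, ages, sex: str,
                  alpha: float = 0.05,
                  extrapolation_guard_years: float = 0.0) -> pd.DataFrame:
    """Population-level mean curve (random effects at zero) with a
    pointwise delta-method confidence band.

    Ages outside the fitted range (plus the guard) trigger a warning —
    the model is normative only over the observed ages.
    """
    ages = np.asarray(ages, dtype=float)
    lo, hi = fit.age_range
    g = extrapolation_guard_years
    if np.any(ages < lo - g) or np.any(ages > hi + g):
        warnings.warn("predicting outside the fitted age range; normative "
                      "curves extrapolate poorly at the extremes", stacklevel=2)
    df = pd.DataFrame({"age": ages, "sex": sex, "source": "any"})
    X, _ = _design(df, fit.basis)
    X = X[fit.params.index]
    beta = fit.params.to_numpy()
    mean = X.to_numpy() @ beta
    cov = fit.cov_params.loc[fit.params.index, fit.params.index].to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(), cov, X.to_numpy()))
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        "age": ages, "sex": sex, "mean": mean, "se": se,
        "lower": mean - z * se, "upper": mean + z * se,
    })
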