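"""Environmental-driver inference for quantum yields.

Two model families, mirroring a two-level analysis of canopy microenvironment
effects:

* **Linear mixed models** (per yield × season × stratum): standardized fixed
  effects of PAR, VPD and height with a species random intercept, variance
  inflation factors for collinearity screening, and Nakagawa–Schielzeth
  marginal/conditional R² splitting explained variance into environmental and
  interspecific shares.
* **Beta-likelihood additive mixed models** (whole-forest): season-specific
  penalized smooths of PAR, VPD and height (basis dimension 5 each), a season
  main effect and a species random intercept, fitted by maximum likelihood on
  a logit link. Seasonal contrasts come from pointwise smooth-difference
  curves, and each predictor's contribution to explained deviance from
  all-subsets (Shapley) hierarchical partitioning.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gam import AdditiveModel

__all__ = [
    "LmmFit",
    "GammFit",
    "fit_lmm",
    "r2_nakagawa",
    "vif",
    "fit_gamm",
    "smooth_difference",
    "hierarchical_partition",
]

DEFAULT_PREDICTORS = ("par", "vpd", "height_m")


@dataclass
class LmmFit:
    """A fitted linear mixed model with standardized predictors."""

    response: str
    coef: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    pvalues: dict[str, float]
    var_fixed: float
    var_random: float
    var_resid: float
    n: int
    n_groups: int
    converged: bool
    singular_fallback: bool = False

    @property
    def significant(self) -> dict[str, bool]:
        """Predictors whose 95% CI excludes zero."""
        return {k: not (self.ci_low[k] <= 0.0 <= self.ci_high[k])
                for k in self.coef if k != "Intercept"}


def fit_lmm(records: pd.DataFrame, response: str,
            predictors=DEFAULT_PREDICTORS, group: str = "species") -> LmmFit:
    """Linear mixed model of a yield on z-scored predictors + random intercept.

    Predictors are standardized (z-scored) before fitting so coefficients are
    comparable across predictors (response units per predictor SD); the
    response is left untransformed. A predictor is significant when its 95%
    CI excludes zero. Singular or non-converging random-effect fits fall back
    to ordinary least squares with a warning.
    """
    import statsmodels.api as sm

    data = records.dropna(subset=[response, group, *predictors])
    if data[group].nunique() < 2:
        raise ValueError("need >=2 groups for a random intercept")
    if len(data) < 10:
        raise ValueError("need >=10 records")
    y = data[response].to_numpy(dtype=float)
    Z = np.column_stack([
        (data[p].to_numpy(dtype=float) - data[p].mean()) / data[p].std(ddof=1)
        for p in predictors])
    X = sm.add_constant(Z)
    names = ["Intercept", *predictors]

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(y, X, groups=data[group].to_numpy())
            res = mod.fit(reml=True, method=["lbfgs", "cg"])
        var_re = float(np.asarray(res.cov_re)[0, 0])
        var_resid = float(res.scale)
        converged = bool(res.converged)
        if not converged or not np.isfinite(var_re):
            raise np.linalg.LinAlgError("mixed fit failed")
        params = res.fe_params
        bse = res.bse_fe
        pvals = res.pvalues[: len(names)]
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("singular random-effect fit; falling back to OLS",
                      stacklevel=2)
        singular = True
        res = sm.OLS(y, X).fit()
        params, bse, pvals = res.params, res.bse, res.pvalues
        var_re, var_resid, converged = 0.0, float(res.mse_resid), True

    coef = dict(zip(names, np.asarray(params, dtype=float)))
    se = dict(zip(names, np.asarray(bse, dtype=float)))
    z975 = 1.959963984540054
    ci_low = {k: coef[k] - z975 * se[k] for k in names}
    ci_high = {k: coef[k] + z975 * se[k] for k in names}
    fitted_fixed = X @ np.asarray(params, dtype=float)[: X.shape[1]]
    return LmmFit(
        response=response, coef=coef, se=se, ci_low=ci_low, ci_high=ci_high,
        pvalues=dict(zip(names, np.asarray(pvals, dtype=float))),
        var_fixed=float(np.var(fitted_fixed)), var_random=var_re,
        var_resid=var_resid, n=len(data),
        n_groups=int(data[group].nunique()), converged=converged,
        singular_fallback=singular,
    )


def r2_nakagawa(fit: LmmFit) -> tuple[float, float]:
    """Nakagawa–Schielzeth marginal and conditional R².

    ``marginal = σ²_f/(σ²_f+σ²_α+σ²_ε)`` captures the fixed (environmental)
    share; ``conditional`` adds the species random-intercept variance; their
    difference is the interspecific share.
    """
    denom = fit.var_fixed + fit.var_random + fit.var_resid
    marginal = fit.var_fixed / denom
    conditional = (fit.var_fixed + fit.var_random) / denom
    return float(marginal), float(conditional)


def vif(records: pd.DataFrame, predictors=DEFAULT_PREDICTORS) -> dict[str, float]:
    """Variance inflation factors, ``1/(1 − R²_j)`` per predictor.

    Perfect collinearity is reported as ``inf`` with a warning rather than an
    exception.
    """
    import statsmodels.api as sm

    data = records.dropna(subset=list(predictors))
    if len(data) <= len(predictors):
        raise ValueError("need n > number of predictors")
    out = {}
    for j, p in enumerate(predictors):
        others = [q for q in predictors if q != p]
        X = sm.add_constant(data[others].to_numpy(dtype=float))
        r2 = sm.OLS(data[p].to_numpy(dtype=float), X).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {p!r} is perfectly collinear",
                          stacklevel=2)
            out[p] = math.inf
        else:
            out[p] = float(1.0 / (1.0 - r2))
    return out


# ---------------------------------------------------------------------------
# additive mixed models

@dataclass
class GammFit:
    """A fitted beta-likelihood additive mixed model with seasonal smooths."""

    response: str
    model: AdditiveModel
    smooth_terms: dict[str, list[str]]    # predictor -> term names (per season)
    seasons: tuple[str, ...]
    edf: dict[str, float]
    deviance_explained: float
    aic: float
    phi: float | None
    n: int
    predictor_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress [0, 1] data to the open interval: ``(y(n−1)+0.5)/n``."""
    y = np.asarray(y, dtype=float)
    n = n or len(y)
    return (y * (n - 1) + 0.5) / n


def fit_gamm(records: pd.DataFrame, response: str,
             predictors=DEFAULT_PREDICTORS, season_col: str = "season",
             group: str = "species", k: int = 5,
             family: str = "beta") -> GammFit:
    """Season-stratified additive mixed model of one quantum yield.

    One penalized smooth per predictor per season (cubic regression splines,
    basis dimension ``k`` = 5), a season main effect, and a ridge-penalized
    species random intercept; beta likelihood on a logit link with the
    precision and smoothing parameters estimated by maximum likelihood.
    Responses on the [0, 1] boundary are squeezed inward with a warning.
    """
    data = records.dropna(subset=[response, season_col, group, *predictors])
    y = data[response].to_numpy(dtype=float)
    seasons = tuple(sorted(data[season_col].unique()))
    if len(seasons) < 2:
        warnings.warn("single season present; seasonal contrasts unavailable",
                      stacklevel=2)
    if family == "beta" and (np.any(y <= 0) or np.any(y >= 1)):
        warnings.warn("response values on the unit-interval boundary; "
                      "applying squeeze transform", stacklevel=2)
        y = squeeze_unit_interval(y)

    model = AdditiveModel(family=family)
    if len(seasons) > 1:
        for s in seasons[1:]:
            model.add_linear((data[season_col] == s).astype(float).to_numpy(),
                             name=f"season[{s}]")
    smooth_terms: dict[str, list[str]] = {}
    for p in predictors:
        names = []
        for s in seasons:
            nm = f"s({p}):{s}"
            model.add_smooth(data[p].to_numpy(dtype=float), k=k, name=nm,
                             by=(data[season_col] == s).astype(float).to_numpy())
            names.append(nm)
        smooth_terms[p] = names
    model.add_random(data[group].to_numpy(), name=f"re({group})")
    model.fit(y)

    return GammFit(
        response=response, model=model, smooth_terms=smooth_terms,
        seasons=seasons, edf=dict(model.edf_),
        deviance_explained=model.deviance_explained_, aic=model.aic_,
        phi=model.phi_, n=len(data),
        predictor_ranges={p: (float(data[p].min()), float(data[p].max()))
                          for p in predictors},
    )


def smooth_difference(fit: GammFit, predictor: str, n_grid: int = 200,
                      seasons: tuple[str, str] | None = None) -> pd.DataFrame:
    """Pointwise seasonal difference of a predictor's smooth (second − first).

    Evaluated on the overlap of the two seasonal covariate ranges, on the
    linear-predictor (logit) scale, with ``CI = ±1.96·√(se₁² + se₂²)``;
    ``significant`` marks points where the CI excludes zero. By default the
    seasons compared are (wet, dry) when present, i.e. the curve is dry − wet.
    """
    if seasons is None:
        if len(fit.seasons) != 2:
            raise ValueError("specify the two seasons to compare")
        # report dry − wet when those are the levels
        seasons = ("wet", "dry") if set(fit.seasons) == {"wet", "dry"} \
            else (fit.seasons[0], fit.seasons[1])
    base, other = seasons
    lo, hi = fit.predictor_ranges[predictor]
    grid = np.linspace(lo, hi, n_grid)
    names = dict(zip(fit.seasons, fit.smooth_terms[predictor]))
    f1, se1 = fit.model.term_effect(names[base], grid)
    f2, se2 = fit.model.term_effect(names[other], grid)
    diff = f2 - f1
    se = np.sqrt(se1 ** 2 + se2 ** 2)
    lo_ci, hi_ci = diff - 1.96 * se, diff + 1.96 * se
    return pd.DataFrame(dict(
        x=grid, difference=diff, se=se, ci_low=lo_ci, ci_high=hi_ci,
        significant=(lo_ci > 0) | (hi_ci < 0)))


def hierarchical_partition(records: pd.DataFrame, response: str,
                           predictors=DEFAULT_PREDICTORS,
                           family: str = "gaussian", k: int = 5,
                           fit_fn=None) -> dict[str, float]:
    """All-subsets hierarchical partitioning of explained deviance.

    Fits the additive model on every predictor subset and averages each
    predictor's marginal contribution over all orderings (its Shapley value),
    so the shares sum to the full model's explained deviance. Negative
    averaged shares are floored at zero and the remainder renormalized (with
    a warning). ``fit_fn(subset) -> explained deviance`` may be supplied to
    partition an arbitrary model family; the default fits the in-house
    additive model with smooths of each predictor.
    """
    predictors = tuple(predictors)
    p = len(predictors)
    if p > 4:
        raise ValueError("hierarchical partitioning supports at most 4 predictors")

    if fit_fn is None:
        data = records.dropna(subset=[response, *predictors])
        y = data[response].to_numpy(dtype=float)
        if family == "beta" and (np.any(y <= 0) or np.any(y >= 1)):
            y = squeeze_unit_interval(y)

        def fit_fn(subset: tuple[str, ...]) -> float:
            if not subset:
                return 0.0
            m = AdditiveModel(family=family)
            for q in subset:
                m.add_smooth(data[q].to_numpy(dtype=float), k=k, name=q)
            m.fit(y)
            return float(m.deviance_explained_)

    dev: dict[frozenset, float] = {}
    for r in range(p + 1):
        for subset in itertools.combinations(predictors, r):
            dev[frozenset(subset)] = fit_fn(subset)

    shares = {}
    for q in predictors:
        total = 0.0
        for subset in dev:
            if q in subset:
                continue
            weight = (math.factorial(len(subset))
                      * math.factorial(p - len(subset) - 1) / math.factorial(p))
            total += weight * (dev[subset | {q}] - dev[subset])
        shares[q] = total

    full = dev[frozenset(predictors)]
    if any(v < 0 for v in shares.values()):
        warnings.warn("negative averaged share floored at zero and "
                      "renormalized", stacklevel=2)
        clipped = {q: max(v, 0.0) for q, v in shares.items()}
        scale = full / sum(clipped.values()) if sum(clipped.values()) > 0 else 0.0
        shares = {q: v * scale for q, v in clipped.items()}
    return {q: float(v) for q, v in shares.items()}
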