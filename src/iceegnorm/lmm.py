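"""Random-intercept linear mixed models for normative band-power mapping.

The model per frequency band is

    RBP_i = x_i' beta + u_{h(i)} + eps_i,
    u_h ~ N(0, sigma2_u),  eps_i ~ N(0, sigma2_e),

with the originating hospital h as the grouping factor (a random
intercept) and candidate fixed effects age (raw years) and sex (0=female,
1=male).  Estimation profiles the (RE)ML criterion down to the single
variance ratio lambda = sigma2_u / sigma2_e: for fixed lambda the GLS
coefficients and the residual variance have closed forms via the Woodbury
identity on the block-diagonal marginal covariance, so fitting reduces to
bounded one-dimensional optimisation.  This keeps every fit cheap enough
for profile-likelihood confidence intervals and simulation studies, and
makes the likelihood easy to validate against a dense grid search.

Reported coefficients and variance components come from REML; ML refits
feed AIC, BIC and likelihood-ratio tests.  A fit is flagged singular when
the estimated variance ratio collapses below ``singular_tol`` (boundary
estimate), typically with few hospitals or few rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

FIXED_EFFECT_ORDER = ("age", "sex", "age:sex")

#: The four candidate fixed-effect structures, simplest first.
CANDIDATE_SPECS: Tuple[Tuple[str, ...], ...] = ((), ("age",), ("sex",), ("age", "sex"))
CANDIDATE_NAMES = {(): "null", ("age",): "age", ("sex",): "sex",
                   ("age", "sex"): "full", ("age", "sex", "age:sex"): "interaction"}


# ---------------------------------------------------------------------------
# core profiled (RE)ML machinery


def _group_codes(groups: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    return labels, codes


def _suffstats(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    H = codes.max() + 1
    n_h = np.bincount(codes, minlength=H).astype(float)
    S = np.column_stack([np.bincount(codes, weights=X[:, j], minlength=H)
                         for j in range(X.shape[1])])
    t = np.bincount(codes, weights=y, minlength=H)
    return dict(XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y),
                S=S, t=t, n_h=n_h, n=X.shape[0], p=X.shape[1])


def _gls_at(lam: float, st: dict):
    """GLS solution and profiled quantities at variance ratio ``lam``."""
    c = lam / (1.0 + lam * st["n_h"])
    A = st["XtX"] - (st["S"] * c[:, None]).T @ st["S"]
    b = st["Xty"] - st["S"].T @ (c * st["t"])
    q = st["yty"] - float(c @ (st["t"] ** 2))
    beta = np.linalg.solve(A, b)
    rss = max(q - float(b @ beta), 1e-300)
    ld = float(np.sum(np.log1p(lam * st["n_h"])))
    return beta, rss, ld, A


def _deviance(lam: float, st: dict, reml: bool) -> float:
    """-2 log (restricted) likelihood profiled over beta and sigma2_e."""
    beta, rss, ld, A = _gls_at(lam, st)
    n, p = st["n"], st["p"]
    if reml:
        s2 = rss / (n - p)
        _, logdetA = np.linalg.slogdet(A)
        return (n - p) * (np.log(2 * np.pi * s2) + 1.0) + ld + logdetA
    s2 = rss / n
    return n * (np.log(2 * np.pi * s2) + 1.0) + ld


def _optimise_lambda(st: dict, reml: bool) -> float:
    """Minimise the profiled deviance over lambda >= 0 (coarse grid + Brent)."""
    grid = np.concatenate(([0.0], 10.0 ** np.linspace(-8, 6, 29)))
    devs = [_deviance(l, st, reml) for l in grid]
    k = int(np.argmin(devs))
    if k == 0:
        # boundary candidate; verify no interior minimum hides below grid[1]
        lo, hi = -10.0, np.log10(grid[2])
    else:
        lo = np.log10(grid[max(k - 1, 1)])
        hi = np.log10(grid[min(k + 1, len(grid) - 1)])
        if k == len(grid) - 1:
            hi = np.log10(grid[-1]) + 2
    res = optimize.minimize_scalar(
        lambda phi: _deviance(10.0 ** phi, st, reml),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    lam = 10.0 ** res.x
    if _deviance(0.0, st, reml) <= res.fun + 1e-10:
        return 0.0
    return float(lam)


def _fit_core(X: np.ndarray, y: np.ndarray, codes: np.ndarray,
              reml: bool, singular_tol: float = 1e-4) -> dict:
    st = _suffstats(X, y, codes)
    n, p = st["n"], st["p"]
    if n <= p:
        raise ValueError("more coefficients than observations")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
    lam = _optimise_lambda(st, reml)
    beta, rss, ld, A = _gls_at(lam, st)
    dof = (n - p) if reml else n
    s2e = rss / dof
    s2u = lam * s2e
    cov = s2e * np.linalg.inv(A)
    c = lam / (1.0 + lam * st["n_h"])
    blup = c * (st["t"] - st["S"] @ beta)
    dev = _deviance(lam, st, reml)
    singular = bool(lam < singular_tol) or codes.max() == 0
    return dict(beta=beta, cov=cov, se=np.sqrt(np.diag(cov)),
                sigma2_group=s2u, sigma2_resid=s2e, ratio=lam,
                loglik=-dev / 2.0, deviance=dev, blup=blup,
                n=n, p=p, n_groups=int(codes.max() + 1), singular=singular)


# ---------------------------------------------------------------------------
# sklearn-style estimator


class RandomInterceptRegressor(RegressorMixin, BaseEstimator):
    """Linear regression with a single random intercept per group.

    Parameters
    ----------
    method : {"reml", "ml"}
        Estimation criterion.  REML (default) debiases the variance
        components; ML is required for likelihood-ratio tests and
        information criteria, so those are always computed from an
        internal ML refit.
    singular_tol : float
        The fit is flagged singular when the estimated variance ratio
        sigma2_group / sigma2_resid falls below this threshold.

    Attributes
    ----------
    coef_ : ndarray (n_features,)
        Fixed-effect coefficients (excluding the intercept).
    intercept_ : float
    se_coef_, se_intercept_ : standard errors of the above.
    sigma2_group_, sigma2_resid_ : variance components.
    icc_ : intraclass correlation sigma2_group / (sigma2_group + sigma2_resid).
    r2_marginal_ : variance of the fixed-effect predictor over total
        modelled variance (fixed + group + residual).
    group_labels_, group_effects_ : BLUPs of the per-group offsets.
    loglik_, loglik_ml_, aic_, bic_, singular_ : fit summaries
        (AIC/BIC from the ML criterion with p + 2 parameters).
    """

    def __init__(self, method: str = "reml", singular_tol: float = 1e-4):
        self.method = method
        self.singular_tol = singular_tol

    def fit(self, X, y, groups=None):
        if self.method not in {"reml", "ml"}:
            raise ValueError("method must be 'reml' or 'ml'")
        if groups is None:
            raise ValueError("groups is required (the random-intercept factor)")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        if not (len(X) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        self.n_features_in_ = X.shape[1]

        labels, codes = _group_codes(groups)
        if len(labels) < 2:
            warnings.warn("single group: hospital variance is unidentifiable; "
                          "fit will be flagged singular", stacklevel=2)
        Xd = np.column_stack([np.ones(len(y)), X])
        # identically-zero covariates carry no information: fit without
        # them and pin their coefficient at 0 (genuinely collinear designs
        # still raise a rank error below)
        zero_cols = np.flatnonzero(np.abs(Xd).max(axis=0) == 0.0)
        keep = np.setdiff1d(np.arange(Xd.shape[1]), zero_cols)
        Xf = Xd[:, keep]
        reml = self.method == "reml"
        res = _fit_core(Xf, y, codes, reml=reml,
                        singular_tol=self.singular_tol)
        ml = res if not reml else _fit_core(Xf, y, codes, reml=False,
                                            singular_tol=self.singular_tol)
        if len(zero_cols):
            warnings.warn("identically-zero covariate(s) dropped; their "
                          "coefficients are pinned at 0", stacklevel=2)
            for r in (res, ml) if res is not ml else (res,):
                beta = np.zeros(Xd.shape[1])
                se = np.full(Xd.shape[1], np.inf)
                cov = np.full((Xd.shape[1], Xd.shape[1]), np.nan)
                beta[keep] = r["beta"]
                se[keep] = r["se"]
                cov[np.ix_(keep, keep)] = r["cov"]
                r.update(beta=beta, se=se, cov=cov, p=Xd.shape[1])

        self.intercept_ = float(res["beta"][0])
        self.coef_ = res["beta"][1:].copy()
        self.se_intercept_ = float(res["se"][0])
        self.se_coef_ = res["se"][1:].copy()
        self.cov_params_ = res["cov"]
        self.sigma2_group_ = float(res["sigma2_group"])
        self.sigma2_resid_ = float(res["sigma2_resid"])
        self.ratio_ = float(res["ratio"])
        self.loglik_ = float(res["loglik"])
        self.loglik_ml_ = float(ml["loglik"])
        k = res["p"] + 2
        self.aic_ = 2 * k - 2 * self.loglik_ml_
        self.bic_ = k * np.log(res["n"]) - 2 * self.loglik_ml_
        self.singular_ = bool(res["singular"])
        self.group_labels_ = labels
        self.group_effects_ = ml["blup"] if not reml else res["blup"]
        self.icc_ = self.sigma2_group_ / (self.sigma2_group_ + self.sigma2_resid_)
        var_f = float(np.var(Xd @ res["beta"]))
        self.r2_marginal_ = var_f / (var_f + self.sigma2_group_ + self.sigma2_resid_)
        self.n_obs_ = res["n"]
        self.n_groups_ = res["n_groups"]
        self._X, self._y, self._codes = Xd, y, codes
        return self

    def predict(self, X, groups=None):
        """Population-level prediction; adds the group BLUP for known groups."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = self.intercept_ + X @ self.coef_
        if groups is not None:
            lut = {g: e for g, e in zip(self.group_labels_, self.group_effects_)}
            out = out + np.array([lut.get(g, 0.0) for g in np.asarray(groups)])
        return out


# ---------------------------------------------------------------------------
# domain layer: band-wise fits on normative-table rows


@dataclass
class LMMFit:
    """A fitted random-intercept model for one band's normative rows."""

    fixed_effects: Tuple[str, ...]
    method: str
    coefficients: pd.Series
    se: pd.Series
    cov_params: np.ndarray
    sigma2_hospital: float
    sigma2_residual: float
    hospital_effects: pd.Series
    loglik: float
    loglik_ml: float
    aic: float
    bic: float
    icc: float
    r2_marginal: float
    singular: bool
    n: int
    n_hospitals: int
    band: str = ""
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _codes: np.ndarray = field(default=None, repr=False)

    @property
    def names(self) -> List[str]:
        return list(self.coefficients.index)


def design_matrix(rows: pd.DataFrame,
                  fixed_effects: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    """Build the fixed-effect design: intercept + requested covariates.

    Age enters in raw years; sex is coded 0=female, 1=male (reference
    female); "age:sex" is their product.
    """
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    sex_num = None
    if "sex" in rows.columns:
        sex_num = (rows["sex"].astype(str) == "male").to_numpy(dtype=float)
    for eff in fixed_effects:
        if eff == "age":
            cols.append(rows["age"].to_numpy(dtype=float))
        elif eff == "sex":
            cols.append(sex_num)
        elif eff == "age:sex":
            cols.append(rows["age"].to_numpy(dtype=float) * sex_num)
        else:
            raise ValueError(f"unknown fixed effect {eff!r}")
        names.append(eff)
    return np.column_stack(cols), names


def fit_lmm(rows: pd.DataFrame, fixed_effects: Sequence[str] = ("age",),
            method: str = "reml", response: str = "rbp",
            singular_tol: float = 1e-4, band: str = "") -> LMMFit:
    """Fit one band's rows (columns hospital, age, sex, ``response``).

    Handles unbalanced hospital sizes by construction; with a single
    hospital the variance decomposition is unidentifiable and the fit is
    returned with the singular flag set (and a warning).
    """
    fixed_effects = tuple(fixed_effects)
    if rows[response].isna().any() or rows[["age", "sex"]].isna().any().any():
        raise ValueError("missing covariates or response")
    X, names = design_matrix(rows, fixed_effects)
    est = RandomInterceptRegressor(method=method, singular_tol=singular_tol)
    est.fit(X[:, 1:], rows[response].to_numpy(dtype=float),
            groups=rows["hospital"].to_numpy())
    beta = np.concatenate([[est.intercept_], est.coef_])
    se = np.concatenate([[est.se_intercept_], est.se_coef_])
    return LMMFit(
        fixed_effects=fixed_effects, method=method,
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov_params=est.cov_params_,
        sigma2_hospital=est.sigma2_group_, sigma2_residual=est.sigma2_resid_,
        hospital_effects=pd.Series(est.group_effects_, index=est.group_labels_),
        loglik=est.loglik_, loglik_ml=est.loglik_ml_,
        aic=est.aic_, bic=est.bic_, icc=est.icc_,
        r2_marginal=0.0 if not fixed_effects else est.r2_marginal_,
        singular=est.singular_, n=est.n_obs_, n_hospitals=est.n_groups_,
        band=band, _X=est._X, _y=est._y, _codes=est._codes,
    )


def icc(fit: LMMFit) -> float:
    """sigma2_hospital / (sigma2_hospital + sigma2_residual)."""
    return fit.sigma2_hospital / (fit.sigma2_hospital + fit.sigma2_residual)


def marginal_r2(fit: LMMFit) -> float:
    """Fixed-effect predictor variance over total modelled variance.

    The denominator includes the hospital and residual variances, so
    values are not additive across models with different fixed effects.
    """
    if not fit.fixed_effects:
        return 0.0
    var_f = float(np.var(fit._X @ fit.coefficients.to_numpy()))
    return var_f / (var_f + fit.sigma2_hospital + fit.sigma2_residual)


def wald_ci(fit: LMMFit, parameter: str, level: float = 0.95) -> Tuple[float, float]:
    j = fit.names.index(parameter)
    z = norm.ppf(0.5 + level / 2.0)
    b, s = fit.coefficients.iloc[j], fit.se.iloc[j]
    return (b - z * s, b + z * s)


def profile_ci(fit: LMMFit, parameter: str,
               level: float = 0.95) -> Tuple[float, float]:
    """Profile-likelihood confidence interval for one fixed effect.

    Profiles the ML deviance over the remaining coefficients and both
    variance components (via an offset refit without the profiled
    column) and cuts at the chi-square(1) quantile.  Falls back to the
    Wald interval, with a logged notice, if the profile fails to bracket
    the cutoff within +/-10 Wald standard errors.
    """
    if parameter not in fit.names:
        raise KeyError(f"parameter {parameter!r} not in the model "
                       f"({fit.names})")
    j = fit.names.index(parameter)
    X, y, codes = fit._X, fit._y, fit._codes
    xj = X[:, j]
    Xr = np.delete(X, j, axis=1)

    dev_full = -2.0 * fit.loglik_ml

    def profile_dev(c: float) -> float:
        st = _suffstats(Xr, y - c * xj, codes)
        lam = _optimise_lambda(st, reml=False)
        return _deviance(lam, st, reml=False)

    cutoff = chi2.ppf(level, 1)
    bhat = float(fit.coefficients.iloc[j])
    se_w = float(fit.se.iloc[j])

    def g(c: float) -> float:
        return profile_dev(c) - dev_full - cutoff

    out = []
    for sign in (-1.0, 1.0):
        hi = bhat + sign * 10.0 * se_w
        if g(hi) <= 0:
            logger.warning("profile CI for %r failed to bracket; "
                           "falling back to Wald", parameter)
            return wald_ci(fit, parameter, level)
        lo = optimize.brentq(g, min(bhat, hi), max(bhat, hi),
                             xtol=max(1e-6 * max(se_w, 1e-12), 1e-15))
        out.append(lo)
    return (min(out), max(out))


def lrt(fit_null: LMMFit, fit_alt: LMMFit) -> Tuple[float, float]:
    """Likelihood-ratio test between ML fits differing by one fixed effect."""
    if fit_null.method != "ml" or fit_alt.method != "ml":
        raise ValueError("likelihood-ratio tests require ML fits "
                         "(REML criteria are not comparable across designs)")
    s0, s1 = set(fit_null.fixed_effects), set(fit_alt.fixed_effects)
    if not (s0 < s1 and len(s1 - s0) == 1):
        raise ValueError("models must be nested, differing by exactly one term")
    if fit_null.n != fit_alt.n or not np.array_equal(fit_null._y, fit_alt._y):
        raise ValueError("fits must use identical rows")
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return stat, float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# model selection


@dataclass
class ModelSelectionResult:
    chosen: Tuple[str, ...]
    chosen_name: str
    fits_ml: Dict[str, LMMFit]
    fits_reml: Dict[str, LMMFit]
    summary: pd.DataFrame
    lrts: pd.DataFrame
    trace: List[str]


def select_model(rows: pd.DataFrame, response: str = "rbp",
                 alpha: float = 0.05, ci_method: str = "profile",
                 include_interaction: bool = False,
                 band: str = "") -> ModelSelectionResult:
    """Choose the fixed-effect structure among null/age/sex/full.

    All four candidates are fitted by ML (information criteria, LRTs)
    and REML (reported estimates).  The metrics *agree* when the
    AIC-best and BIC-best model coincide with the unique largest model
    whose every term has a 95% CI excluding zero and whose single-term
    LRTs all reject at ``alpha``.  When metrics split, the simpler of
    the contending models is retained, and the trace records the
    tie-break.  An age x sex interaction can be added to the candidate
    set but is off by default.
    """
    trace: List[str] = []
    cands = list(CANDIDATE_SPECS)
    if include_interaction:
        cands.append(("age", "sex", "age:sex"))
    fits_ml = {CANDIDATE_NAMES[c]: fit_lmm(rows, c, method="ml",
                                           response=response, band=band)
               for c in cands}
    fits_reml = {CANDIDATE_NAMES[c]: fit_lmm(rows, c, method="reml",
                                             response=response, band=band)
                 for c in cands}

    # nested single-term LRTs
    lrt_rows = []
    for name0, name1 in [("null", "age"), ("null", "sex"),
                         ("age", "full"), ("sex", "full")]:
        stat, p = lrt(fits_ml[name0], fits_ml[name1])
        added = (set(fits_ml[name1].fixed_effects)
                 - set(fits_ml[name0].fixed_effects)).pop()
        lrt_rows.append((name0, name1, added, stat, p))
    lrts = pd.DataFrame(lrt_rows, columns=["null", "alt", "term", "stat", "p"])

    ci_fun = profile_ci if ci_method == "profile" else wald_ci
    support: Dict[str, bool] = {}
    ci_notes: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for name, f in fits_ml.items():
        ok = True
        cis = {}
        for term in f.fixed_effects:
            lo, hi = ci_fun(f, term)
            cis[term] = (lo, hi)
            if lo <= 0.0 <= hi:
                ok = False
            sub = lrts[(lrts["alt"] == name) & (lrts["term"] == term)]
            if len(sub) and float(sub["p"].iloc[0]) >= alpha:
                ok = False
        support[name] = ok
        ci_notes[name] = cis

    sizes = {n: len(f.fixed_effects) for n, f in fits_ml.items()}
    aic_best = min(fits_ml, key=lambda n: fits_ml[n].aic)
    bic_best = min(fits_ml, key=lambda n: fits_ml[n].bic)
    supported = [n for n, ok in support.items() if ok]
    maximal = [n for n in supported
               if not any(set(fits_ml[n].fixed_effects)
                          < set(fits_ml[m].fixed_effects)
                          for m in supported)]
    sig_best = maximal[0] if len(maximal) == 1 else None
    trace.append(f"AIC best: {aic_best}; BIC best: {bic_best}; "
                 f"significance-supported maximal: {maximal}")

    if sig_best is not None and aic_best == bic_best == sig_best:
        chosen = aic_best
        trace.append(f"all metrics agree on the {chosen} model")
    else:
        contenders = {aic_best, bic_best}
        if sig_best is not None:
            contenders.add(sig_best)
        simplest = min(sizes[n] for n in contenders)
        simple_set = [n for n in contenders if sizes[n] == simplest]
        if len(simple_set) == 1:
            chosen = simple_set[0]
        else:
            chosen = min(simple_set, key=lambda n: fits_ml[n].bic)
        trace.append(f"metrics split between {sorted(contenders)}; "
                     f"retaining the simpler {chosen} model (tie-break)")

    summary = pd.DataFrame({
        "model": list(fits_ml),
        "n_terms": [sizes[n] for n in fits_ml],
        "aic": [fits_ml[n].aic for n in fits_ml],
        "bic": [fits_ml[n].bic for n in fits_ml],
        "loglik_ml": [fits_ml[n].loglik_ml for n in fits_ml],
        "icc": [fits_reml[n].icc for n in fits_ml],
        "r2_marginal": [fits_reml[n].r2_marginal for n in fits_ml],
        "supported": [support[n] for n in fits_ml],
        "singular": [fits_reml[n].singular for n in fits_ml],
    })
    for name, cis in ci_notes.items():
        for term, (lo, hi) in cis.items():
            trace.append(f"{name}: CI({term}) = ({lo:.6g}, {hi:.6g})")

    return ModelSelectionResult(
        chosen=fits_ml[chosen].fixed_effects, chosen_name=chosen,
        fits_ml=fits_ml, fits_reml=fits_reml, summary=summary,
        lrts=lrts, trace=trace)


# ---------------------------------------------------------------------------
# regional (per-ROI) normative maps


REGIONAL_COLUMNS = ["roi", "band", "n", "n_hospitals", "fitted", "reason",
                    "intercept", "b_age", "se_age", "ci_lo", "ci_hi",
                    "ci_contains_zero", "sigma2_hospital", "sigma2_residual",
                    "singular"]


def fit_regional(table, band: str, fixed_effects: Sequence[str] = ("age",),
                 min_rows: int = 10, ci_method: str = "wald",
                 level: float = 0.95,
                 allow_unmirrored: bool = False) -> pd.DataFrame:
    """Fit the age model per ROI and summarise it map-style.

    Returns one row per ROI (ordered by decreasing n): age slope, its
    standard error, the 95% CI and whether it contains zero, the variance
    components and the singular flag.  All fits are retained, including
    singular ones; ROIs with fewer than ``min_rows`` rows are marked
    unfitted with a reason.
    """
    from .cohort import NormativeTable  # local import avoids cycles

    if isinstance(table, NormativeTable):
        if not table.mirrored and not allow_unmirrored:
            raise ValueError("regional maps expect the mirrored table "
                             "(pass allow_unmirrored=True to override)")
        rows = table.band_rows(band)
        universe = table.regions
    else:
        rows = table
        universe = sorted(rows["roi"].unique())

    out = []
    for roi in universe:
        sub = rows[rows["roi"] == roi]
        n = len(sub)
        if n < min_rows:
            out.append(dict(roi=roi, band=band, n=n,
                            n_hospitals=sub["hospital"].nunique(),
                            fitted=False, reason=f"fewer than {min_rows} rows",
                            intercept=np.nan, b_age=np.nan, se_age=np.nan,
                            ci_lo=np.nan, ci_hi=np.nan,
                            ci_contains_zero=pd.NA,
                            sigma2_hospital=np.nan, sigma2_residual=np.nan,
                            singular=pd.NA))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-hospital ROIs warn
            f = fit_lmm(sub, fixed_effects, method="reml", band=band)
        ci_fun = profile_ci if ci_method == "profile" else wald_ci
        lo, hi = ci_fun(f, "age", level)
        out.append(dict(
            roi=roi, band=band, n=n, n_hospitals=f.n_hospitals, fitted=True,
            reason="", intercept=f.coefficients["intercept"],
            b_age=f.coefficients["age"], se_age=f.se["age"],
            ci_lo=lo, ci_hi=hi, ci_contains_zero=bool(lo <= 0.0 <= hi),
            sigma2_hospital=f.sigma2_hospital,
            sigma2_residual=f.sigma2_residual, singular=f.singular))
    df = pd.DataFrame(out, columns=REGIONAL_COLUMNS)
    return df.sort_values("n", ascending=False, kind="stable").reset_index(drop=True)
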