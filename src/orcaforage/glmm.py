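"""Mixed-effects models for deployment- and dive-level foraging responses.

Four response families cover the analysis: Poisson and NB1 (negative
binomial with variance linear in the mean, mu * (1 + alpha)) for capture
counts with a log link and an offset; beta with a logit link for time-budget
proportions, optionally with a log-linear dispersion covariate; Gaussian for
log-transformed depths.

Count and beta families with a single random intercept are fitted by
maximum likelihood with adaptive Gauss-Hermite quadrature over the random
effect (15 nodes by default; the likelihood is integrated exactly enough
that doubling the nodes moves it by < 1e-4 on cohort-scale data).  Gaussian
responses go through statsmodels' MixedLM (REML by default, ML for
likelihood-ratio tests), which also handles two crossed random intercepts.

Model-building utilities implement the surrounding protocol: AIC selection
of the random structure with a delta-2 threshold, recursive single-term
deletion by likelihood-ratio test honoring marginality, Tukey-style
single-step pairwise contrasts of estimated marginal means, and a
simulation-based overdispersion check.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "ContrastResult",
    "transform_beta_response",
    "fit_glmm",
    "select_random_structure",
    "drop_terms_lrt",
    "pairwise_contrasts",
    "overdispersion_check",
]

_FAMILIES = ("poisson", "nbinom1", "beta", "gaussian")
_OFFSET_TRANSFORMS = {"log": np.log, "sqrt": np.sqrt, "identity": lambda x: x}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed`` lists main effects and ``a:b`` interactions by column name.
    ``offset`` is a ``(transform, column)`` pair entering the linear
    predictor with coefficient one.  ``dispersion_covariate`` names a factor
    whose levels get their own beta precision (log-linear), as in variable-
    dispersion beta regression.
    """

    response: str
    family: str
    fixed: tuple = ()
    random_intercepts: tuple = ()
    offset: Optional[tuple] = None
    dispersion_covariate: Optional[str] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random_intercepts", tuple(self.random_intercepts))
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.random_intercepts) > 2:
            raise ValueError("at most two random intercepts are supported")
        if self.family != "gaussian" and len(self.random_intercepts) > 1:
            raise ValueError("non-Gaussian families support one random intercept")
        if self.offset is not None and self.family not in ("poisson", "nbinom1"):
            raise ValueError("offsets are only meaningful for count families")
        if self.dispersion_covariate is not None and self.family != "beta":
            raise ValueError("dispersion covariates apply to the beta family only")

    def drop_term(self, term: str) -> "ModelSpec":
        return dataclasses.replace(self, fixed=tuple(t for t in self.fixed if t != term))

    @property
    def link(self) -> str:
        return {"poisson": "log", "nbinom1": "log", "beta": "logit", "gaussian": "identity"}[
            self.family
        ]


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: dict
    standard_errors: dict
    statistics: dict  # z (non-Gaussian) or t (Gaussian)
    p_values: dict
    variance_components: dict  # random factor -> variance
    dispersion: dict  # {"alpha": ...} for nbinom1, {"log_phi coefs"} for beta
    loglik: float
    n_params: int
    converged: bool
    method: str
    n_obs: int
    # internals used by contrasts / simulation
    _names: list = field(repr=False, default_factory=list)
    _beta: np.ndarray = field(repr=False, default=None)
    _vcov_fixed: np.ndarray = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)
    _levels: dict = field(repr=False, default_factory=dict)
    _offset: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple  # (level_a, level_b)
    estimate: float  # difference a - b on the link scale
    se: float
    statistic: float
    p_value: float  # familywise single-step adjusted
    p_unadjusted: float


# ---------------------------------------------------------------------------
# design matrices


def _is_categorical(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s) or pd.api.types.is_bool_dtype(s)


def _term_columns(data: pd.DataFrame, name: str, levels: dict):
    s = data[name]
    if _is_categorical(s):
        levs = levels.setdefault(name, sorted(map(str, s.unique())))
        sv = s.astype(str)
        cols = [(f"{name}[{lv}]", (sv == lv).to_numpy(float)) for lv in levs[1:]]
        if not cols:
            raise ValueError(f"factor {name!r} has a single level")
        return cols
    return [(name, s.to_numpy(float))]


def build_design(data: pd.DataFrame, terms: Sequence[str], levels: Optional[dict] = None):
    """Treatment-coded design matrix with intercept.

    ``levels`` fixes factor level order (first level is the baseline); it is
    filled in on first use so later calls (reference grids, simulations)
    stay column-compatible.
    """
    levels = levels if levels is not None else {}
    n = len(data)
    names = ["(Intercept)"]
    cols = [np.ones(n)]
    for term in terms:
        parts = term.split(":")
        part_cols = [_term_columns(data, p, levels) for p in parts]
        combos = [[]]
        for pc in part_cols:
            combos = [c + [item] for c in combos for item in pc]
        for combo in combos:
            names.append(":".join(nm for nm, _ in combo))
            prod = np.ones(n)
            for _, v in combo:
                prod = prod * v
            cols.append(prod)
    return np.column_stack(cols), names, levels


# ---------------------------------------------------------------------------
# family log-likelihoods (per-observation) and derivatives w.r.t. eta


class _Poisson:
    n_extra = 0

    @staticmethod
    def aux(extra, disp_design):
        return None

    @staticmethod
    def ll(y, eta, aux):
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)

    @staticmethod
    def d1(y, eta, aux):
        return y - np.exp(eta)

    @staticmethod
    def d2(y, eta, aux):
        return -np.exp(eta)

    @staticmethod
    def variance(mu, aux):
        return mu

    @staticmethod
    def simulate(rng, mu, aux):
        return rng.poisson(mu)


class _NBinom1:
    """Negative binomial, variance mu * (1 + alpha): r = mu/alpha, p = 1/(1+alpha)."""

    n_extra = 1

    @staticmethod
    def aux(extra, disp_design):
        return np.exp(extra[0])  # alpha > 0

    @staticmethod
    def ll(y, eta, alpha):
        r = np.exp(eta) / alpha
        return (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            - r * np.log1p(alpha)
            + y * (np.log(alpha) - np.log1p(alpha))
        )

    @staticmethod
    def d1(y, eta, alpha):
        r = np.exp(eta) / alpha
        return r * (special.digamma(y + r) - special.digamma(r) - np.log1p(alpha))

    @staticmethod
    def d2(y, eta, alpha):
        r = np.exp(eta) / alpha
        d1 = r * (special.digamma(y + r) - special.digamma(r) - np.log1p(alpha))
        return d1 + r * r * (special.polygamma(1, y + r) - special.polygamma(1, r))

    @staticmethod
    def variance(mu, alpha):
        return mu * (1.0 + alpha)

    @staticmethod
    def simulate(rng, mu, alpha):
        lam = rng.gamma(shape=mu / alpha, scale=alpha)
        return rng.poisson(lam)


class _Beta:
    """Beta regression with logit link; precision phi log-linear in extras."""

    n_extra = None  # depends on the dispersion design

    @staticmethod
    def aux(extra, disp_design):
        return np.exp(disp_design @ extra)  # per-observation phi

    @staticmethod
    def ll(y, eta, phi):
        mu = special.expit(eta)
        a, b = mu * phi, (1.0 - mu) * phi
        return (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )

    @staticmethod
    def d1(y, eta, phi):
        mu = special.expit(eta)
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
        return phi * (ystar - mustar) * mu * (1.0 - mu)

    @staticmethod
    def d2(y, eta, phi, _h=1e-5):
        return (_Beta.d1(y, eta + _h, phi) - _Beta.d1(y, eta - _h, phi)) / (2 * _h)

    @staticmethod
    def variance(mu, phi):
        return mu * (1.0 - mu) / (1.0 + phi)

    @staticmethod
    def simulate(rng, mu, phi):
        return rng.beta(mu * phi, (1.0 - mu) * phi)


_FAMILY_IMPL = {"poisson": _Poisson, "nbinom1": _NBinom1, "beta": _Beta}


def transform_beta_response(y, n: int):
    """Squeeze boundary proportions off 0 and 1: (y (n-1) + 0.5) / n.

    Applied to exact 0s and 1s only; interior values pass through.  ``n``
    is the sample size of the model the response enters.
    """
    if n < 2:
        raise ValueError("boundary transform needs a sample size of at least 2")
    y = np.asarray(y, dtype=float)
    out = y.copy()
    boundary = (y == 0.0) | (y == 1.0)
    out[boundary] = (y[boundary] * (n - 1) + 0.5) / n
    return out


# ---------------------------------------------------------------------------
# AGQ machinery


def _group_modes(fam, y, eta, aux, codes, n_groups, sigma2, b0):
    """Per-group posterior modes of the random intercept, vectorized Newton."""
    b = b0.copy()
    for _ in range(100):
        eb = eta + b[codes]
        g1 = np.bincount(codes, fam.d1(y, eb, aux), minlength=n_groups) - b / sigma2
        g2 = np.bincount(codes, fam.d2(y, eb, aux), minlength=n_groups) - 1.0 / sigma2
        g2 = np.minimum(g2, -1e-10)
        step = g1 / g2
        # dampen the occasional overshoot in early iterations
        step = np.clip(step, -5.0, 5.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-11:
            break
    return b, g2


def _agq_loglik(fam, y, eta, aux, codes, n_groups, sigma, z, logw, b0):
    if sigma < 1e-8:
        return float(fam.ll(y, eta, aux).sum()), b0 * 0.0
    sigma2 = sigma * sigma
    b_hat, g2 = _group_modes(fam, y, eta, aux, codes, n_groups, sigma2, b0)
    s_hat = 1.0 / np.sqrt(-g2)
    # nodes: (K, G)
    bk = b_hat[None, :] + np.sqrt(2.0) * s_hat[None, :] * z[:, None]
    ll_obs = fam.ll(y[None, :], eta[None, :] + bk[:, codes], aux)
    ll_group = np.zeros((z.size, n_groups))
    for k in range(z.size):
        ll_group[k] = np.bincount(codes, ll_obs[k], minlength=n_groups)
    log_prior = -0.5 * (bk**2) / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
    log_integrand = logw[:, None] + z[:, None] ** 2 + ll_group + log_prior
    group_ll = np.log(np.sqrt(2.0) * s_hat) + special.logsumexp(log_integrand, axis=0)
    return float(group_ll.sum()), b_hat


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    used = {spec.response}
    for t in spec.fixed:
        used.update(t.split(":"))
    used.update(spec.random_intercepts)
    if spec.offset is not None:
        used.add(spec.offset[1])
    if spec.dispersion_covariate is not None:
        used.add(spec.dispersion_covariate)
    df = data.dropna(subset=sorted(used)).reset_index(drop=True)
    X, names, levels = build_design(df, spec.fixed)
    y = df[spec.response].to_numpy(float)
    if spec.offset is not None:
        tf, col = spec.offset
        offset = _OFFSET_TRANSFORMS[tf](df[col].to_numpy(float))
    else:
        offset = np.zeros(len(df))
    if spec.dispersion_covariate is not None:
        Zd, disp_names, _ = build_design(df, [spec.dispersion_covariate], levels)
    else:
        Zd, disp_names = np.ones((len(df), 1)), ["(Intercept)"]
    return df, X, names, y, offset, Zd, disp_names, levels


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, n_quad: int = 15) -> FitResult:
    """Maximum-likelihood (or REML for Gaussian) fit of a mixed model.

    Non-convergence is flagged on the result, never silently replaced by a
    fallback fit.
    """
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data, reml=True)
    df, X, names, y, offset, Zd, disp_names, levels = _prepare(spec, data)
    if spec.family == "beta" and (np.any(y <= 0) or np.any(y >= 1)):
        raise ValueError("beta responses must lie in (0, 1); apply transform_beta_response")
    fam = _FAMILY_IMPL[spec.family]
    n_extra = Zd.shape[1] if spec.family == "beta" else fam.n_extra
    has_re = len(spec.random_intercepts) == 1
    if has_re:
        codes, uniques = pd.factorize(df[spec.random_intercepts[0]].astype(str))
        n_groups = len(uniques)
    else:
        codes, n_groups = np.zeros(len(df), dtype=int), 1
    z, w = hermgauss(n_quad)
    logw = np.log(w)
    p = X.shape[1]
    b_cache = np.zeros(n_groups)

    def unpack(theta):
        beta = theta[:p]
        k = p
        sigma = 0.0
        if has_re:
            sigma = abs(theta[k])
            k += 1
        extra = theta[k : k + n_extra]
        return beta, sigma, extra

    def negll(theta):
        beta, sigma, extra = unpack(theta)
        aux = fam.aux(extra, Zd)
        eta = X @ beta + offset
        if has_re:
            ll, _ = _agq_loglik(fam, y, eta, aux, codes, n_groups, sigma, z, logw, b_cache)
        else:
            ll = float(fam.ll(y, eta, aux).sum())
        if not np.isfinite(ll):
            return 1e10
        return -ll

    # starting values: link-scale mean response, unit-ish dispersion
    x0 = np.zeros(p + (1 if has_re else 0) + n_extra)
    ybar = y.mean()
    if spec.family in ("poisson", "nbinom1"):
        x0[0] = np.log(max(ybar, 0.1)) - offset.mean()
    else:
        x0[0] = special.logit(np.clip(ybar, 1e-3, 1 - 1e-3))
    if has_re:
        x0[p] = 0.5
    if spec.family == "beta":
        x0[p + (1 if has_re else 0)] = np.log(5.0)

    res = optimize.minimize(
        negll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-7}
    )
    if not res.success or np.linalg.norm(res.jac) > 1e-3:
        # simplex restart rescues the occasional bad BFGS path, then polish
        res_nm = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        res = optimize.minimize(
            negll, res_nm.x, method="BFGS", options={"maxiter": 500, "gtol": 1e-7}
        )
        if not res.success and res_nm.fun < res.fun:
            res = res_nm
            res.jac = np.zeros_like(res.x)
    theta = res.x
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-3)
    beta, sigma, extra = unpack(theta)
    loglik = -negll(theta)

    # observed-information covariance by central finite differences
    free = np.ones(theta.size, dtype=bool)
    if has_re and sigma < 1e-5:
        free[p] = False  # variance at the boundary: no curvature to invert
    H = _numeric_hessian(negll, theta, free)
    try:
        vcov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_free = np.linalg.pinv(H)
        converged = False
    vcov = np.zeros((theta.size, theta.size))
    vcov[np.ix_(free, free)] = vcov_free
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))

    coeffs = dict(zip(names, beta))
    ses = dict(zip(names, se[:p]))
    zvals = {k: coeffs[k] / ses[k] if ses[k] > 0 else np.nan for k in names}
    pvals = {k: 2 * stats.norm.sf(abs(zvals[k])) for k in names}
    vc = {}
    if has_re:
        vc[spec.random_intercepts[0]] = sigma**2
    dispersion = {}
    if spec.family == "nbinom1":
        dispersion["alpha"] = float(np.exp(extra[0]))
    elif spec.family == "beta":
        dispersion = {f"log_phi:{nm}": float(v) for nm, v in zip(disp_names, extra)}
    n_params = p + (1 if has_re else 0) + n_extra
    return FitResult(
        spec=spec,
        coefficients=coeffs,
        standard_errors=ses,
        statistics=zvals,
        p_values=pvals,
        variance_components=vc,
        dispersion=dispersion,
        loglik=loglik,
        n_params=n_params,
        converged=converged,
        method=f"ML (adaptive GH quadrature, {n_quad} nodes)" if has_re else "ML",
        n_obs=len(df),
        _names=names,
        _beta=beta,
        _vcov_fixed=vcov[:p, :p],
        _data=df,
        _levels=levels,
        _offset=offset,
        _X=X,
    )


def _numeric_hessian(f, x, free, h=1e-4):
    idx = np.flatnonzero(free)
    m = idx.size
    H = np.zeros((m, m))
    f0 = f(x)
    steps = h * (1.0 + np.abs(x[idx]))
    for a in range(m):
        for b in range(a, m):
            ea = np.zeros_like(x)
            eb = np.zeros_like(x)
            ea[idx[a]] = steps[a]
            eb[idx[b]] = steps[b]
            fpp = f(x + ea + eb)
            fpm = f(x + ea - eb)
            fmp = f(x - ea + eb)
            fmm = f(x - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * steps[a] * steps[b])
    return H


# ---------------------------------------------------------------------------
# Gaussian LMM via statsmodels


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame, reml: bool = True) -> FitResult:
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    df, X, names, y, offset, _, _, levels = _prepare(spec, data)
    n = len(df)
    res_kwargs = {}
    if len(spec.random_intercepts) <= 1:
        if spec.random_intercepts:
            groups = df[spec.random_intercepts[0]].astype(str).to_numpy()
        else:
            groups = np.zeros(n)  # single group; residual variance only
        model = MixedLM(y, X, groups=groups)
    else:
        # two crossed intercepts: everyone in one group, one variance
        # component per factor via one-hot indicator matrices
        mats, vc_names, colnames = [], [], []
        for f in spec.random_intercepts:
            codes, uniq = pd.factorize(df[f].astype(str))
            ind = np.zeros((n, len(uniq)))
            ind[np.arange(n), codes] = 1.0
            mats.append([ind])
            vc_names.append(f)
            colnames.append([list(map(str, uniq))])
        vcs = VCSpec(vc_names, colnames, mats)
        model = MixedLM(y, X, groups=np.zeros(n), exog_vc=vcs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method="lbfgs", maxiter=500)
    beta = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    coeffs = dict(zip(names, beta))
    ses = dict(zip(names, se))
    tvals = {k: coeffs[k] / ses[k] for k in names}
    pvals = dict(zip(names, np.asarray(result.pvalues)[: len(names)]))
    vc = {}
    if len(spec.random_intercepts) == 1:
        vc[spec.random_intercepts[0]] = float(np.asarray(result.cov_re)[0, 0])
    elif len(spec.random_intercepts) == 2:
        for f, v in zip(spec.random_intercepts, np.asarray(result.vcomp)):
            vc[f] = float(v)
    p = X.shape[1]
    n_params = p + len(spec.random_intercepts) + 1  # + residual variance
    return FitResult(
        spec=spec,
        coefficients=coeffs,
        standard_errors=ses,
        statistics=tvals,
        p_values=pvals,
        variance_components=vc,
        dispersion={"residual_variance": float(result.scale)},
        loglik=float(result.llf),
        n_params=n_params,
        converged=bool(result.converged),
        method="REML" if reml else "ML",
        n_obs=n,
        _names=names,
        _beta=beta,
        _vcov_fixed=np.asarray(result.cov_params())[:p, :p],
        _data=df,
        _levels=levels,
        _offset=offset,
        _X=X,
    )


def _fit_ml(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """ML fit regardless of family (LRTs must not compare REML fits)."""
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data, reml=False)
    return fit_glmm(spec, data)


# ---------------------------------------------------------------------------
# model-building protocol


def select_random_structure(
    candidates: Sequence[ModelSpec], data: pd.DataFrame, delta: float = 2.0
) -> ModelSpec:
    """AIC selection of the random structure with a delta threshold.

    Among candidates within ``delta`` of the smallest AIC the one with the
    fewest parameters wins; ties break toward fewer random factors, then
    listed order.  Non-convergent candidates are excluded with a warning.
    """
    fits = []
    for cand in candidates:
        fit = _fit_ml(cand, data)
        if not fit.converged:
            warnings.warn(f"candidate {cand.random_intercepts} did not converge; excluded")
            continue
        fits.append((cand, fit))
    if not fits:
        raise ValueError("no candidate converged")
    best_aic = min(f.aic for _, f in fits)
    eligible = [
        (i, c, f) for i, (c, f) in enumerate(fits) if f.aic <= best_aic + delta
    ]
    eligible.sort(key=lambda t: (t[2].n_params, len(t[1].random_intercepts), t[0]))
    return eligible[0][1]


def _droppable(spec: ModelSpec) -> list:
    """Terms not protected by marginality (no retained higher-order term)."""
    out = []
    for t in spec.fixed:
        parts = set(t.split(":"))
        protected = any(
            parts < set(other.split(":")) for other in spec.fixed if other != t
        )
        if not protected:
            out.append(t)
    return out


def drop_terms_lrt(full: ModelSpec, data: pd.DataFrame, alpha: float = 0.05):
    """Recursive single-term deletion by likelihood-ratio test.

    Interactions are eligible before their main effects (marginality).  At
    each round the least significant droppable term with LRT p >= alpha is
    removed; fits are by ML.  Returns ``(final_spec, trace)`` where trace
    records each tested deletion as (term, lrt_statistic, df, p, dropped).
    """
    spec = full
    trace = []
    current = _fit_ml(spec, data)
    while True:
        best = None
        for term in _droppable(spec):
            reduced_spec = spec.drop_term(term)
            reduced = _fit_ml(reduced_spec, data)
            lr = 2.0 * (current.loglik - reduced.loglik)
            df_diff = current.n_params - reduced.n_params
            pval = stats.chi2.sf(max(lr, 0.0), df_diff)
            trace.append((term, lr, df_diff, pval, False))
            if pval >= alpha and (best is None or pval > best[3]):
                best = (term, reduced_spec, reduced, pval)
        if best is None:
            return spec, trace
        term, spec, current, pval = best
        trace.append((term, np.nan, 0, pval, True))
        if not spec.fixed:
            return spec, trace


def _reference_grid(fit: FitResult, factor: str):
    """Rows of the full factorial over model factors; numerics at their mean."""
    factors = {f: levs for f, levs in fit._levels.items()}
    if factor not in factors:
        raise ValueError(f"{factor!r} is not a factor in the fitted model")
    keys = list(factors)
    grids = np.meshgrid(*[np.arange(len(factors[k])) for k in keys], indexing="ij")
    rows = {k: [factors[k][i] for i in g.ravel()] for k, g in zip(keys, grids)}
    grid = pd.DataFrame(rows)
    numeric_terms = set()
    for t in fit.spec.fixed:
        for p in t.split(":"):
            if p not in factors:
                numeric_terms.add(p)
    for p in numeric_terms:
        grid[p] = float(fit._data[p].mean())
    return grid


def pairwise_contrasts(
    fit: FitResult, factor: str, n_mc: int = 200_000, seed: int = 12345
) -> list[ContrastResult]:
    """Tukey-style all-pairs contrasts of estimated marginal means.

    Marginal means are averages of link-scale predictions over the full
    factorial reference grid (offsets excluded; they cancel in contrasts of
    a common grid).  Familywise adjustment is single-step: each p-value is
    P(max |Z| over all contrasts exceeds the observed |z|) under the joint
    normal of the contrast estimates, evaluated by a seeded Monte-Carlo
    sample of the estimated-mean distribution.
    """
    grid = _reference_grid(fit, factor)
    Xg, _, _ = build_design(grid, fit.spec.fixed, dict(fit._levels))
    levels = fit._levels[factor]
    if len(levels) < 2:
        raise ValueError("pairwise contrasts need a factor with at least two levels")
    emm_rows = []
    for lv in levels:
        mask = (grid[factor] == lv).to_numpy()
        emm_rows.append(Xg[mask].mean(axis=0))
    L = np.asarray(emm_rows)  # (k, p): EMM = L @ beta
    emm_cov = L @ fit._vcov_fixed @ L.T
    emm = L @ fit._beta
    pairs = [(a, b) for a in range(len(levels)) for b in range(a + 1, len(levels))]
    C = np.zeros((len(pairs), len(levels)))
    for i, (a, b) in enumerate(pairs):
        C[i, a], C[i, b] = 1.0, -1.0
    est = C @ emm
    cov = C @ emm_cov @ C.T
    se = np.sqrt(np.diag(cov))
    zstat = est / se
    p_unadj = 2 * stats.norm.sf(np.abs(zstat))
    if len(pairs) == 1:
        p_adj = p_unadj
    else:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            np.zeros(len(levels)), emm_cov, size=n_mc, method="svd"
        )
        zdraws = np.abs(draws @ C.T) / se
        maxz = zdraws.max(axis=1)
        p_adj = np.array([(maxz >= abs(zi)).mean() for zi in zstat])
        p_adj = np.maximum(p_adj, p_unadj)
    return [
        ContrastResult(
            pair=(levels[a], levels[b]),
            estimate=float(est[i]),
            se=float(se[i]),
            statistic=float(zstat[i]),
            p_value=float(p_adj[i]),
            p_unadjusted=float(p_unadj[i]),
        )
        for i, (a, b) in enumerate(pairs)
    ]


def overdispersion_check(
    fit: FitResult, n_sim: int = 250, seed: int = 0
) -> dict:
    """Simulation-based dispersion test for count-family fits.

    Simulates the fitted model (random intercepts redrawn) ``n_sim`` times
    and compares the observed Pearson residual dispersion to the simulated
    distribution; the two-sided p-value uses the add-one empirical rank.
    A ratio near 1 indicates the family's mean-variance law holds.
    """
    if fit.spec.family not in ("poisson", "nbinom1"):
        raise ValueError("overdispersion check applies to count families")
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    fam = _FAMILY_IMPL[fit.spec.family]
    aux = fit.dispersion.get("alpha")
    df = fit._data
    eta_fixed = fit._X @ fit._beta + fit._offset
    has_re = len(fit.spec.random_intercepts) == 1
    if has_re:
        fname = fit.spec.random_intercepts[0]
        codes, uniq = pd.factorize(df[fname].astype(str))
        sigma = np.sqrt(fit.variance_components[fname])
    y = df[fit.spec.response].to_numpy(float)

    def pearson(yv, mu):
        return float(np.sum((yv - mu) ** 2 / fam.variance(mu, aux)))

    rng = np.random.default_rng(seed)

    def conditional_stat(yv):
        # Pearson dispersion against the conditional means at the posterior
        # modes of the random effects given yv.  Simulated replicates go
        # through the same conditioning as the observed data, otherwise the
        # shrinkage of conditional residuals biases the comparison.
        if has_re and sigma > 1e-8:
            b_hat, _ = _group_modes(
                fam, yv, eta_fixed, aux, codes, len(uniq), sigma**2,
                np.zeros(len(uniq)),
            )
            mu = np.exp(eta_fixed + b_hat[codes])
        else:
            mu = np.exp(eta_fixed)
        return pearson(yv, mu)

    obs = conditional_stat(y)
    sims = np.empty(n_sim)
    for s in range(n_sim):
        if has_re and sigma > 1e-8:
            b = rng.normal(0.0, sigma, len(uniq))
            mu = np.exp(eta_fixed + b[codes])
        else:
            mu = np.exp(eta_fixed)
        ysim = fam.simulate(rng, mu, aux).astype(float)
        sims[s] = conditional_stat(ysim)
    p_hi = (np.sum(sims >= obs) + 1.0) / (n_sim + 1.0)
    p_lo = (np.sum(sims <= obs) + 1.0) / (n_sim + 1.0)
    return {"ratio": obs / sims.mean(), "p": float(min(1.0, 2.0 * min(p_hi, p_lo)))}
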