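"""Mixed models fitted from scratch: Laplace-approximate ML for binomial and
Poisson GLMMs with crossed random intercepts, exact marginal ML/REML for
Gaussian LMMs, single-term-deletion likelihood-ratio tests, and predictor
scaling.

Model
-----
For response y with linear predictor η = Xβ + Zu, u ~ N(0, Σ(θ)) with Σ block
diagonal (one variance σ_f² per grouping factor; an observation-level random
effect is just a factor with one level per row), the marginal likelihood

    L(β, θ) = ∫ f(y | η) φ(u; 0, Σ) du

is integrated by the Laplace approximation around the conditional mode û:

    log L ≈ log f(y | η̂) − ½ ûᵀΣ⁻¹û − ½ log|Σ| − ½ log|H|,
    H = ZᵀWZ + Σ⁻¹,

with W the conditional-likelihood curvature at η̂.  The inner mode is found by
penalised Newton iterations (with step halving); the outer problem maximises
over (β, log σ) by L-BFGS-B.  For Gaussian responses the Laplace identity is
exact, and we instead profile β by GLS and evaluate the marginal multivariate
normal likelihood through the Woodbury identity, which also yields REML.

The small crossed designs this pipeline meets (two group factors of ~11 levels
each) make the dense Hessian cheap; models with a single grouping factor
(including OLRE-only Poisson models) take an O(n) diagonal path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln
from scipy.stats import chi2

from .errors import FitError, ScalingError

LOGSIGMA_MIN, LOGSIGMA_MAX = -6.0, 3.0
SEPARATION_BETA = 15.0
_INNER_TOL = 1e-10
_INNER_MAXIT = 60

FAMILIES = ("binomial", "poisson", "gaussian")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model specification.

    ``fixed`` lists predictor column names (an intercept is always added);
    ``random`` lists grouping-factor column names, each contributing one
    random-intercept variance.  A random term may also be a pair
    ``(plus_col, minus_col)``: both columns then index one shared set of
    levels entering the linear predictor as u[plus] − u[minus] (the
    equal-and-opposite "ability difference" structure for symmetric dyadic
    contests).  ``olre`` appends an observation-level random effect.
    ``trials`` names a binomial-denominator column (omit for 0/1 responses).
    """

    response: str
    fixed: tuple = ()
    random: tuple = ()
    family: str = "binomial"
    olre: bool = False
    trials: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicate fixed terms")
        if len(set(self.random)) != len(self.random):
            raise ValueError("duplicate random terms")

    @property
    def term_key(self) -> frozenset:
        return frozenset(self.fixed)

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"{term!r} not a fixed term of this model")
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))


@dataclass
class ScalingRecord:
    """Per-column centering/scaling constants (sample SD, ddof=1)."""

    means: pd.Series
    sds: pd.Series

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for c in self.means.index:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def inverse(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for c in self.means.index:
            out[c] = out[c] * self.sds[c] + self.means[c]
        return out


def scale_predictors(data: pd.DataFrame, columns) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center and scale ``columns`` to mean 0, sample SD 1.

    Constant columns are a :class:`ScalingError` (named), since a scaled
    constant is undefined.
    """
    columns = list(columns)
    means = data[columns].mean()
    sds = data[columns].std(ddof=1)
    bad = [c for c in columns if not np.isfinite(sds[c]) or sds[c] == 0]
    if bad:
        raise ScalingError(f"cannot scale constant/degenerate predictor(s): {bad}")
    rec = ScalingRecord(means=means, sds=sds)
    return rec.transform(data), rec


# ---------------------------------------------------------------------------
# families


class _Family:
    name = ""

    def loglik(self, y, m, eta):  # pragma: no cover - interface
        raise NotImplementedError

    def deta(self, y, m, eta):
        raise NotImplementedError

    def weights(self, y, m, eta):
        raise NotImplementedError


class _Binomial(_Family):
    name = "binomial"

    def __init__(self, y, m):
        self.const = float(np.sum(gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)))

    def loglik(self, y, m, eta):
        return float(np.sum(y * eta - m * np.logaddexp(0.0, eta)) + self.const)

    def deta(self, y, m, eta):
        return y - m * expit(eta)

    def weights(self, y, m, eta):
        p = expit(eta)
        return np.maximum(m * p * (1.0 - p), 1e-12)


class _Poisson(_Family):
    name = "poisson"

    def __init__(self, y):
        self.const = float(-np.sum(gammaln(y + 1)))

    def loglik(self, y, m, eta):
        return float(np.sum(y * eta - np.exp(eta)) + self.const)

    def deta(self, y, m, eta):
        return y - np.exp(eta)

    def weights(self, y, m, eta):
        return np.maximum(np.exp(eta), 1e-12)


# ---------------------------------------------------------------------------
# design


class _Design:
    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        n = len(data)
        if n == 0:
            raise FitError("empty dataset")
        self.y = data[spec.response].to_numpy(float)
        self.m = (
            data[spec.trials].to_numpy(float) if spec.trials else np.ones(n)
        )
        cols = [np.ones(n)]
        for t in spec.fixed:
            cols.append(data[t].to_numpy(float))
        self.X = np.column_stack(cols)
        self.coef_names = ["(Intercept)", *spec.fixed]
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise FitError("fixed-effect design matrix is rank deficient")
        self.factor_names = []
        self.factor_nlev, self.factor_levels = [], []
        factor_codes = []  # per factor: list of (codes, sign)
        for f in spec.random:
            if isinstance(f, (tuple, list)):
                if len(f) != 2:
                    raise FitError("a paired random term must name exactly two columns")
                plus, minus = f
                levels = sorted(set(data[plus]) | set(data[minus]))
                lut = {lv: i for i, lv in enumerate(levels)}
                cp = data[plus].map(lut).to_numpy(np.intp)
                cm = data[minus].map(lut).to_numpy(np.intp)
                self.factor_names.append(f"{plus}-{minus}")
                self.factor_nlev.append(len(levels))
                self.factor_levels.append(levels)
                factor_codes.append([(cp, +1.0), (cm, -1.0)])
            else:
                codes, levels = pd.factorize(data[f], sort=True)
                if (codes < 0).any():
                    raise FitError(f"missing values in grouping factor {f!r}")
                self.factor_names.append(f)
                self.factor_nlev.append(len(levels))
                self.factor_levels.append(list(levels))
                factor_codes.append([(codes.astype(np.intp), +1.0)])
        if spec.olre:
            self.factor_names.append("_olre")
            self.factor_nlev.append(n)
            self.factor_levels.append(list(range(n)))
            factor_codes.append([(np.arange(n, dtype=np.intp), +1.0)])
        self.offsets = np.concatenate([[0], np.cumsum(self.factor_nlev)]).astype(int)
        self.q = int(self.offsets[-1])
        self.n = n
        self.p = self.X.shape[1]
        self.nf = len(self.factor_names)
        # loading terms: (global column index per row, sign)
        self.terms = [
            (codes + self.offsets[k], sign)
            for k, loads in enumerate(factor_codes)
            for codes, sign in loads
        ]
        self.single_factor = len(self.terms) == 1

    def Zu(self, u):
        eta = np.zeros(self.n)
        for g, s in self.terms:
            eta += s * u[g]
        return eta

    def Zt(self, v):
        out = np.zeros(self.q)
        for g, s in self.terms:
            np.add.at(out, g, s * v)
        return out

    def prec_vector(self, sigma2):
        """Per-element prior precision for the stacked u."""
        prec = np.empty(self.q)
        for k, s2 in enumerate(sigma2):
            prec[self.offsets[k]:self.offsets[k + 1]] = 1.0 / s2
        return prec

    def hessian(self, W, prec):
        """H = ZᵀWZ + diag(prec), dense (only called with ≥2 loading terms)."""
        H = np.diag(prec.copy())
        for a, (ga, sa) in enumerate(self.terms):
            np.add.at(H, (ga, ga), W)
            for gb, sb in self.terms[a + 1:]:
                np.add.at(H, (ga, gb), sa * sb * W)
                np.add.at(H, (gb, ga), sa * sb * W)
        return H


# ---------------------------------------------------------------------------
# fits


@dataclass
class LRTestResult:
    """Likelihood-ratio test of a single-term deletion."""

    term: str
    chisq: float
    df: int
    p: float


@dataclass
class GlmmFit:
    """A fitted mixed model (coefficients on whatever metric the data carried)."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series | None
    random_variances: dict
    loglik: float
    k: int
    n: int
    converged: bool
    method: str = "ML"
    warnings: list = field(default_factory=list)
    ranef_modes: dict = field(default_factory=dict)
    theta: np.ndarray | None = None
    cov_beta: np.ndarray | None = None
    residual_variance: float | None = None

    @property
    def separation_flag(self) -> bool:
        return any("separation" in w for w in self.warnings)


def _glm_irls(des: _Design, fam: _Family, maxit: int = 50) -> np.ndarray:
    """Plain fixed-effects GLM via IRLS; used only as a starting value."""
    beta = np.zeros(des.p)
    if fam.name == "binomial":
        p0 = np.clip((des.y + 0.5) / (des.m + 1.0), 1e-3, 1 - 1e-3)
        beta[0] = np.log(p0.mean() / (1 - p0.mean()))
    elif fam.name == "poisson":
        beta[0] = np.log(max(des.y.mean(), 0.1))
    for _ in range(maxit):
        eta = des.X @ beta
        g = des.X.T @ fam.deta(des.y, des.m, eta)
        W = fam.weights(des.y, des.m, eta)
        Hb = des.X.T @ (W[:, None] * des.X)
        try:
            step = np.linalg.solve(Hb, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return np.clip(beta, -SEPARATION_BETA * 2, SEPARATION_BETA * 2)


def _inner_mode(des, fam, beta, prec, u0):
    """Penalised Newton for the conditional mode û; returns (û, log|H|, loglik)."""
    u = u0.copy()
    Xb = des.X @ beta

    def penalised(uv):
        return fam.loglik(des.y, des.m, Xb + des.Zu(uv)) - 0.5 * float(np.sum(prec * uv * uv))

    obj = penalised(u)
    logdetH = None
    for _ in range(_INNER_MAXIT):
        eta = Xb + des.Zu(u)
        g = des.Zt(fam.deta(des.y, des.m, eta)) - prec * u
        W = fam.weights(des.y, des.m, eta)
        if des.single_factor:
            h = np.bincount(des.terms[0][0], weights=W, minlength=des.q) + prec
            step = g / h
            logdetH = float(np.sum(np.log(h)))
        else:
            H = des.hessian(W, prec)
            try:
                c, low = cho_factor(H, lower=True)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - safeguarded
                raise FitError("conditional-mode Hessian not positive definite") from exc
            step = cho_solve((c, low), g)
            logdetH = 2.0 * float(np.sum(np.log(np.diag(c))))
        if np.max(np.abs(g)) < _INNER_TOL:
            break
        t = 1.0
        for _ in range(30):
            cand = u + t * step
            cand_obj = penalised(cand)
            if cand_obj >= obj - 1e-12:
                u, obj = cand, cand_obj
                break
            t *= 0.5
        else:
            break
    eta = Xb + des.Zu(u)
    return u, logdetH, fam.loglik(des.y, des.m, eta)


def laplace_loglik(des: _Design, fam: _Family, beta, sigma2, u0=None):
    """Laplace marginal log-likelihood at fixed (β, σ²); returns (value, û)."""
    prec = des.prec_vector(sigma2)
    u0 = np.zeros(des.q) if u0 is None else u0
    u, logdetH, condll = _inner_mode(des, fam, beta, prec, u0)
    val = (
        condll
        - 0.5 * float(np.sum(prec * u * u))
        - 0.5 * float(np.sum(np.array(des.factor_nlev) * np.log(sigma2)))
        - 0.5 * logdetH
    )
    return val, u


def _XtWZ(des, W, X):
    """p × q cross-product of the fixed and random designs under weights W."""
    B = np.zeros((des.p, des.q))
    for g, s in des.terms:
        for j in range(des.p):
            B[j] += np.bincount(g, weights=s * W * X[:, j], minlength=des.q)
    return B


def _inner_joint(des, fam, prec, v0):
    """Penalised Newton over the joint (β, u) vector with β unpenalised.

    Block elimination through the u-block Hessian C = ZᵀWZ + Σ⁻¹ yields the
    Newton step, log|C| (the Laplace determinant), and the Schur complement
    S = XᵀWX − XᵀWZ·C⁻¹·ZᵀWX whose inverse is the fixed-effect covariance.
    """
    p, q, X = des.p, des.q, des.X
    v = v0.copy()

    def penalised(vv):
        eta = X @ vv[:p] + des.Zu(vv[p:])
        return fam.loglik(des.y, des.m, eta) - 0.5 * float(np.sum(prec * vv[p:] ** 2))

    obj = penalised(v)
    logdetC = None
    S = None
    for _ in range(_INNER_MAXIT):
        beta, u = v[:p], v[p:]
        eta = X @ beta + des.Zu(u)
        r = fam.deta(des.y, des.m, eta)
        W = fam.weights(des.y, des.m, eta)
        gb = X.T @ r
        gu = des.Zt(r) - prec * u
        A = X.T @ (W[:, None] * X)
        B = _XtWZ(des, W, X)
        if des.single_factor:
            c = np.bincount(des.terms[0][0], weights=W, minlength=q) + prec
            logdetC = float(np.sum(np.log(c)))
            Cinv_gu = gu / c
            Cinv_Bt = B.T / c[:, None]
        else:
            C = des.hessian(W, prec)
            try:
                cf = cho_factor(C, lower=True)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - safeguarded
                raise FitError("conditional-mode Hessian not positive definite") from exc
            logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            Cinv_gu = cho_solve(cf, gu)
            Cinv_Bt = cho_solve(cf, B.T)
        S = A - B @ Cinv_Bt
        try:
            db = np.linalg.solve(S, gb - B @ Cinv_gu)
        except np.linalg.LinAlgError as exc:
            raise FitError("fixed-effect Schur complement singular") from exc
        du = Cinv_gu - Cinv_Bt @ db
        if max(np.max(np.abs(gb)), np.max(np.abs(gu))) < _INNER_TOL * (1 + abs(obj)):
            break
        step = np.concatenate([db, du])
        t = 1.0
        for _ in range(30):
            cand = v + t * step
            cand_obj = penalised(cand)
            if cand_obj >= obj - 1e-12:
                v, obj = cand, cand_obj
                break
            t *= 0.5
        else:
            break
    eta = X @ v[:p] + des.Zu(v[p:])
    return v, logdetC, S, fam.loglik(des.y, des.m, eta)


def _schur_at(des, fam, beta, u, prec):
    """Fixed-effect information S = XᵀWX − XᵀWZ·C⁻¹·ZᵀWX at given (β, u)."""
    eta = des.X @ beta + des.Zu(u)
    W = fam.weights(des.y, des.m, eta)
    A = des.X.T @ (W[:, None] * des.X)
    B = _XtWZ(des, W, des.X)
    if des.single_factor:
        c = np.bincount(des.terms[0][0], weights=W, minlength=des.q) + prec
        Cinv_Bt = B.T / c[:, None]
    else:
        cf = cho_factor(des.hessian(W, prec), lower=True)
        Cinv_Bt = cho_solve(cf, B.T)
    return A - B @ Cinv_Bt


def _fit_glmm_laplace(spec, data, start=None, compute_se=True, maxiter=200,
                      ftol=1e-11, profile_beta=False):
    des = _Design(spec, data)
    if spec.family == "binomial":
        if np.any((des.y < 0) | (des.y > des.m)):
            raise FitError("binomial response outside [0, trials]")
        fam = _Binomial(des.y, des.m)
    else:
        if np.any(des.y < 0):
            raise FitError("poisson response must be nonnegative")
        fam = _Poisson(des.y)

    p, nf = des.p, des.nf
    if start is not None and len(start) == p + nf:
        start = np.asarray(start, float)
        beta0 = start[:p]
        logsig0 = np.clip(start[p:], LOGSIGMA_MIN, LOGSIGMA_MAX)
    else:
        beta0 = _glm_irls(des, fam)
        logsig0 = np.full(nf, np.log(0.3))

    cache = {"v": np.concatenate([beta0, np.zeros(des.q)]), "at": None}

    def profiled_nll(logsig):
        sigma2 = np.exp(2.0 * np.asarray(logsig))
        prec = des.prec_vector(sigma2)
        v, logdetC, S, condll = _inner_joint(des, fam, prec, cache["v"])
        cache["v"] = v
        cache["at"] = (np.asarray(logsig).copy(), v, logdetC, S, condll)
        val = (
            condll
            - 0.5 * float(np.sum(prec * v[p:] ** 2))
            - 0.5 * float(np.sum(np.array(des.factor_nlev) * np.log(sigma2)))
            - 0.5 * logdetC
        )
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        profiled_nll, logsig0, method="L-BFGS-B",
        bounds=[(LOGSIGMA_MIN, LOGSIGMA_MAX)] * nf,
        options=dict(maxiter=maxiter, ftol=ftol, gtol=1e-7),
    )
    # re-evaluate at the optimum so the cache holds the final state
    final_nll = profiled_nll(res.x)
    logsig, v, logdetC, S, condll = cache["at"]
    beta = v[:p]
    u_hat = v[p:]
    sigma2 = np.exp(2.0 * logsig)
    loglik = -float(final_nll)
    converged = bool(res.success) and np.isfinite(loglik)

    if not profile_beta:
        # exact Laplace ML: release β into the outer problem, warm-started at
        # the profiled solution (the two optima differ only at O(1e-2))
        ucache = {"u": u_hat.copy()}

        def full_nll(theta):
            s2 = np.exp(2.0 * theta[p:])
            val, u = laplace_loglik(des, fam, theta[:p], s2, ucache["u"])
            ucache["u"] = u
            return -val if np.isfinite(val) else 1e12

        res2 = optimize.minimize(
            full_nll, np.concatenate([beta, logsig]), method="L-BFGS-B",
            bounds=[(None, None)] * p + [(LOGSIGMA_MIN, LOGSIGMA_MAX)] * nf,
            options=dict(maxiter=maxiter, ftol=ftol, gtol=1e-6),
        )
        if -float(res2.fun) >= loglik:
            beta = res2.x[:p]
            logsig = res2.x[p:]
            sigma2 = np.exp(2.0 * logsig)
            loglik = -float(res2.fun)
            converged = bool(res2.success) and np.isfinite(loglik)
            _, u_hat = laplace_loglik(des, fam, beta, sigma2, ucache["u"])
            S = _schur_at(des, fam, beta, u_hat, des.prec_vector(sigma2))
            if compute_se:
                # observed information of the full Laplace objective: slightly
                # larger than the Schur block (it carries the curvature of the
                # determinant term and the β–σ cross terms); matches the
                # reference mixed-model convention
                Hfull = _numeric_hessian(full_nll, np.concatenate([beta, logsig]))
                try:
                    covfull = np.linalg.inv(Hfull)
                    if np.all(np.diag(covfull)[:p] > 0):
                        S = np.linalg.inv(covfull[:p, :p])
                except np.linalg.LinAlgError:
                    pass

    warnings = []
    if np.max(np.abs(beta)) > SEPARATION_BETA:
        warnings.append("possible separation: |beta| > 15 on the scaled metric")
    if not converged:
        warnings.append(f"optimizer: {res.message}")

    se = None
    cov_beta = None
    if compute_se:
        try:
            cov_beta = np.linalg.inv(S)
            d = np.diag(cov_beta)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError
            se = pd.Series(np.sqrt(d), index=des.coef_names)
        except np.linalg.LinAlgError:
            cov_beta = np.linalg.pinv(S)
            se = pd.Series(np.sqrt(np.abs(np.diag(cov_beta))), index=des.coef_names)
            warnings.append("fixed-effect information singular; SEs from pseudo-inverse")

    modes = {}
    for kf, name in enumerate(des.factor_names):
        sl = slice(des.offsets[kf], des.offsets[kf + 1])
        modes[name] = pd.Series(u_hat[sl], index=des.factor_levels[kf])

    return GlmmFit(
        spec=spec,
        beta=pd.Series(beta, index=des.coef_names),
        se=se,
        random_variances=dict(zip(des.factor_names, sigma2)),
        loglik=loglik,
        k=p + nf,
        n=des.n,
        converged=converged,
        warnings=warnings,
        ranef_modes=modes,
        theta=np.concatenate([beta, logsig]),
        cov_beta=cov_beta,
    )


def _numeric_hessian(fun, x, rel_step=1e-4):
    """Central finite-difference Hessian (symmetrised)."""
    x = np.asarray(x, float)
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                fpp = fun(x + ei + ej); fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej); fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# gaussian (exact marginal likelihood via Woodbury)


def _gaussian_marginal(des: _Design, logsig, reml: bool):
    """Profile-β marginal (or restricted) log-likelihood of a Gaussian LMM.

    ``logsig`` stacks the factor log-SDs and the residual log-SD (last).
    Returns (loglik, beta, cov_beta, extras).
    """
    nf = des.nf
    sigma2 = np.exp(2.0 * logsig[:nf])
    sig2e = float(np.exp(2.0 * logsig[nf]))
    prec = des.prec_vector(sigma2)
    W = 1.0 / sig2e

    def Vinv(M):
        # V⁻¹M with V = σe²I + ZΣZᵀ, via H = ZᵀZ/σe² + Σ⁻¹
        ZtM = np.column_stack([des.Zt(M[:, j]) for j in range(M.shape[1])])
        sol = _solveH(ZtM * W)
        out = M * W
        for g, s in des.terms:
            out -= W * s * sol[g, :]
        return out

    if des.single_factor:
        hdiag = (
            np.bincount(des.terms[0][0], weights=np.full(des.n, W), minlength=des.q)
            + prec
        )
        logdetH = float(np.sum(np.log(hdiag)))

        def _solveH(B):
            return B / hdiag[:, None]
    else:
        H = des.hessian(np.full(des.n, W), prec)
        c, low = cho_factor(H, lower=True)
        logdetH = 2.0 * float(np.sum(np.log(np.diag(c))))

        def _solveH(B):
            return cho_solve((c, low), B)

    logdetV = (
        des.n * np.log(sig2e)
        + logdetH
        + float(np.sum(np.array(des.factor_nlev) * np.log(sigma2)))
    )
    ViX = Vinv(des.X)
    XtViX = des.X.T @ ViX
    Viy = Vinv(des.y[:, None])[:, 0]
    XtViy = des.X.T @ Viy
    cf = cho_factor(XtViX, lower=True)
    beta = cho_solve(cf, XtViy)
    r = des.y - des.X @ beta
    quad = float(r @ Vinv(r[:, None])[:, 0])
    ll = -0.5 * (des.n * np.log(2 * np.pi) + logdetV + quad)
    if reml:
        logdetXtViX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll += -0.5 * logdetXtViX + 0.5 * des.p * np.log(2 * np.pi)
    cov_beta = np.linalg.inv(XtViX)
    # conditional modes: û = Σ Zᵀ V⁻¹ r
    Vir = Vinv(r[:, None])[:, 0]
    with np.errstate(invalid="ignore"):
        u = np.where(prec > 0, des.Zt(Vir) / prec, 0.0)
    return ll, beta, cov_beta, (sigma2, sig2e, u)


def _fit_gaussian(spec, data, start=None, compute_se=True, reml=False, maxiter=300):
    des = _Design(spec, data)
    nf = des.nf
    resid_sd = max(np.std(des.y), 1e-3)
    if start is not None and len(start) == nf + 1:
        x0 = np.clip(np.asarray(start, float), LOGSIGMA_MIN, None)
    else:
        x0 = np.full(nf + 1, np.log(max(resid_sd / 2, 1e-2)))
    bounds = [(LOGSIGMA_MIN + np.log(max(resid_sd, 1e-2)), None)] * (nf + 1)

    def nobj(logsig):
        ll, *_ = _gaussian_marginal(des, logsig, reml)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        nobj, x0, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=maxiter, ftol=1e-13, gtol=1e-7),
    )
    ll, beta, cov_beta, (sigma2, sig2e, u) = _gaussian_marginal(des, res.x, reml)
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=des.coef_names) if compute_se else None
    modes = {}
    for kf, name in enumerate(des.factor_names):
        sl = slice(des.offsets[kf], des.offsets[kf + 1])
        modes[name] = pd.Series(u[sl], index=des.factor_levels[kf])
    return GlmmFit(
        spec=spec,
        beta=pd.Series(beta, index=des.coef_names),
        se=se,
        random_variances=dict(zip(des.factor_names, sigma2)),
        loglik=float(ll),
        k=des.p + nf + 1,
        n=des.n,
        converged=bool(res.success),
        method="REML" if reml else "ML",
        ranef_modes=modes,
        theta=res.x,
        cov_beta=cov_beta,
        residual_variance=sig2e,
    )


# ---------------------------------------------------------------------------
# public API


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, *, start=None,
             compute_se: bool = True, reml: bool = False,
             profile_beta: bool = False) -> GlmmFit:
    """Fit the model described by ``spec`` on ``data``.

    Binomial and Poisson families maximise the Laplace-approximate marginal
    likelihood; Gaussian models use the exact marginal likelihood (ML, or REML
    when ``reml=True``).  ``start`` warm-starts the optimizer with a previous
    fit's ``theta``.  ``profile_beta=True`` keeps β profiled through the joint
    penalised mode (the fast deviance used inside the iterated pipeline)
    instead of polishing it in the outer optimizer.
    """
    if not (spec.random or spec.olre):
        raise FitError("no random terms; use a plain GLM for fixed-effects-only models")
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data, start=start, compute_se=compute_se, reml=reml)
    if reml:
        raise FitError("REML is only defined here for gaussian models")
    return _fit_glmm_laplace(spec, data, start=start, compute_se=compute_se,
                             profile_beta=profile_beta)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, *, reml: bool = False, **kw) -> GlmmFit:
    """Gaussian linear mixed model (``spec.family`` must be 'gaussian')."""
    if spec.family != "gaussian":
        raise FitError("fit_lmm requires a gaussian spec")
    return fit_glmm(spec, data, reml=reml, **kw)


def fit_poisson_olre(spec: ModelSpec, data: pd.DataFrame, **kw) -> GlmmFit:
    """Poisson GLMM with an observation-level random effect (lognormal-Poisson)."""
    if spec.family != "poisson":
        raise FitError("fit_poisson_olre requires a poisson spec")
    if not spec.olre:
        spec = replace(spec, olre=True)
    return fit_glmm(spec, data, **kw)


def drop1_lr(full: GlmmFit, term: str, data: pd.DataFrame) -> LRTestResult:
    """Single-term-deletion LR test: χ² = 2·(ll_full − ll_reduced), df = 1.

    The reduced model keeps the full model's random structure and is fitted by
    ML (never REML), as LR comparisons across fixed structures require.
    """
    if not full.converged:
        raise FitError("full model did not converge; LR test undefined")
    reduced_spec = full.spec.drop(term)
    if full.spec.family == "gaussian" and full.method == "REML":
        full = fit_glmm(full.spec, data, reml=False, compute_se=False)
    reduced = fit_glmm(reduced_spec, data, compute_se=False)
    if not reduced.converged:
        raise FitError("reduced model did not converge")
    chisq = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(chi2.sf(chisq, df=1))
    return LRTestResult(term=term, chisq=float(chisq), df=1, p=p)
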