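"""Penalized-spline additive models with automatic smoothness selection.

A compact generalized-additive-model engine used by the regression and phase
analysis modules. Smooth terms are cubic B-spline bases with second-order
difference penalties; each smooth's basis dimension ``k`` fixes its maximum
flexibility and a per-term smoothing parameter, selected by the generalized
Fellner–Schall (marginal-likelihood) update, controls the actual wiggliness.
Identifiability is handled by absorbing the sum-to-zero constraint into the
basis. Factor random intercepts are ridge-penalized dummy blocks whose
smoothing parameter plays the role of a precision, so shrinkage is estimated
from the data exactly like a variance component.

Two likelihoods are supported:

* ``gaussian`` — identity link, residual variance profiled as RSS/(n − edf);
* ``beta``     — logit link for responses strictly inside (0, 1), with the
  precision φ estimated by maximum likelihood alongside the coefficients
  (Fisher scoring on the penalized log-likelihood).

Reported per-term effective degrees of freedom are ``tr(V X'WX)`` restricted
to the term's columns, with ``V`` the penalized information inverse, which is
also the (Bayesian) covariance used for pointwise confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln, polygamma

__all__ = ["AdditiveModel", "SmoothTerm", "LinearTerm", "RandomTerm"]


def _trigamma(x):
    return polygamma(1, x)


# ---------------------------------------------------------------------------
# terms

class _Term:
    name: str
    ncol: int
    sl: slice  # assigned at assembly

    def design(self, x) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    penalty: np.ndarray | None = None
    rank: int = 0


class LinearTerm(_Term):
    """Unpenalized parametric column(s), e.g. a season dummy."""

    def __init__(self, x, name: str):
        x = np.asarray(x, dtype=float)
        self._train = x.reshape(len(x), -1)
        self.ncol = self._train.shape[1]
        self.name = name

    def design(self, x=None):
        if x is None:
            return self._train
        x = np.asarray(x, dtype=float)
        return x.reshape(len(x), -1)


class SmoothTerm(_Term):
    """Cubic B-spline smooth of one covariate with a difference penalty.

    ``k`` is the basis dimension before the sum-to-zero constraint (so the
    fitted smooth has at most ``k − 1`` free coefficients and the penalty has
    rank ``k − 2``). ``by`` multiplies the whole basis by a weight/indicator
    vector, giving level-specific smooths with their own smoothing parameters.
    """

    def __init__(self, x, k: int = 10, name: str = "s(x)", by=None):
        x = np.asarray(x, dtype=float)
        if k < 4:
            raise ValueError("basis dimension k must be >= 4")
        self.k = k
        self.name = name
        self._by = None if by is None else np.asarray(by, dtype=float)
        self.lo, self.hi = float(np.min(x)), float(np.max(x))
        if self.hi <= self.lo:
            raise ValueError(f"covariate of smooth {name!r} is constant")
        # interior knots at quantiles; clamped boundary knots
        n_int = k - 4
        if n_int > 0:
            probs = np.linspace(0, 1, n_int + 2)[1:-1]
            interior = np.quantile(x, probs)
            # keep knots strictly increasing even for heavily tied data
            interior = np.clip(interior, self.lo + 1e-9, self.hi - 1e-9)
            interior = np.maximum.accumulate(
                interior + np.arange(n_int) * 1e-12 * (self.hi - self.lo))
        else:
            interior = np.array([])
        self.t = np.concatenate([[self.lo] * 4, interior, [self.hi] * 4])
        # sum-to-zero constraint absorbed by reparametrisation X -> X Z
        B = self._raw(x)
        c = B.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(c.T, mode="complete")
        self.Z = q[:, 1:]                       # k × (k−1)
        S = self._curvature_penalty()
        Sz = self.Z.T @ S @ self.Z
        # rescale to unit Frobenius norm so smoothing parameters are
        # dimensionless and the covariate's range cannot starve the penalty
        self.penalty = Sz / np.linalg.norm(Sz)
        self.rank = k - 2
        self.ncol = k - 1
        self._train = B @ self.Z
        if self._by is not None:
            self._train = self._train * self._by[:, None]

    def _curvature_penalty(self) -> np.ndarray:
        """Integrated squared second derivative, ∫ B''(x)B''(x)ᵀ dx.

        Exact for cubic B-splines: B'' is piecewise linear, so two-point
        Gauss–Legendre quadrature per knot span is exact.
        """
        t = self.t
        k = self.k
        S = np.zeros((k, k))
        gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        spans = np.unique(t)
        for a, b in zip(spans[:-1], spans[1:]):
            half = 0.5 * (b - a)
            for g in gauss:
                xg = 0.5 * (a + b) + half * g
                d2 = np.array([
                    BSpline(t, np.eye(k)[j], 3)(xg, nu=2) for j in range(k)])
                S += half * np.outer(d2, d2)
        return S

    def _raw(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.t, 3).toarray()

    def design(self, x=None, by=None):
        if x is None:
            return self._train
        X = self._raw(x) @ self.Z
        if by is not None:
            X = X * np.asarray(by, dtype=float)[:, None]
        return X


class RandomTerm(_Term):
    """Factor random intercept as a ridge-penalized dummy block."""

    def __init__(self, labels, name: str = "random"):
        labels = np.asarray(labels)
        self.levels, codes = np.unique(labels, return_inverse=True)
        self.ncol = len(self.levels)
        self._train = np.zeros((len(labels), self.ncol))
        self._train[np.arange(len(labels)), codes] = 1.0
        self.penalty = np.eye(self.ncol)
        self.rank = self.ncol
        self.name = name

    def design(self, labels=None):
        if labels is None:
            return self._train
        labels = np.asarray(labels)
        X = np.zeros((len(labels), self.ncol))
        lookup = {lv: i for i, lv in enumerate(self.levels)}
        for r, lab in enumerate(labels):
            if lab in lookup:
                X[r, lookup[lab]] = 1.0
        return X


# ---------------------------------------------------------------------------
# model

@dataclass
class _FitState:
    beta: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    W: np.ndarray           # Fisher weights on the likelihood scale
    loglik: float
    phi: float | None       # beta precision, or None
    sigma2: float | None    # gaussian residual variance, or None


class AdditiveModel:
    """Additive model: intercept + parametric + smooth + random-intercept terms."""

    def __init__(self, family: str = "gaussian"):
        if family not in ("gaussian", "beta"):
            raise ValueError("family must be 'gaussian' or 'beta'")
        self.family = family
        self.terms: list[_Term] = []

    # -- construction -----------------------------------------------------
    def add_linear(self, x, name: str) -> LinearTerm:
        t = LinearTerm(x, name)
        self.terms.append(t)
        return t

    def add_smooth(self, x, k: int = 10, name: str = "s(x)", by=None) -> SmoothTerm:
        t = SmoothTerm(x, k=k, name=name, by=by)
        self.terms.append(t)
        return t

    def add_random(self, labels, name: str = "random") -> RandomTerm:
        t = RandomTerm(labels, name)
        self.terms.append(t)
        return t

    def _assemble(self):
        cols = [np.ones((self._n, 1))]
        pos = 1
        for t in self.terms:
            X = t.design()
            t.sl = slice(pos, pos + t.ncol)
            pos += t.ncol
            cols.append(X)
        self.X_ = np.hstack(cols)
        self.penalized_ = [t for t in self.terms if t.penalty is not None]

    def _S_total(self, lambdas):
        p = self.X_.shape[1]
        S = np.zeros((p, p))
        for lam, t in zip(lambdas, self.penalized_):
            S[t.sl, t.sl] += lam * t.penalty
        return S

    # -- likelihood internals ---------------------------------------------
    def _loglik(self, y, mu, phi=None, sigma2=None):
        if self.family == "gaussian":
            n = len(y)
            rss = float(np.sum((y - mu) ** 2))
            return -0.5 * n * np.log(2 * np.pi * sigma2) - rss / (2 * sigma2)
        a, b = mu * phi, (1 - mu) * phi
        return float(np.sum(gammaln(phi) - gammaln(a) - gammaln(b)
                            + (a - 1) * np.log(y) + (b - 1) * np.log(1 - y)))

    def _fit_coefs(self, y, lambdas, state: _FitState | None) -> _FitState:
        X = self.X_
        S = self._S_total(lambdas)
        if self.family == "gaussian":
            sigma2 = state.sigma2 if state else float(np.var(y)) or 1.0
            for _ in range(50):
                beta = np.linalg.solve(X.T @ X + sigma2 * S, X.T @ y)
                eta = X @ beta
                rss = float(np.sum((y - eta) ** 2))
                V = np.linalg.inv(X.T @ X / sigma2 + S)
                edf = float(np.trace(V @ (X.T @ X) / sigma2))
                new_s2 = rss / max(len(y) - edf, 1.0)
                if abs(new_s2 - sigma2) < 1e-8 * sigma2:
                    sigma2 = new_s2
                    break
                sigma2 = new_s2
            W = np.full(len(y), 1.0 / sigma2)
            ll = self._loglik(y, eta, sigma2=sigma2)
            return _FitState(beta, eta, eta, W, ll, None, sigma2)

        # beta likelihood, logit link, Fisher scoring with step halving
        if state is None:
            mu0 = np.clip(y, 1e-3, 1 - 1e-3)
            eta = np.log(mu0 / (1 - mu0))
            resid = y - mu0
            phi = max(float(np.mean(mu0 * (1 - mu0)) / max(np.var(resid), 1e-8)) - 1.0,
                      2.0)
            beta = np.zeros(X.shape[1])
            beta[0] = float(np.mean(eta))
        else:
            beta, phi = state.beta.copy(), state.phi
        ystar = np.log(y / (1 - y))

        def penll(b, ph):
            e = X @ b
            m = 1.0 / (1.0 + np.exp(-e))
            m = np.clip(m, 1e-10, 1 - 1e-10)
            return self._loglik(y, m, phi=ph) - 0.5 * float(b @ S @ b), m

        cur, mu = penll(beta, phi)
        for _ in range(200):
            mustar = digamma(mu * phi) - digamma((1 - mu) * phi)
            dmu = mu * (1 - mu)
            u = phi * (ystar - mustar) * dmu
            W = phi ** 2 * (_trigamma(mu * phi) + _trigamma((1 - mu) * phi)) * dmu ** 2
            W = np.maximum(W, 1e-10)
            eta = X @ beta
            z = eta + u / W
            XtW = X.T * W
            beta_new = np.linalg.solve(XtW @ X + S, XtW @ z)
            step = beta_new - beta
            new, mu_new = penll(beta_new, phi)
            halved = 0
            while not np.isfinite(new) or new < cur - 1e-10:
                step *= 0.5
                halved += 1
                if halved > 30:
                    break
                beta_new = beta + step
                new, mu_new = penll(beta_new, phi)
            improved = np.isfinite(new) and new > cur + 1e-9 * (abs(cur) + 1)
            beta, mu = beta_new, mu_new
            cur = new
            # profile out phi every few iterations
            if (_ + 1) % 4 == 0 or not improved:
                res = minimize_scalar(
                    lambda lp: -self._loglik(y, mu, phi=np.exp(lp)),
                    bounds=(np.log(1.2), np.log(1e5)), method="bounded",
                    options={"xatol": 1e-6})
                phi = float(np.exp(res.x))
                cur, mu = penll(beta, phi)
            if not improved and (_ + 1) % 4 == 0:
                break
        eta = X @ beta
        dmu = mu * (1 - mu)
        W = phi ** 2 * (_trigamma(mu * phi) + _trigamma((1 - mu) * phi)) * dmu ** 2
        ll = self._loglik(y, mu, phi=phi)
        return _FitState(beta, eta, mu, np.maximum(W, 1e-10), ll, phi, None)

    # -- fitting -----------------------------------------------------------
    def fit(self, y, max_outer: int = 80, tol: float = 3e-3):
        """Fit by alternating coefficient estimation and Fellner–Schall
        smoothing-parameter updates until the log smoothing parameters settle.
        """
        y = np.asarray(y, dtype=float)
        self._n = len(y)
        if self.family == "beta" and (np.any(y <= 0) or np.any(y >= 1)):
            raise ValueError("beta family requires responses strictly in (0, 1)")
        self._assemble()
        lambdas = np.ones(len(self.penalized_))
        state = None
        for _ in range(max_outer):
            state = self._fit_coefs(y, lambdas, state)
            XtWX = (self.X_.T * state.W) @ self.X_
            V = np.linalg.inv(XtWX + self._S_total(lambdas))
            new = np.empty_like(lambdas)
            for j, t in enumerate(self.penalized_):
                Sj = np.zeros_like(V)
                Sj[t.sl, t.sl] = t.penalty
                num = t.rank - lambdas[j] * float(np.trace(V @ Sj))
                den = float(state.beta @ Sj @ state.beta)
                new[j] = np.clip(max(num, 1e-10) / max(den, 1e-14), 1e-9, 1e13)
            if not len(lambdas) or np.max(np.abs(np.log(new) - np.log(lambdas))) < tol:
                lambdas = new
                break
            lambdas = new
        self.lambdas_ = lambdas
        state = self._fit_coefs(y, lambdas, state)
        self.state_ = state
        self.beta_ = state.beta
        self.phi_ = state.phi
        self.sigma2_ = state.sigma2
        XtWX = (self.X_.T * state.W) @ self.X_
        self.V_ = np.linalg.inv(XtWX + self._S_total(lambdas))
        edf_all = np.diag(self.V_ @ XtWX)
        self.edf_total_ = float(np.sum(edf_all))
        self.edf_ = {t.name: float(np.sum(edf_all[t.sl])) for t in self.terms}
        self.loglik_ = state.loglik
        n_scale = 1
        self.aic_ = -2 * state.loglik + 2 * (self.edf_total_ + n_scale)
        self._y = y
        self._deviance_stats(y)
        return self

    def _deviance_stats(self, y):
        if self.family == "gaussian":
            self.deviance_ = float(np.sum((y - self.state_.mu) ** 2))
            self.null_deviance_ = float(np.sum((y - np.mean(y)) ** 2))
        else:
            phi = self.phi_
            l_sat = self._loglik(y, np.clip(y, 1e-10, 1 - 1e-10), phi=phi)
            self.deviance_ = 2.0 * (l_sat - self.state_.loglik)
            res = minimize_scalar(
                lambda m: -self._loglik(y, np.full_like(y, 1 / (1 + np.exp(-m))),
                                        phi=phi),
                bounds=(-8, 8), method="bounded")
            mu0 = 1.0 / (1.0 + np.exp(-res.x))
            l_null = self._loglik(y, np.full_like(y, mu0), phi=phi)
            self.null_deviance_ = 2.0 * (l_sat - l_null)
        nd = self.null_deviance_
        self.deviance_explained_ = float(1.0 - self.deviance_ / nd) if nd > 0 else 0.0

    # -- prediction ---------------------------------------------------------
    def term_effect(self, name: str, x, by=None):
        """Partial effect of one term on the linear-predictor scale.

        Returns ``(fit, se)`` arrays; the intercept is not included.
        """
        t = self._term(name)
        X = t.design(x, by=by) if isinstance(t, SmoothTerm) else t.design(x)
        fit = X @ self.beta_[t.sl]
        se = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", X, self.V_[t.sl, t.sl], X), 0.0))
        return fit, se

    def predict(self, newdata: dict | None = None, se: bool = False):
        """Linear-predictor prediction summing intercept and provided terms.

        ``newdata`` maps term names to covariate values (smooths/linear) or
        labels (random terms); terms absent from ``newdata`` contribute zero
        (population-level prediction). With ``se=True`` returns ``(eta, se)``.
        """
        newdata = newdata or {}
        n = len(next(iter(newdata.values()))) if newdata else 1
        p = self.X_.shape[1]
        X = np.zeros((n, p))
        X[:, 0] = 1.0
        for nm, vals in newdata.items():
            t = self._term(nm)
            X[:, t.sl] = t.design(vals)
        eta = X @ self.beta_
        if not se:
            return eta
        s = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.V_, X), 0.0))
        return eta, s

    def fitted(self):
        return self.state_.mu

    def _term(self, name: str) -> _Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")
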