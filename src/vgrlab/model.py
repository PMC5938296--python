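"""Cumulative-logit (proportional-odds) regression for pairwise gradings.

The visual grading regression (VGR) model relates the ordinal relative score
of a presented image pair to covariate *differences* between the right and
left image: the natural-log tube-load difference (coefficient ``a``) and
signed indicators for each non-reference reconstruction algorithm
(coefficients ``b``).  Patient and observer heterogeneity enter as crossed
random intercepts on the latent scale; the marginal likelihood is maximized
via a Laplace approximation (joint mode of the random effects plus a
log-determinant curvature correction), which remains valid for crossed
(non-nested) grouping where quadrature factorizations do not apply.

The estimator follows scikit-learn conventions (``fit``, ``predict_proba``,
``get_params``); module-level helpers :func:`fit_fixed`, :func:`fit_mixed`
and :func:`tube_load_effect_by_algorithm` are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._numdiff import approx_hess

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when an optimizer fails to converge or the fit is degenerate."""


def significance_stars(p: float) -> str:
    """Render a p-value at the conventional reporting levels.

    ``***`` p < 0.001, ``**`` p < 0.01, ``*`` p < 0.05, ``°`` otherwise.
    """
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "\N{DEGREE SIGN}"


@dataclass
class ModelSpec:
    """Which effects enter the VGR model and which records are eligible.

    ``dose_interval`` restricts the fit to records whose two tube loads both
    lie inside the closed interval (the proportional-odds model assumes a
    linear latent effect of log tube load, which may only hold locally).
    """

    covariates: Sequence[str] = ("log_tube_load", "algorithm")
    random_effects: Sequence[str] = ("patient", "observer")
    dose_interval: tuple[float, float] | None = None
    reference: str = "FBP"

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("at least one fixed effect is required")
        unknown = set(self.covariates) - {"log_tube_load", "algorithm"}
        if unknown:
            raise ValueError(f"unknown covariates: {unknown}")
        unknown = set(self.random_effects) - {"patient", "observer"}
        if unknown:
            raise ValueError(f"unknown random effects: {unknown}")


@dataclass
class ModelData:
    """Prepared model matrix and indices for one criterion's records."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray            # response mapped to 0..K-1
    K: int
    categories: np.ndarray   # observed score values, ascending
    patient_idx: np.ndarray
    observer_idx: np.ndarray
    patient_labels: list[str]
    observer_labels: list[str]
    frame: pd.DataFrame


@dataclass
class VGRFit:
    """A fitted VGR model for one criterion.

    ``a`` is the coefficient for the natural-log tube-load difference, ``b``
    maps each non-reference algorithm to its coefficient.  ``thresholds`` are
    the ordered cut points over the observed response categories.
    """

    criterion: object
    a: float | None
    b: dict
    thresholds: np.ndarray
    coef: dict
    se: dict
    p_values: dict
    cov_fixed: np.ndarray
    fixed_names: list[str]
    loglik: float
    converged: bool
    n_obs: int
    method: str
    categories: np.ndarray
    sigma2_patient: float | None = None
    sigma2_observer: float | None = None
    warnings: list = field(default_factory=list)
    reference: str = "FBP"

    def stars(self, name: str) -> str:
        return significance_stars(self.p_values[name])

    def summary(self) -> str:
        lines = [
            f"VGR fit ({self.method}), criterion={self.criterion}, "
            f"n={self.n_obs}, loglik={self.loglik:.3f}, converged={self.converged}"
        ]
        for name in self.fixed_names:
            lines.append(
                f"  {name:>14s} = {self.coef[name]:+.4f}  (SE {self.se[name]:.4f})"
                f"  p={self.p_values[name]:.4g} {self.stars(name)}"
            )
        th = ", ".join(f"{t:+.3f}" for t in self.thresholds)
        lines.append(f"  thresholds: [{th}]")
        if self.sigma2_patient is not None:
            lines.append(f"  sigma2_patient  = {self.sigma2_patient:.4f}")
        if self.sigma2_observer is not None:
            lines.append(f"  sigma2_observer = {self.sigma2_observer:.4f}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "method": self.method,
            "a": self.a,
            "b": dict(self.b),
            "coef": dict(self.coef),
            "se": dict(self.se),
            "p_values": dict(self.p_values),
            "thresholds": [float(t) for t in self.thresholds],
            "sigma2_patient": self.sigma2_patient,
            "sigma2_observer": self.sigma2_observer,
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "warnings": list(self.warnings),
            "reference": self.reference,
        }


# ---------------------------------------------------------------------------
# covariate preparation
# ---------------------------------------------------------------------------

def prepare_covariates(records: pd.DataFrame, spec: ModelSpec) -> ModelData:
    """Build the model matrix from a grading table.

    One row per record: Δlog-mAs = ln(right mAs) − ln(left mAs); for each
    non-reference algorithm ``g`` a signed indicator
    ``[right algo = g] − [left algo = g]``; the ordinal response is the score
    mapped onto its observed ordered categories.  Records with a tube load
    outside ``spec.dose_interval`` are excluded.
    """
    df = records
    if spec.dose_interval is not None:
        lo, hi = sorted(spec.dose_interval)
        keep = (
            df["left_mAs"].between(lo, hi) & df["right_mAs"].between(lo, hi)
        )
        df = df[keep]
    df = df.reset_index(drop=True)

    cols: list[str] = []
    mats: list[np.ndarray] = []
    if "log_tube_load" in spec.covariates:
        cols.append("log_tube_load")
        mats.append(
            (np.log(df["right_mAs"].to_numpy(float))
             - np.log(df["left_mAs"].to_numpy(float)))[:, None]
        )
    if "algorithm" in spec.covariates:
        algos = sorted(set(df["left_algo"]) | set(df["right_algo"]))
        if len(df) and spec.reference not in algos:
            raise ValueError(
                f"reference algorithm {spec.reference!r} absent from records"
            )
        for g in algos:
            if g == spec.reference:
                continue
            cols.append(f"algo:{g}")
            ind = (
                (df["right_algo"] == g).to_numpy(int)
                - (df["left_algo"] == g).to_numpy(int)
            )
            mats.append(ind[:, None].astype(float))
    X = np.hstack(mats) if mats else np.empty((len(df), 0))

    scores = df["score"].to_numpy(int)
    categories, y = np.unique(scores, return_inverse=True)
    pat_labels, patient_idx = np.unique(df["patient_id"].to_numpy(str),
                                        return_inverse=True)
    obs_labels, observer_idx = np.unique(df["observer_id"].to_numpy(str),
                                         return_inverse=True)
    return ModelData(
        X=X,
        columns=cols,
        y=y,
        K=len(categories),
        categories=categories,
        patient_idx=patient_idx,
        observer_idx=observer_idx,
        patient_labels=list(pat_labels),
        observer_labels=list(obs_labels),
        frame=df,
    )


# ---------------------------------------------------------------------------
# ordinal log-likelihood terms
# ---------------------------------------------------------------------------

def _cut_arrays(theta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower cut points per observation (±inf at the extremes)."""
    full = np.concatenate([[-np.inf], theta, [np.inf]])
    return full[y + 1], full[y]


def _ordinal_terms(theta: np.ndarray, y: np.ndarray, eta: np.ndarray):
    """Per-record log-probability and its first/second derivatives in eta.

    For category c with cut points θ_{c-1}, θ_c:
    P = F(θ_c − η) − F(θ_{c−1} − η) with F the standard-logistic CDF.
    """
    hi, lo = _cut_arrays(theta, y)
    z_hi = hi - eta
    z_lo = lo - eta
    F_hi = np.where(np.isposinf(z_hi), 1.0,
                    np.where(np.isneginf(z_hi), 0.0, expit(z_hi)))
    F_lo = np.where(np.isposinf(z_lo), 1.0,
                    np.where(np.isneginf(z_lo), 0.0, expit(z_lo)))
    f_hi = np.where(np.isfinite(z_hi), F_hi * (1.0 - F_hi), 0.0)
    f_lo = np.where(np.isfinite(z_lo), F_lo * (1.0 - F_lo), 0.0)
    fp_hi = np.where(np.isfinite(z_hi), f_hi * (1.0 - 2.0 * F_hi), 0.0)
    fp_lo = np.where(np.isfinite(z_lo), f_lo * (1.0 - 2.0 * F_lo), 0.0)
    P = np.clip(F_hi - F_lo, 1e-300, None)
    logp = np.log(P)
    d1 = (f_lo - f_hi) / P
    d2 = (fp_hi - fp_lo) / P - d1 * d1
    return logp, d1, d2, f_hi, f_lo, P


def _theta_from_t(t: np.ndarray) -> np.ndarray:
    """Monotone threshold parameterization: θ_0 = t_0, θ_k = θ_{k−1} + e^{t_k}."""
    theta = np.empty_like(t)
    theta[0] = t[0]
    if t.size > 1:
        theta[1:] = t[0] + np.cumsum(np.exp(t[1:]))
    return theta


def _t_from_theta(theta: np.ndarray) -> np.ndarray:
    t = np.empty_like(theta)
    t[0] = theta[0]
    if theta.size > 1:
        t[1:] = np.log(np.maximum(np.diff(theta), 1e-8))
    return t


def _grad_theta_to_t(g_theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Chain rule from raw-threshold gradient to increment parameterization."""
    g_t = np.empty_like(g_theta)
    rev = np.cumsum(g_theta[::-1])[::-1]  # rev[k] = sum_{j>=k} g_theta[j]
    g_t[0] = rev[0]
    if t.size > 1:
        g_t[1:] = np.exp(t[1:]) * rev[1:]
    return g_t


def _fixed_nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, K: int):
    """Negative log-likelihood and gradient of the fixed-effects model.

    ``params`` = (β, t) with thresholds in the monotone increment
    parameterization.
    """
    p = X.shape[1]
    beta = params[:p]
    t = params[p:]
    theta = _theta_from_t(t)
    eta = X @ beta
    logp, d1, _, f_hi, f_lo, P = _ordinal_terms(theta, y, eta)
    nll = -float(np.sum(logp))

    g_beta = -(X.T @ d1)
    # raw-threshold gradient: +f(z_c)/P into θ_c, −f(z_{c−1})/P into θ_{c−1}
    g_theta = np.zeros(K - 1)
    w_hi = f_hi / P
    w_lo = f_lo / P
    mask_hi = y < K - 1
    mask_lo = y > 0
    np.add.at(g_theta, y[mask_hi], w_hi[mask_hi])
    np.add.at(g_theta, y[mask_lo] - 1, -w_lo[mask_lo])
    g_t = _grad_theta_to_t(g_theta, t)
    return nll, np.concatenate([g_beta, -g_t])


def _fixed_nll_raw(params: np.ndarray, X: np.ndarray, y: np.ndarray, K: int) -> float:
    """Negative log-likelihood with raw thresholds (for covariance Hessian)."""
    p = X.shape[1]
    theta = params[p:]
    logp, *_ = _ordinal_terms(theta, y, X @ params[:p])
    return -float(np.sum(logp))


def _init_params(data: ModelData) -> np.ndarray:
    """β = 0; thresholds from empirical cumulative score frequencies."""
    counts = np.bincount(data.y, minlength=data.K).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    theta0 = np.log(cum / (1 - cum))
    theta0 = np.maximum.accumulate(theta0)
    # enforce strict increase for the log-increment transform
    for i in range(1, theta0.size):
        if theta0[i] - theta0[i - 1] < 1e-6:
            theta0[i] = theta0[i - 1] + 1e-6
    return np.concatenate([np.zeros(data.X.shape[1]), _t_from_theta(theta0)])


# ---------------------------------------------------------------------------
# Laplace machinery for crossed random intercepts
# ---------------------------------------------------------------------------

class _LaplaceWork:
    """Marginal log-likelihood of the crossed random-intercept model.

    Groups is a list of (index array, size) for each random-effect factor;
    the mode of the joint log-density over all random effects is found by
    damped Newton (dense curvature over the stacked effects, fine at the
    tens-of-levels scale of observer studies) and reused as a warm start
    across nearby parameter values.
    """

    def __init__(self, X, y, K, groups):
        self.X = X
        self.y = y
        self.K = K
        self.groups = groups  # list of (idx, q)
        self.q_total = sum(q for _, q in groups)
        self._warm = np.zeros(self.q_total)

    def _split(self, w):
        out = []
        s = 0
        for _, q in self.groups:
            out.append(w[s:s + q])
            s += q
        return out

    def _joint(self, w, Xb, theta, sigmas):
        eta = Xb.copy()
        parts = self._split(w)
        for (idx, q), wi, sig in zip(self.groups, parts, sigmas):
            eta += wi[idx]
        logp, *_ = _ordinal_terms(theta, self.y, eta)
        val = float(np.sum(logp))
        for (idx, q), wi, sig in zip(self.groups, parts, sigmas):
            val += float(
                -0.5 * np.sum(wi ** 2) / sig ** 2
                - q * np.log(sig)
                - 0.5 * q * _LOG2PI
            )
        return val

    def marginal_loglik(self, beta, theta, sigmas):
        Xb = self.X @ beta
        w = self._warm.copy()
        parts_idx = [g[0] for g in self.groups]
        sizes = [g[1] for g in self.groups]
        offsets = np.cumsum([0] + sizes)

        val = self._joint(w, Xb, theta, sigmas)
        H = None
        for _ in range(100):
            eta = Xb.copy()
            for (idx, q), off, sig in zip(self.groups, offsets[:-1], sigmas):
                eta += w[off:off + q][idx]
            _, d1, d2, *_ = _ordinal_terms(theta, self.y, eta)
            grad = np.empty(self.q_total)
            H = np.zeros((self.q_total, self.q_total))
            for gi, ((idx, q), off, sig) in enumerate(
                zip(self.groups, offsets[:-1], sigmas)
            ):
                wi = w[off:off + q]
                grad[off:off + q] = (
                    np.bincount(idx, weights=d1, minlength=q) - wi / sig ** 2
                )
                diag = np.bincount(idx, weights=d2, minlength=q) - 1.0 / sig ** 2
                H[off:off + q, off:off + q] = np.diag(diag)
                for gj in range(gi + 1, len(self.groups)):
                    jdx, qj = self.groups[gj]
                    offj = offsets[gj]
                    B = np.zeros((q, qj))
                    np.add.at(B, (idx, jdx), d2)
                    H[off:off + q, offj:offj + qj] = B
                    H[offj:offj + qj, off:off + q] = B.T
            if np.max(np.abs(grad)) < 1e-10 * max(1.0, abs(val)):
                break
            try:
                delta = np.linalg.solve(-H, grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(-H, grad, rcond=None)[0]
            step = 1.0
            for _ls in range(30):
                new = self._joint(w + step * delta, Xb, theta, sigmas)
                if new >= val - 1e-12:
                    break
                step *= 0.5
            w = w + step * delta
            if abs(new - val) < 1e-12 * max(1.0, abs(val)):
                val = new
                break
            val = new
        self._warm = w

        sign, logdet = np.linalg.slogdet(-H)
        if sign <= 0:
            # curvature not PD (should not happen at an interior mode)
            return -np.inf
        return val + 0.5 * self.q_total * _LOG2PI - 0.5 * logdet


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class CumulativeLogitVGR(BaseEstimator):
    """Proportional-odds VGR regression with optional crossed random intercepts.

    Parameters
    ----------
    covariates : sequence of {"log_tube_load", "algorithm"}
        Fixed effects to include.
    random_effects : sequence of {"patient", "observer"}
        Random intercepts; empty for a pure fixed-effects fit.
    dose_interval : (float, float) or None
        Closed tube-load interval restricting which records enter the fit.
    reference : str
        Reference reconstruction algorithm (its coefficient is fixed at 0).
    criterion : int or None
        Criterion to fit when the table holds several; None requires a
        single-criterion table.
    max_iter, tol, gtol
        Optimizer iteration cap, relative log-likelihood tolerance and
        gradient max-norm tolerance.

    Attributes (after ``fit``)
    --------------------------
    coef_log_tube_load_ : float — the ``a`` coefficient.
    coef_algorithm_ : dict — the ``b`` coefficients per non-reference algorithm.
    thresholds_ : ndarray — ordered cut points.
    sigma2_patient_, sigma2_observer_ : float or None — intercept variances.
    cov_fixed_ : ndarray — covariance of the fixed-effect coefficients.
    result_ : :class:`VGRFit` — full fit record.
    """

    def __init__(
        self,
        covariates: Sequence[str] = ("log_tube_load", "algorithm"),
        random_effects: Sequence[str] = (),
        dose_interval: tuple[float, float] | None = None,
        reference: str = "FBP",
        criterion: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-8,
        gtol: float = 1e-6,
    ):
        self.covariates = covariates
        self.random_effects = random_effects
        self.dose_interval = dose_interval
        self.reference = reference
        self.criterion = criterion
        self.max_iter = max_iter
        self.tol = tol
        self.gtol = gtol

    # -- helpers ----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            covariates=tuple(self.covariates),
            random_effects=tuple(self.random_effects),
            dose_interval=self.dose_interval,
            reference=self.reference,
        )

    def _select(self, X: pd.DataFrame) -> tuple[pd.DataFrame, object]:
        crits = sorted(set(X["criterion"]))
        if self.criterion is not None:
            if self.criterion not in crits:
                raise ValueError(f"criterion {self.criterion} absent from records")
            return X[X["criterion"] == self.criterion], self.criterion
        if len(crits) > 1:
            raise ValueError(
                "records span several criteria; pass criterion=<label> "
                "(each criterion is fitted separately)"
            )
        return X, (crits[0] if crits else None)

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "CumulativeLogitVGR":
        """Fit the model to a grading table (one criterion)."""
        df, crit = self._select(X)
        data = prepare_covariates(df, self._spec())
        if data.K < 2:
            raise ConvergenceError(
                "degenerate response: fewer than 2 score categories observed"
            )
        if data.X.shape[1] == 0:
            raise ValueError("model matrix has no fixed-effect columns")
        rank = np.linalg.matrix_rank(data.X)
        if rank < data.X.shape[1]:
            sd = data.X.std(axis=0)
            bad = [c for c, s in zip(data.columns, sd) if s == 0]
            culprit = bad[0] if bad else "collinear covariates"
            raise ConvergenceError(
                f"model matrix rank deficient ({culprit}); cannot fit"
            )

        warnings: list[str] = []
        re_requested = list(self.random_effects)
        if "patient" in re_requested and len(data.patient_labels) < 2:
            re_requested.remove("patient")
            warnings.append(
                "patient variance pinned at 0: fewer than 2 patients"
            )
        if "observer" in re_requested and len(data.observer_labels) < 2:
            re_requested.remove("observer")
            warnings.append(
                "observer variance pinned at 0: fewer than 2 observers"
            )

        fixed = self._fit_fixed_params(data)
        if re_requested:
            fit = self._fit_laplace(data, crit, fixed, re_requested, warnings)
        else:
            fit = self._finalize_fixed(data, crit, fixed, warnings)

        self.result_ = fit
        self.coef_log_tube_load_ = fit.a
        self.coef_algorithm_ = dict(fit.b)
        self.thresholds_ = fit.thresholds
        self.sigma2_patient_ = fit.sigma2_patient
        self.sigma2_observer_ = fit.sigma2_observer
        self.cov_fixed_ = fit.cov_fixed
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_obs_ = fit.n_obs
        self.p_values_ = dict(fit.p_values)
        self.se_ = dict(fit.se)
        self.fixed_names_ = list(fit.fixed_names)
        self.categories_ = fit.categories
        return self

    def _fit_fixed_params(self, data: ModelData):
        x0 = _init_params(data)
        res = minimize(
            _fixed_nll_grad,
            x0,
            args=(data.X, data.y, data.K),
            jac=True,
            method="BFGS",
            options={"gtol": min(self.gtol, 1e-7), "maxiter": 5 * self.max_iter},
        )
        x, gmax = res.x, float(np.max(np.abs(res.jac)))
        if gmax > self.gtol:
            x, gmax = self._newton_polish(x, data)
        p = data.X.shape[1]
        beta = x[:p]
        if np.max(np.abs(beta)) > 30:
            worst = data.columns[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"coefficient for {worst} diverged (possible separation)"
            )
        if not res.success and gmax > 100 * self.gtol:
            raise ConvergenceError(
                f"fixed-effects optimizer failed: {res.message} "
                f"(|grad|max={gmax:.2e})"
            )
        res.x = x
        nll, _ = _fixed_nll_grad(x, data.X, data.y, data.K)
        res.fun = nll
        theta = _theta_from_t(res.x[p:])
        return beta, theta, -float(res.fun), bool(gmax <= self.gtol or res.success)

    def _newton_polish(self, x, data):
        """Damped Newton steps to drive the gradient below ``gtol``."""
        def fg(v):
            return _fixed_nll_grad(v, data.X, data.y, data.K)

        val, grad = fg(x)
        for _ in range(20):
            gmax = float(np.max(np.abs(grad)))
            if gmax <= self.gtol:
                break
            H = approx_hess(lambda v: fg(v)[0], x)
            try:
                delta = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                break
            step = 1.0
            for _ls in range(30):
                new_val, new_grad = fg(x + step * delta)
                if new_val <= val + 1e-12:
                    break
                step *= 0.5
            else:
                break
            x, val, grad = x + step * delta, new_val, new_grad
        return x, float(np.max(np.abs(grad)))

    def _finalize_fixed(self, data, crit, fixed, warnings) -> VGRFit:
        beta, theta, loglik, converged = fixed
        p = data.X.shape[1]
        raw = np.concatenate([beta, theta])
        H = approx_hess(
            lambda v: _fixed_nll_raw(v, data.X, data.y, data.K), raw
        )
        cov = _safe_inv(H)
        cov_fixed = cov[:p, :p]
        return _make_fit(
            data, crit, beta, theta, cov_fixed, loglik, converged,
            method="fixed", warnings=warnings, reference=self.reference,
        )

    def _fit_laplace(self, data, crit, fixed, re_names, warnings) -> VGRFit:
        beta0, theta0, _, _ = fixed
        p = data.X.shape[1]
        groups = []
        for name in re_names:
            if name == "patient":
                groups.append((data.patient_idx, len(data.patient_labels)))
            else:
                groups.append((data.observer_idx, len(data.observer_labels)))
        work = _LaplaceWork(data.X, data.y, data.K, groups)
        n_sig = len(groups)

        def negll(phi):
            beta = phi[:p]
            theta = _theta_from_t(phi[p:p + data.K - 1])
            sigmas = np.exp(phi[p + data.K - 1:])
            return -work.marginal_loglik(beta, theta, sigmas)

        x0 = np.concatenate(
            [beta0, _t_from_theta(theta0), np.full(n_sig, np.log(0.3))]
        )
        bounds = (
            [(None, None)] * (p + data.K - 1)
            + [(-5.0, 3.0)] * n_sig
        )
        res = minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": self.max_iter,
                "ftol": max(self.tol * 1e-3, 1e-12),
                "gtol": 1e-5,
                # FD step large enough to dominate inner-solver noise
                "eps": 1e-6,
            },
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            # line search stalled on FD noise; polish derivative-free
            res2 = minimize(
                negll, res.x, method="Nelder-Mead",
                options={"maxiter": 5000, "xatol": 1e-6, "fatol": 1e-8},
            )
            improvement = res.fun - res2.fun
            if res2.fun <= res.fun:
                res = res2
                # a vanishing polish gain means the stall was at the optimum
                if improvement < 1e-4 * max(1.0, abs(res2.fun)):
                    res.success = True
            if not res.success and not res2.success:
                raise ConvergenceError(
                    f"Laplace optimizer failed: {res.message}"
                )
        phi = res.x
        beta = phi[:p]
        theta = _theta_from_t(phi[p:p + data.K - 1])
        log_sig = phi[p + data.K - 1:]
        sigmas = np.exp(log_sig)
        loglik = -float(res.fun)

        pinned = log_sig <= -4.0
        for name, pin in zip(re_names, pinned):
            if pin:
                warnings.append(f"{name} variance pinned at 0")

        # covariance: profile Hessian over non-pinned parameters
        free = np.concatenate(
            [np.ones(p + data.K - 1, bool), ~pinned]
        )
        idx_free = np.where(free)[0]

        def negll_free(v):
            full = phi.copy()
            full[idx_free] = v
            return negll(full)

        H = approx_hess(negll_free, phi[idx_free])
        cov_free = _safe_inv(H)
        cov_fixed = cov_free[:p, :p]

        sig2 = {name: float(s ** 2) for name, s in zip(re_names, sigmas)}
        fit = _make_fit(
            data, crit, beta, theta, cov_fixed, loglik,
            converged=bool(res.success), method="laplace",
            warnings=warnings, reference=self.reference,
        )
        fit.sigma2_patient = sig2.get("patient")
        fit.sigma2_observer = sig2.get("observer")
        return fit

    # -- prediction -------------------------------------------------------

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Category probabilities per record at random effects = 0."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        df, _ = self._select(X)
        spec = self._spec()
        data = prepare_covariates(df, spec)
        beta = np.array(
            [self.result_.coef[c] for c in data.columns]
        )
        eta = data.X @ beta
        th = self.thresholds_
        cdf = expit(th[None, :] - eta[:, None])
        cum = np.concatenate(
            [np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1
        )
        return np.diff(cum, axis=1)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-record log-likelihood at the fitted fixed effects."""
        proba = self.predict_proba(X)
        df, _ = self._select(X)
        data = prepare_covariates(df, self._spec())
        rows = proba[np.arange(len(data.y)), data.y]
        return float(np.mean(np.log(np.clip(rows, 1e-300, None))))


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _make_fit(data, crit, beta, theta, cov_fixed, loglik, converged, method,
              warnings, reference) -> VGRFit:
    names = data.columns
    se = np.sqrt(np.clip(np.diag(cov_fixed), 0.0, None))
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2.0 * norm.sf(np.abs(z))
    coef = {n: float(v) for n, v in zip(names, beta)}
    a = coef.get("log_tube_load")
    b = {n.split(":", 1)[1]: v for n, v in coef.items() if n.startswith("algo:")}
    return VGRFit(
        criterion=crit,
        a=a,
        b=b,
        thresholds=theta,
        coef=coef,
        se={n: float(s) for n, s in zip(names, se)},
        p_values={n: float(pv) for n, pv in zip(names, pvals)},
        cov_fixed=cov_fixed,
        fixed_names=list(names),
        loglik=loglik,
        converged=converged,
        n_obs=len(data.y),
        method=method,
        categories=data.categories,
        warnings=list(warnings),
        reference=reference,
    )


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def fit_fixed(records: pd.DataFrame, spec: ModelSpec | None = None,
              criterion: int | None = None) -> VGRFit:
    """Maximum-likelihood fixed-effects cumulative-logit fit."""
    spec = spec or ModelSpec(random_effects=())
    est = CumulativeLogitVGR(
        covariates=spec.covariates,
        random_effects=(),
        dose_interval=spec.dose_interval,
        reference=spec.reference,
        criterion=criterion,
    )
    return est.fit(records).result_


def fit_mixed(records: pd.DataFrame, spec: ModelSpec | None = None,
              criterion: int | None = None) -> VGRFit:
    """Laplace-approximated fit with crossed patient/observer intercepts."""
    spec = spec or ModelSpec()
    re = spec.random_effects or ("patient", "observer")
    est = CumulativeLogitVGR(
        covariates=spec.covariates,
        random_effects=re,
        dose_interval=spec.dose_interval,
        reference=spec.reference,
        criterion=criterion,
    )
    return est.fit(records).result_


def tube_load_effect_by_algorithm(
    records: pd.DataFrame,
    algorithm: str,
    dose_pair: tuple[float, float],
    criterion: int | None = None,
    random_effects: Sequence[str] = (),
) -> VGRFit:
    """Tube-load effect within one algorithm for one dose comparison.

    Fits the log-tube-load-only model on the records whose pair presents the
    given algorithm on both sides at the two requested tube loads, giving the
    per-algorithm dose-dependency coefficient.
    """
    lo, hi = sorted(float(d) for d in dose_pair)
    df = records
    same_algo = (df["left_algo"] == algorithm) & (df["right_algo"] == algorithm)
    loads = df[["left_mAs", "right_mAs"]].astype(float)
    match = (
        (loads.min(axis=1) == lo) & (loads.max(axis=1) == hi)
    )
    sub = df[same_algo & match]
    if not len(sub):
        raise ValueError(
            f"no records compare {lo:g} vs {hi:g} mAs within algorithm {algorithm!r}"
        )
    est = CumulativeLogitVGR(
        covariates=("log_tube_load",),
        random_effects=tuple(random_effects),
        criterion=criterion,
    )
    return est.fit(sub).result_
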