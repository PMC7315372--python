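"""Multilevel discrete-time hazard estimation.

The hazard of meeting one's average daily MVPA in hour interval t is modelled
as a logistic regression on the person-period table:

    logit h_i(t) = b0 + b1 t + b2 t^2 + b3 t^3
                 + moderator main effects + moderator x time interactions
                 + u_i,    u_i ~ N(0, sigma_u^2)

with a person-level random intercept u_i shared by all days of a person.
The marginal likelihood integrates u_i out by adaptive Gauss-Hermite
quadrature (1 node = Laplace approximation).  Internally, time is centred at
the reference hour and divided by 10 before powering to condition the cubic
design; all reported coefficients and covariances are back-transformed to the
original hour scale, so downstream odds ratios and probabilities are
invariant to the internal coding.

Model selection follows forward likelihood-ratio testing of the time
polynomial degree; moderated models inherit the selected base degree and add
one moderator at a time (main effect plus interactions with every time term),
each estimated separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .events import MODERATOR_DUMMIES

__all__ = [
    "Term",
    "ModelSpec",
    "HazardFit",
    "fit_hazard",
    "lrt",
    "select_time_polynomial",
    "fit_moderator_model",
]


@dataclass(frozen=True)
class Term:
    """One design column: (optional dummy covariate) x t**power."""

    power: int
    covariate: str | None = None

    @property
    def name(self) -> str:
        t = {0: "", 1: ":t", 2: ":t^2", 3: ":t^3"}[self.power]
        if self.covariate is None:
            return f"t^{self.power}" if self.power > 1 else ("t" if self.power else "const")
        return f"{self.covariate}{t}"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: time polynomial, optional moderator, random intercept."""

    degree: int = 3
    moderator: str | None = None
    include_interactions: bool = False
    time_center: float = 8.0
    time_scale: float = 10.0
    random_intercept: bool = True
    n_quad: int = 9

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("polynomial degree must be 1, 2 or 3")
        if self.include_interactions and self.moderator is None:
            raise ValueError("interactions require a moderator")
        if self.moderator is not None and self.moderator not in MODERATOR_DUMMIES:
            raise ValueError(f"unknown moderator {self.moderator!r}")
        if self.n_quad < 1:
            raise ValueError("need at least one quadrature node")

    def terms(self) -> list[Term]:
        out = [Term(power=k) for k in range(self.degree + 1)]
        if self.moderator is not None:
            for dummy in MODERATOR_DUMMIES[self.moderator]:
                out.append(Term(power=0, covariate=dummy))
                if self.include_interactions:
                    out.extend(
                        Term(power=k, covariate=dummy)
                        for k in range(1, self.degree + 1)
                    )
        return out


@dataclass
class HazardFit:
    """Fitted hazard model, coefficients on the original hour scale."""

    spec: ModelSpec
    terms: list[Term]
    beta: np.ndarray
    vcov: np.ndarray
    sigma_u: float
    minus2LL: float
    n_rows: int
    n_persons: int
    n_events: int
    converged: bool
    dropped: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def n_params(self) -> int:
        return len(self.terms) + int(self.spec.random_intercept)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0, None))
        return pd.DataFrame({"term": self.names, "estimate": self.beta, "se": se})

    def design_row(self, t: float, profile: dict | None = None) -> np.ndarray:
        """Design row on the original hour scale for a covariate profile."""
        profile = profile or {}
        known = {term.covariate for term in self.terms if term.covariate}
        unknown = set(profile) - known
        if unknown:
            raise ValueError(f"unknown covariate(s) in profile: {sorted(unknown)}")
        return np.array(
            [
                (1.0 if term.covariate is None else float(profile.get(term.covariate, 0.0)))
                * float(t) ** term.power
                for term in self.terms
            ]
        )

    def to_record(self) -> dict:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0, None))
        return {
            "coefficients": [
                {"term": n, "estimate": float(b), "se": float(s)}
                for n, b, s in zip(self.names, self.beta, se)
            ],
            "sigma_u": float(self.sigma_u),
            "minus2LL": float(self.minus2LL),
            "n_rows": self.n_rows,
            "n_persons": self.n_persons,
            "n_events": self.n_events,
            "converged": bool(self.converged),
            "dropped_columns": self.dropped,
            "spec": {
                "degree": self.spec.degree,
                "moderator": self.spec.moderator,
                "include_interactions": self.spec.include_interactions,
                "time_center": self.spec.time_center,
                "time_scale": self.spec.time_scale,
                "random_intercept": self.spec.random_intercept,
                "n_quad": self.spec.n_quad,
            },
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# design construction


def _scaled_design(table: pd.DataFrame, spec: ModelSpec, terms: Sequence[Term]):
    """Design matrix on the scaled time u=(t-c)/s, plus the back-transform.

    Returns (X_scaled, M) with eta = X_scaled @ beta_scaled and
    beta_original = B @ beta_scaled where B maps scaled-basis coefficients to
    the original monomial basis (blockwise binomial expansion of
    ((t-c)/s)^k).
    """
    t = table["t"].to_numpy(dtype=float)
    u = (t - spec.time_center) / spec.time_scale
    cols = []
    for term in terms:
        base = u**term.power
        if term.covariate is not None:
            base = base * table[term.covariate].to_numpy(dtype=float)
        cols.append(base)
    X = np.column_stack(cols)

    # B[i, j]: contribution of scaled coefficient j to original coefficient i,
    # within each (covariate, powers) block: ((t-c)/s)^k = sum_m C(k,m)(-c)^(k-m) s^-k t^m
    p = len(terms)
    B = np.zeros((p, p))
    c, s = spec.time_center, spec.time_scale
    for j, tj in enumerate(terms):
        for i, ti in enumerate(terms):
            if ti.covariate == tj.covariate and ti.power <= tj.power:
                k, m = tj.power, ti.power
                B[i, j] = comb(k, m) * (-c) ** (k - m) / s**k
    return X, B


def _drop_deficient(X: np.ndarray, terms: list[Term]):
    """Drop constant-zero and collinear columns (keeping the intercept)."""
    keep = list(range(X.shape[1]))
    dropped: list[int] = []
    # constant columns other than the intercept
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if np.ptp(col) < 1e-12:
            dropped.append(j)
    keep = [j for j in keep if j not in dropped]
    # collinearity via rank-revealing QR on the remaining columns
    while len(keep) > 1:
        sub = X[:, keep]
        norms = np.linalg.norm(sub, axis=0)
        _, R = np.linalg.qr(sub / np.where(norms > 0, norms, 1.0))
        diag = np.abs(np.diag(R))
        if diag.min() > 1e-8:
            break
        j = int(np.argmin(diag))
        dropped.append(keep[j])
        keep = keep[:j] + keep[j + 1 :]
    return keep, sorted(dropped)


# ---------------------------------------------------------------------------
# plain logistic (no random intercept)


def _logistic_newton(X: np.ndarray, y: np.ndarray, tol=1e-10, max_iter=100):
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = np.maximum(p * (1 - p), 1e-12)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - p)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    p = special.expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    w = np.maximum(p * (1 - p), 1e-12)
    H = (X * w[:, None]).T @ X
    vcov = np.linalg.inv(H + 1e-10 * np.eye(H.shape[0]))
    return beta, vcov, -2.0 * ll, converged


# ---------------------------------------------------------------------------
# mixed logistic via adaptive Gauss-Hermite quadrature


class _MixedLogLik:
    """Negative marginal log-likelihood with per-person AGQ.

    Persons are integer-coded; all per-person reductions are bincounts.  The
    random-intercept modes are warm-started across objective evaluations.
    """

    def __init__(self, X, y, person_idx, n_persons, n_quad):
        self.X = X
        self.y = y
        self.idx = person_idx
        self.n_persons = n_persons
        z, w = special.roots_hermite(n_quad)
        self.z = z
        self.logw = np.log(w)
        self.u_hat = np.zeros(n_persons)

    def _mode(self, xb, sigma2, n_newton=50, tol=1e-10):
        """Per-person mode of the joint log-density in u (1-d Newton)."""
        u = self.u_hat.copy()
        ev_y = np.bincount(self.idx, weights=self.y, minlength=self.n_persons)
        for _ in range(n_newton):
            eta = xb + u[self.idx]
            p = special.expit(eta)
            g = ev_y - np.bincount(self.idx, weights=p, minlength=self.n_persons) - u / sigma2
            h = -np.bincount(self.idx, weights=p * (1 - p), minlength=self.n_persons) - 1.0 / sigma2
            step = g / h
            u = u - step
            if np.max(np.abs(step)) < tol:
                break
        self.u_hat = u
        eta = xb + u[self.idx]
        p = special.expit(eta)
        fpp = -np.bincount(self.idx, weights=p * (1 - p), minlength=self.n_persons) - 1.0 / sigma2
        return u, fpp

    def __call__(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        sigma2 = sigma * sigma
        xb = self.X @ beta
        u, fpp = self._mode(xb, sigma2)
        tau = 1.0 / np.sqrt(-fpp)

        # log integrand at shifted nodes, summed per person
        acc = np.full((self.n_persons, self.z.size), -np.inf)
        log_phi_const = -0.5 * np.log(2 * np.pi * sigma2)
        for k, (zk, lwk) in enumerate(zip(self.z, self.logw)):
            uk = u + np.sqrt(2.0) * tau * zk
            eta = xb + uk[self.idx]
            ll_rows = self.y * eta - np.logaddexp(0.0, eta)
            ll_pers = np.bincount(self.idx, weights=ll_rows, minlength=self.n_persons)
            g = ll_pers + log_phi_const - 0.5 * uk**2 / sigma2
            acc[:, k] = lwk + zk * zk + g
        li = 0.5 * np.log(2.0) + np.log(tau) + special.logsumexp(acc, axis=1)
        return -float(np.sum(li))


def _numerical_hessian(f, x, h=1e-4):
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp_ = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            H[i, j] = H[j, i] = fpp_ / (4 * h * h)
    return H


# ---------------------------------------------------------------------------
# public fitting API


def fit_hazard(table: pd.DataFrame, spec: ModelSpec) -> HazardFit:
    """Fit the discrete-time hazard model specified by ``spec``.

    Never raises on optimizer failure: ``converged`` is False with
    diagnostics in ``message``.  Degenerate all-event / all-censor tables and
    missing moderator columns are rejected.
    """
    if table.empty:
        raise ValueError("person-period table is empty")
    y = table["event"].to_numpy(dtype=float)
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError(
            "degenerate table (all events or all censored): the hazard model is separated"
        )
    if spec.moderator is not None:
        for col in MODERATOR_DUMMIES[spec.moderator]:
            if col not in table.columns:
                raise ValueError(f"moderator column {col!r} missing from table")

    terms = spec.terms()
    X, B = _scaled_design(table, spec, terms)
    keep, dropped_idx = _drop_deficient(X, terms)
    dropped = [terms[j].name for j in dropped_idx]
    if dropped:
        warnings.warn(
            "dropping rank-deficient design column(s): " + ", ".join(dropped),
            stacklevel=2,
        )
    terms = [terms[j] for j in keep]
    X = X[:, keep]
    B = B[np.ix_(keep, keep)]

    pid_codes, pid_idx = np.unique(table["participant_id"].to_numpy(), return_inverse=True)
    n_persons = pid_codes.size

    beta0, vcov0, m2ll0, conv0 = _logistic_newton(X, y)

    if not spec.random_intercept:
        beta = B @ beta0
        vcov = B @ vcov0 @ B.T
        return HazardFit(
            spec=spec, terms=terms, beta=beta, vcov=vcov, sigma_u=0.0,
            minus2LL=m2ll0, n_rows=len(y), n_persons=n_persons,
            n_events=n_events, converged=conv0,
            dropped=dropped, message="fixed-effects logistic (Newton)",
        )

    nll = _MixedLogLik(X, y, pid_idx, n_persons, spec.n_quad)
    x0 = np.concatenate([beta0, [np.log(0.5)]])
    bounds = [(None, None)] * X.shape[1] + [(-10.0, 3.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
    theta = res.x
    beta_s, sigma = theta[:-1], float(np.exp(theta[-1]))
    minus2LL = 2.0 * float(res.fun)

    converged = bool(res.success) and bool(np.isfinite(minus2LL))
    message = str(res.message)

    # observed information at the optimum; beta block transformed to the
    # original time scale
    try:
        H = _numerical_hessian(nll, theta)
        vcov_all = np.linalg.inv(H)
        vcov_s = vcov_all[: X.shape[1], : X.shape[1]]
        # guard: numerical Hessians can fail psd-ness far from a clean optimum
        if not np.all(np.isfinite(vcov_s)) or np.any(np.diag(vcov_s) <= 0):
            raise np.linalg.LinAlgError("non-PSD covariance")
    except np.linalg.LinAlgError:
        vcov_s = np.full((X.shape[1], X.shape[1]), np.nan)
        converged = False
        message += "; covariance not available (singular information)"

    beta = B @ beta_s
    vcov = B @ vcov_s @ B.T
    return HazardFit(
        spec=spec, terms=terms, beta=beta, vcov=vcov, sigma_u=sigma,
        minus2LL=minus2LL, n_rows=len(y), n_persons=n_persons,
        n_events=n_events, converged=converged, dropped=dropped,
        message=message,
    )


def lrt(nested: HazardFit, full: HazardFit) -> tuple[float, int, float]:
    """Chi-square difference test of two nested fits on the same table."""
    if nested.n_rows != full.n_rows:
        raise ValueError("fits are not on the same table (row counts differ)")
    if not set(nested.names) <= set(full.names) or not (
        nested.spec.random_intercept <= full.spec.random_intercept
    ):
        raise ValueError("models are not nested")
    df = full.n_params - nested.n_params
    if df <= 0:
        if nested.n_params == full.n_params and set(nested.names) == set(full.names):
            return 0.0, 0, 1.0
        raise ValueError("full model has no extra parameters")
    chi2 = max(0.0, nested.minus2LL - full.minus2LL)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def select_time_polynomial(
    table: pd.DataFrame,
    max_degree: int = 3,
    alpha: float = 0.05,
    **spec_kwargs,
) -> tuple[int, dict[int, HazardFit], list[dict]]:
    """Forward selection of the time polynomial degree by sequential LRT.

    Degree k+1 replaces k iff the k-vs-(k+1) likelihood-ratio test has
    p < alpha; selection stops at the first non-significant step.  Returns
    (chosen degree, fits by degree, LRT trail).
    """
    if not 1 <= max_degree <= 3:
        raise ValueError("max_degree must be 1..3")
    fits: dict[int, HazardFit] = {}
    trail: list[dict] = []
    chosen = 1
    fits[1] = fit_hazard(table, ModelSpec(degree=1, **spec_kwargs))
    for k in range(2, max_degree + 1):
        fits[k] = fit_hazard(table, ModelSpec(degree=k, **spec_kwargs))
        chi2, df, p = lrt(fits[k - 1], fits[k])
        trail.append({"nested": k - 1, "full": k, "chi2": chi2, "df": df, "p": p})
        if p < alpha:
            chosen = k
        else:
            break
    return chosen, fits, trail


def fit_moderator_model(
    table: pd.DataFrame,
    moderator: str,
    base_degree: int,
    **spec_kwargs,
) -> HazardFit:
    """Base polynomial model plus one moderator and its time interactions."""
    spec = ModelSpec(
        degree=base_degree,
        moderator=moderator,
        include_interactions=True,
        **spec_kwargs,
    )
    return fit_hazard(table, spec)
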