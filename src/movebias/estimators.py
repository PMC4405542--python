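"""Maximum-likelihood estimation of directional bias in BCRW models.

Two circular-regression likelihoods for the step angles of a biased
correlated random walk are implemented:

* the *angular* model — step angles are von Mises about the compromise
  direction with a constant concentration ``kappa``; parameters are the
  bias weights ``beta_k`` and ``kappa``;
* the *consensus* model — the concentration is ``kappa * l_t`` where
  ``l_t`` is the agreement length of the compromise vector.  In its
  exponential-family form the parameters are concentrations
  ``kappa_1`` (persistence) and ``kappa_{k+1}`` (bias toward target k),
  with bias strength ``beta_k = kappa_{k+1} / kappa_1``.

Both fitters use quasi-Newton optimization with analytic gradients,
which also yield the per-record score contributions needed for
cluster-robust (sandwich) variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .circular import (
    DEGENERATE_FLOOR,
    bessel_ratio,
    log_bessel_i0,
    wrap_angle,
)

__all__ = [
    "StepSeries",
    "BCRWParams",
    "FitResult",
    "UnidentifiableError",
    "loglik_angular",
    "loglik_consensus",
    "fit_angular",
    "fit_consensus",
    "sandwich_vcov",
    "delta_method_beta_se",
]

#: upper box bound on any concentration during optimization
KAPPA_BOUND = 500.0
#: gradient-norm convergence tolerance
GRAD_TOL = 1e-8


class UnidentifiableError(RuntimeError):
    """Raised when the design carries no information on the parameters."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class StepSeries:
    """Time-ordered step records for one or more animals.

    Arrays are aligned; ``psi2`` is None unless a second taxis is
    present.  The first record of each animal has no previous bearing
    and is excluded from every likelihood (``usable`` mask), so two
    animals observed for 61 steps contribute 120 records.
    """

    animal: np.ndarray  # label per record
    t: np.ndarray  # step index within animal
    y: np.ndarray  # step angle, radians
    psi1: np.ndarray  # bearing to first target
    psi2: Optional[np.ndarray] = None  # bearing to second target
    d: Optional[np.ndarray] = None  # step length, map units

    def __post_init__(self):
        self.animal = np.asarray(self.animal)
        self.t = np.asarray(self.t, dtype=int)
        self.y = wrap_angle(np.asarray(self.y, dtype=float))
        self.psi1 = wrap_angle(np.asarray(self.psi1, dtype=float))
        if self.psi2 is not None:
            self.psi2 = wrap_angle(np.asarray(self.psi2, dtype=float))
        if self.d is not None:
            self.d = np.asarray(self.d, dtype=float)
        n = self.y.size
        for arr in (self.animal, self.t, self.psi1):
            if arr.shape[0] != n:
                raise ValueError("all StepSeries columns must share one length")
        # previous bearing within each animal; first record unusable
        self.y_prev = np.full(n, np.nan)
        self.usable = np.zeros(n, dtype=bool)
        for lab in pd.unique(self.animal):
            idx = np.flatnonzero(self.animal == lab)
            if np.any(np.diff(self.t[idx]) <= 0):
                raise ValueError(f"t must be strictly increasing within animal {lab!r}")
            self.y_prev[idx[1:]] = self.y[idx[:-1]]
            self.usable[idx[1:]] = True

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def usable_arrays(self):
        """(y, y_prev, psi list, animal labels) restricted to usable records."""
        m = self.usable
        psis = [self.psi1[m]]
        if self.psi2 is not None:
            psis.append(self.psi2[m])
        return self.y[m], self.y_prev[m], psis, self.animal[m]

    def to_frame(self) -> pd.DataFrame:
        cols = {"animal_id": self.animal, "t": self.t, "y_angle": self.y, "psi1": self.psi1}
        if self.psi2 is not None:
            cols["psi2"] = self.psi2
        if self.d is not None:
            cols["d"] = self.d
        return pd.DataFrame(cols)

    @staticmethod
    def concat(series: Sequence["StepSeries"]) -> "StepSeries":
        has2 = any(s.psi2 is not None for s in series)
        hasd = all(s.d is not None for s in series)
        return StepSeries(
            animal=np.concatenate([s.animal for s in series]),
            t=np.concatenate([s.t for s in series]),
            y=np.concatenate([s.y for s in series]),
            psi1=np.concatenate([s.psi1 for s in series]),
            psi2=np.concatenate([s.psi2 for s in series]) if has2 else None,
            d=np.concatenate([s.d for s in series]) if hasd else None,
        )


@dataclass(frozen=True)
class BCRWParams:
    """Concentration parameterization shared by all three methods.

    ``kappa1`` is the directional-persistence concentration and
    ``kappa2``/``kappa3`` the target-bias concentrations; the bias
    strengths are the ratios ``beta_k = kappa_{k+1}/kappa1``.  For the
    angular model ``kappa1`` plays the role of the error concentration
    ``kappa`` and ``kappa_{k+1} = kappa * beta_k``, so the ``beta``
    properties are consistent across methods.
    """

    kappa1: float
    kappa2: float
    kappa3: Optional[float] = None

    @property
    def beta1(self) -> float:
        if self.kappa1 == 0:
            raise ZeroDivisionError("beta undefined when kappa1 = 0")
        return self.kappa2 / self.kappa1

    @property
    def beta2(self) -> Optional[float]:
        if self.kappa3 is None:
            return None
        if self.kappa1 == 0:
            raise ZeroDivisionError("beta undefined when kappa1 = 0")
        return self.kappa3 / self.kappa1

    @property
    def kappas(self) -> np.ndarray:
        ks = [self.kappa1, self.kappa2]
        if self.kappa3 is not None:
            ks.append(self.kappa3)
        return np.asarray(ks)


@dataclass
class FitResult:
    """Point estimates plus model-based and robust uncertainty."""

    method: str
    params: BCRWParams
    param_names: list[str]
    estimates: np.ndarray
    loglik: float
    vcov_model: Optional[np.ndarray]
    vcov_sandwich: Optional[np.ndarray]
    beta: dict[str, float]
    beta_se: dict[str, float]
    converged: bool
    at_bound: bool
    n_obs: int
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        se_m = (
            np.sqrt(np.clip(np.diag(self.vcov_model), 0, None))
            if self.vcov_model is not None
            else np.full(len(self.param_names), np.nan)
        )
        se_r = (
            np.sqrt(np.clip(np.diag(self.vcov_sandwich), 0, None))
            if self.vcov_sandwich is not None
            else np.full(len(self.param_names), np.nan)
        )
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.estimates,
                "se_model": se_m,
                "se_robust": se_r,
            }
        )


# ---------------------------------------------------------------------------
# likelihoods (vectorized internals return per-record contributions)
# ---------------------------------------------------------------------------


def _compromise(y_prev, psis, betas):
    """Components, length and direction of the per-record compromise vector."""
    east = np.cos(y_prev).copy()
    north = np.sin(y_prev).copy()
    for psi, b in zip(psis, betas):
        east += b * np.cos(psi)
        north += b * np.sin(psi)
    length = np.hypot(east, north)
    mu = np.where(length < DEGENERATE_FLOOR, 0.0, np.arctan2(north, east))
    return east, north, length, mu


def _angular_terms(betas, kappa, y, y_prev, psis):
    _, _, length, mu = _compromise(y_prev, psis, betas)
    ll_t = kappa * np.cos(y - mu) - math.log(2 * math.pi) - log_bessel_i0(kappa)
    return ll_t, length, mu


def loglik_angular(params: BCRWParams, data: StepSeries) -> float:
    """Log-likelihood of the constant-concentration angular model.

    ``params`` follows the shared concentration parameterization:
    the error concentration is ``params.kappa1`` and the bias weights
    are ``params.beta1`` (and ``beta2`` for two taxes).
    """
    kappa = params.kappa1
    if kappa <= 0:
        raise ValueError("angular model requires a positive concentration")
    y, y_prev, psis, _ = data.usable_arrays()
    betas = [params.beta1] + ([params.beta2] if params.kappa3 is not None else [])
    if len(betas) > len(psis):
        raise ValueError("data lacks a second target bearing for a two-taxis model")
    ll_t, _, _ = _angular_terms(betas, kappa, y, y_prev, psis[: len(betas)])
    return float(ll_t.sum())


def _consensus_terms(kappas, y, y_prev, psis):
    """Per-record consensus log-density and the resultant of the kappa-weighted
    unit vectors (whose norm is kappa1 * l_t)."""
    dirs = [y_prev] + list(psis)
    rx = np.zeros_like(y)
    ry = np.zeros_like(y)
    lin = np.zeros_like(y)
    for k, ang in zip(kappas, dirs):
        rx += k * np.cos(ang)
        ry += k * np.sin(ang)
        lin += k * np.cos(y - ang)
    r = np.hypot(rx, ry)
    ll_t = lin - math.log(2 * math.pi) - log_bessel_i0(r)
    return ll_t, rx, ry, r


def loglik_consensus(params: BCRWParams, data: StepSeries) -> float:
    """Exponential-family log-likelihood of the consensus model.

    Well defined for any real concentrations, including zero and
    negative (repulsive) values.
    """
    y, y_prev, psis, _ = data.usable_arrays()
    kappas = params.kappas
    if kappas.size - 1 > len(psis):
        raise ValueError("data lacks a second target bearing for a two-taxis model")
    ll_t, *_ = _consensus_terms(kappas, y, y_prev, psis[: kappas.size - 1])
    return float(ll_t.sum())


def _consensus_scores(kappas, y, y_prev, psis):
    ll_t, rx, ry, r = _consensus_terms(kappas, y, y_prev, psis)
    # A(r)/r -> 1/2 as r -> 0
    ratio = np.where(r < 1e-8, 0.5, bessel_ratio(r) / np.where(r < 1e-8, 1.0, r))
    dirs = [y_prev] + list(psis)
    scores = np.empty((y.size, len(kappas)))
    for j, ang in enumerate(dirs):
        scores[:, j] = np.cos(y - ang) - ratio * (np.cos(ang) * rx + np.sin(ang) * ry)
    return ll_t, scores


def _angular_scores(betas, kappa, y, y_prev, psis):
    _, _, length, mu = _compromise(y_prev, psis, betas)
    ll_t = kappa * np.cos(y - mu) - math.log(2 * math.pi) - log_bessel_i0(kappa)
    safe_l = np.where(length < DEGENERATE_FLOOR, 1.0, length)
    scores = np.empty((y.size, len(betas) + 1))
    for k, psi in enumerate(psis):
        scores[:, k] = kappa * np.sin(y - mu) * np.sin(psi - mu) / safe_l
    scores[:, -1] = np.cos(y - mu) - bessel_ratio(kappa)
    return ll_t, scores


# ---------------------------------------------------------------------------
# variance machinery
# ---------------------------------------------------------------------------


def sandwich_vcov(score_contributions, hessian, clusters=None) -> np.ndarray:
    """Cluster-robust sandwich covariance H^{-1} (sum g g') H^{-1}.

    ``score_contributions`` is the n x p table of per-record gradients of
    the log-likelihood at the optimum and ``hessian`` the p x p Hessian
    (either sign; the sign cancels in the sandwich).  When ``clusters``
    is given, scores are summed within cluster before the outer product,
    the conservative choice for serially dependent steps of one animal.
    """
    g = np.asarray(score_contributions, dtype=float)
    h = np.asarray(hessian, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if clusters is not None:
        clusters = np.asarray(clusters)
        g = np.vstack([g[clusters == c].sum(axis=0) for c in pd.unique(clusters)])
    bread = np.linalg.inv(h)
    meat = g.T @ g
    out = bread @ meat @ bread.T
    return 0.5 * (out + out.T)


def delta_method_beta_se(fit_or_kappas, vcov=None) -> np.ndarray:
    """Standard errors of the ratios beta_k = kappa_{k+1}/kappa_1.

    Accepts either a :class:`FitResult` in the concentration
    parameterization, or ``(kappas, vcov)`` arrays directly.  The
    gradient of the ratio is (-kappa_{k+1}/kappa_1^2, ..., 1/kappa_1,
    ...); the SE is invariant to rescaling kappas by c with vcov by c^2.
    """
    if isinstance(fit_or_kappas, FitResult):
        kappas = fit_or_kappas.params.kappas
        vcov = fit_or_kappas.vcov_sandwich
        if vcov is None:
            vcov = fit_or_kappas.vcov_model
    else:
        kappas = np.asarray(fit_or_kappas, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    k1 = kappas[0]
    if abs(k1) < 1e-10:
        raise ZeroDivisionError("beta SE undefined: kappa1 is (numerically) zero")
    ses = np.empty(kappas.size - 1)
    for k in range(1, kappas.size):
        grad = np.zeros(kappas.size)
        grad[0] = -kappas[k] / k1**2
        grad[k] = 1.0 / k1
        ses[k - 1] = math.sqrt(max(float(grad @ vcov @ grad), 0.0))
    return ses


def _numeric_hessian(grad_fn, theta, h=1e-5):
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        step = h * max(1.0, abs(theta[j]))
        up = theta.copy()
        up[j] += step
        dn = theta.copy()
        dn[j] -= step
        H[:, j] = (grad_fn(up) - grad_fn(dn)) / (2 * step)
    return 0.5 * (H + H.T)


def _safe_inv(mat):
    try:
        inv = np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(mat)
    return 0.5 * (inv + inv.T)


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------


def _cluster_labels(animals, cluster: bool):
    """Cluster scores by animal only when enough clusters exist.

    With k clusters the cluster score sums add to zero at the optimum,
    so the meat matrix has rank at most k - 1; below 3 animals the
    clustered sandwich is degenerate and per-record robust scores are
    used instead.
    """
    if cluster and pd.unique(animals).size >= 3:
        return animals
    return None


def _softplus(s):
    return np.logaddexp(0.0, s)


def _softplus_inv(b):
    return math.log(math.expm1(b))


def fit_angular(data: StepSeries, n_biases: int = 1, cluster: bool = True) -> FitResult:
    """ML fit of the angular model: bias weights beta_k >= 0 and error
    concentration kappa.

    beta is parameterized through a softplus and kappa through its log
    with an upper box bound; estimates pinned at the bound are flagged.
    Robust SEs come from per-animal clustered sandwich variances.
    """
    y, y_prev, psis, animals = data.usable_arrays()
    if y.size < 10:
        raise ValueError("need at least 10 usable records")
    if n_biases not in (1, 2):
        raise ValueError("n_biases must be 1 or 2")
    if n_biases > len(psis):
        raise ValueError("two-taxis fit requires a psi2 column")
    psis = psis[:n_biases]
    if all(np.max(np.abs(wrap_angle(psi - y_prev))) < 1e-12 for psi in psis):
        raise UnidentifiableError(
            "all target bearings coincide with the previous bearing; "
            "beta and kappa are not jointly identifiable"
        )

    def unpack(theta):
        return _softplus(theta[:-1]), math.exp(theta[-1])

    def negloglik(theta):
        betas, kappa = unpack(theta)
        ll_t, _ = _angular_scores(list(betas), kappa, y, y_prev, psis)
        return -float(ll_t.sum())

    def neggrad(theta):
        betas, kappa = unpack(theta)
        _, scores = _angular_scores(list(betas), kappa, y, y_prev, psis)
        g_nat = scores.sum(axis=0)
        jac = np.empty(theta.size)
        jac[:-1] = g_nat[:-1] * special.expit(theta[:-1])  # d beta / d s
        jac[-1] = g_nat[-1] * kappa  # d kappa / d u
        return -jac

    theta0 = np.r_[np.full(n_biases, _softplus_inv(0.1)), 0.0]
    bounds = [(None, None)] * n_biases + [(None, math.log(KAPPA_BOUND))]
    res = optimize.minimize(
        negloglik,
        theta0,
        jac=neggrad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": GRAD_TOL},
    )
    betas, kappa = unpack(res.x)
    at_bound = kappa >= KAPPA_BOUND * (1 - 1e-6)
    estimates = np.r_[betas, kappa]
    names = [f"beta{k+1}" for k in range(n_biases)] + ["kappa"]
    ll_t, scores = _angular_scores(list(betas), kappa, y, y_prev, psis)

    def nat_grad(theta_nat):
        # clip to the parameter domain so finite-difference steps stay valid
        bs = np.clip(theta_nat[:-1], 0.0, None)
        _, s = _angular_scores(list(bs), max(theta_nat[-1], 1e-9), y, y_prev, psis)
        return s.sum(axis=0)

    vcov_model = vcov_sandwich = None
    if not at_bound:
        H = _numeric_hessian(nat_grad, estimates)
        vcov_model = _safe_inv(-H)
        vcov_sandwich = sandwich_vcov(scores, H, _cluster_labels(animals, cluster))
    beta = {names[k]: float(betas[k]) for k in range(n_biases)}
    beta_se = {
        names[k]: float(math.sqrt(max(vcov_sandwich[k, k], 0.0))) if vcov_sandwich is not None else math.nan
        for k in range(n_biases)
    }
    params = BCRWParams(
        kappa1=kappa,
        kappa2=kappa * betas[0],
        kappa3=kappa * betas[1] if n_biases == 2 else None,
    )
    return FitResult(
        method="angular",
        params=params,
        param_names=names,
        estimates=estimates,
        loglik=float(ll_t.sum()),
        vcov_model=vcov_model,
        vcov_sandwich=vcov_sandwich,
        beta=beta,
        beta_se=beta_se,
        converged=bool(res.success) or at_bound,
        at_bound=bool(at_bound),
        n_obs=int(y.size),
        message=str(res.message),
    )


def fit_consensus(data: StepSeries, n_biases: int = 1, cluster: bool = True) -> FitResult:
    """ML fit of the consensus model over unconstrained concentrations.

    The exponential-family likelihood is well defined for negative
    concentrations (a repulsive bias), so no positivity constraint is
    imposed; bias strengths beta_k = kappa_{k+1}/kappa_1 carry
    delta-method standard errors based on the clustered sandwich
    covariance of the kappas.
    """
    y, y_prev, psis, animals = data.usable_arrays()
    if y.size < 10:
        raise ValueError("need at least 10 usable records")
    if n_biases not in (1, 2):
        raise ValueError("n_biases must be 1 or 2")
    if n_biases > len(psis):
        raise ValueError("two-taxis fit requires a psi2 column")
    psis = psis[:n_biases]
    p = 1 + n_biases

    def negloglik(kappas):
        ll_t, _ = _consensus_scores(kappas, y, y_prev, psis)
        return -float(ll_t.sum())

    def neggrad(kappas):
        _, scores = _consensus_scores(kappas, y, y_prev, psis)
        return -scores.sum(axis=0)

    res = optimize.minimize(
        negloglik,
        np.ones(p),
        jac=neggrad,
        method="L-BFGS-B",
        bounds=[(-KAPPA_BOUND, KAPPA_BOUND)] * p,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": GRAD_TOL},
    )
    kappas = res.x
    at_bound = bool(np.any(np.abs(kappas) >= KAPPA_BOUND * (1 - 1e-6)))
    ll_t, scores = _consensus_scores(kappas, y, y_prev, psis)

    def nat_grad(k):
        _, s = _consensus_scores(k, y, y_prev, psis)
        return s.sum(axis=0)

    H = _numeric_hessian(nat_grad, kappas)
    vcov_model = _safe_inv(-H)
    vcov_sandwich = sandwich_vcov(scores, H, _cluster_labels(animals, cluster))
    names = [f"kappa{j+1}" for j in range(p)]
    params = BCRWParams(
        kappa1=float(kappas[0]),
        kappa2=float(kappas[1]),
        kappa3=float(kappas[2]) if p == 3 else None,
    )
    beta, beta_se = _beta_with_se(kappas, vcov_sandwich, n_biases)
    return FitResult(
        method="consensus",
        params=params,
        param_names=names,
        estimates=kappas.copy(),
        loglik=float(ll_t.sum()),
        vcov_model=vcov_model,
        vcov_sandwich=vcov_sandwich,
        beta=beta,
        beta_se=beta_se,
        converged=bool(res.success) and not at_bound,
        at_bound=at_bound,
        n_obs=int(y.size),
        message=str(res.message),
    )


def _beta_with_se(kappas, vcov, n_biases):
    """beta_k point estimates and delta-method SEs; NaN when kappa1 ~ 0."""
    beta, beta_se = {}, {}
    k1 = kappas[0]
    degenerate = abs(k1) < 1e-10
    try:
        ses = delta_method_beta_se(kappas, vcov) if not degenerate else None
    except (ZeroDivisionError, np.linalg.LinAlgError):
        ses = None
    for k in range(n_biases):
        name = f"beta{k+1}"
        beta[name] = math.nan if degenerate else float(kappas[k + 1] / k1)
        beta_se[name] = float(ses[k]) if ses is not None else math.nan
    return beta, beta_se
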