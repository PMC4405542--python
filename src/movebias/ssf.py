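"""Step-selection-function (case-control) estimation of directional bias.

Each observed step angle is compared against J "available" control
angles that share the same anchors (previous bearing and target
bearings); a conditional-logistic likelihood with the cosine covariates
cos(angle - y_prev) and cos(angle - psi_k) then estimates the same
concentrations (kappa_1, kappa_2[, kappa_3]) as the consensus BCRW
model.  With many uniformly distributed controls the per-stratum
log-denominator converges (law of large numbers) to log I0(kappa_1 *
l_t), making the SSF and consensus likelihoods asymptotically
identical.

The fitter maximizes the conditional-logistic likelihood directly with
analytic gradient and Hessian, so the J-control denominator matches the
formula term for term; the long-format serialization lets any standard
conditional-logistic routine cross-check it.

A pixel-trail design is included: for a trail snapped to a raster, the
7 neighbors of the current pixel other than the previously occupied one
form the choice set (1 case + 6 exhaustive controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .circular import wrap_angle
from .estimators import (
    BCRWParams,
    FitResult,
    KAPPA_BOUND,
    GRAD_TOL,
    StepSeries,
    _beta_with_se,
    _safe_inv,
)

__all__ = [
    "CaseControlStratum",
    "sample_controls",
    "build_design",
    "fit_ssf",
    "trail_ssf_design",
    "strata_to_frame",
    "DesignMismatchError",
]

NEIGHBOR_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)


class DesignMismatchError(ValueError):
    """Controls not aligned one-to-one with the usable records."""


@dataclass
class CaseControlStratum:
    """One observed step and its J control angles.

    The anchors (previous bearing, target bearings) are shared by case
    and controls; covariates are the cosines of each alternative's angle
    minus each anchor, case in row 0.
    """

    stratum_id: int
    y: float
    controls: np.ndarray
    y_prev: float
    psi1: float
    psi2: Optional[float] = None

    def __post_init__(self):
        self.controls = np.atleast_1d(np.asarray(self.controls, dtype=float))
        if self.controls.size < 1:
            raise ValueError("a stratum needs at least one control")

    @property
    def n_alternatives(self) -> int:
        return 1 + self.controls.size

    def angles(self) -> np.ndarray:
        return np.r_[self.y, self.controls]

    def covariates(self) -> np.ndarray:
        """(1+J) x p matrix of cosine covariates, case first."""
        ang = self.angles()
        cols = [np.cos(ang - self.y_prev), np.cos(ang - self.psi1)]
        if self.psi2 is not None:
            cols.append(np.cos(ang - self.psi2))
        return np.column_stack(cols)


def sample_controls(observed_angles, J: int, scheme: str = "empirical", rng=None):
    """Control angles for one stratum per observed angle.

    ``empirical`` draws J angles per stratum with replacement from the
    pooled observed angles (duplicates are legitimate resamples and are
    kept); ``uniform`` draws them iid on [-pi, pi).  Returns a T x J
    array aligned with the observed angles.
    """
    observed_angles = np.asarray(observed_angles, dtype=float)
    n = observed_angles.size
    if J < 1:
        raise ValueError("J must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if scheme == "uniform":
        return rng.uniform(-math.pi, math.pi, size=(n, J))
    if scheme == "empirical":
        if n == 0:
            raise ValueError("empirical control sampling needs a nonempty pool")
        return observed_angles[rng.integers(0, n, size=(n, J))]
    raise ValueError(f"unknown control scheme {scheme!r}")


def build_design(data: StepSeries, controls) -> list[CaseControlStratum]:
    """One stratum per usable record of ``data``.

    ``controls`` must be a (n_usable, J) array aligned with the usable
    records in their stored order.
    """
    y, y_prev, psis, _ = data.usable_arrays()
    controls = np.asarray(controls, dtype=float)
    if controls.ndim != 2 or controls.shape[0] != y.size:
        raise DesignMismatchError(
            f"controls shape {controls.shape} does not match {y.size} usable records"
        )
    psi2 = psis[1] if len(psis) > 1 else [None] * y.size
    return [
        CaseControlStratum(
            stratum_id=i,
            y=y[i],
            controls=controls[i],
            y_prev=y_prev[i],
            psi1=psis[0][i],
            psi2=psi2[i],
        )
        for i in range(y.size)
    ]


def _stack_design(strata: Sequence[CaseControlStratum]):
    """Covariate tensor (n_strata, 1+J, p); requires constant J."""
    sizes = {s.n_alternatives for s in strata}
    if len(sizes) != 1:
        raise DesignMismatchError("J must be constant across strata within a design")
    X = np.stack([s.covariates() for s in strata])
    return X


def ssf_loglik(kappas, X) -> float:
    """Conditional-logistic log-likelihood on a stacked design tensor."""
    eta = X @ np.asarray(kappas, dtype=float)
    return float((eta[:, 0] - logsumexp(eta, axis=1)).sum())


def _ssf_score_hess(kappas, X):
    eta = X @ kappas
    ll = float((eta[:, 0] - logsumexp(eta, axis=1)).sum())
    p = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    xbar = np.einsum("ta,tap->tp", p, X)
    scores = X[:, 0, :] - xbar
    exx = np.einsum("ta,tap,taq->pq", p, X, X)
    hess = -(exx - xbar.T @ xbar)
    return ll, scores, hess


def fit_ssf(strata: Sequence[CaseControlStratum], n_biases: int = 1) -> FitResult:
    """Conditional-logistic fit of the SSF concentrations.

    Maximizes the product over strata of exp(case linear predictor)
    divided by the sum over the case and all J controls.  Standard
    errors come from the inverse conditional-logistic information
    matrix; bias strengths beta_k = kappa_{k+1}/kappa_1 carry
    delta-method SEs.  Designs in which every alternative carries
    identical covariates are flagged unidentifiable (the likelihood is
    flat at -sum log(J+1)).
    """
    strata = list(strata)
    if len(strata) < 10:
        raise ValueError("need at least 10 strata")
    if n_biases not in (1, 2):
        raise ValueError("n_biases must be 1 or 2")
    X = _stack_design(strata)
    if n_biases == 2 and X.shape[2] < 3:
        raise ValueError("two-taxis fit requires strata with a psi2 anchor")
    X = X[:, :, : 1 + n_biases]
    p = X.shape[2]

    # uninformative design: covariates constant within every stratum
    if np.all(np.abs(X - X[:, :1, :]) < 1e-12):
        kappas = np.zeros(p)
        names = [f"kappa{j+1}" for j in range(p)]
        return FitResult(
            method="ssf",
            params=BCRWParams(0.0, 0.0, 0.0 if p == 3 else None),
            param_names=names,
            estimates=kappas,
            loglik=ssf_loglik(kappas, X),
            vcov_model=None,
            vcov_sandwich=None,
            beta={f"beta{k+1}": math.nan for k in range(n_biases)},
            beta_se={f"beta{k+1}": math.nan for k in range(n_biases)},
            converged=False,
            at_bound=False,
            n_obs=len(strata),
            message="unidentifiable: identical covariates across alternatives",
        )

    def negloglik(kappas):
        eta = X @ kappas
        return -float((eta[:, 0] - logsumexp(eta, axis=1)).sum())

    def neggrad(kappas):
        _, scores, _ = _ssf_score_hess(kappas, X)
        return -scores.sum(axis=0)

    res = optimize.minimize(
        negloglik,
        np.zeros(p),
        jac=neggrad,
        method="L-BFGS-B",
        bounds=[(-KAPPA_BOUND, KAPPA_BOUND)] * p,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": GRAD_TOL},
    )
    kappas = res.x
    at_bound = bool(np.any(np.abs(kappas) >= KAPPA_BOUND * (1 - 1e-6)))
    ll, scores, hess = _ssf_score_hess(kappas, X)
    vcov_model = _safe_inv(-hess)
    names = [f"kappa{j+1}" for j in range(p)]
    params = BCRWParams(
        kappa1=float(kappas[0]),
        kappa2=float(kappas[1]),
        kappa3=float(kappas[2]) if p == 3 else None,
    )
    beta, beta_se = _beta_with_se(kappas, vcov_model, n_biases)
    return FitResult(
        method="ssf",
        params=params,
        param_names=names,
        estimates=kappas.copy(),
        loglik=ll,
        vcov_model=vcov_model,
        vcov_sandwich=vcov_model,
        beta=beta,
        beta_se=beta_se,
        converged=bool(res.success) and not at_bound,
        at_bound=at_bound,
        n_obs=len(strata),
        message=str(res.message),
    )


def _pixel_bearing(frm, to, pixel_size: float) -> float:
    """Center-to-center bearing; row 0 is the north edge, east = +x."""
    d_east = (to[1] - frm[1]) * pixel_size
    d_north = (frm[0] - to[0]) * pixel_size
    return wrap_angle(math.atan2(d_north, d_east))


#: bearing of each 8-neighbor offset (independent of pixel size)
NEIGHBOR_BEARINGS = np.arctan2(-NEIGHBOR_OFFSETS[:, 0], NEIGHBOR_OFFSETS[:, 1])


def trail_ssf_design(
    pixel_path,
    targets,
    grid_shape: Optional[tuple[int, int]] = None,
    pixel_size: float = 10.0,
) -> list[CaseControlStratum]:
    """Case-control strata for a trail snapped to a raster.

    ``pixel_path`` is an ordered (n, 2) array of (row, col) pixels,
    8-connected and without immediate backtracking.  ``targets`` maps
    anchor names to per-pixel target bearings: a dict with key ``psi1``
    (and optionally ``psi2``), each an array of length n giving the
    bearing from that path pixel.  For each interior position t the
    choice set is the 8-neighborhood of the current pixel minus the
    pixel occupied at t-1: the pixel entered at t+1 is the case and the
    remaining 6 are exhaustive controls.  First and last path pixels
    yield no stratum.
    """
    path = np.asarray(pixel_path, dtype=int)
    if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 3:
        raise ValueError("pixel_path must be an (n >= 3, 2) array of (row, col)")
    steps = np.abs(np.diff(path, axis=0))
    if np.any(steps.max(axis=1) != 1):
        raise ValueError("consecutive path pixels must be distinct 8-neighbors")
    if np.any(np.all(path[2:] == path[:-2], axis=1)):
        raise ValueError("path revisits the previous pixel (backtracking triple)")
    if grid_shape is not None:
        rows, cols = grid_shape
        if np.any(path < 0) or np.any(path[:, 0] >= rows) or np.any(path[:, 1] >= cols):
            raise ValueError("path leaves the grid (out of bounds)")
    psi1 = np.asarray(targets["psi1"], dtype=float)
    psi2 = np.asarray(targets["psi2"], dtype=float) if "psi2" in targets and targets["psi2"] is not None else None
    if psi1.size != path.shape[0]:
        raise DesignMismatchError("targets must supply one bearing per path pixel")

    strata = []
    for t in range(1, path.shape[0] - 1):
        cur, prev, nxt = path[t], path[t - 1], path[t + 1]
        neighbors = cur + NEIGHBOR_OFFSETS
        keep = ~np.all(neighbors == prev, axis=1)
        bearings = NEIGHBOR_BEARINGS[keep]
        alts = neighbors[keep]
        is_case = np.all(alts == nxt, axis=1)
        if is_case.sum() != 1:
            raise ValueError(f"path position {t}: next pixel not a valid alternative")
        strata.append(
            CaseControlStratum(
                stratum_id=t,
                y=float(bearings[is_case][0]),
                controls=bearings[~is_case],
                y_prev=_pixel_bearing(prev, cur, pixel_size),
                psi1=psi1[t],
                psi2=None if psi2 is None else psi2[t],
            )
        )
    return strata


def strata_to_frame(strata: Sequence[CaseControlStratum]) -> pd.DataFrame:
    """Long-format table (stratum_id, is_case, cos_turn, cos_target1[,
    cos_target2]) consumable by any conditional-logistic routine."""
    rows = []
    for s in strata:
        cov = s.covariates()
        for a in range(cov.shape[0]):
            rec = {
                "stratum_id": s.stratum_id,
                "is_case": int(a == 0),
                "cos_turn": cov[a, 0],
                "cos_target1": cov[a, 1],
            }
            if cov.shape[1] > 2:
                rec["cos_target2"] = cov[a, 2]
            rows.append(rec)
    return pd.DataFrame(rows)
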