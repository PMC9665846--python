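"""Dyadic mixed models for distances and association counts.

Two model families operate on tables with one row per unordered dyad:

* a Gaussian linear mixed model for facial distance with a "diallel"
  dyad random effect — correlation ``rho`` between dyads sharing one
  individual, 0 otherwise, so the random-effect covariance is
  ``sigma_u^2 (I + rho A)`` with A the share-one-individual adjacency —
  and heteroscedastic residuals with prior weights (the number of
  picture pairs behind each dyad's mean distance). ``rho = 0.5`` is the
  special case of two additive individual effects ("general combining
  ability"); deviations capture pair-specific effects.

* negative-binomial log-link GLMMs for scan counts with a
  fixed-coefficient-1 offset (log total scans) and either symmetric
  additive individual random effects (infant-infant, mother-mother) or
  two crossed individual effects (mother-infant). Fitting maximizes the
  Laplace-approximated marginal likelihood; the NB shape parameterizes
  the variance as ``mu + mu^2/shape``.

Likelihood-ratio tests compare nested ML fits; Wald statistics are also
reported per term, since published per-term chi-squares may be either.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "Design",
    "build_design",
    "LmmFit",
    "GlmmFit",
    "LrtResult",
    "fit_facial_distance_lmm",
    "residual_facial_distance",
    "fit_association_glmm",
    "lrt",
    "vif",
    "association_correlation",
    "directionality_summary",
    "filter_dyads",
]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Names the response, predictors and auxiliary columns of a model.

    ``categorical`` maps a column to its reference level (dummy-coded
    against it); ``continuous`` columns are z-scored on the fitted table.
    """

    response: str
    continuous: Sequence[str] = ()
    categorical: Mapping[str, str] = field(default_factory=dict)
    offset: Optional[str] = None   # column of total counts; log applied
    weights: Optional[str] = None  # prior weights (LMM)
    intercept: bool = True


@dataclass
class Design:
    X: np.ndarray
    names: list[str]
    y: np.ndarray
    offset_log: Optional[np.ndarray]
    weights: Optional[np.ndarray]
    centers: dict[str, float]
    scales: dict[str, float]


def build_design(table: pd.DataFrame, model_spec: ModelSpec) -> Design:
    """Build a model matrix: z-scored continuous predictors, dummy-coded
    categorical predictors against their stated reference level.

    Returns the standardization constants so estimates can be mapped back
    to natural units. A zero-variance continuous predictor, or a
    categorical predictor with a single observed level, is an error
    naming the column.
    """
    cols, names = [], []
    centers, scales = {}, {}
    if model_spec.intercept:
        cols.append(np.ones(len(table)))
        names.append("intercept")
    for c in model_spec.continuous:
        v = table[c].to_numpy(float)
        m, s = float(v.mean()), float(v.std(ddof=0))
        if s == 0.0:
            raise ValueError(f"zero-variance continuous predictor: {c!r}")
        centers[c], scales[c] = m, s
        cols.append((v - m) / s)
        names.append(c)
    for c, ref in model_spec.categorical.items():
        v = table[c].astype(str)
        levels = sorted(v.unique())
        if len(levels) < 2:
            raise ValueError(
                f"categorical predictor {c!r} has a single level "
                f"({levels[0]!r}) in the fitted table"
            )
        if ref not in levels:
            ref = v.value_counts().idxmax()
            logger.warning(
                "reference level absent for %r; using most frequent "
                "level %r instead", c, ref
            )
        for lev in levels:
            if lev == ref:
                continue
            cols.append((v == lev).to_numpy(float))
            names.append(f"{c}[{lev}]")
    y = table[model_spec.response].to_numpy(float)
    off = None
    if model_spec.offset is not None:
        tot = table[model_spec.offset].to_numpy(float)
        if np.any(tot <= 0):
            raise ValueError("offset totals must be positive")
        off = np.log(tot)
    w = None
    if model_spec.weights is not None:
        w = table[model_spec.weights].to_numpy(float)
        if np.any(w <= 0):
            raise ValueError("prior weights must be positive")
    X = np.column_stack(cols)
    return Design(X=X, names=names, y=y, offset_log=off, weights=w,
                  centers=centers, scales=scales)


def _member_codes(table: pd.DataFrame) -> tuple[np.ndarray, int]:
    both = pd.concat([table["id_a"], table["id_b"]], ignore_index=True)
    codes, uniques = pd.factorize(both)
    n = len(table)
    return np.column_stack([codes[:n], codes[n:]]), len(uniques)


def _digest(y: np.ndarray) -> str:
    return hashlib.md5(np.ascontiguousarray(y).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Gaussian LMM with diallel random effect
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma_u2: float
    rho: float
    sigma_e2: float
    loglik: float          # ML, for likelihood-ratio tests
    loglik_reml: float
    converged: bool
    n: int
    rho_bounds: tuple[float, float]
    y_digest: str
    random_kind: str = "diallel"

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {
                "predictor": self.names,
                "estimate": self.beta,
                "se": self.se,
                "wald_chi2": z**2,
                "p": stats.chi2.sf(z**2, 1),
            }
        )


def _rho_bounds(C: np.ndarray, m: int) -> tuple[float, float]:
    """PSD-admissible interval for rho from the spectrum of the
    share-one-individual adjacency A = ZZ' - 2I (a line-graph adjacency,
    so its eigenvalues are the squared singular values of Z minus 2,
    padded with -2 when dyads outnumber individuals)."""
    n = len(C)
    ones = np.ones(n)
    ZtZ = np.zeros(m * m)
    for t1 in (0, 1):
        for t2 in (0, 1):
            ZtZ += np.bincount(C[:, t1] * m + C[:, t2], weights=ones,
                               minlength=m * m)
    sv2 = np.linalg.eigvalsh(ZtZ.reshape(m, m))
    lam_max = float(sv2[-1]) - 2.0
    if n > m:
        lam_min = -2.0
    else:
        Z = np.zeros((n, m))
        Z[np.arange(n), C[:, 0]] += 1.0
        Z[np.arange(n), C[:, 1]] += 1.0
        lam_min = float(np.min(np.linalg.eigvalsh(Z @ Z.T))) - 2.0
    if lam_max <= 1e-9:
        return (0.0, 0.0)  # no two dyads overlap: rho unidentifiable
    lo = -1.0 / lam_max
    hi = 0.5 if lam_min <= -2.0 + 1e-12 else min(0.5, -1.0 / lam_min)
    return (lo, hi)


class _LmmProblem:
    def __init__(self, y, X, w, C, m):
        self.y, self.X, self.w, self.C, self.m = y, X, w, C, m
        self.n = len(y)
        # flat indices for sparse assembly of Z' D^-1 Z (Z has exactly two
        # ones per row, at the dyad's two members)
        self._flat = [C[:, t1] * m + C[:, t2] for t1 in (0, 1) for t2 in (0, 1)]
        self.rho_bounds = _rho_bounds(C, m)

    def _zt(self, mat: np.ndarray) -> np.ndarray:
        """Z' @ mat for (n, k) mat, via bincount."""
        m, C = self.m, self.C
        out = np.empty((m, mat.shape[1]))
        for j in range(mat.shape[1]):
            out[:, j] = (
                np.bincount(C[:, 0], weights=mat[:, j], minlength=m)
                + np.bincount(C[:, 1], weights=mat[:, j], minlength=m)
            )
        return out

    def eval(self, su2: float, rho: float, se2: float, reml: bool):
        """Negative log-likelihood (up to no constant) with beta profiled
        out by GLS, using the Woodbury identity on
        V = diag(d) + c ZZ', d = su2 (1-2 rho) + se2/w, c = su2 rho."""
        y, X, w, C, m = self.y, self.X, self.w, self.C, self.m
        n, p = X.shape
        d = su2 * (1.0 - 2.0 * rho) + se2 / w
        if np.min(d) <= 1e-12:
            return None
        c = su2 * rho
        Xy = np.column_stack([X, y])
        Dinv_Xy = Xy / d[:, None]
        if abs(c) > 1e-13:
            dinv = 1.0 / d
            S = np.zeros(m * m)
            for idx in self._flat:
                S += np.bincount(idx, weights=dinv, minlength=m * m)
            B = c * S.reshape(m, m)
            B[np.diag_indices(m)] += 1.0
            sign, logdetB = np.linalg.slogdet(B)
            if sign <= 0:
                return None
            t = self._zt(Dinv_Xy)
            u = np.linalg.solve(B, t)
            Vinv_Xy = Dinv_Xy - (c * (u[C[:, 0]] + u[C[:, 1]])) / d[:, None]
            logdetV = float(np.sum(np.log(d))) + logdetB
        else:
            Vinv_Xy = Dinv_Xy
            logdetV = float(np.sum(np.log(d)))
        XtVi = Xy.T @ Vinv_Xy  # (p+1, p+1): [[X'ViX, X'Viy],[y'ViX, y'Viy]]
        XtViX = XtVi[:p, :p]
        XtViy = XtVi[:p, p]
        ytViy = XtVi[p, p]
        try:
            cf = cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return None
        beta = cho_solve(cf, XtViy)
        quad = ytViy - XtViy @ beta
        if quad < 0:
            quad = 0.0
        nll = 0.5 * (n * np.log(2 * np.pi) + logdetV + quad)
        if reml:
            nll += 0.5 * float(np.linalg.slogdet(XtViX)[1])
        cov_beta = cho_solve(cf, np.eye(p))
        return nll, beta, cov_beta


def _fit_lmm_core(y, X, w, C, m, include_random=True):
    prob = _LmmProblem(y, X, w, C, m)
    n, p = X.shape

    if not include_random or prob.rho_bounds == (0.0, 0.0):
        # sigma_u^2 = 0: weighted least squares closed form
        XtWX = (X * w[:, None]).T @ X
        beta = np.linalg.solve(XtWX, (X * w[:, None]).T @ y)
        r = y - X @ beta
        se2 = float(np.sum(w * r * r) / n)
        nll_ml = 0.5 * (
            n * np.log(2 * np.pi) + np.sum(np.log(se2 / w)) + np.sum(w * r * r) / se2
        )
        se2_reml = float(np.sum(w * r * r) / (n - p))
        nll_reml = 0.5 * (
            n * np.log(2 * np.pi)
            + np.sum(np.log(se2_reml / w))
            + np.sum(w * r * r) / se2_reml
            + np.linalg.slogdet(XtWX / se2_reml)[1]
        )
        cov = np.linalg.inv(XtWX) * se2_reml
        return dict(
            beta=beta, se=np.sqrt(np.diag(cov)), sigma_u2=0.0, rho=0.0,
            sigma_e2=se2_reml, loglik=-nll_ml, loglik_reml=-nll_reml,
            converged=True, rho_bounds=prob.rho_bounds,
        )

    lo, hi = prob.rho_bounds
    var0 = float(np.var(y)) if np.var(y) > 0 else 1.0

    def unpack(t):
        su2 = np.exp(np.clip(t[0], -25, 25))
        rho = lo + (hi - lo) * expit(t[1])
        se2 = np.exp(np.clip(t[2], -25, 25))
        return su2, rho, se2

    def make_obj(reml):
        def obj(t):
            res = prob.eval(*unpack(t), reml=reml)
            return 1e10 if res is None else res[0]
        return obj

    x0 = np.array([np.log(var0 / 2), 0.0, np.log(var0 / 2)])
    opt_ml = optimize.minimize(
        make_obj(False), x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    opt_reml = optimize.minimize(
        make_obj(True), opt_ml.x, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    su2, rho, se2 = unpack(opt_reml.x)
    nll_reml, beta, cov_beta = prob.eval(su2, rho, se2, reml=True)
    nll_ml = prob.eval(*unpack(opt_ml.x), reml=False)[0]
    return dict(
        beta=beta, se=np.sqrt(np.diag(cov_beta)), sigma_u2=float(su2),
        rho=float(rho), sigma_e2=float(se2), loglik=-float(nll_ml),
        loglik_reml=-float(nll_reml),
        converged=bool(opt_ml.success and opt_reml.success),
        rho_bounds=(lo, hi),
    )


def fit_facial_distance_lmm(
    table: pd.DataFrame,
    design: Design,
    include_random: bool = True,
) -> LmmFit:
    """Fit the Gaussian facial-distance LMM with the diallel random
    effect and heteroscedastic residuals ``sigma_e^2 / w_d``.

    ``table`` must carry ``id_a``/``id_b`` (for the share-one-individual
    structure) and ``design`` the response, model matrix and prior
    weights. Both the ML (reported as ``loglik``, for LRTs) and REML
    (reported variance components and estimates) solutions are computed.
    With ``include_random=False`` the fit reduces to weighted least
    squares (the sigma_u^2 = 0 path).
    """
    if design.weights is None:
        raise ValueError("facial-distance LMM requires prior weights")
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise ValueError("singular design matrix")
    C, m = _member_codes(table)
    res = _fit_lmm_core(
        design.y, design.X, design.weights, C, m, include_random=include_random
    )
    return LmmFit(
        names=list(design.names),
        beta=res["beta"], se=res["se"], sigma_u2=res["sigma_u2"],
        rho=res["rho"], sigma_e2=res["sigma_e2"], loglik=res["loglik"],
        loglik_reml=res["loglik_reml"], converged=res["converged"],
        n=len(design.y), rho_bounds=res["rho_bounds"],
        y_digest=_digest(design.y),
    )


def residual_facial_distance(dyad_distances: pd.DataFrame) -> pd.DataFrame:
    """Residualize facial distance on (standardized) mean age distance.

    Fits the LMM of ``mean_distance`` on standardized
    ``mean_age_distance`` with the diallel random effect and picture-pair
    prior weights, and returns the table with a
    ``facial_distance_residual`` column holding the *marginal* residuals
    ``y - X beta_hat`` (fixed effects only, so the dyad-level resemblance
    signal is not absorbed by the dyad random effect).
    """
    if len(dyad_distances) < 3:
        raise ValueError("need at least 3 dyads to residualize")
    spec = ModelSpec(
        response="mean_distance",
        continuous=("mean_age_distance",),
        weights="n_picture_pairs",
    )
    design = build_design(dyad_distances, spec)
    fit = fit_facial_distance_lmm(dyad_distances, design)
    out = dyad_distances.copy()
    out["facial_distance_residual"] = design.y - design.X @ fit.beta
    return out


# ---------------------------------------------------------------------------
# negative-binomial GLMM (Laplace approximation)
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma_a2: tuple[float, ...]
    nb_shape: float
    loglik: float
    converged: bool
    n: int
    random_kind: Optional[str]
    y_digest: str
    trace: list[float] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {
                "predictor": self.names,
                "estimate": self.beta,
                "se": self.se,
                "wald_chi2": z**2,
                "p": stats.chi2.sf(z**2, 1),
            }
        )


def _nb_const(y, shape):
    return float(
        np.sum(gammaln(y + shape) - gammaln(shape) - gammaln(y + 1))
        + len(y) * shape * np.log(shape)
    )


class _GlmmProblem:
    """Laplace-approximated NB GLMM with beta profiled at the joint
    penalized mode (the random-effect integral is the Laplace part; the
    profile uses the joint (beta, a) Newton solution)."""

    def __init__(self, y, X, off, blocks):
        self.y = y.astype(float)
        self.X = X
        self.off = off if off is not None else np.zeros(len(y))
        self.blocks = blocks  # list of (codes (n, arity), n_levels)
        self.n, self.p = X.shape
        sizes = [m for _, m in blocks]
        self.M = int(sum(sizes))
        offs, acc = [], 0
        cols = []
        for (codes, m) in blocks:
            cols.append(codes + acc)
            offs.append(acc)
            acc += m
        self.C = np.hstack(cols) if cols else np.zeros((self.n, 0), int)
        self.t = self.C.shape[1]
        self.block_of = np.concatenate(
            [np.full(m, b) for b, (_, m) in enumerate(blocks)]
        ) if blocks else np.zeros(0, int)
        # flattened index for H_aa assembly
        if self.t:
            self.flatHidx = [
                self.C[:, t1] * self.M + self.C[:, t2]
                for t1 in range(self.t) for t2 in range(self.t)
            ]
        self.theta = np.zeros(self.p + self.M)

    def _eta(self, theta):
        eta = self.off + self.X @ theta[: self.p]
        if self.M:
            a = theta[self.p:]
            for t in range(self.t):
                eta = eta + a[self.C[:, t]]
        return eta

    def _f(self, eta, shape):
        # NB log-likelihood without the shape-only constant terms
        return float(self.y @ eta - (self.y + shape) @ np.log(shape + np.exp(eta)))

    def _penalty(self, theta, prec):
        if not self.M:
            return 0.0
        a = theta[self.p:]
        return 0.5 * float(a @ (prec * a))

    def joint_mode(self, sig2_blocks, shape, max_iter=60, tol=1e-9):
        prec = (1.0 / np.asarray(sig2_blocks)[self.block_of]
                if self.M else np.zeros(0))
        theta = self.theta.copy()
        eta = np.clip(self._eta(theta), -30, 30)
        obj = self._f(eta, shape) - self._penalty(theta, prec)
        X, y, n, p, M = self.X, self.y, self.n, self.p, self.M
        for _ in range(max_iter):
            mu = np.exp(eta)
            u = y - mu * (y + shape) / (mu + shape)
            ww = (y + shape) * shape * mu / (mu + shape) ** 2
            ww = np.maximum(ww, 1e-10)
            g = np.empty(p + M)
            g[:p] = X.T @ u
            H = np.empty((p + M, p + M))
            Xw = X * ww[:, None]
            H[:p, :p] = Xw.T @ X
            if M:
                a = theta[p:]
                ua = np.zeros(M)
                for t in range(self.t):
                    ua += np.bincount(self.C[:, t], weights=u, minlength=M)
                g[p:] = ua - prec * a
                XwZ = np.zeros((p, M))
                for t in range(self.t):
                    for j in range(p):
                        XwZ[j] += np.bincount(
                            self.C[:, t], weights=Xw[:, j], minlength=M
                        )
                H[:p, p:] = XwZ
                H[p:, :p] = XwZ.T
                Haa = np.zeros(M * M)
                for idx in self.flatHidx:
                    Haa += np.bincount(idx, weights=ww, minlength=M * M)
                Haa = Haa.reshape(M, M)
                Haa[np.diag_indices(M)] += prec
                H[p:, p:] = Haa
            try:
                cf = cho_factor(H)
            except np.linalg.LinAlgError:
                H[np.diag_indices(p + M)] += 1e-6
                cf = cho_factor(H)
            step = cho_solve(cf, g)
            lam = 1.0
            for _ls in range(30):
                cand = theta + lam * step
                eta_c = np.clip(self._eta(cand), -30, 30)
                obj_c = self._f(eta_c, shape) - self._penalty(cand, prec)
                if obj_c >= obj - 1e-12:
                    break
                lam *= 0.5
            improved = obj_c - obj
            theta, eta, obj = cand, eta_c, obj_c
            if abs(improved) < tol:
                break
        self.theta = theta
        # pieces for the Laplace correction and Wald SEs
        mu = np.exp(eta)
        ww = np.maximum((y + shape) * shape * mu / (mu + shape) ** 2, 1e-10)
        return theta, eta, obj, ww, prec

    def laplace(self, sig2_blocks, shape):
        theta, eta, obj, ww, prec = self.joint_mode(sig2_blocks, shape)
        ll = self._f(eta, shape) + _nb_const(self.y, shape)
        if self.M:
            a = theta[self.p:]
            M = self.M
            Haa = np.zeros(M * M)
            for idx in self.flatHidx:
                Haa += np.bincount(idx, weights=ww, minlength=M * M)
            Haa = Haa.reshape(M, M)
            Haa[np.diag_indices(M)] += prec
            sign, logdetH = np.linalg.slogdet(Haa)
            if sign <= 0:
                return -np.inf
            ll += (
                -0.5 * float(np.sum(np.log(np.asarray(sig2_blocks)[self.block_of])))
                - 0.5 * float(a @ (prec * a))
                - 0.5 * logdetH
            )
        return float(ll)

    def wald_cov(self, sig2_blocks, shape):
        _, eta, _, ww, prec = self.joint_mode(sig2_blocks, shape)
        X, p, M = self.X, self.p, self.M
        Xw = X * ww[:, None]
        I_bb = Xw.T @ X
        if M:
            XwZ = np.zeros((p, M))
            for t in range(self.t):
                for j in range(p):
                    XwZ[j] += np.bincount(
                        self.C[:, t], weights=Xw[:, j], minlength=M
                    )
            Haa = np.zeros(M * M)
            for idx in self.flatHidx:
                Haa += np.bincount(idx, weights=ww, minlength=M * M)
            Haa = Haa.reshape(M, M)
            Haa[np.diag_indices(M)] += prec
            cf = cho_factor(Haa)
            I_bb = I_bb - XwZ @ cho_solve(cf, XwZ.T)
        return np.linalg.inv(I_bb)


def fit_association_glmm(
    table: pd.DataFrame,
    design: Design,
    random_spec: Optional[str] = "gca",
    fix_shape: Optional[float] = None,
    fix_sigma_a2: Optional[float] = None,
) -> GlmmFit:
    """Fit the NB log-link association GLMM by Laplace approximation.

    ``random_spec``: ``"gca"`` for symmetric additive individual effects
    (one variance over the union of ``id_a``/``id_b`` — infant-infant,
    mother-mother); ``"crossed"`` for two independent individual effects
    with separate variances (``id_a`` = mothers, ``id_b`` = infants);
    ``None`` for a plain NB GLM. The offset (log total scans) enters with
    fixed coefficient 1. ``fix_shape`` / ``fix_sigma_a2`` pin those
    parameters (used by oracle equivalence checks).

    Non-convergence is flagged on the returned fit, never silent.
    """
    y = design.y
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response counts must be nonnegative integers")
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise ValueError("singular design matrix")

    if random_spec == "gca":
        C, m = _member_codes(table)
        blocks = [(C, m)]
    elif random_spec == "crossed":
        ca, ua = pd.factorize(table["id_a"])
        cb, ub = pd.factorize(table["id_b"])
        blocks = [(ca[:, None], len(ua)), (cb[:, None], len(ub))]
    elif random_spec is None:
        blocks = []
    else:
        raise ValueError(f"unknown random_spec {random_spec!r}")

    prob = _GlmmProblem(y, design.X, design.offset_log, blocks)
    n_sig = len(blocks) if fix_sigma_a2 is None else 0
    est_shape = fix_shape is None
    trace: list[float] = []

    def unpack(psi):
        k = 0
        if fix_sigma_a2 is not None:
            sig2 = [fix_sigma_a2] * len(blocks)
        else:
            sig2 = [float(np.exp(np.clip(v, -12, 6))) for v in psi[:n_sig]]
            k = n_sig
        shape = (float(np.exp(np.clip(psi[k], -6, 16))) if est_shape
                 else float(fix_shape))
        return sig2, shape

    def obj(psi):
        sig2, shape = unpack(psi)
        ll = prob.laplace(sig2, shape)
        val = 1e10 if not np.isfinite(ll) else -ll
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    n_outer = n_sig + (1 if est_shape else 0)
    if n_outer:
        # start from the best of a coarse shape grid: a poor dispersion
        # start can send the simplex up a variance ridge
        if est_shape:
            candidates = [
                np.concatenate([np.full(n_sig, np.log(0.25)), [lk]])
                for lk in np.log([0.5, 1.0, 2.5, 6.0, 15.0])
            ]
            psi0 = min(candidates, key=obj)
        else:
            psi0 = np.full(n_sig, np.log(0.25))
        # warm-started inner solves make the objective very slightly
        # history-dependent, so the outer tolerances stay modest; a
        # restart from the first optimum guards against premature
        # simplex collapse
        opt = optimize.minimize(
            obj, psi0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 500},
        )
        opt2 = optimize.minimize(
            obj, opt.x, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 500},
        )
        # converged if either pass terminated cleanly, or the restart
        # found essentially nothing better (objective plateau)
        converged = bool(opt.success or opt2.success
                         or abs(opt2.fun - opt.fun) < 1e-3)
        if opt2.fun <= opt.fun:
            opt = opt2
        sig2, shape = unpack(opt.x)
        ll = prob.laplace(sig2, shape)
    else:
        sig2, shape = unpack(np.zeros(1))
        ll = prob.laplace(sig2, shape)
        converged = True
    if not converged:
        logger.warning("NB GLMM outer optimizer did not converge")

    cov = prob.wald_cov(sig2, shape)
    beta = prob.theta[: prob.p].copy()
    return GlmmFit(
        names=list(design.names),
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma_a2=tuple(float(s) for s in sig2) if blocks else (),
        nb_shape=float(shape),
        loglik=float(ll),
        converged=converged,
        n=len(y),
        random_kind=random_spec,
        y_digest=_digest(y),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test, VIF, descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    chi2: float
    df: int
    p_value: float


def lrt(full, reduced) -> LrtResult:
    """Likelihood-ratio test of nested ML fits.

    Requires the reduced model's terms to be a subset of the full
    model's, fitted on identical data with the same random structure;
    chi-square is ``2 (ll_full - ll_reduced)`` clipped at 0 with df the
    difference in fixed-effect count.
    """
    for f in (full, reduced):
        if not hasattr(f, "loglik") or not hasattr(f, "names"):
            raise ValueError("lrt expects fitted model objects")
    if type(full) is not type(reduced):
        raise ValueError("cannot compare fits of different model families")
    if full.n != reduced.n or full.y_digest != reduced.y_digest:
        raise ValueError("models were fitted on different data")
    if getattr(full, "random_kind", None) != getattr(reduced, "random_kind", None):
        raise ValueError("models have different random-effect structures")
    if not set(reduced.names).issubset(full.names):
        raise ValueError("reduced model terms are not a subset of the full model")
    df = len(full.names) - len(reduced.names)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LrtResult(chi2=chi2, df=df, p_value=p)


def vif(design, names: Optional[Sequence[str]] = None) -> dict[str, float]:
    """Variance inflation factors, ``1 / (1 - R_k^2)`` from regressing
    each predictor on all others (with intercept). Perfect collinearity
    is reported as ``inf``, not an error."""
    if isinstance(design, Design):
        keep = [i for i, nm in enumerate(design.names) if nm != "intercept"]
        X = design.X[:, keep]
        names = [design.names[i] for i in keep]
    else:
        X = np.asarray(design, dtype=float)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for j in range(k):
        target = X[:, j]
        others = np.column_stack(
            [np.ones(n)] + [X[:, i] for i in range(k) if i != j]
        )
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = np.sum((target - target.mean()) ** 2)
        if sst == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def association_correlation(
    infant_infant: pd.DataFrame,
    mother_infant: pd.DataFrame,
    mother_of: Mapping[str, str],
) -> tuple[float, float]:
    """Correlation between infant-infant association rates and the mean
    of the two corresponding mother-infant rates.

    The mother-infant table stores the mother in ``id_a`` and the infant
    in ``id_b``. Each infant-infant dyad (i, j) is matched to the mean
    rate of (mother(i), j) and (mother(j), i); unmatched dyads are
    skipped with a warning. Returns Pearson r and r^2 (variance
    explained).
    """
    mi_rate = {
        (ra, rb): c / t
        for ra, rb, c, t in zip(
            mother_infant["id_a"], mother_infant["id_b"],
            mother_infant["count"], mother_infant["total_scans"],
        )
    }
    xs, ys = [], []
    skipped = 0
    for row in infant_infant.itertuples():
        i, j = row.id_a, row.id_b
        k1, k2 = (mother_of.get(i), j), (mother_of.get(j), i)
        if k1 not in mi_rate or k2 not in mi_rate:
            skipped += 1
            continue
        xs.append(row.count / row.total_scans)
        ys.append(0.5 * (mi_rate[k1] + mi_rate[k2]))
    if skipped:
        warnings.warn(f"{skipped} infant dyads had no matching mother-infant rates")
    if len(xs) < 3:
        raise ValueError("too few matched dyads for a correlation")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, r * r


def directionality_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Percentage of events initiated by the infant, per behaviour.

    Accepts the aggregated event table (one row per dyad and behaviour
    with ``n_events`` and ``n_infant_initiated``); dyads with zero events
    contribute to neither the percentage nor the dyad count.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    ev = events[events["n_events"] > 0]
    if len(ev) == 0:
        raise ValueError("no dyads with recorded events")
    rows = []
    for behavior, grp in ev.groupby("behavior"):
        tot = int(grp["n_events"].sum())
        init = int(grp["n_infant_initiated"].sum())
        rows.append(
            {
                "behavior": behavior,
                "pct_infant_initiated": 100.0 * init / tot,
                "n_events": tot,
                "n_dyads": len(grp),
            }
        )
    return pd.DataFrame(rows)


def filter_dyads(
    table: pd.DataFrame,
    min_total_scans: int = 5,
    min_offset: Optional[float] = None,
    offset_col: str = "total_scans",
) -> pd.DataFrame:
    """Dyad eligibility filter (e.g. at least 5 scans per dyad for the
    association models, or a minimum observation time for grooming)."""
    thr = min_offset if min_offset is not None else min_total_scans
    return table[table[offset_col] >= thr].reset_index(drop=True)
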