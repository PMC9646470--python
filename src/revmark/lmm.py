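"""Weighted random-intercept linear mixed models with Satterthwaite inference.

Per gene, the model is

    y = X beta + Z b + eps,   b_p ~ N(0, tau^2),   eps_i ~ N(0, sigma^2 / w_i),

with one random intercept per patient and fixed, known precision weights
``w_i`` carried over from the mean-variance trend.  Estimation is REML with
``sigma^2`` profiled out, leaving a one-dimensional search over the variance
ratio ``theta = tau^2 / sigma^2``.  All per-gene quantities reduce, via the
Woodbury identity on the block-diagonal covariance, to per-patient weighted
sums, so thousands of genes are fitted simultaneously with array operations.

Inference on a fixed effect uses the Satterthwaite approximation

    df = 2 * (se^2)^2 / Var(se^2),

with ``Var(se^2)`` from the delta method: the gradient of ``se^2`` with
respect to ``(tau^2, sigma^2)`` combined with the inverse observed
information of the REML log-likelihood.  Both the gradient and the observed
information are computed in closed form (no finite differences), so the
balanced-pairs limit reproduces the paired t-test to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Model",
    "DesignMatrix",
    "LMMFit",
    "build_design",
    "fit_lmm_reml",
    "satterthwaite_test",
    "fit_all_genes",
]

_LOG2PI = np.log(2.0 * np.pi)

#: upper bound of the variance-ratio search interval (weights are
#: normalised to mean one internally, so theta is on a natural scale)
THETA_MAX = 1e4
#: variance ratios below this are treated as the tau^2 = 0 boundary
BOUNDARY_EPS = 1e-10


class Model(str, Enum):
    """The three per-gene regression designs."""

    CBT = "cbt"
    CTG = "ctg"
    RESPONSE = "response"


@dataclass
class DesignMatrix:
    """Fixed-effect design plus the patient grouping for the random intercept.

    ``coef_index`` marks the covariate of interest (the timepoint indicator
    for the therapy model, the repeat length or the response score
    otherwise).
    """

    matrix: np.ndarray            # (n_samples, p)
    colnames: list[str]
    groups: np.ndarray            # integer patient codes, one per row
    sample_ids: list[str]
    coef_index: int

    @property
    def n_groups(self) -> int:
        return int(len(np.unique(self.groups)))


@dataclass
class LMMFit:
    """A single-gene REML fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    reml_loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    n_groups: int
    # retained so that Satterthwaite df can be computed after the fact
    _engine: "_BatchedREML" = field(repr=False, default=None)
    _theta: float = field(repr=False, default=0.0)


def build_design(
    samples: pd.DataFrame,
    scores: pd.DataFrame | None,
    model: Model | str,
) -> DesignMatrix:
    """Build the fixed-effect design for one of the three gene models.

    ``samples`` needs columns ``sample_id``, ``patient_id``, ``timepoint``
    (values ``T0``/``T10M``) and, for the repeat-length model,
    ``ctg_length``.  ``scores`` (columns ``patient_id``,
    ``compound_response``) is required for the response model only.  The
    repeat length enters on a per-100-repeats scale so reported
    coefficients are directly "per 100 CTGs"; the response covariate is the
    patient's compound score on post-therapy rows and exactly zero at
    baseline, so its coefficient captures response-associated change.
    """
    model = Model(model)
    samples = samples.reset_index(drop=True)
    _validate_pairing(samples)

    cbt = (samples["timepoint"].to_numpy() == "T10M").astype(float)
    cols = [np.ones(len(samples)), cbt]
    names = ["intercept", "cbt"]

    if model is Model.CTG:
        ctg = samples["ctg_length"].to_numpy(dtype=float)
        _check_constant_within_patient(samples, "ctg_length")
        cols.append(ctg / 100.0)
        names.append("ctg_per100")
    elif model is Model.RESPONSE:
        if scores is None:
            raise ValueError("the response model requires compound response scores")
        lookup = dict(
            zip(scores["patient_id"].astype(str), scores["compound_response"])
        )
        missing = [
            p for p in samples["patient_id"].astype(str).unique() if p not in lookup
        ]
        if missing:
            raise ValueError(f"no compound response score for patient(s): {missing}")
        resp = np.array(
            [lookup[p] for p in samples["patient_id"].astype(str)], dtype=float
        )
        cols.append(resp * cbt)  # zero at baseline by construction
        names.append("response")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for model '{model.value}' "
            f"(columns {names}); check covariate variation"
        )
    codes = pd.Categorical(samples["patient_id"].astype(str)).codes.astype(np.int64)
    return DesignMatrix(
        matrix=X,
        colnames=names,
        groups=codes,
        sample_ids=list(samples["sample_id"].astype(str)),
        coef_index=len(names) - 1 if model is not Model.CBT else 1,
    )


def _validate_pairing(samples: pd.DataFrame) -> None:
    counts = samples.groupby(["patient_id", "timepoint"], observed=True).size()
    per_patient = counts.unstack(fill_value=0)
    for tp in ("T0", "T10M"):
        if tp not in per_patient.columns:
            raise ValueError(f"no samples at timepoint {tp}")
    bad = per_patient[(per_patient["T0"] != 1) | (per_patient["T10M"] != 1)]
    if len(bad):
        raise ValueError(f"unpaired patient(s): {list(bad.index.astype(str))}")


def _check_constant_within_patient(samples: pd.DataFrame, col: str) -> None:
    spread = samples.groupby("patient_id")[col].nunique()
    bad = spread[spread > 1]
    if len(bad):
        raise ValueError(f"{col} varies within patient(s): {list(bad.index)}")


class _BatchedREML:
    """Profiled REML for many genes sharing one design and grouping.

    Observations are re-ordered so that groups are contiguous; all
    per-group reductions use ``np.add.reduceat``.  With
    ``V(theta) = W^-1 + theta Z Z'`` the Woodbury identity gives

        V^-1 = W - W Z diag(c) Z' W,     c_p = theta / (1 + theta s_p),

    where ``s_p`` is the within-group weight sum, so every quantity below
    is a weighted segment sum.
    """

    def __init__(self, Y: np.ndarray, W: np.ndarray, X: np.ndarray, groups: np.ndarray):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        W = np.atleast_2d(np.asarray(W, dtype=float))
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        if Y.shape != W.shape:
            raise ValueError("y and weights must have identical shapes")
        if not (np.isfinite(Y).all() and np.isfinite(W).all()):
            raise ValueError("non-finite values in y or weights")
        if (W <= 0).any():
            raise ValueError("weights must be strictly positive")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient fixed-effect design")
        n, p = X.shape
        if Y.shape[1] != n or len(groups) != n:
            raise ValueError("y, design and grouping are misaligned")
        if n <= p + 1:
            raise ValueError("too few observations for the design")

        order = np.argsort(groups, kind="stable")
        self.order = order
        self.X = X[order]
        self.groups = groups[order]
        self.starts = np.flatnonzero(
            np.r_[True, self.groups[1:] != self.groups[:-1]]
        )
        self.q = len(self.starts)
        self.n, self.p = n, p

        # normalise weights to mean one per gene; sigma^2 is rescaled back
        self.w_scale = W.mean(axis=1)
        self.W = (W / self.w_scale[:, None])[:, order]
        self.Y = Y[:, order]

        # theta-independent pieces
        W_, Y_, X_ = self.W, self.Y, self.X
        self.WY = W_ * Y_
        self.S = np.add.reduceat(W_, self.starts, axis=1)           # (G, q)
        self.Gy = np.add.reduceat(self.WY, self.starts, axis=1)     # (G, q)
        WX = W_[:, :, None] * X_[None, :, :]
        self.GX = np.add.reduceat(WX, self.starts, axis=1)          # (G, q, p)
        self.XtWX = np.einsum("ni,gn,nj->gij", X_, W_, X_)          # (G, p, p)
        self.XtWy = np.einsum("gn,ni->gi", self.WY, X_)             # (G, p)
        self.yWy = (self.WY * Y_).sum(axis=1)                       # (G,)
        self.sumlogW = np.log(W_).sum(axis=1)                       # (G,)

    # -- profiled criterion -------------------------------------------------

    def _core(self, theta: np.ndarray):
        th = np.asarray(theta, dtype=float)[:, None]
        c = th / (1.0 + th * self.S)                                # (G, q)
        A = self.XtWX - np.einsum("gq,gqi,gqj->gij", c, self.GX, self.GX)
        b = self.XtWy - np.einsum("gq,gqi,gq->gi", c, self.GX, self.Gy)
        yy = self.yWy - (c * self.Gy**2).sum(axis=1)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        rss = yy - (b * beta).sum(axis=1)
        logdetV = -self.sumlogW + np.log1p(th * self.S).sum(axis=1)
        _, logdetA = np.linalg.slogdet(A)
        return c, A, beta, rss, logdetV, logdetA

    def profiled_loglik(self, theta: np.ndarray) -> np.ndarray:
        """REML log-likelihood at ``theta`` with sigma^2 profiled out."""
        _, _, _, rss, logdetV, logdetA = self._core(theta)
        npm = self.n - self.p
        rss = np.maximum(rss, 1e-300)
        return -0.5 * (
            npm * (_LOG2PI + 1.0 - np.log(npm))
            + npm * np.log(rss)
            + logdetV
            + logdetA
        )

    def profiled_score(self, theta: np.ndarray) -> np.ndarray:
        """Analytic derivative of the profiled REML log-likelihood in theta.

        Function-value-only searches stall at sqrt(machine-eps) accuracy in
        theta; a sign change of this score is bisected to machine
        precision, which the closed-form Satterthwaite df inherits.
        """
        c, A, beta, rss, _, _ = self._core(theta)
        th = np.asarray(theta, dtype=float)[:, None]
        onep = 1.0 + th * self.S
        npm = self.n - self.p

        d_logdetV = (self.S / onep).sum(axis=1)
        Ainv = np.linalg.inv(A)
        FV = self.GX / onep[:, :, None]                      # X' V^-1 Z columns
        d_logdetA = -np.einsum("gqi,gij,gqj->g", FV, Ainv, FV)

        E = self.Y - beta @ self.X.T
        segWE = np.add.reduceat(self.W * E, self.starts, axis=1)
        t_p = segWE / onep
        d_rss = -(t_p**2).sum(axis=1)
        return -0.5 * (d_logdetV + d_logdetA + npm * d_rss / np.maximum(rss, 1e-300))

    # -- optimisation -------------------------------------------------------

    def optimize(self, n_grid: int = 33, golden_iters: int = 80):
        """Global grid bracket followed by golden-section refinement.

        Returns ``theta_hat``, the profiled log-likelihood there, and a
        boundary mask for genes whose variance ratio is estimated at zero.
        """
        grid = np.r_[0.0, np.geomspace(1e-6, THETA_MAX, n_grid - 1)]
        G = self.Y.shape[0]
        vals = np.empty((len(grid), G))
        for i, t in enumerate(grid):
            vals[i] = self.profiled_loglik(np.full(G, t))
        best = vals.argmax(axis=0)
        lo = grid[np.maximum(best - 1, 0)]
        hi = grid[np.minimum(best + 1, len(grid) - 1)]

        log_mode = lo > 0
        ratio = np.where(log_mode, hi / np.where(lo > 0, lo, 1.0), 1.0)
        span = hi - lo

        def theta_of(t: np.ndarray) -> np.ndarray:
            return np.where(log_mode, lo * ratio**t, lo + t * span)

        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a = np.zeros(G)
        b = np.ones(G)
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = self.profiled_loglik(theta_of(x1))
        f2 = self.profiled_loglik(theta_of(x2))
        for _ in range(golden_iters):
            move_right = f1 < f2
            a = np.where(move_right, x1, a)
            b = np.where(move_right, b, x2)
            x1_new = np.where(move_right, x2, b - invphi * (b - a))
            x2_new = np.where(move_right, a + invphi * (b - a), x1)
            # one fresh evaluation per iteration; the other point is reused
            fresh = np.where(move_right, x2_new, x1_new)
            f_fresh = self.profiled_loglik(theta_of(fresh))
            f1, f2 = (
                np.where(move_right, f2, f_fresh),
                np.where(move_right, f_fresh, f1),
            )
            x1, x2 = x1_new, x2_new
        t_mid = 0.5 * (a + b)
        theta = theta_of(t_mid)

        # polish interior optima to machine precision: bisect the analytic
        # score on a small bracket around the golden-section point
        t_lo = theta_of(np.maximum(t_mid - 1e-4, 0.0))
        t_hi = theta_of(np.minimum(t_mid + 1e-4, 1.0))
        s_lo = self.profiled_score(t_lo)
        s_hi = self.profiled_score(t_hi)
        refine = (s_lo > 0) & (s_hi < 0) & (t_hi > t_lo)
        if refine.any():
            blo, bhi = t_lo.copy(), t_hi.copy()
            for _ in range(60):
                mid = 0.5 * (blo + bhi)
                smid = self.profiled_score(mid)
                go_up = smid > 0
                blo = np.where(refine & go_up, mid, blo)
                bhi = np.where(refine & ~go_up, mid, bhi)
            theta = np.where(refine, 0.5 * (blo + bhi), theta)
        ll = self.profiled_loglik(theta)

        # candidate comparison: exact boundary and the coarse-grid best
        ll0 = vals[0]
        at_boundary = ll0 + 1e-12 >= ll
        theta = np.where(at_boundary, 0.0, theta)
        ll = np.where(at_boundary, ll0, ll)
        grid_best = vals.max(axis=0)
        take_grid = grid_best > ll
        theta = np.where(take_grid, grid[best], theta)
        ll = np.where(take_grid, grid_best, ll)
        boundary = theta <= BOUNDARY_EPS
        return theta, ll, boundary

    # -- estimates at the optimum -------------------------------------------

    def estimates(self, theta: np.ndarray):
        """GLS estimates and variance components at ``theta``.

        ``sigma2`` is reported on the scale of the *original* weights.
        """
        c, A, beta, rss, logdetV, logdetA = self._core(theta)
        npm = self.n - self.p
        sigma2_norm = rss / npm
        Ainv = np.linalg.inv(A)
        cov_beta = Ainv * sigma2_norm[:, None, None]
        tau2 = theta * sigma2_norm
        loglik = -0.5 * (
            npm * (_LOG2PI + 1.0) + npm * np.log(sigma2_norm) + logdetV + logdetA
        )
        return {
            "beta": beta,
            "cov_beta": cov_beta,
            "sigma2_norm": sigma2_norm,
            "sigma2": sigma2_norm * self.w_scale,
            "tau2": tau2,
            "loglik": loglik,
            "A": A,
            "Ainv": Ainv,
            "c": c,
            "rss": rss,
        }

    # -- Satterthwaite ------------------------------------------------------

    def satterthwaite(self, theta: np.ndarray, j: int, boundary: np.ndarray):
        """Closed-form Satterthwaite df for coefficient ``j``.

        Gradient of ``se_j^2`` and the observed REML information are
        evaluated analytically in ``(tau^2, sigma^2)``; at the tau^2 = 0
        boundary the random intercept is dropped from the delta method,
        which recovers the weighted-least-squares residual df exactly.
        """
        est = self.estimates(theta)
        sigma2 = est["sigma2_norm"]                        # (G,)
        Ainv = est["Ainv"]                                 # (G, p, p)
        beta = est["beta"]
        c = est["c"]                                       # (G, q)
        th = np.asarray(theta)[:, None]
        S, GX, Gy = self.S, self.GX, self.Gy
        G = self.Y.shape[0]
        n, p, q = self.n, self.p, self.q
        s2 = sigma2[:, None]
        onep = 1.0 + th * S                                # (G, q)

        se2 = sigma2 * Ainv[:, j, j]

        # gradient of se_j^2 wrt (tau2, sigma2):
        #   M1 = X' Sigma^-1 Z Z' Sigma^-1 X,  M2 = X' Sigma^-1 W^-1 Sigma^-1 X
        #   g_k = [A_Sigma^-1 M_k A_Sigma^-1]_jj, A_Sigma^-1 = sigma2 * Ainv
        M1 = np.einsum("gq,gqi,gqj->gij", 1.0 / onep**2, GX, GX) / s2[:, :, None] ** 2
        M2 = (
            self.XtWX
            - np.einsum("gq,gqi,gqj->gij", 2.0 * c - c**2 * S, GX, GX)
        ) / s2[:, :, None] ** 2
        AinvS = Ainv * s2[:, :, None]                      # A_Sigma^-1
        g1 = np.einsum("gi,gij,gj->g", AinvS[:, j, :], M1, AinvS[:, :, j])
        g2 = np.einsum("gi,gij,gj->g", AinvS[:, j, :], M2, AinvS[:, :, j])

        # residual-side vectors: d = Sigma^-1 e with e = y - X beta
        E = self.Y - beta @ self.X.T                       # (G, n)
        WE = self.W * E
        segWE = np.add.reduceat(WE, self.starts, axis=1)   # (G, q)
        cseg = c * segWE
        d = (WE - self.W * np.repeat(cseg, np.diff(np.r_[self.starts, n]), axis=1)) / s2

        u1 = np.repeat(
            np.add.reduceat(d, self.starts, axis=1), np.diff(np.r_[self.starts, n]), axis=1
        )                                                  # Z Z' d
        u2 = d / self.W                                    # W^-1 d

        def quad_P(u, v):
            # u' P v with P = Sigma^-1 - Sigma^-1 X A_Sigma^-1 X' Sigma^-1
            Wu, Wv = self.W * u, self.W * v
            su = np.add.reduceat(Wu, self.starts, axis=1)
            sv = np.add.reduceat(Wv, self.starts, axis=1)
            uSv = ((Wu * v).sum(1) - (c * su * sv).sum(1)) / sigma2
            Xu = (np.einsum("gn,ni->gi", Wu, self.X) - np.einsum("gq,gqi->gi", c * su, GX)) / s2
            Xv = (np.einsum("gn,ni->gi", Wv, self.X) - np.einsum("gq,gqi->gi", c * sv, GX)) / s2
            corr = np.einsum("gi,gij,gj->g", Xu, AinvS, Xv)
            return uSv - corr

        Q11 = quad_P(u1, u1)
        Q12 = quad_P(u1, u2)
        Q22 = quad_P(u2, u2)

        # trace terms tr(P Sigma_k P Sigma_l) = T1 - 2 T2 + T3
        T1_11 = ((S / (sigma2[:, None] * onep)) ** 2).sum(1)
        T1_12 = (S / (onep**2)).sum(1) / sigma2**2
        T1_22 = (n - 2.0 * (c * S).sum(1) + (c**2 * S**2).sum(1)) / sigma2**2

        C11 = np.einsum("gq,gqi,gqj->gij", S / onep**3, GX, GX) / s2[:, :, None] ** 3
        C12 = np.einsum("gq,gqi,gqj->gij", 1.0 / onep**3, GX, GX) / s2[:, :, None] ** 3
        C22 = (
            self.XtWX
            - np.einsum("gq,gqi,gqj->gij", 2.0 * c - c**2 * S, GX, GX)
            - np.einsum("gq,gqi,gqj->gij", c / onep**2, GX, GX)
        ) / s2[:, :, None] ** 3

        def trA(Cm):
            return np.einsum("gij,gji->g", AinvS, Cm)

        T2_11, T2_12, T2_22 = trA(C11), trA(C12), trA(C22)

        def trAA(Mk, Ml):
            return np.einsum("gij,gjk,gkl,gli->g", AinvS, Mk, AinvS, Ml)

        T3_11, T3_12, T3_22 = trAA(M1, M1), trAA(M1, M2), trAA(M2, M2)

        tr11 = T1_11 - 2 * T2_11 + T3_11
        tr12 = T1_12 - 2 * T2_12 + T3_12
        tr22 = T1_22 - 2 * T2_22 + T3_22

        # observed information J_kl = y'P Sig_k P Sig_l P y - 0.5 tr(P Sig_k P Sig_l)
        J11 = Q11 - 0.5 * tr11
        J12 = Q12 - 0.5 * tr12
        J22 = Q22 - 0.5 * tr22

        detJ = J11 * J22 - J12**2
        var_full = np.full(G, np.nan)
        ok = (detJ > 0) & (J11 > 0) & (J22 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_full = (g1**2 * J22 - 2 * g1 * g2 * J12 + g2**2 * J11) / detJ
            var_sig_only = g2**2 / J22

        var = np.where(boundary | ~ok, var_sig_only, var_full)
        fallback = ~np.isfinite(var) | (var <= 0)
        df = np.where(fallback, float(n - p), 2.0 * se2**2 / np.where(var > 0, var, 1.0))
        df = np.minimum(np.maximum(df, 1e-8), 1e12)
        return se2, df, fallback


# -- public single-gene API ---------------------------------------------------


def fit_lmm_reml(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray | None = None,
) -> LMMFit:
    """Fit one weighted random-intercept model by profiled REML.

    ``X`` may be a :class:`DesignMatrix` (carrying its own grouping) or a
    plain array together with ``groups``.
    """
    if isinstance(X, DesignMatrix):
        groups = X.groups
        Xm = X.matrix
    else:
        Xm = np.asarray(X, dtype=float)
        if groups is None:
            raise ValueError("groups required when X is a plain array")
    eng = _BatchedREML(np.asarray(y, float)[None, :], np.asarray(weights, float)[None, :], Xm, groups)
    theta, _, boundary = eng.optimize()
    est = eng.estimates(theta)
    return LMMFit(
        beta=est["beta"][0],
        cov_beta=est["cov_beta"][0],
        sigma2=float(est["sigma2"][0]),
        tau2=float(est["tau2"][0]),
        reml_loglik=float(est["loglik"][0]),
        converged=bool(np.isfinite(est["loglik"][0])),
        boundary=bool(boundary[0]),
        n_obs=eng.n,
        n_groups=eng.q,
        _engine=eng,
        _theta=float(theta[0]),
    )


def satterthwaite_test(fit: LMMFit, coef_index: int):
    """t-statistic, Satterthwaite df and two-sided p for one coefficient."""
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    eng = fit._engine
    theta = np.array([fit._theta])
    boundary = np.array([fit.boundary])
    se2, df, _ = eng.satterthwaite(theta, coef_index, boundary)
    se = float(np.sqrt(se2[0]))
    t = float(fit.beta[coef_index] / se)
    p = float(2.0 * stats.t.sf(abs(t), df[0]))
    return t, float(df[0]), p


def fit_all_genes(
    expr,
    samples: pd.DataFrame,
    scores: pd.DataFrame | None,
    model: Model | str,
) -> pd.DataFrame:
    """Fit the chosen model for every gene and return a tidy result table.

    ``expr`` is a :class:`revmark.prep.WeightedExpression`; columns must
    match the sample sheet's ``sample_id`` order (verified, not assumed).
    Returns one row per gene with the covariate-of-interest estimate, its
    Satterthwaite test, BH-adjusted q-values and the fold change
    ``2**coef``.
    """
    from .discovery import bh_fdr  # local import to avoid a cycle

    design = build_design(samples, scores, model)
    if list(expr.sample_ids) != design.sample_ids:
        raise ValueError("expression columns and sample sheet are misaligned")

    eng = _BatchedREML(expr.logcpm, expr.weights, design.matrix, design.groups)
    theta, _, boundary = eng.optimize()
    est = eng.estimates(theta)
    j = design.coef_index
    se2, df, fallback = eng.satterthwaite(theta, j, boundary)

    coef = est["beta"][:, j]
    se = np.sqrt(se2)
    tval = coef / se
    converged = np.isfinite(est["loglik"]) & np.isfinite(se) & (se > 0)
    p = np.where(converged, 2.0 * stats.t.sf(np.abs(tval), df), np.nan)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[~converged] = np.nan

    out = pd.DataFrame(
        {
            "gene_id": list(expr.gene_ids),
            "coef": coef,
            "se": se,
            "t": tval,
            "df": df,
            "p": p,
            "q_fdr": bh_fdr(p),
            "fold_change": 2.0**coef,
            "tau2": est["tau2"],
            "sigma2": est["sigma2"],
            "boundary": boundary,
            "df_fallback": fallback,
            "converged": converged,
        }
    )
    return out
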