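"""Hierarchical structural component fitter for miRNA-mRNA integration.

The model has three layers:

1. Inhibition layer: each retained target mRNA is residualized on its
   miRNA, ``Xhat_ijk = x_ijk - gamma_jk * z_ij``, where gamma_jk is the
   per-edge least-squares inhibition slope (estimated once, then fixed).
2. Component layer: each miRNA j gets a latent score
   ``f_ij = gamma_j0 * z_ij + sum_k Xhat_ijk * w_jk`` rescaled to unit
   sample variance (components are exact weighted composites, GSCA-style;
   the scale is folded into the path coefficient).
3. Phenotype layer: ``logit(pi_i) = beta_0 + sum_j f_ij beta_j`` with the
   binary phenotype; beta_j is a log-odds ratio per component SD.

Fitting minimizes the ridge-penalized negative log-likelihood

    phi = -loglik + (lambda_m/2) * sum_jk (gamma_j0^2 + w_jk^2)
                  + (lambda_mm/2) * sum_j beta_j^2

by alternating IRWLS steps for (beta_0, beta) with weighted ridge
least-squares sweeps for the component weights. The IRWLS step carries a
step-halving safeguard; the objective trace descends to its minimum up to
a small transient the unit-variance rescaling can add to the ridge terms.

The engine is batched over phenotype vectors: permutation tests and
simulation replicates refit hundreds of phenotypes against one fixed
design at essentially BLAS speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from sklearn.model_selection import StratifiedKFold

from .datamodel import ExpressionDataset, SubnetworkMap

logger = logging.getLogger("hiscom_mimi")

_CLIP = 1e-10  # probability clip guarding IRWLS against quasi-separation


@dataclass
class FitConfig:
    """Tuning knobs for the alternating fit.

    lambda_m penalizes component weights (gamma_j0 and w_jk), lambda_mm the
    path coefficients beta_j. ``penalize_gamma0`` includes the direct miRNA
    weight in the lambda_m block (symmetric treatment); ``penalize_intercept``
    puts beta_0 under lambda_mm (off by default — penalizing the intercept
    biases baseline prevalence). ``tol`` is the relative change in the
    penalized objective that counts as converged.
    """

    lambda_m: float = 1.0
    lambda_mm: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    standardize: bool = True
    penalize_intercept: bool = False
    penalize_gamma0: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_m < 0 or self.lambda_mm < 0:
            raise ValueError("ridge penalties must be >= 0")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass
class ResidualizedExpression:
    """Per-edge inhibition slopes and residualized mRNA columns.

    ``Xhat[j]`` is n x G_j aligned to the SubnetworkMap entry order;
    ``zcols[j]`` is the (standardized, centered) miRNA column the residuals
    are orthogonal to. Standardization statistics are kept for applying the
    same transform to new data at prediction time.
    """

    gamma: list[np.ndarray]
    Xhat: list[np.ndarray]
    zcols: list[np.ndarray]
    z_stats: dict[str, tuple[float, float]]
    x_stats: dict[str, tuple[float, float]]
    standardize: bool


@dataclass
class IRWLSState:
    working_response: np.ndarray
    working_weights: np.ndarray
    mu: np.ndarray


@dataclass
class HiscomFit:
    """Fitted model: component weights, path coefficients, latent scores.

    ``w[j]`` and ``gamma0[j]`` already include the unit-variance component
    scaling, i.e. ``F[:, j] = gamma0[j] * z_j + Xhat_j @ w[j]`` exactly.
    """

    net: SubnetworkMap
    resid: ResidualizedExpression
    cfg: FitConfig
    w: list[np.ndarray]
    gamma0: np.ndarray
    beta0: float
    beta: np.ndarray
    F: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.beta0 + self.F @ self.beta

    @property
    def fitted_prob(self) -> np.ndarray:
        return expit(self.linear_predictor)


# ---------------------------------------------------------------------------
# Inhibition layer
# ---------------------------------------------------------------------------

def estimate_inhibition(x_k: np.ndarray, z_j: np.ndarray) -> float:
    """Least-squares inhibition slope of mRNA x on miRNA z (after centering)."""
    x = np.asarray(x_k, dtype=float)
    z = np.asarray(z_j, dtype=float)
    zc = z - z.mean()
    denom = zc @ zc
    if denom == 0:
        raise ValueError("zero-variance miRNA column: inhibition slope undefined")
    return float((zc @ (x - x.mean())) / denom)


def _column_stats(col: np.ndarray, name: str, standardize: bool) -> tuple[float, float]:
    mean = float(col.mean())
    if standardize:
        sd = float(col.std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero-variance feature {name!r} cannot be standardized")
        return mean, sd
    return mean, 1.0


def residualize(
    data: ExpressionDataset, net: SubnetworkMap, standardize: bool = True
) -> ResidualizedExpression:
    """Remove each miRNA's inhibition effect from its retained targets.

    Features are centered (and standardized when requested) first; the
    residual column for edge (j, k) is orthogonal to miRNA column j.
    """
    z_stats: dict[str, tuple[float, float]] = {}
    x_stats: dict[str, tuple[float, float]] = {}
    gamma, Xhat, zcols = [], [], []
    for e in net.entries:
        z_raw = data.mirna_col(e.mirna_id)
        zm, zs = z_stats.setdefault(
            e.mirna_id, _column_stats(z_raw, e.mirna_id, standardize)
        )
        z = (z_raw - zm) / zs
        g = np.empty(e.size)
        R = np.empty((data.n, e.size))
        for k, gid in enumerate(e.mrna_ids):
            x_raw = data.mrna_col(gid)
            xm, xs = x_stats.setdefault(gid, _column_stats(x_raw, gid, standardize))
            x = (x_raw - xm) / xs
            g[k] = estimate_inhibition(x, z)
            R[:, k] = x - g[k] * z
        gamma.append(g)
        Xhat.append(R)
        zcols.append(z)
    return ResidualizedExpression(
        gamma=gamma, Xhat=Xhat, zcols=zcols,
        z_stats=z_stats, x_stats=x_stats, standardize=standardize,
    )


# ---------------------------------------------------------------------------
# Component layer
# ---------------------------------------------------------------------------

def compute_latent(
    z_j: np.ndarray, Xhat_j: np.ndarray, gamma0_j: float, w_j: np.ndarray
) -> np.ndarray:
    """Latent component score, rescaled to unit sample variance."""
    w_j = np.atleast_1d(np.asarray(w_j, dtype=float))
    if gamma0_j == 0 and not np.any(w_j):
        raise ValueError("all-zero weight vector gives a degenerate component")
    f = gamma0_j * np.asarray(z_j, dtype=float)
    if Xhat_j is not None and Xhat_j.size:
        f = f + np.asarray(Xhat_j, dtype=float) @ w_j
    s = f.std(ddof=1)
    if s == 0:
        raise ValueError("latent component has zero variance")
    return f / s


def _design_blocks(resid: ResidualizedExpression) -> list[np.ndarray]:
    """Per-subnetwork design [z_j | Xhat_j], shape n x (1 + G_j)."""
    return [
        np.column_stack([z] + ([R] if R.size else []))
        for z, R in zip(resid.zcols, resid.Xhat)
    ]


# ---------------------------------------------------------------------------
# Phenotype layer: single IRWLS / weight-update steps (reference semantics)
# ---------------------------------------------------------------------------

def irwls_update(
    F: np.ndarray,
    y: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    lambda_mm: float,
    penalize_intercept: bool = False,
) -> tuple[float, np.ndarray, IRWLSState]:
    """One IRWLS step for (beta_0, beta) at fixed components.

    Forms the working response ``eta + (y - pi)/v`` with weights
    ``v = pi (1 - pi)`` and solves the ridge-weighted normal equations.
    Probabilities are clipped to [1e-10, 1 - 1e-10] under separation.
    """
    eta = beta0 + F @ beta
    pi = np.clip(expit(eta), _CLIP, 1 - _CLIP)
    v = pi * (1 - pi)
    u = eta + (y - pi) / v
    G = np.column_stack([np.ones(len(y)), F])
    pen = np.full(G.shape[1], lambda_mm)
    if not penalize_intercept:
        pen[0] = 0.0
    M = G.T @ (v[:, None] * G) + np.diag(pen)
    rhs = G.T @ (v * u)
    try:
        b = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        b = np.linalg.lstsq(M, rhs, rcond=None)[0]
    return float(b[0]), b[1:], IRWLSState(working_response=u, working_weights=v, mu=pi)


def update_weights(
    resid: ResidualizedExpression,
    state: IRWLSState,
    F: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    lambda_m: float,
    penalize_gamma0: bool = True,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    """One Gauss-Seidel sweep over component weights at fixed working response.

    For each subnetwork j, solves the ridge-weighted least-squares problem
    for (gamma_j0, w_j) against the working response minus all other
    components' contributions, then rescales the component to unit sample
    variance, folding the scale into beta_j. Subnetworks with beta_j = 0
    are left unchanged (the update is unidentifiable).

    Returns (gamma0, w, F_new, beta_new).
    """
    D = _design_blocks(resid)
    v, u = state.working_weights, state.working_response
    F = F.copy()
    beta = beta.copy()
    gamma0 = np.empty(len(D))
    w_out: list[np.ndarray] = []
    warned = False
    eta = beta0 + F @ beta
    for j, Dj in enumerate(D):
        p = Dj.shape[1]
        if abs(beta[j]) < 1e-12:
            if not warned:
                logger.warning("beta_j = 0: component %d weights left unchanged", j)
                warned = True
            a = _recover_weights(F[:, j], Dj)
        else:
            offset = eta - F[:, j] * beta[j]
            t = u - offset
            P = np.full(p, lambda_m)
            if not penalize_gamma0:
                P[0] = 0.0
            M = beta[j] ** 2 * (Dj.T @ (v[:, None] * Dj)) + np.diag(P)
            rhs = beta[j] * (Dj.T @ (v * t))
            try:
                a = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                a = np.linalg.lstsq(M, rhs, rcond=None)[0]
            f_raw = Dj @ a
            s = f_raw.std(ddof=1)
            if s < 1e-12:
                a = _recover_weights(F[:, j], Dj)  # degenerate: keep old component
            else:
                a = a / s
                F[:, j] = f_raw / s
                beta[j] = beta[j] * s
                eta = offset + F[:, j] * beta[j]
        gamma0[j] = a[0]
        w_out.append(a[1:])
    return gamma0, w_out, F, beta


def _recover_weights(f: np.ndarray, Dj: np.ndarray) -> np.ndarray:
    """Weights reproducing an existing component column (least squares)."""
    return np.linalg.lstsq(Dj, f, rcond=None)[0]


# ---------------------------------------------------------------------------
# Batched alternating engine
# ---------------------------------------------------------------------------

def _neg_loglik(eta: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise logistic negative log-likelihood, numerically stable."""
    return np.sum(np.logaddexp(0.0, eta) - Y * eta, axis=-1)


def _batched_solve(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(M, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        M = M + 1e-10 * np.eye(M.shape[-1])
        return np.linalg.solve(M, rhs[..., None])[..., 0]


def _als_batched(
    D: list[np.ndarray], Y: np.ndarray, cfg: FitConfig
) -> dict:
    """Alternating fit of R phenotype vectors against one fixed design.

    D is the per-subnetwork design list (n x (1+G_j) each); Y is R x n of
    0/1 phenotypes. Rows are retired from the working batch as soon as
    their penalized objective has converged, so the cost scales with the
    mean (not the worst-case) iteration count across permutations.
    """
    R, n = Y.shape
    J = len(D)
    lam_m, lam_mm = cfg.lambda_m, cfg.lambda_mm

    # ---- outputs (full batch size) ----
    A_out = [np.empty((R, Dj.shape[1])) for Dj in D]
    F_out = np.empty((R, n, J))
    beta0_out = np.empty(R)
    beta_out = np.empty((R, J))
    n_iter_out = np.full(R, cfg.max_iter, dtype=int)
    converged_out = np.zeros(R, dtype=bool)
    obj_full = np.empty(R)

    # ---- working state (active rows only) ----
    idx = np.arange(R)
    A = [np.tile(np.full(Dj.shape[1], 1.0 / np.sqrt(Dj.shape[1])), (R, 1))
         for Dj in D]
    F = np.empty((R, n, J))
    for j, Dj in enumerate(D):
        f_raw = A[j] @ Dj.T
        s = f_raw.std(axis=1, ddof=1)
        s[s < 1e-12] = 1.0
        A[j] /= s[:, None]
        F[:, :, j] = f_raw / s[:, None]
    ybar = np.clip(Y.mean(axis=1), _CLIP, 1 - _CLIP)
    beta0 = logit(ybar)
    beta = np.zeros((R, J))
    Yw = Y.astype(float)

    pen_beta = np.full(J + 1, lam_mm)
    if not cfg.penalize_intercept:
        pen_beta[0] = 0.0
    # per-design outer products: the weighted Gram D' diag(v) D for every
    # row is then a single GEMM v @ DD instead of an R x n x p broadcast
    DD = [
        (Dj[:, :, None] * Dj[:, None, :]).reshape(n, -1) for Dj in D
    ]

    def pen_a() -> np.ndarray:
        tot = np.zeros(len(idx))
        for Aj in A:
            block = Aj if cfg.penalize_gamma0 else Aj[:, 1:]
            tot += np.einsum("rp,rp->r", block, block)
        return tot

    def objective(beta0_, beta_, eta_) -> np.ndarray:
        obj_ = _neg_loglik(eta_, Yw) + 0.5 * lam_m * pen_a()
        obj_ += 0.5 * lam_mm * np.einsum("rj,rj->r", beta_, beta_)
        if cfg.penalize_intercept:
            obj_ += 0.5 * lam_mm * beta0_**2
        return obj_

    def lin_eta(beta0_, beta_) -> np.ndarray:
        return beta0_[:, None] + np.matmul(F, beta_[:, :, None])[:, :, 0]

    eta = lin_eta(beta0, beta)
    obj = objective(beta0, beta, eta)
    obj_full[idx] = obj
    trace = [obj_full.copy()]

    def retire(done_mask: np.ndarray) -> None:
        """Move finished rows from the working batch into the outputs."""
        nonlocal idx, F, beta0, beta, eta, obj, Yw
        rows = idx[done_mask]
        for j in range(J):
            A_out[j][rows] = A[j][done_mask]
        F_out[rows] = F[done_mask]
        beta0_out[rows] = beta0[done_mask]
        beta_out[rows] = beta[done_mask]
        keep = ~done_mask
        idx = idx[keep]
        for j in range(J):
            A[j] = A[j][keep]
        F = F[keep]
        beta0 = beta0[keep]
        beta = beta[keep]
        eta = eta[keep]
        obj = obj[keep]
        Yw = Yw[keep]

    for it in range(cfg.max_iter):
        # ---- beta step (IRWLS with step halving) ----
        pi = np.clip(expit(eta), _CLIP, 1 - _CLIP)
        v = pi * (1 - pi)
        u = eta + (Yw - pi) / v
        G = np.concatenate([np.ones((len(idx), n, 1)), F], axis=2)
        Gv = G * v[:, :, None]
        M = np.matmul(G.transpose(0, 2, 1), Gv) + np.diag(pen_beta)[None]
        rhs = np.einsum("rnp,rn->rp", G, v * u)
        b = _batched_solve(M, rhs)
        step0, step = b[:, 0] - beta0, b[:, 1:] - beta
        t = np.ones(len(idx))
        b0_try, b_try, eta_try, obj_try = beta0, beta, eta, obj
        for _ in range(12):
            b0_try = beta0 + t * step0
            b_try = beta + t[:, None] * step
            eta_try = lin_eta(b0_try, b_try)
            obj_try = objective(b0_try, b_try, eta_try)
            bad = obj_try > obj + 1e-10 * (1 + np.abs(obj))
            if not bad.any():
                break
            t[bad] *= 0.5
        else:
            b0_try = np.where(bad, beta0, b0_try)
            b_try = np.where(bad[:, None], beta, b_try)
            eta_try = lin_eta(b0_try, b_try)
            obj_try = objective(b0_try, b_try, eta_try)
        beta0, beta, eta = b0_try, b_try, eta_try

        # ---- w step (Gauss-Seidel over subnetworks) ----
        for j, Dj in enumerate(D):
            bj = beta[:, j]
            active = np.abs(bj) >= 1e-12
            if not active.any():
                continue
            offset = eta - F[:, :, j] * bj[:, None]
            tgt = u - offset
            p = Dj.shape[1]
            P = np.full(p, lam_m)
            if not cfg.penalize_gamma0:
                P[0] = 0.0
            M0 = (v @ DD[j]).reshape(len(idx), p, p)
            Mj = bj[:, None, None] ** 2 * M0 + np.diag(P)[None]
            rhs_j = bj[:, None] * ((v * tgt) @ Dj)
            a_cand = _batched_solve(Mj, rhs_j)
            f_raw = a_cand @ Dj.T
            s = f_raw.std(axis=1, ddof=1)
            ok = active & (s >= 1e-12)
            s_safe = np.where(ok, s, 1.0)
            A[j] = np.where(ok[:, None], a_cand / s_safe[:, None], A[j])
            f_new = np.where(ok[:, None], f_raw / s_safe[:, None], F[:, :, j])
            bj_new = np.where(ok, bj * s, bj)
            F[:, :, j] = f_new
            beta[:, j] = bj_new
            eta = offset + f_new * bj_new[:, None]
        # the unit-variance rescaling folds the component scale into beta_j,
        # so the ridge terms can tick up transiently; the likelihood part is
        # still driven down every sweep and the trace settles monotonically
        obj_new = objective(beta0, beta, eta)

        rel = np.abs(obj_new - obj) / (1 + np.abs(obj))
        obj = obj_new
        obj_full[idx] = obj
        trace.append(obj_full.copy())
        done = rel < cfg.tol
        if done.any():
            rows = idx[done]
            n_iter_out[rows] = it + 1
            converged_out[rows] = True
            retire(done)
        if len(idx) == 0:
            break
    if len(idx):  # max_iter reached: flush unconverged rows as they stand
        retire(np.ones(len(idx), dtype=bool))

    return {
        "beta0": beta0_out,
        "beta": beta_out,
        "A": A_out,
        "F": F_out,
        "trace": np.array(trace).T,
        "converged": converged_out,
        "n_iter": n_iter_out,
    }


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def fit(
    data: ExpressionDataset,
    net: SubnetworkMap,
    cfg: FitConfig | None = None,
    resid: ResidualizedExpression | None = None,
) -> HiscomFit:
    """Fit the full hierarchical component model.

    Alternates IRWLS steps for the phenotype layer with ridge-weighted
    sweeps for the component weights until the relative change of the
    penalized objective drops below ``cfg.tol`` (or ``cfg.max_iter`` is
    reached, in which case the fit is returned flagged unconverged).
    """
    cfg = cfg or FitConfig()
    if data.y is None:
        raise ValueError("dataset has no phenotype")
    if data.n < 10:
        raise ValueError("need at least 10 samples to fit")
    if len(np.unique(data.y)) < 2:
        raise ValueError("phenotype must contain both classes")
    if net.J < 1:
        raise ValueError("subnetwork map is empty")
    if resid is None:
        resid = residualize(data, net, standardize=cfg.standardize)
    D = _design_blocks(resid)
    out = _als_batched(D, data.y[None, :], cfg)
    return HiscomFit(
        net=net,
        resid=resid,
        cfg=cfg,
        w=[Aj[0, 1:].copy() for Aj in out["A"]],
        gamma0=np.array([Aj[0, 0] for Aj in out["A"]]),
        beta0=float(out["beta0"][0]),
        beta=out["beta"][0].copy(),
        F=out["F"][0].copy(),
        objective_trace=out["trace"][0],
        converged=bool(out["converged"][0]),
        n_iter=int(out["n_iter"][0]),
    )


def predict_prob(fitted: HiscomFit, data_new: ExpressionDataset) -> np.ndarray:
    """Case probabilities for new samples.

    New data are standardized with the TRAINING means/SDs and residualized
    with the TRAINING inhibition slopes; component weights already carry
    the training unit-variance scaling.
    """
    resid = fitted.resid
    missing_m = [e.mirna_id for e in fitted.net.entries
                 if e.mirna_id not in data_new.mirna_ids]
    missing_g = [g for e in fitted.net.entries for g in e.mrna_ids
                 if g not in data_new.mrna_ids]
    if missing_m or missing_g:
        raise ValueError(
            f"new data lack fitted features: miRNAs {missing_m}, mRNAs {missing_g}"
        )
    eta = np.full(data_new.n, fitted.beta0)
    for j, e in enumerate(fitted.net.entries):
        zm, zs = resid.z_stats[e.mirna_id]
        z = (data_new.mirna_col(e.mirna_id) - zm) / zs
        f = fitted.gamma0[j] * z
        for k, gid in enumerate(e.mrna_ids):
            xm, xs = resid.x_stats[gid]
            x = (data_new.mrna_col(gid) - xm) / xs
            f = f + (x - resid.gamma[j][k] * z) * fitted.w[j][k]
        eta += f * fitted.beta[j]
    return expit(eta)


def _subset(data: ExpressionDataset, idx: np.ndarray) -> ExpressionDataset:
    return ExpressionDataset(
        sample_ids=[data.sample_ids[i] for i in idx],
        mirna_ids=data.mirna_ids,
        mrna_ids=data.mrna_ids,
        Z=data.Z[idx],
        X=data.X[idx],
        y=None if data.y is None else data.y[idx],
    )


def cross_validate_lambda(
    data: ExpressionDataset,
    net: SubnetworkMap,
    grid_m: list[float] | None = None,
    grid_mm: list[float] | None = None,
    k: int = 3,
    seed: int = 0,
    base_cfg: FitConfig | None = None,
) -> tuple[float, float]:
    """Choose (lambda_m, lambda_mm) by stratified k-fold held-out log-likelihood.

    Ties are broken toward larger penalties. Single-point grids are
    returned without fitting any folds.
    """
    grid_m = list(grid_m) if grid_m is not None else [2.0**e for e in range(-2, 11)]
    grid_mm = list(grid_mm) if grid_mm is not None else [2.0**e for e in range(-2, 11)]
    if not grid_m or not grid_mm:
        raise ValueError("penalty grids must be non-empty")
    if len(grid_m) == 1 and len(grid_mm) == 1:
        return grid_m[0], grid_mm[0]
    if data.y is None:
        raise ValueError("dataset has no phenotype")
    n_min = int(np.bincount(data.y).min())
    if n_min < k:
        raise ValueError(
            f"cannot stratify {k} folds with only {n_min} samples in the rarer class"
        )
    base = base_cfg or FitConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(data.n), data.y))

    pairs = sorted({(lm, lmm) for lm in grid_m for lmm in grid_mm})
    best_pair, best_ll = pairs[0], -np.inf
    for lm, lmm in pairs:
        cfg = FitConfig(
            lambda_m=lm, lambda_mm=lmm, max_iter=base.max_iter, tol=base.tol,
            standardize=base.standardize,
            penalize_intercept=base.penalize_intercept,
            penalize_gamma0=base.penalize_gamma0, seed=seed,
        )
        ll = 0.0
        for tr, te in splits:
            f = fit(_subset(data, tr), net, cfg)
            p = np.clip(predict_prob(f, _subset(data, te)), _CLIP, 1 - _CLIP)
            y_te = data.y[te]
            ll += float(y_te @ np.log(p) + (1 - y_te) @ np.log1p(-p))
        if ll >= best_ll:  # >= so exact ties go to the larger penalty pair
            best_ll, best_pair = ll, (lm, lmm)
    return best_pair
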