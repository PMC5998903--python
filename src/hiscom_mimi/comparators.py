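"""Penalized logistic-regression baselines on the pooled miRNA + mRNA design.

The comparator model is ``logit(pi) = beta_0 + sum_j theta_j z_j +
sum_k rho_k x_k`` with a lasso, elastic-net (mixing weight alpha) or
group-lasso penalty; a group is one miRNA plus its retained target mRNAs,
weighted by sqrt(group size) under the standard Euclidean group norm.
mRNA columns enter raw (not residualized). The penalty strength delta is
tuned by stratified k-fold cross-validated deviance over a descending
warm-started path, then the model is refit on the full data.

All three penalties share one proximal-gradient (FISTA) solver, so
solutions carry exact zeros from the soft-threshold / block-threshold
proximal maps — "selected" means exactly nonzero, no epsilon rule.

The threshold-T rule calls a subnetwork selected when its miRNA
coefficient is nonzero and at least T of its mRNA coefficients are
nonzero; T is calibrated on null simulations to match a target FPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.model_selection import StratifiedKFold

from .datamodel import ExpressionDataset, SubnetworkMap

logger = logging.getLogger("hiscom_mimi")

PENALTY_KINDS = ("lasso", "elastic_net", "group_lasso")


@dataclass
class CompConfig:
    penalty_kind: str = "lasso"
    alpha_mix: float = 0.5
    cv_folds: int = 3
    delta_grid: list[float] | None = None
    n_deltas: int = 30
    delta_min_ratio: float = 1e-3
    tol: float = 1e-6
    max_iter: int = 5000
    path_stop_after: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty_kind not in PENALTY_KINDS:
            raise ValueError(f"penalty_kind must be one of {PENALTY_KINDS}")
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must lie in [0, 1]")
        if self.delta_grid is not None:
            dg = list(self.delta_grid)
            if any(d <= 0 for d in dg) or any(
                later >= earlier for later, earlier in zip(dg[1:], dg)
            ):
                raise ValueError("delta_grid must be positive and descending")
            self.delta_grid = dg


@dataclass
class CompFit:
    """Fitted comparator: coefficients, chosen penalty, selection counts."""

    net: SubnetworkMap
    cfg: CompConfig
    beta0: float
    theta: np.ndarray              # miRNA coefficients, net entry order
    features: pd.DataFrame         # feature_id, role, subnetwork_id, coef
    delta_chosen: float
    nonzero_sets: np.ndarray       # K_j per subnetwork
    col_stats: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    coef_std: np.ndarray = field(repr=False, default=None)

    @property
    def rho(self) -> pd.DataFrame:
        return self.features[self.features.role == "mRNA"]


@dataclass
class SelectionRule:
    T: int = 1
    require_mirna: bool = True

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("threshold T must be >= 0")


# ---------------------------------------------------------------------------
# Proximal-gradient solver (shared by all three penalties)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pg_objective(Xf, y, b, l1, l2, gw, gs, ge):
    n = Xf.shape[0]
    eta = Xf @ b
    val = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            val += e + np.log1p(np.exp(-e)) - y[i] * e
        else:
            val += np.log1p(np.exp(e)) - y[i] * e
    val /= n
    pen = 0.0
    ss_all = 0.0
    for g in range(gw.size):
        ss = 0.0
        for k in range(gs[g], ge[g]):
            ss += b[k] * b[k]
        pen += gw[g] * np.sqrt(ss)
        ss_all += ss
    return val + l1 * pen + l2 * ss_all


@njit(cache=True)
def _pg_prox(z, t, l1, l2, gw, gs, ge):
    b = z.copy()
    shrink = 1.0 / (1.0 + 2.0 * t * l2)
    for g in range(gw.size):
        ss = 0.0
        for k in range(gs[g], ge[g]):
            ss += z[k] * z[k]
        nrm = np.sqrt(ss)
        thr = t * l1 * gw[g]
        if nrm <= thr:
            for k in range(gs[g], ge[g]):
                b[k] = 0.0
        else:
            scale = (1.0 - thr / nrm) * shrink
            for k in range(gs[g], ge[g]):
                b[k] = z[k] * scale
    return b


@njit(cache=True)
def _pg_grad(Xf, y, b):
    n = Xf.shape[0]
    eta = Xf @ b
    p = 1.0 / (1.0 + np.exp(-eta))
    return Xf.T @ (p - y) / n


@njit(cache=True)
def _fista(Xf, y, L, l1, l2, gw, gs, ge, b_init, max_iter, tol):
    """FISTA with function-value restart; intercept is column 0, unpenalized."""
    b = b_init.copy()
    z = b.copy()
    tk = 1.0
    step = 1.0 / L
    obj = _pg_objective(Xf, y, b, l1, l2, gw, gs, ge)
    for _ in range(max_iter):
        g = _pg_grad(Xf, y, z)
        b_new = _pg_prox(z - step * g, step, l1, l2, gw, gs, ge)
        obj_new = _pg_objective(Xf, y, b_new, l1, l2, gw, gs, ge)
        if obj_new > obj + 1e-14:
            g = _pg_grad(Xf, y, b)  # momentum restart: plain ISTA step
            b_new = _pg_prox(b - step * g, step, l1, l2, gw, gs, ge)
            obj_new = _pg_objective(Xf, y, b_new, l1, l2, gw, gs, ge)
            tk = 1.0
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        diff = 0.0
        for k in range(b.size):
            d = abs(b_new[k] - b[k])
            if d > diff:
                diff = d
        z = b_new + ((tk - 1.0) / tk_new) * (b_new - b)
        b = b_new
        tk = tk_new
        obj = obj_new
        if diff < tol:
            break
    return b


def _lipschitz(Xf: np.ndarray) -> float:
    s = np.linalg.svd(Xf, compute_uv=False)[0]
    return float(s * s / (4.0 * Xf.shape[0]) + 1e-12)


def _penalty_mults(cfg: CompConfig, delta: float) -> tuple[float, float]:
    if cfg.penalty_kind == "lasso":
        return delta, 0.0
    if cfg.penalty_kind == "elastic_net":
        return delta * cfg.alpha_mix, delta * (1.0 - cfg.alpha_mix)
    return delta, 0.0  # group_lasso


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _assemble_design(
    data: ExpressionDataset, net: SubnetworkMap, kind: str
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled design plus group structure for the penalty.

    lasso/EN: one column per miRNA and per unique retained mRNA; every
    column is its own (unit-weight) group. Group lasso: columns ordered
    group-by-group (miRNA then its mRNAs, one column per edge so groups
    partition even when an mRNA belongs to several subnetworks), weighted
    sqrt(group size).
    Returns (X, feature frame, group_weights, group_start, group_end);
    start/end index into the intercept-augmented design (column 0 = 1).
    """
    cols: list[np.ndarray] = []
    rows: list[dict] = []
    gw: list[float] = []
    gs: list[int] = []
    ge: list[int] = []
    if kind == "group_lasso":
        pos = 1
        for e in net.entries:
            size = 1 + e.size
            gs.append(pos)
            ge.append(pos + size)
            gw.append(np.sqrt(size))
            cols.append(data.mirna_col(e.mirna_id))
            rows.append({"feature_id": e.mirna_id, "role": "miRNA",
                         "subnetwork_id": e.mirna_id})
            for gid in e.mrna_ids:
                cols.append(data.mrna_col(gid))
                rows.append({"feature_id": gid, "role": "mRNA",
                             "subnetwork_id": e.mirna_id})
            pos += size
    else:
        for e in net.entries:
            cols.append(data.mirna_col(e.mirna_id))
            rows.append({"feature_id": e.mirna_id, "role": "miRNA",
                         "subnetwork_id": e.mirna_id})
        seen: set[str] = set()
        for e in net.entries:
            for gid in e.mrna_ids:
                if gid in seen:
                    continue
                seen.add(gid)
                cols.append(data.mrna_col(gid))
                rows.append({"feature_id": gid, "role": "mRNA",
                             "subnetwork_id": ""})
        gs = list(range(1, len(cols) + 1))
        ge = list(range(2, len(cols) + 2))
        gw = [1.0] * len(cols)
    X = np.column_stack(cols)
    return (
        X,
        pd.DataFrame(rows),
        np.asarray(gw, dtype=float),
        np.asarray(gs, dtype=np.int64),
        np.asarray(ge, dtype=np.int64),
    )


def _standardize_cols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant design column cannot be standardized")
    return (X - mean) / sd, mean, sd


def _delta_max(Xs: np.ndarray, y: np.ndarray, cfg: CompConfig,
               gw: np.ndarray, gs: np.ndarray, ge: np.ndarray) -> float:
    """Smallest delta at which the null (intercept-only) model is optimal."""
    g = Xs.T @ (y.mean() - y) / len(y)  # gradient sign flipped is irrelevant
    norms = np.array(
        [np.linalg.norm(g[s - 1:e - 1]) / w for s, e, w in zip(gs, ge, gw)]
    )
    dmax = float(np.max(np.abs(norms)))
    if cfg.penalty_kind == "elastic_net":
        dmax /= max(cfg.alpha_mix, 1e-2)
    return dmax * 1.0001


def _fit_path(
    Xf: np.ndarray, y: np.ndarray, deltas: np.ndarray, cfg: CompConfig,
    gw: np.ndarray, gs: np.ndarray, ge: np.ndarray,
) -> np.ndarray:
    """Warm-started coefficient path over a descending delta grid."""
    L = _lipschitz(Xf)
    p1 = Xf.shape[1]
    b = np.zeros(p1)
    ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
    b[0] = np.log(ybar / (1 - ybar))
    path = np.empty((len(deltas), p1))
    for i, d in enumerate(deltas):
        l1, l2 = _penalty_mults(cfg, d)
        b = _fista(Xf, y, L, l1, l2, gw, gs, ge, b, cfg.max_iter, cfg.tol)
        path[i] = b
    return path


def _heldout_nll(Xf: np.ndarray, y: np.ndarray, path: np.ndarray) -> np.ndarray:
    eta = Xf @ path.T
    return np.mean(np.logaddexp(0.0, eta) - y[:, None] * eta, axis=0)


def fit_penalized_lr(
    data: ExpressionDataset, net: SubnetworkMap, cfg: CompConfig | None = None
) -> CompFit:
    """Cross-validated penalized logistic regression on the pooled design.

    delta minimizing the mean held-out deviance is chosen over a
    descending path (ties toward larger delta), then the model is refit on
    the full data at that delta.
    """
    cfg = cfg or CompConfig()
    if data.y is None:
        raise ValueError("dataset has no phenotype")
    y = data.y.astype(float)
    X, feats, gw, gs, ge = _assemble_design(data, net, cfg.penalty_kind)
    Xs, mean, sd = _standardize_cols(X)
    Xf = np.ascontiguousarray(np.column_stack([np.ones(len(y)), Xs]))

    if cfg.delta_grid is not None:
        deltas = np.asarray(cfg.delta_grid, dtype=float)
    else:
        dmax = _delta_max(Xs, y, cfg, gw, gs, ge)
        deltas = dmax * np.logspace(0, np.log10(cfg.delta_min_ratio), cfg.n_deltas)

    if len(deltas) > 1:
        n_min = int(np.bincount(data.y).min())
        k = min(cfg.cv_folds, n_min)
        if k < 2:
            raise ValueError("too few samples in the rarer class for CV")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        folds = [
            (np.ascontiguousarray(Xf[tr]), y[tr], Xf[te], y[te], _lipschitz(Xf[tr]))
            for tr, te in skf.split(Xs, data.y)
        ]
        warm = []
        for Xtr, ytr, _, _, _ in folds:
            b = np.zeros(Xf.shape[1])
            ybar = min(max(ytr.mean(), 1e-10), 1 - 1e-10)
            b[0] = np.log(ybar / (1 - ybar))
            warm.append(b)
        # descend the path with warm starts, stopping once the CV deviance
        # is clearly past its minimum (standard path-wise early exit)
        cv_nll = []
        best = 0
        for i, d in enumerate(deltas):
            l1, l2 = _penalty_mults(cfg, d)
            tot = 0.0
            for f_idx, (Xtr, ytr, Xte, yte, L) in enumerate(folds):
                warm[f_idx] = _fista(Xtr, ytr, L, l1, l2, gw, gs, ge,
                                     warm[f_idx], cfg.max_iter, cfg.tol)
                tot += _heldout_nll(Xte, yte, warm[f_idx][None, :])[0]
            cv_nll.append(tot / k)
            if cv_nll[i] < cv_nll[best]:  # strict: ties keep the larger delta
                best = i
            if i - best >= cfg.path_stop_after:
                break
        delta = float(deltas[best])
    else:
        delta = float(deltas[0])
        best = 0

    full_path = _fit_path(Xf, y, deltas[: best + 1], cfg, gw, gs, ge)
    b = full_path[-1]
    coef_std = b[1:]
    coef_raw = coef_std / sd
    beta0 = float(b[0] - np.sum(coef_std * mean / sd))
    feats = feats.copy()
    feats["coef"] = coef_raw

    theta = np.empty(net.J)
    K = np.zeros(net.J, dtype=int)
    for j, e in enumerate(net.entries):
        if cfg.penalty_kind == "group_lasso":
            block = feats[feats.subnetwork_id == e.mirna_id]
            theta[j] = block[block.role == "miRNA"].coef.iloc[0]
            K[j] = int((block[block.role == "mRNA"].coef != 0).sum())
        else:
            theta[j] = feats[(feats.role == "miRNA")
                             & (feats.feature_id == e.mirna_id)].coef.iloc[0]
            sub = feats[(feats.role == "mRNA")
                        & feats.feature_id.isin(e.mrna_ids)]
            K[j] = int((sub.coef != 0).sum())
    if not np.any(coef_std != 0):
        logger.warning("penalized fit selected nothing: null model returned")

    return CompFit(
        net=net, cfg=cfg, beta0=beta0, theta=theta, features=feats,
        delta_chosen=delta, nonzero_sets=K,
        col_stats=(mean, sd), coef_std=coef_std,
    )


def comp_predict_prob(fit: CompFit, data_new: ExpressionDataset) -> np.ndarray:
    """Case probabilities from a fitted comparator on new samples."""
    X, _, _, _, _ = _assemble_design(data_new, fit.net, fit.cfg.penalty_kind)
    eta = fit.beta0 + X @ fit.features.coef.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def subnetwork_selected(fit: CompFit, j: int, rule: SelectionRule) -> bool:
    """Threshold-T selection: miRNA coefficient nonzero and K_j >= T."""
    if rule.require_mirna and fit.theta[j] == 0:
        return False
    return int(fit.nonzero_sets[j]) >= rule.T


def calibrate_threshold(null_fprs: dict[int, float], target: float = 0.05) -> int:
    """T whose null FPR is closest to the target; ties toward larger T."""
    if not null_fprs:
        raise ValueError("empty FPR map")
    best_t, best_d = None, np.inf
    for t in sorted(null_fprs):
        d = abs(null_fprs[t] - target)
        if d <= best_d:  # <= so ties advance to the larger T
            best_t, best_d = t, d
    return best_t
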