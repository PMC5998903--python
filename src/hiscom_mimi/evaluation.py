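"""Cross-validated prediction evaluation of marker sets and prediction models.

A *selector* picks markers (subnetworks/features) on training samples
only; a *predictor* fits a model on those markers and scores held-out
samples; performance is the pooled Mann-Whitney AUC of the held-out
scores. Selection runs inside each training fold by default (leakage-free
protocol); ``fixed_markers=True`` emulates the optimistic protocol where
one marker set, chosen on all data, is reused in every fold.

Folds are stratified by class (the motivating data are heavily
imbalanced, 97 cases / 17 controls) and seeded; k-fold evaluation is
repeated over iterations and averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .comparators import CompConfig, comp_predict_prob, fit_penalized_lr
from .datamodel import ExpressionDataset, SubnetworkEntry, SubnetworkMap
from .hiscom import FitConfig, _subset, fit, predict_prob
from .inference import permutation_pvalues

logger = logging.getLogger("hiscom_mimi")

SELECTORS = ("hiscom", "lasso", "en", "gl")
PREDICTORS = ("hiscom", "lasso", "en", "gl")
_KIND = {"lasso": "lasso", "en": "elastic_net", "gl": "group_lasso"}


@dataclass
class EvalConfig:
    """Knobs for selection and prediction inside CV folds.

    ``select_alpha`` / ``select_B`` drive the permutation-based selector;
    comparator selection and prediction reuse the penalized-regression CV
    machinery (smaller path by default, for speed inside folds).
    """

    fit_cfg: FitConfig = field(default_factory=FitConfig)
    comp_cfg: CompConfig = field(default_factory=lambda: CompConfig(n_deltas=12))
    select_alpha: float = 0.05
    select_B: int = 100
    fixed_markers: bool = False
    seed: int = 0


@dataclass
class AUCReport:
    marker_set_source: str
    prediction_model: str
    auc_loocv: float | None
    auc_kfold: dict[int, float]
    n_iterations: int


def _restrict_net(net: SubnetworkMap, keep_subnets: list[int],
                  keep_mrnas: set[str] | None) -> SubnetworkMap:
    """Subnetwork map induced by a selection.

    Keeps the listed subnetworks; within each, keeps either all mRNAs
    (subnetwork-level selection) or only those in ``keep_mrnas``
    (feature-level selection). The miRNA always anchors its component.
    """
    entries = []
    for j in keep_subnets:
        e = net.entries[j]
        if keep_mrnas is None:
            entries.append(e)
        else:
            idx = [k for k, g in enumerate(e.mrna_ids) if g in keep_mrnas]
            entries.append(
                SubnetworkEntry(
                    mirna_id=e.mirna_id,
                    mrna_ids=[e.mrna_ids[k] for k in idx],
                    r=e.r[idx] if e.r.size else e.r,
                    p=e.p[idx] if e.p.size else e.p,
                )
            )
    return SubnetworkMap(entries=entries)


def _select(name: str, train: ExpressionDataset, net: SubnetworkMap,
            cfg: EvalConfig, rng: np.random.Generator) -> SubnetworkMap:
    """Marker selection on training data; returns the induced map (may be empty)."""
    if name == "hiscom":
        inf, _ = permutation_pvalues(
            train, net, cfg.fit_cfg, B=cfg.select_B, rng=rng
        )
        keep = [j for j in range(net.J) if inf.p_perm[j] < cfg.select_alpha]
        return _restrict_net(net, keep, None)
    ccfg = replace(cfg.comp_cfg, penalty_kind=_KIND[name],
                   seed=int(rng.integers(2**31 - 1)))
    cfit = fit_penalized_lr(train, net, ccfg)
    nz = cfit.features[cfit.features.coef != 0]
    sel_mirnas = set(nz[nz.role == "miRNA"].feature_id)
    sel_mrnas = set(nz[nz.role == "mRNA"].feature_id)
    keep = [
        j for j, e in enumerate(net.entries)
        if e.mirna_id in sel_mirnas or any(g in sel_mrnas for g in e.mrna_ids)
    ]
    return _restrict_net(net, keep, sel_mrnas)


def _predict(name: str, train: ExpressionDataset, test: ExpressionDataset,
             markers: SubnetworkMap, cfg: EvalConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Held-out scores from the predictor fit on the selected markers.

    An empty marker set yields constant scores (AUC 0.5 by convention).
    """
    if markers.J == 0:
        return np.full(test.n, 0.5)
    if name == "hiscom":
        f = fit(train, markers, cfg.fit_cfg)
        return predict_prob(f, test)
    ccfg = replace(cfg.comp_cfg, penalty_kind=_KIND[name],
                   seed=int(rng.integers(2**31 - 1)))
    cfit = fit_penalized_lr(train, markers, ccfg)
    return comp_predict_prob(cfit, test)


def _fold_scores(data, net, selector, predictor, cfg, splits, rng,
                 fixed_net=None):
    scores = np.empty(data.n)
    for tr, te in splits:
        train, test = _subset(data, tr), _subset(data, te)
        markers = fixed_net if fixed_net is not None else _select(
            selector, train, net, cfg, rng
        )
        scores[te] = _predict(predictor, train, test, markers, cfg, rng)
    return scores


def loocv_auc(data: ExpressionDataset, net: SubnetworkMap, selector: str,
              predictor: str, cfg: EvalConfig | None = None) -> float:
    """Leave-one-out AUC: selection and fitting on the n-1 remaining samples."""
    cfg = cfg or EvalConfig()
    if data.n < 20:
        raise ValueError("need at least 20 samples for LOOCV evaluation")
    rng = np.random.default_rng(cfg.seed)
    fixed = _select(selector, data, net, cfg, rng) if cfg.fixed_markers else None
    splits = [
        (np.delete(np.arange(data.n), i), np.array([i])) for i in range(data.n)
    ]
    scores = _fold_scores(data, net, selector, predictor, cfg, splits, rng, fixed)
    return float(roc_auc_score(data.y, scores))


def repeated_kfold_auc(
    data: ExpressionDataset,
    net: SubnetworkMap,
    selector: str,
    predictor: str,
    folds: int = 4,
    iterations: int = 100,
    seed: int = 0,
    cfg: EvalConfig | None = None,
    return_per_iteration: bool = False,
):
    """Mean over iterations of the pooled held-out AUC under stratified k-fold."""
    cfg = cfg or EvalConfig()
    n_min = int(np.bincount(data.y).min())
    if folds > n_min:
        raise ValueError(
            f"{folds} stratified folds infeasible with {n_min} rarer-class samples"
        )
    rng = np.random.default_rng(seed)
    fixed = _select(selector, data, net, cfg, rng) if cfg.fixed_markers else None
    aucs = np.empty(iterations)
    for it in range(iterations):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        splits = list(skf.split(np.zeros(data.n), data.y))
        scores = _fold_scores(data, net, selector, predictor, cfg, splits, rng, fixed)
        aucs[it] = roc_auc_score(data.y, scores)
    if return_per_iteration:
        return aucs
    return float(aucs.mean())


def auc_report(
    data: ExpressionDataset,
    net: SubnetworkMap,
    selector: str,
    predictor: str,
    iterations: int = 100,
    seed: int = 0,
    cfg: EvalConfig | None = None,
    include_loocv: bool = True,
) -> AUCReport:
    """LOOCV plus 4- and 8-fold repeated-CV AUC for one selector/predictor pair."""
    cfg = cfg or EvalConfig()
    kfold = {
        k: repeated_kfold_auc(data, net, selector, predictor, folds=k,
                              iterations=iterations, seed=seed, cfg=cfg)
        for k in (4, 8)
    }
    return AUCReport(
        marker_set_source=selector,
        prediction_model=predictor,
        auc_loocv=loocv_auc(data, net, selector, predictor, cfg) if include_loocv else None,
        auc_kfold=kfold,
        n_iterations=iterations,
    )
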