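"""Per-subnetwork significance: permutation p-values and FDR q-values.

The test statistic is |beta_j| on unit-variance components (beta_j is the
log-odds effect per component SD, so magnitudes are comparable across
subnetworks). The phenotype is permuted with (Z, X) fixed, preserving the
miRNA-mRNA correlation structure under the null of no phenotype
association; ridge penalties are chosen once on the observed data and held
fixed across permutations. The add-one estimator
``p = (1 + #{|beta_perm| >= |beta_obs|}) / (B + 1)`` avoids zero p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset, ResultTable, SubnetworkMap
from .hiscom import FitConfig, HiscomFit, _als_batched, _design_blocks, residualize


@dataclass
class InferenceResult:
    """Observed path coefficients with permutation p and BH q per subnetwork."""

    mirna_ids: list[str]
    beta_obs: np.ndarray
    p_perm: np.ndarray
    q_value: np.ndarray
    B_used: int


def permutation_pvalues(
    data: ExpressionDataset,
    net: SubnetworkMap,
    cfg: FitConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[InferenceResult, HiscomFit]:
    """Permutation p-values for every subnetwork's path coefficient.

    Fits the observed data and B label permutations in one batched
    alternating-least-squares run. Permutations preserve the class counts,
    so no permuted fit can lose a class.
    """
    cfg = cfg or FitConfig()
    if B < 1:
        raise ValueError("need at least one permutation")
    if data.y is None:
        raise ValueError("dataset has no phenotype")
    if rng is None:
        rng = np.random.default_rng(seed)
    Y = np.empty((B + 1, data.n), dtype=float)
    Y[0] = data.y
    for b in range(1, B + 1):
        Y[b] = rng.permutation(data.y)
    resid = residualize(data, net, standardize=cfg.standardize)
    out = _als_batched(_design_blocks(resid), Y, cfg)
    absb = np.abs(out["beta"])
    p = (1 + np.sum(absb[1:] >= absb[0][None, :], axis=0)) / (B + 1)
    q = fdr_qvalues(p)
    res = InferenceResult(
        mirna_ids=[e.mirna_id for e in net.entries],
        beta_obs=out["beta"][0].copy(),
        p_perm=p,
        q_value=q,
        B_used=B,
    )
    observed = HiscomFit(
        net=net, resid=resid, cfg=cfg,
        w=[Aj[0, 1:].copy() for Aj in out["A"]],
        gamma0=np.array([Aj[0, 0] for Aj in out["A"]]),
        beta0=float(out["beta0"][0]),
        beta=out["beta"][0].copy(),
        F=out["F"][0].copy(),
        objective_trace=out["trace"][0],
        converged=bool(out["converged"][0]),
        n_iter=int(out["n_iter"][0]),
    )
    return res, observed


def fdr_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def result_table(net: SubnetworkMap, inf: InferenceResult,
                 alpha_screen: float = 0.05) -> ResultTable:
    """Assemble the per-subnetwork result rows (sorted by p ascending).

    ``n_significant_mrnas`` counts the retained edges whose screening
    p-value is below ``alpha_screen`` — the only defined per-mRNA notion
    of significance in the model.
    """
    rows = pd.DataFrame(
        {
            "mirna_id": inf.mirna_ids,
            "G_j": [e.size for e in net.entries],
            "n_significant_mrnas": [
                int(np.sum(e.p < alpha_screen)) if e.size else 0 for e in net.entries
            ],
            "beta": inf.beta_obs,
            "p_value": inf.p_perm,
            "q_value": inf.q_value,
        }
    )
    return ResultTable(rows=rows)
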