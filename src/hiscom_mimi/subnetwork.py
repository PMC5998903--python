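"""miRNA-mRNA subnetwork construction.

A subnetwork is one miRNA plus the candidate target mRNAs (from the pair
table) whose Pearson correlation with the miRNA is negative and significant
(two-sided p < alpha_screen by default). miRNAs with no surviving targets
are recorded separately rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ExpressionDataset, SubnetworkEntry, SubnetworkMap, TargetPairTable

logger = logging.getLogger("hiscom_mimi")


@dataclass
class CorrScreenResult:
    r: float
    p: float
    n_used: int


def pearson_screen(x: np.ndarray, z: np.ndarray) -> CorrScreenResult:
    """Pearson correlation of a target mRNA with a miRNA.

    The two-sided p-value corresponds to t = r * sqrt((n-2)/(1-r^2)) on
    n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape or x.ndim != 1:
        raise ValueError("x and z must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.std(x) == 0 or np.std(z) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = stats.pearsonr(x, z)
    return CorrScreenResult(r=float(res.statistic), p=float(res.pvalue), n_used=n)


def build_subnetworks(
    data: ExpressionDataset,
    pairs: TargetPairTable,
    alpha_screen: float = 0.05,
    one_sided: bool = False,
    require_negative: bool = True,
) -> SubnetworkMap:
    """Screen candidate pairs and assemble per-miRNA subnetworks.

    An edge (miRNA j, mRNA k) is retained when r_jk < 0 and its p-value is
    below ``alpha_screen``. With ``one_sided=True`` the reported two-sided p
    is halved before thresholding (the screen is ambiguous between the two
    conventions; both retain only negative correlations).
    ``require_negative=False`` disables the sign condition (sanity checks
    only). Pairs whose ids are absent from the dataset are logged and
    skipped. Entry order follows first appearance of each miRNA in the
    pair table; retained mRNAs keep pair-table order.
    """
    mirna_set = set(data.mirna_ids)
    mrna_set = set(data.mrna_ids)
    candidates: dict[str, list[str]] = {}
    n_unresolved = 0
    for m, g in pairs.pairs:
        if m not in mirna_set or g not in mrna_set:
            n_unresolved += 1
            continue
        candidates.setdefault(m, []).append(g)
    if n_unresolved:
        logger.info("skipped %d pairs with ids absent from the dataset", n_unresolved)
    if not pairs.pairs:
        logger.warning("empty pair table: no subnetworks constructed")

    entries: list[SubnetworkEntry] = []
    dropped: list[str] = []
    for mirna_id, mrnas in candidates.items():
        z = data.mirna_col(mirna_id)
        kept, rs, ps = [], [], []
        for g in mrnas:
            scr = pearson_screen(data.mrna_col(g), z)
            p_eff = scr.p / 2 if (one_sided and scr.r < 0) else scr.p
            if (scr.r < 0 or not require_negative) and p_eff < alpha_screen:
                kept.append(g)
                rs.append(scr.r)
                ps.append(scr.p)
        if kept:
            entries.append(
                SubnetworkEntry(mirna_id=mirna_id, mrna_ids=kept,
                                r=np.array(rs), p=np.array(ps))
            )
        else:
            dropped.append(mirna_id)
    net = SubnetworkMap(entries=entries, dropped_mirnas=dropped)
    logger.info("built %d subnetworks with %d edges (%d miRNAs screened out)",
                net.J, net.n_edges, len(dropped))
    return net


def write_subnetworks(net: SubnetworkMap, path: str) -> None:
    """Edge-list TSV: mirna_id, mrna_id, r, p."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tmrna_id\tr\tp\n")
        for e in net.entries:
            for k, g in enumerate(e.mrna_ids):
                fh.write(f"{e.mirna_id}\t{g}\t{e.r[k]:.10g}\t{e.p[k]:.10g}\n")
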