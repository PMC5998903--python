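"""Deterministic on-disk fixtures with known ground truth.

Each named fixture regenerates byte-identically from its spec and writes
Z.tsv, X.tsv, y.tsv, pairs.tsv plus truth.tsv (causal labels and
generating parameters), exercising every pipeline stage without
downloads. miRNA labels are reused purely as mnemonic ids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from . import simulation as sim
from .datamodel import write_expression, write_phenotype, write_target_pairs


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    n: int
    scenario: int | None  # None for the hand-built tiny fixture
    effect_beta: float
    seed: int


REGISTRY: dict[str, FixtureSpec] = {
    s.name: s
    for s in [
        FixtureSpec("scenario1-null", 114, 1, 0.0, 11),
        FixtureSpec("scenario2-null", 114, 2, 0.0, 12),
        FixtureSpec("scenario1-power35", 114, 1, 0.35, 13),
        FixtureSpec("scenario2-power35", 114, 2, 0.35, 14),
        FixtureSpec("tiny-exact", 12, None, 0.0, 15),
    ]
}


def _tiny_exact(spec: FixtureSpec):
    """n=12, two subnetworks, exact inhibition (zero residuals).

    Each mRNA is an exact negative multiple of its miRNA, so the
    residualized columns are identically zero — closed-form territory.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    Z = rng.standard_normal((n, 2))
    X = np.column_stack([-2.0 * Z[:, 0], -0.5 * Z[:, 0], -1.0 * Z[:, 1]])
    y = np.array([0, 1] * (n // 2))
    layout = [("miR-A", True, ["gA1", "gA2"]), ("miR-B", False, ["gB1"])]
    return Z, X, y, ["miR-A", "miR-B"], ["gA1", "gA2", "gB1"], layout


def make_fixture(name: str, out_dir: str) -> dict[str, str]:
    """Write the named fixture into ``out_dir``; returns the file paths."""
    if name not in REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(REGISTRY)}")
    spec = REGISTRY[name]
    os.makedirs(out_dir, exist_ok=True)
    if spec.scenario is None:
        Z, X, y, mirnas, mrnas, layout = _tiny_exact(spec)
        params = {"corr_inhibition": "", "corr_background": ""}
    else:
        sc = replace(
            sim.make_scenario(spec.scenario),
            n_samples=spec.n, effect_beta=spec.effect_beta,
        )
        data = sim.simulate_dataset(sc, spec.seed)
        Z, X, y = data.Z, data.X, data.y
        mirnas, mrnas = data.mirna_ids, data.mrna_ids
        layout = sc.subnetworks
        params = {
            "corr_inhibition": sc.corr_inhibition,
            "corr_background": sc.corr_background,
        }
    samples = [f"s{i:03d}" for i in range(spec.n)]
    paths = {k: os.path.join(out_dir, f"{k}.tsv")
             for k in ("Z", "X", "y", "pairs", "truth")}
    write_expression(paths["Z"], samples, mirnas, Z)
    write_expression(paths["X"], samples, mrnas, X)
    write_phenotype(paths["y"], samples, y)
    write_target_pairs(paths["pairs"],
                       [(m, g) for m, _, ms in layout for g in ms])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tcausal\tmrna_ids\teffect_beta\t"
                 "corr_inhibition\tcorr_background\tseed\n")
        for m, causal, ms in layout:
            fh.write(
                f"{m}\t{int(causal)}\t{','.join(ms)}\t{spec.effect_beta}\t"
                f"{params['corr_inhibition']}\t{params['corr_background']}\t"
                f"{spec.seed}\n"
            )
    return paths
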