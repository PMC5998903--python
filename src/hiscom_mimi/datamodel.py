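"""Shared domain types and tab-delimited readers/writers.

Expression matrices are TSV with samples in rows (first column = sample id,
header row = feature ids). The phenotype file is two columns (sample id,
0/1). Target pairs are two columns (miRNA id, mRNA/gene symbol). All files
are UTF-8 with "." decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hiscom_mimi")


@dataclass
class ExpressionDataset:
    """Aligned miRNA/mRNA expression with a binary phenotype.

    Z is n x J_all (miRNA, log-scale a.u.), X is n x M (mRNA), y is the
    0/1 phenotype (1 = case). All three share the same sample order; ``y``
    may be None for prediction-only data.
    """

    sample_ids: list[str]
    mirna_ids: list[str]
    mrna_ids: list[str]
    Z: np.ndarray
    X: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.sample_ids)
        if self.Z.shape != (n, len(self.mirna_ids)):
            raise ValueError(
                f"Z shape {self.Z.shape} does not match "
                f"{n} samples x {len(self.mirna_ids)} miRNAs"
            )
        if self.X.shape != (n, len(self.mrna_ids)):
            raise ValueError(
                f"X shape {self.X.shape} does not match "
                f"{n} samples x {len(self.mrna_ids)} mRNAs"
            )
        if np.isnan(self.Z).any() or np.isnan(self.X).any():
            raise ValueError("expression matrices contain missing values")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (n,):
                raise ValueError("phenotype length does not match sample count")
            bad = ~np.isin(self.y, (0, 1))
            if bad.any():
                offender = self.sample_ids[int(np.nonzero(bad)[0][0])]
                raise ValueError(
                    f"phenotype must be 0/1; sample {offender!r} has "
                    f"value {self.y[bad][0]!r}"
                )
            self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def mirna_col(self, mirna_id: str) -> np.ndarray:
        return self.Z[:, self.mirna_ids.index(mirna_id)]

    def mrna_col(self, mrna_id: str) -> np.ndarray:
        return self.X[:, self.mrna_ids.index(mrna_id)]


@dataclass
class TargetPairTable:
    """Deduplicated candidate miRNA -> target-mRNA pairs (e.g. exported
    from TargetScan-style predictions)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise ValueError("target pair ids must be non-empty")
        seen: dict[tuple[str, str], None] = {}
        for p in self.pairs:
            seen.setdefault(p, None)
        self.pairs = list(seen)


@dataclass
class SubnetworkEntry:
    """One miRNA with its retained (negatively correlated) target mRNAs.

    ``r`` / ``p`` are the Pearson screening statistics per retained mRNA,
    in the order of ``mrna_ids``. ``mrna_ids`` may be empty for a singleton
    component (direct miRNA effect only), which ``build_subnetworks`` never
    produces but direct construction allows.
    """

    mirna_id: str
    mrna_ids: list[str]
    r: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def size(self) -> int:
        """G_j: number of retained target mRNAs."""
        return len(self.mrna_ids)


@dataclass
class SubnetworkMap:
    """Ordered miRNA-mRNA subnetworks plus the miRNAs screened out."""

    entries: list[SubnetworkEntry]
    dropped_mirnas: list[str] = field(default_factory=list)

    @property
    def J(self) -> int:
        return len(self.entries)

    @property
    def n_edges(self) -> int:
        return sum(e.size for e in self.entries)

    def index_of(self, mirna_id: str) -> int:
        for j, e in enumerate(self.entries):
            if e.mirna_id == mirna_id:
                return j
        raise KeyError(mirna_id)


RESULT_COLUMNS = ["mirna_id", "G_j", "n_significant_mrnas", "beta", "p_value", "q_value"]


@dataclass
class ResultTable:
    """Per-subnetwork association results, sorted by p ascending."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        self.rows = (
            self.rows[RESULT_COLUMNS]
            .sort_values(["p_value", "mirna_id"], kind="mergesort")
            .reset_index(drop=True)
        )


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def load_phenotype(path: str) -> pd.Series:
    """Read the two-column (sample id, 0/1) phenotype file.

    A header line is tolerated: the first row is skipped when its second
    field does not parse as a number.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"phenotype file {path} must have exactly 2 columns")
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        offender = ids[vals.isna()].iloc[0]
        raise ValueError(f"non-numeric phenotype for sample {offender!r}")
    for sid, v in zip(ids, vals):
        if v not in (0, 1):
            raise ValueError(f"phenotype must be 0/1; sample {sid!r} has value {v}")
    return pd.Series(vals.to_numpy(dtype=int), index=ids.to_numpy())


def load_expression(path_mirna: str, path_mrna: str, path_pheno: str) -> ExpressionDataset:
    """Load and align the three input files on their shared samples.

    Samples are intersected across the files and canonically sorted by
    sample id, so downstream results do not depend on file row order.
    Missing cells and non-binary phenotypes are hard errors.
    """
    zdf = _read_matrix(path_mirna)
    xdf = _read_matrix(path_mrna)
    pheno = load_phenotype(path_pheno)

    for name, df in (("miRNA", zdf), ("mRNA", xdf)):
        if df.isna().any().any():
            row, col = next(
                (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
            )
            raise ValueError(f"missing {name} value at sample {row!r}, feature {col!r}")

    common = sorted(set(zdf.index) & set(xdf.index) & set(pheno.index))
    if not common:
        raise ValueError("no samples shared by the miRNA, mRNA and phenotype files")
    n_drop = max(len(zdf), len(xdf), len(pheno)) - len(common)
    if n_drop:
        logger.warning("dropped %d samples not present in all three files", n_drop)

    return ExpressionDataset(
        sample_ids=list(common),
        mirna_ids=[str(c) for c in zdf.columns],
        mrna_ids=[str(c) for c in xdf.columns],
        Z=zdf.loc[common].to_numpy(dtype=float),
        X=xdf.loc[common].to_numpy(dtype=float),
        y=pheno.loc[common].to_numpy(),
    )


def load_target_pairs(path: str) -> TargetPairTable:
    """Read the two-column miRNA/mRNA pair file; duplicates are dropped."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1 and (fields[0].lower() in ("mirna", "mirna_id", "#mirna")):
                continue
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        logger.warning("target pair file %s is empty", path)
    table = TargetPairTable(pairs=pairs)
    n_dup = len(pairs) - len(table.pairs)
    if n_dup:
        logger.info("dropped %d duplicate target pairs", n_dup)
    return table


def write_expression(path: str, sample_ids: list[str], feature_ids: list[str],
                     M: np.ndarray) -> None:
    pd.DataFrame(M, index=sample_ids, columns=feature_ids).to_csv(
        path, sep="\t", index_label="sample_id", float_format="%.10g"
    )


def write_phenotype(path: str, sample_ids: list[str], y: np.ndarray) -> None:
    pd.DataFrame({"sample_id": sample_ids, "phenotype": np.asarray(y, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def write_target_pairs(path: str, pairs: list[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in pairs:
            fh.write(f"{m}\t{g}\n")


def write_result_table(results: ResultTable, path: str) -> None:
    """Write the per-subnetwork result TSV (p ascending, ties by miRNA id)."""
    results.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
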