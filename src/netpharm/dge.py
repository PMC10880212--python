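"""Two-group differential expression and signature extraction.

The pipeline consumes gene-level tables of (log2 fold change, p-value,
FDR).  They can either be imported from an external fit or computed
here with a per-gene Welch t-test on a log2 expression matrix.  The
"signature" of a perturbation is the set of genes passing the
significance thresholds together with their up/down sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, NetpharmError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "read_expression",
    "read_deg_table",
    "differential_expression",
    "bh_adjust",
    "select_degs",
]

CONTROL = "control"
TREATED = "treated"


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with a two-group design."""

    values: pd.DataFrame  # index = genes, columns = samples
    groups: Mapping[str, str]  # sample -> {"control", "treated"}

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise NetpharmError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise NetpharmError("duplicate sample ids in expression matrix")
        labels = set(self.groups.values())
        if not labels <= {CONTROL, TREATED}:
            raise NetpharmError(f"group labels must be {CONTROL}/{TREATED}, got {labels}")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise NetpharmError(f"samples without group labels: {sorted(missing)}")
        for grp in (CONTROL, TREATED):
            if not any(v == grp for v in self.groups.values()):
                raise NetpharmError(f"group {grp!r} is empty")

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ctrl = [s for s in self.values.columns if self.groups[s] == CONTROL]
        trt = [s for s in self.values.columns if self.groups[s] == TREATED]
        return self.values[ctrl], self.values[trt]


@dataclass
class GeneSignature:
    """Deregulation signs (+1 up / -1 down) of thresholded genes.

    ``magnitudes`` holds |log2FC| for genes where it is known; genes in
    ``signs`` without a magnitude are allowed (e.g. literature targets
    carry no expression change and are handled upstream).
    """

    signs: dict[str, int] = field(default_factory=dict)
    magnitudes: dict[str, float] = field(default_factory=dict)
    name: str = "signature"

    def __post_init__(self):
        bad = {g: s for g, s in self.signs.items() if s not in (-1, 1)}
        if bad:
            raise NetpharmError(f"signature signs must be +/-1, got {bad}")

    @property
    def genes(self) -> set[str]:
        return set(self.signs)

    def __len__(self) -> int:
        return len(self.signs)

    def __bool__(self) -> bool:
        return bool(self.signs)


def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a two-column (sample, group) file."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.map(lambda g: str(g).strip().upper())
    groups_df = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"], comment="#"
    )
    if list(groups_df.iloc[0]) == ["sample", "group"]:
        groups_df = groups_df.iloc[1:]
    groups = dict(zip(groups_df["sample"].astype(str), groups_df["group"].astype(str)))
    return ExpressionMatrix(values, groups)


def read_deg_table(path) -> pd.DataFrame:
    """Import a precomputed DEG table (gene, log2fc, pvalue[, fdr]).

    The FDR column is computed with Benjamini-Hochberg when absent, so
    externally fitted tables (e.g. from an empirical-Bayes moderated
    t-test) can be consumed without re-deriving their p-values.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "log2fc", "pvalue"}
    if not required <= set(df.columns):
        raise NetpharmError(
            f"{path}: DEG table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    df["gene"] = df["gene"].map(lambda g: str(g).strip().upper())
    if df["gene"].duplicated().any():
        raise NetpharmError(f"{path}: duplicate gene rows in DEG table")
    if "fdr" not in df.columns:
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    return df[["gene", "log2fc", "pvalue", "fdr"]]


def differential_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Welch t-test between treated and control samples.

    Returns a DEG table with columns gene, log2fc, pvalue, fdr where
    log2fc = mean(treated) - mean(control).  Genes with missing values
    are dropped (count logged); genes constant across all samples get
    p = 1 with a warning.
    """
    ctrl, trt = expr.split()
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise InsufficientDataError("need >=2 samples per group for a t-test")
    complete = expr.values.dropna(axis=0)
    n_dropped = expr.values.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info("differential_expression: dropped %d genes with missing values", n_dropped)
    ctrl = complete[ctrl.columns].to_numpy(float)
    trt = complete[trt.columns].to_numpy(float)
    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    constant = complete.to_numpy(float).std(axis=1) == 0
    degenerate = np.isnan(pvals)
    if degenerate.any() or constant.any():
        warnings.warn(
            f"{int((degenerate | constant).sum())} constant/degenerate genes "
            "assigned p = 1",
            stacklevel=2,
        )
    pvals = np.where(degenerate | constant, 1.0, pvals)
    table = pd.DataFrame(
        {
            "gene": complete.index,
            "log2fc": log2fc,
            "pvalue": pvals,
        }
    )
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return table.reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise NetpharmError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return np.clip(adjusted, 0.0, 1.0)


def select_degs(
    table: pd.DataFrame,
    lfc_min: float = 1.2,
    fdr_max: float = 0.05,
    name: str = "signature",
) -> GeneSignature:
    """Threshold a DEG table into a signed signature.

    A gene is kept iff fdr < fdr_max AND |log2FC| > lfc_min, both
    strict.  An empty result is a warning, not an error: some weak
    perturbations genuinely deregulate nothing at these thresholds.
    """
    if lfc_min <= 0 or fdr_max <= 0:
        raise ParameterError("thresholds must be positive")
    keep = (table["fdr"] < fdr_max) & (table["log2fc"].abs() > lfc_min)
    sub = table[keep]
    if sub.empty:
        warnings.warn(f"{name}: no genes pass fdr<{fdr_max}, |log2FC|>{lfc_min}", stacklevel=2)
    signs = {g: (1 if fc > 0 else -1) for g, fc in zip(sub["gene"], sub["log2fc"])}
    mags = {g: abs(fc) for g, fc in zip(sub["gene"], sub["log2fc"])}
    return GeneSignature(signs=signs, magnitudes=mags, name=name)
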