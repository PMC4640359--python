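"""Differential-expression tables, common-DE sets, and overlap significance.

The pipeline normally consumes DE tables produced by a dedicated caller
(edgeR-style TSV: gene, logFC, PValue, FDR).  For synthetic end-to-end runs a
minimal stand-in caller is provided: counts-per-million normalization, a
per-gene Welch t-test on log2 CPM, and Benjamini-Hochberg adjustment.  The
overlap between two DE gene sets is scored with the upper-tail inclusive
hypergeometric test, P(X >= k).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "logFC", "PValue", "FDR"]


@dataclass(frozen=True)
class OverlapResult:
    universe_size: int
    set1_size: int
    set2_size: int
    overlap_size: int
    p_hypergeometric: float
    overlap_genes: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE table TSV; requires the gene/logFC/PValue/FDR header, extra
    columns are ignored."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: DE table missing required columns {missing}")
    df = df[DE_COLUMNS].copy()
    df["gene"] = df["gene"].astype(str)
    for col in ("PValue", "FDR"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise DataError(f"{path}: {col} outside [0, 1] for genes {list(bad['gene'][:5])}")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def hypergeom_upper_tail(k: int, universe: int, set1_size: int, set2_size: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=universe, K=set1_size, n=set2_size), inclusive."""
    return float(stats.hypergeom.sf(k - 1, universe, set1_size, set2_size))


# ---------------------------------------------------------------------------
# Stand-in DE caller (synthetic data only; real data should bring its own
# edgeR/DESeq2 tables)
# ---------------------------------------------------------------------------

def _size_factors(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Each sample's factor is the median, over genes expressed in every
    sample, of its counts divided by the gene's geometric mean — so a
    minority of strongly DE genes cannot drag the normalization, unlike
    total-count scaling.  Falls back to relative library size when too few
    genes are expressed everywhere.
    """
    everywhere = (mat > 0).all(axis=1)
    if everywhere.sum() < 10:
        lib = mat.sum(axis=0)
        return lib / np.exp(np.mean(np.log(lib)))
    ref = np.exp(np.mean(np.log(mat[everywhere]), axis=1))
    return np.median(mat[everywhere] / ref[:, None], axis=0)

def call_de_standin(
    counts: pd.DataFrame,
    condition_labels: Sequence[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Simple two-group DE test on a genes x samples count matrix.

    Normalizes library sizes with median-of-ratios size factors (robust to
    an asymmetric DE fraction, which biases plain total-count scaling),
    tests each gene with a Welch t-test on the log2 normalized counts, and
    applies Benjamini-Hochberg.  The contrast is second condition vs first,
    in order of first appearance in ``condition_labels``.  Genes with zero
    counts in every sample are dropped (and counted in the log).  Returns a
    DE table DataFrame (gene, logFC, PValue, FDR).
    """
    if len(condition_labels) != counts.shape[1]:
        raise ConfigurationError(
            f"{len(condition_labels)} labels for {counts.shape[1]} sample columns"
        )
    labels = pd.Series(condition_labels)
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ConfigurationError(f"exactly two conditions required, got {levels}")
    mask_a = (labels == levels[0]).to_numpy()
    mask_b = (labels == levels[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DataError(
            "need >= 2 samples per condition for the stand-in caller; "
            "supply a precomputed DE table instead"
        )
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise DataError("counts must be non-negative")

    nonzero = mat.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("call_de_standin: dropped %d all-zero genes", n_dropped)
    mat = mat[nonzero]
    genes = counts.index[nonzero]

    factors = _size_factors(mat)
    libsize = counts.to_numpy(dtype=float).sum(axis=0)
    # scale size factors so the normalized values stay on a CPM-like scale
    eff_lib = factors * libsize.mean()
    logcpm = np.log2(mat / eff_lib * 1e6 + 1.0)
    a, b = logcpm[:, mask_a], logcpm[:, mask_b]

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    log_fc = b.mean(axis=1) - a.mean(axis=1)
    # constant-in-both-groups genes: the t statistic is undefined; call them
    # unchanged unless the two constants differ
    nan = np.isnan(p)
    p[nan] = np.where(np.isclose(log_fc[nan], 0.0), 1.0, 0.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({"gene": genes, "logFC": log_fc, "PValue": p, "FDR": fdr})
    logger.info(
        "call_de_standin: %d genes tested, %d significant at FDR<%g",
        len(out), int((out["FDR"] < fdr_threshold).sum()), fdr_threshold,
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Common DE set and overlap significance
# ---------------------------------------------------------------------------

def significant_genes(table: pd.DataFrame, fdr_threshold: float = 0.05) -> set[str]:
    return set(table.loc[table["FDR"] < fdr_threshold, "gene"])


def common_de(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    fdr_threshold: float = 0.05,
    require_concordant_sign: bool = False,
) -> list[str]:
    """Genes significant in both tables, optionally with agreeing fold-change
    direction; returned sorted."""
    if len(table1) == 0 or len(table2) == 0:
        logger.warning("common_de: empty DE table supplied; overlap is empty")
        return []
    sig1 = table1[table1["FDR"] < fdr_threshold]
    sig2 = table2[table2["FDR"] < fdr_threshold]
    merged = sig1.merge(sig2, on="gene", suffixes=("_1", "_2"))
    if require_concordant_sign:
        merged = merged[np.sign(merged["logFC_1"]) == np.sign(merged["logFC_2"])]
    return sorted(merged["gene"])


def overlap_test(
    universe_size: int | None,
    set1: Iterable[str],
    set2: Iterable[str],
    universe: Iterable[str] | None = None,
) -> OverlapResult:
    """Upper-tail inclusive hypergeometric test of the overlap of two sets.

    Either pass ``universe_size`` directly, or pass the ``universe`` itself
    (in which case membership of both sets is checked and its size used).
    """
    s1, s2 = set(set1), set(set2)
    if universe is not None:
        uni = set(universe)
        stray = (s1 | s2) - uni
        if stray:
            raise ConfigurationError(
                f"sets contain ids outside the universe: {sorted(stray)[:10]}"
            )
        universe_size = len(uni)
    if universe_size is None:
        raise ConfigurationError("either universe_size or universe must be given")
    if universe_size < len(s1 | s2):
        raise ConfigurationError(
            f"universe_size {universe_size} smaller than |set1 ∪ set2| = {len(s1 | s2)}"
        )
    overlap = s1 & s2
    p = hypergeom_upper_tail(len(overlap), universe_size, len(s1), len(s2))
    return OverlapResult(
        universe_size=int(universe_size),
        set1_size=len(s1),
        set2_size=len(s2),
        overlap_size=len(overlap),
        p_hypergeometric=p,
        overlap_genes=tuple(sorted(overlap)),
    )


def tested_universe(table1: pd.DataFrame, table2: pd.DataFrame) -> set[str]:
    """Default overlap universe: genes assayed in BOTH tables — only jointly
    tested genes can possibly overlap."""
    return set(table1["gene"]) & set(table2["gene"])
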