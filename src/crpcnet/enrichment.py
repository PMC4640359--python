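"""Hypergeometric gene-set enrichment against GMT collections.

Each set is scored with the upper-tail inclusive hypergeometric test shared
with the overlap machinery, followed by multiple-testing correction across
all tested sets (Benjamini-Hochberg by default, Bonferroni optional).  A
separate raw-count mode reports, per pathway, how many significant DE genes
it contains — useful when two datasets are compared at the pathway level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt
from statsmodels.stats.multitest import multipletests

from .de_overlap import hypergeom_upper_tail, significant_genes
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

CORRECTIONS = {"BH": "fdr_bh", "Bonferroni": "bonferroni"}


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    source: str = ""

    def filtered_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with the universe and drop sets that empty out."""
        kept = {name: members & universe for name, members in self.sets.items()}
        return GeneSetCollection(
            sets={n: m for n, m in kept.items() if m}, source=self.source
        )


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Load a GMT file (set name, description, tab-separated members)."""
    raw = _gseapy_read_gmt(str(path))
    if not raw:
        raise DataError(f"{path}: no gene sets parsed")
    return GeneSetCollection(
        sets={name: set(members) for name, members in raw.items()},
        source=str(path),
    )


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    correction: str = "BH",
) -> pd.DataFrame:
    """Score every gene set for over-representation of the query.

    Query genes outside the universe are dropped with a log line; gene sets
    are intersected with the universe before testing.  Returns one row per
    set, sorted by adjusted p ascending (ties by raw p, then set name).
    """
    if correction not in CORRECTIONS:
        raise ConfigurationError(f"correction must be one of {sorted(CORRECTIONS)}")
    universe = set(universe)
    if not universe:
        raise DataError("universe is empty")
    query = set(query)
    stray = query - universe
    if stray:
        logger.info("enrich: dropping %d query genes outside the universe", len(stray))
        query &= universe
    if not query:
        raise DataError("query is empty after filtering to the universe")

    filtered = collection.filtered_to(universe)
    if not filtered.sets:
        raise DataError("no gene set overlaps the universe")

    names = sorted(filtered.sets)
    rows = []
    for name in names:
        members = filtered.sets[name]
        k = len(query & members)
        p = hypergeom_upper_tail(k, len(universe), len(members), len(query))
        rows.append({
            "set_name": name,
            "overlap_count": k,
            "set_size_in_universe": len(members),
            "query_size": len(query),
            "universe_size": len(universe),
            "p_raw": p,
        })
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"], method=CORRECTIONS[correction])[1]
    df = df.sort_values(["p_adjusted", "p_raw", "set_name"])
    return df.reset_index(drop=True)


def pathway_hit_counts(
    de_table: pd.DataFrame,
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> dict[str, int]:
    """Per pathway, the raw count of significant DE genes it contains."""
    sig = significant_genes(de_table, fdr_threshold)
    return {name: len(sig & members) for name, members in collection.sets.items()}


def write_enrichment(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
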