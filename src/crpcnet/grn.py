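"""Tree-ensemble gene-regulatory-network inference and the influence-shift statistic.

Following the GENIE3 scheme, each gene's expression is regressed on the
expression of all transcription factors (excluding itself when the target is
a TF) with a random forest; a TF's importance for a target is its share of
the forest's total variance reduction, normalized so each target's
importances sum to one.  A TF's *network size* in a condition is the number
of targets whose importance exceeds a global threshold, and its *increased
influence* is the after-minus-before difference in network size — the
statistic used to rank nuclear receptors by how much regulatory programme
they gain under androgen deprivation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 1000


def default_importance_threshold(n_tfs: int) -> float:
    """Twice the uniform-attribution level 1/K.

    Under the null, a forest spreads each target's unit importance roughly
    evenly over the K candidate TFs, so an irrelevant TF scores about 1/K;
    a cutoff of 2/K keeps only TFs attributed at least double that share.
    """
    return 2.0 / n_tfs


@dataclass
class RegulatoryNetwork:
    """Importance matrix (TF x target) with a threshold defining discrete edges."""

    importances: pd.DataFrame  # rows = TFs, columns = targets
    tf_list: list[str]
    condition_label: str = ""
    importance_threshold: float = 0.1

    def edges(self) -> pd.DataFrame:
        """Edges with importance above the threshold, as (tf, target, importance)."""
        stacked = self.importances.stack()
        stacked = stacked[stacked > self.importance_threshold]
        df = stacked.rename("importance").reset_index()
        df.columns = ["tf", "target", "importance"]
        return df.sort_values(["tf", "target"]).reset_index(drop=True)


def infer_grn(
    expression: pd.DataFrame,
    tf_list: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    importance_threshold: float | None = None,
    seed: int = 0,
    condition_label: str = "",
    max_features: str | int | float = "sqrt",
) -> RegulatoryNetwork:
    """Fit one random forest per target gene and collect TF importances.

    ``expression`` is genes x samples (assumed normalized; apply log2(x+1)
    upstream if working with counts).  Zero-variance genes are dropped from
    both the predictor and target sides with a logged count.  Candidate
    predictors per split follow the GENIE3 default, sqrt(#TFs); pass
    ``max_features=1.0`` to consider every TF at every split.  A TF is never
    allowed to predict itself, so the network has no self-edges.  When
    ``importance_threshold`` is None, the edge cutoff defaults to twice the
    uniform-attribution level, 2/#TFs (see
    :func:`default_importance_threshold`).
    """
    tf_list = list(dict.fromkeys(tf_list))
    if not tf_list:
        raise ConfigurationError("tf_list is empty")
    if expression.shape[1] < 3:
        raise DataError(
            "need >= 3 samples to fit tree ensembles; pool conditions or add replicates"
        )
    missing = [t for t in tf_list if t not in expression.index]
    if missing:
        raise ConfigurationError(f"TFs absent from the expression matrix: {missing[:10]}")

    variances = expression.var(axis=1)
    constant = variances[variances == 0].index
    if len(constant):
        logger.info("infer_grn: dropping %d zero-variance genes", len(constant))
    expr = expression.drop(index=constant)
    tfs = [t for t in tf_list if t in expr.index]
    if not tfs:
        raise DataError("all TFs have zero variance; nothing to regress on")

    x_all = expr.loc[tfs].to_numpy(dtype=np.float32).T  # samples x TFs
    expr_np = expr.to_numpy(dtype=np.float32)
    targets = list(expr.index)
    tf_pos = {t: i for i, t in enumerate(tfs)}

    imp_mat = np.zeros((len(tfs), len(targets)))
    seeds = np.random.SeedSequence(seed).generate_state(len(targets)) % (2 ** 31)
    for j, gene in enumerate(targets):
        y = expr_np[j]
        if gene in tf_pos:
            keep = np.array([i for i in range(len(tfs)) if i != tf_pos[gene]])
            if keep.size == 0:
                continue
            x = x_all[:, keep]
        else:
            keep = np.arange(len(tfs))
            x = x_all
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(seeds[j]),
            n_jobs=1,
        )
        forest.fit(x, y)
        imp_mat[keep, j] = forest.feature_importances_

    imp = pd.DataFrame(imp_mat, index=pd.Index(tfs, name="tf"),
                       columns=pd.Index(targets, name="target"))

    if importance_threshold is None:
        importance_threshold = default_importance_threshold(len(tfs))
    return RegulatoryNetwork(
        importances=imp,
        tf_list=tfs,
        condition_label=condition_label,
        importance_threshold=importance_threshold,
    )


def network_size(net: RegulatoryNetwork, tf: str) -> int:
    """Number of distinct targets regulated by ``tf`` above the threshold."""
    if tf not in net.tf_list:
        raise ConfigurationError(f"unknown TF {tf!r}; network TFs: {net.tf_list[:10]}...")
    row = net.importances.loc[tf]
    return int((row > net.importance_threshold).sum())


def influence_table(
    sizes_before: Mapping[str, int],
    sizes_after: Mapping[str, int],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank TFs by increased influence given per-condition network sizes.

    Rows are sorted by increased influence descending, ties broken
    lexicographically by TF id, and truncated to ``top_k`` when given.
    """
    tfs = sorted(set(sizes_before) & set(sizes_after))
    rows = [
        {
            "tf": tf,
            "network_size_before": int(sizes_before[tf]),
            "network_size_after": int(sizes_after[tf]),
            "increased_influence": int(sizes_after[tf]) - int(sizes_before[tf]),
        }
        for tf in tfs
    ]
    df = pd.DataFrame(rows, columns=["tf", "network_size_before", "network_size_after",
                                     "increased_influence"])
    df = df.sort_values(["increased_influence", "tf"], ascending=[False, True])
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)


def influence_shift(
    net_before: RegulatoryNetwork,
    net_after: RegulatoryNetwork,
    tf_subset: Iterable[str] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """The ranked influence-shift table between two condition networks."""
    shared = [t for t in net_before.tf_list if t in set(net_after.tf_list)]
    subset = list(tf_subset) if tf_subset is not None else shared
    missing = [t for t in subset if t not in shared]
    if missing:
        raise ConfigurationError(f"TFs missing from one of the networks: {missing}")
    before = {t: network_size(net_before, t) for t in subset}
    after = {t: network_size(net_after, t) for t in subset}
    return influence_table(before, after, top_k=top_k)


def threshold_sweep(
    net_before: RegulatoryNetwork,
    net_after: RegulatoryNetwork,
    thresholds: Sequence[float],
    tf: str,
) -> pd.DataFrame:
    """Sensitivity of one TF's network sizes and shift to the importance cutoff.

    The mapping from a continuous importance matrix to a discrete network
    size depends entirely on this cutoff, so any size-based conclusion should
    be checked across a range of values.
    """
    rows = []
    for thr in thresholds:
        nb = int((net_before.importances.loc[tf] > thr).sum())
        na = int((net_after.importances.loc[tf] > thr).sum())
        rows.append({"threshold": thr, "network_size_before": nb,
                     "network_size_after": na, "increased_influence": na - nb})
    return pd.DataFrame(rows)


def stability_report(
    expr_before: pd.DataFrame,
    expr_after: pd.DataFrame,
    tf_list: Sequence[str],
    seeds: Sequence[int],
    n_trees: int = 100,
    top_n: int = 3,
    **infer_kwargs,
) -> dict:
    """How stable the top of the influence-shift ranking is across seeds.

    Re-runs the two-condition inference once per seed and reports the
    top-``top_n`` TFs of each run plus the fraction of runs agreeing with
    the modal top set.  Informational: forest randomness perturbs
    importances, and a ranking that reshuffles across seeds should not be
    over-interpreted.
    """
    tops = []
    for s in seeds:
        nb = infer_grn(expr_before, tf_list, n_trees=n_trees, seed=s, **infer_kwargs)
        na = infer_grn(expr_after, tf_list, n_trees=n_trees, seed=s, **infer_kwargs)
        table = influence_shift(nb, na, top_k=top_n)
        tops.append(tuple(table["tf"]))
    counts: dict[tuple, int] = {}
    for t in tops:
        counts[t] = counts.get(t, 0) + 1
    modal = max(counts, key=counts.get)
    return {
        "seeds": list(seeds),
        "top_per_seed": [list(t) for t in tops],
        "modal_top": list(modal),
        "agreement_fraction": counts[modal] / len(tops),
    }


def plot_influence_shift(table: pd.DataFrame, path: str | Path) -> None:
    """Horizontal bar chart of increased influence per TF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1.2))
    ordered = table.iloc[::-1]
    ax.barh(ordered["tf"], ordered["increased_influence"], color="#4878d0")
    ax.set_xlabel("increased influence (targets gained)")
    ax.axvline(0, color="black", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_edges(net: RegulatoryNetwork, path: str | Path) -> None:
    net.edges().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_shift_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_run_metadata(path: str | Path, **meta) -> None:
    Path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
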