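"""Synthetic inputs for the network pipeline.

Generates everything the downstream stages consume, so the whole analysis is
testable without any external download:

* paired-condition RNA-seq-like count matrices for two "datasets" (e.g. a
  cell-line contrast and a clinical contrast) with a controlled fraction of
  differentially expressed (DE) genes shared between them;
* a scale-free protein interactome containing one extreme-degree mega-hub,
  mimicking the role ubiquitin C plays in real interaction databases;
* a ground-truth transcription-factor (TF) -> target regulatory structure in
  which one designated "gainer" TF controls many more targets in the second
  condition than in the first, so that influence-shift recovery can be scored
  against a known answer.

All randomness flows from a single design seed through named substreams
(assignment -> counts dataset 1 -> counts dataset 2 -> interactome ->
regulatory truth), so stages can be regenerated independently and
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

# substream indices under SeedSequence(design.seed)
_STREAMS = {
    "assignment": 0,
    "counts1": 1,
    "counts2": 2,
    "interactome": 3,
    "regulatory": 4,
}

CONDITIONS = ("A", "B")  # A = untreated / androgen-sensitive, B = deprived / resistant


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the synthetic study.

    Defaults describe the benchmark conditions used throughout the test
    suite: two contrasts with 10 % DE genes each, half of them shared, a
    1000-node preferential-attachment interactome with a degree-200 hub, and
    a 20-TF regulatory layer with 50 samples per condition (enough for
    tree-ensemble fitting).
    """

    n_genes: int = 220
    n_tfs: int = 20
    n_samples_per_condition: int = 50
    frac_de_dataset1: float = 0.1
    frac_de_dataset2: float = 0.1
    frac_shared_de: float = 0.05
    nb_dispersion: float = 0.1
    mean_log_fc: float = 2.0
    interactome_nodes: int = 1000
    interactome_attachment: int = 2
    hub_degree: int = 200
    tf_out_degree_range: tuple[int, int] = (2, 10)
    gainer_targets: tuple[int, int] = (2, 40)
    regulatory_noise_sd: float = 0.5
    concordant_shared_sign: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_samples_per_condition": self.n_samples_per_condition,
            "interactome_nodes": self.interactome_nodes,
            "interactome_attachment": self.interactome_attachment,
            "hub_degree": self.hub_degree,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name in ("frac_de_dataset1", "frac_de_dataset2", "frac_shared_de"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.frac_shared_de > min(self.frac_de_dataset1, self.frac_de_dataset2):
            raise ConfigurationError(
                "frac_shared_de exceeds min(frac_de_dataset1, frac_de_dataset2)"
            )
        if self.nb_dispersion < 0:
            raise ConfigurationError(f"nb_dispersion must be >= 0, got {self.nb_dispersion!r}")
        if self.regulatory_noise_sd < 0:
            raise ConfigurationError(
                f"regulatory_noise_sd must be >= 0, got {self.regulatory_noise_sd!r}"
            )
        if self.n_tfs >= self.n_genes:
            raise ConfigurationError("n_tfs must be smaller than n_genes")
        lo, hi = self.tf_out_degree_range
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"tf_out_degree_range invalid: {self.tf_out_degree_range!r}")
        if hi > self.n_genes - self.n_tfs:
            raise ConfigurationError(
                "tf_out_degree_range max exceeds the number of available targets "
                f"(n_genes - n_tfs = {self.n_genes - self.n_tfs})"
            )
        if max(self.gainer_targets) > self.n_genes - self.n_tfs:
            raise ConfigurationError("gainer_targets exceeds the number of available targets")
        if self.interactome_nodes <= self.hub_degree:
            raise ConfigurationError("interactome_nodes must exceed hub_degree")
        if self.interactome_attachment >= self.interactome_nodes:
            raise ConfigurationError("interactome_attachment must be < interactome_nodes")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def rng(self, stream: str) -> np.random.Generator:
        """Named RNG substream; identical (seed, stream) always reproduces."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class GroundTruth:
    """Known answers emitted alongside synthetic data."""

    de_genes_1: set[str] = field(default_factory=set)
    de_genes_2: set[str] = field(default_factory=set)
    shared_de: set[str] = field(default_factory=set)
    # (tf, target, weight in condition A, weight in condition B)
    true_edges: list[tuple[str, str, float, float]] = field(default_factory=list)
    hub_id: str | None = None
    gainer_tf: str | None = None

    def to_json(self) -> str:
        payload = {
            "de_genes_1": sorted(self.de_genes_1),
            "de_genes_2": sorted(self.de_genes_2),
            "shared_de": sorted(self.shared_de),
            "true_edges": self.true_edges,
            "hub_id": self.hub_id,
            "gainer_tf": self.gainer_tf,
        }
        return json.dumps(payload, indent=1)


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# DE gene assignment (shared between the two datasets' count generators)
# ---------------------------------------------------------------------------

def de_assignment(design: SyntheticDesign) -> tuple[dict[str, float], dict[str, float], set[str]]:
    """Pick the DE gene sets for both datasets and their log2 fold changes.

    Returns (lfc_dataset1, lfc_dataset2, shared) where each map assigns a
    signed log2 fold change to every DE gene of that dataset.  Shared genes
    get one sign drawn once so direction agrees across datasets (unless
    ``concordant_shared_sign`` is off, in which case signs are independent).
    """
    rng = design.rng("assignment")
    genes = np.array(gene_ids(design.n_genes))
    n_shared = round(design.frac_shared_de * design.n_genes)
    n1 = round(design.frac_de_dataset1 * design.n_genes)
    n2 = round(design.frac_de_dataset2 * design.n_genes)
    n_shared = min(n_shared, n1, n2)

    perm = rng.permutation(design.n_genes)
    shared = genes[perm[:n_shared]]
    only1 = genes[perm[n_shared: n_shared + (n1 - n_shared)]]
    only2 = genes[perm[n_shared + (n1 - n_shared): n_shared + (n1 - n_shared) + (n2 - n_shared)]]

    def _magnitudes(k: int) -> np.ndarray:
        # fold-change magnitudes scatter around the design mean but stay
        # bounded away from zero so every "DE" gene is genuinely shifted
        return np.maximum(rng.normal(design.mean_log_fc, 0.25, size=k), 0.25)

    shared_sign = rng.choice([-1.0, 1.0], size=n_shared)
    lfc1 = dict(zip(shared, shared_sign * _magnitudes(n_shared)))
    if design.concordant_shared_sign:
        sign2 = np.sign(list(lfc1.values())) if n_shared else np.array([])
        lfc2 = dict(zip(shared, sign2 * _magnitudes(n_shared)))
    else:
        lfc2 = dict(zip(shared, rng.choice([-1.0, 1.0], size=n_shared) * _magnitudes(n_shared)))
    lfc1.update(zip(only1, rng.choice([-1.0, 1.0], size=len(only1)) * _magnitudes(len(only1))))
    lfc2.update(zip(only2, rng.choice([-1.0, 1.0], size=len(only2)) * _magnitudes(len(only2))))
    return lfc1, lfc2, set(shared)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts, mean/dispersion form: var = mu + phi*mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_counts(
    design: SyntheticDesign, dataset_index: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Paired-condition count matrix for one of the two synthetic datasets.

    Rows are genes, columns ``A_1..A_n, B_1..B_n``.  Non-DE genes share one
    negative-binomial mean across conditions; DE genes have their condition-B
    mean multiplied by ``2**lfc`` with the gene's assigned log fold change.
    """
    if dataset_index not in (1, 2):
        raise ConfigurationError(f"dataset_index must be 1 or 2, got {dataset_index!r}")
    lfc1, lfc2, shared = de_assignment(design)
    lfc = lfc1 if dataset_index == 1 else lfc2
    rng = design.rng(f"counts{dataset_index}")

    genes = gene_ids(design.n_genes)
    n = design.n_samples_per_condition
    base = np.exp(rng.normal(np.log(100.0), 1.0, size=design.n_genes))
    base = np.maximum(base, 5.0)
    fold = np.array([2.0 ** lfc.get(g, 0.0) for g in genes])

    mat = np.empty((design.n_genes, 2 * n), dtype=np.int64)
    for j in range(n):
        mat[:, j] = _nb_draw(rng, base, design.nb_dispersion)
    for j in range(n):
        mat[:, n + j] = _nb_draw(rng, base * fold, design.nb_dispersion)
    # guarantee no all-zero rows: resample the cheapest sample until nonzero
    zero_rows = np.flatnonzero(mat.sum(axis=1) == 0)
    for i in zero_rows:
        while mat[i].sum() == 0:
            mat[i, 0] = _nb_draw(rng, np.array([base[i]]), design.nb_dispersion)[0]

    cols = [f"A_{j + 1}" for j in range(n)] + [f"B_{j + 1}" for j in range(n)]
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=cols)
    truth = GroundTruth(
        de_genes_1=set(lfc1),
        de_genes_2=set(lfc2),
        shared_de=shared,
    )
    return df, truth


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def generate_interactome(design: SyntheticDesign) -> tuple[nx.Graph, str]:
    """Scale-free interactome with one designated mega-hub.

    Built by preferential attachment, then the highest-degree node is wired
    to additional random partners until it reaches ``hub_degree`` — the
    stand-in for an extreme hub like ubiquitin C, which hub-removal filtering
    is meant to strip.
    """
    rng = design.rng("interactome")
    g = nx.barabasi_albert_graph(
        design.interactome_nodes,
        design.interactome_attachment,
        seed=int(rng.integers(2 ** 31)),
    )
    hub = max(g.degree, key=lambda kv: (kv[1], -kv[0]))[0]
    others = [v for v in g.nodes if v != hub and not g.has_edge(hub, v)]
    deficit = design.hub_degree - g.degree[hub]
    if deficit > 0:
        extra = rng.choice(len(others), size=min(deficit, len(others)), replace=False)
        g.add_edges_from((hub, others[i]) for i in extra)

    names = gene_ids(max(design.interactome_nodes, design.n_genes))[: design.interactome_nodes]
    mapping = dict(zip(range(design.interactome_nodes), names))
    g = nx.relabel_nodes(g, mapping)
    return g, mapping[hub]


# ---------------------------------------------------------------------------
# Regulatory ground truth
# ---------------------------------------------------------------------------

def generate_regulatory_truth(
    design: SyntheticDesign,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Expression matrices realizing a known TF -> target structure.

    TF expression is i.i.d. standard normal; every regulated target is a
    linear combination of its TFs plus Gaussian noise.  The first TF is the
    "gainer": it drives ``gainer_targets[0]`` targets in condition A and
    ``gainer_targets[1]`` in condition B (a superset), emulating a receptor
    that assumes a much larger regulatory programme after treatment.
    Unregulated background genes are i.i.d. standard normal.
    """
    rng = design.rng("regulatory")
    genes = gene_ids(design.n_genes)
    tfs = genes[: design.n_tfs]
    targets_pool = genes[design.n_tfs:]
    gainer = tfs[0]

    lo, hi = design.tf_out_degree_range
    edges: list[tuple[str, str, float, float]] = []

    def _weights(k: int) -> np.ndarray:
        return rng.uniform(0.5, 2.0, size=k) * rng.choice([-1.0, 1.0], size=k)

    n_a, n_b = design.gainer_targets
    gainer_b = list(rng.choice(targets_pool, size=n_b, replace=False))
    gainer_a = gainer_b[:n_a]  # condition-A targets are a subset of B's
    w_b = _weights(n_b)
    for t, wb in zip(gainer_b, w_b):
        wa = wb if t in gainer_a else 0.0
        edges.append((gainer, t, float(wa), float(wb)))

    for tf in tfs[1:]:
        k = int(rng.integers(lo, hi + 1))
        tf_targets = rng.choice(targets_pool, size=k, replace=False)
        for t, w in zip(tf_targets, _weights(k)):
            edges.append((tf, str(t), float(w), float(w)))

    regulators: dict[str, list[tuple[int, float, float]]] = {}
    tf_index = {tf: i for i, tf in enumerate(tfs)}
    for tf, t, wa, wb in edges:
        regulators.setdefault(t, []).append((tf_index[tf], wa, wb))

    n = design.n_samples_per_condition
    matrices: dict[str, pd.DataFrame] = {}
    for ci, cond in enumerate(CONDITIONS):
        tf_expr = rng.normal(size=(design.n_tfs, n))
        mat = np.empty((design.n_genes, n))
        mat[: design.n_tfs] = tf_expr
        for gi, g in enumerate(targets_pool, start=design.n_tfs):
            regs = regulators.get(g)
            if regs:
                y = np.zeros(n)
                for ti, wa, wb in regs:
                    y += (wa if ci == 0 else wb) * tf_expr[ti]
                if design.regulatory_noise_sd > 0:
                    y = y + rng.normal(0, design.regulatory_noise_sd, size=n)
                mat[gi] = y
            else:
                mat[gi] = rng.normal(size=n)
        matrices[cond] = pd.DataFrame(
            mat, index=pd.Index(genes, name="gene"), columns=[f"{cond}_{j + 1}" for j in range(n)]
        )

    truth = GroundTruth(true_edges=edges, gainer_tf=gainer)
    return matrices, truth


def generate_all(design: SyntheticDesign) -> dict:
    """Run all three generators in their documented substream order."""
    counts1, truth = generate_counts(design, 1)
    counts2, _ = generate_counts(design, 2)
    interactome, hub_id = generate_interactome(design)
    grn_matrices, grn_truth = generate_regulatory_truth(design)
    truth.hub_id = hub_id
    truth.true_edges = grn_truth.true_edges
    truth.gainer_tf = grn_truth.gainer_tf
    return {
        "counts1": counts1,
        "counts2": counts2,
        "interactome": interactome,
        "grn_matrices": grn_matrices,
        "truth": truth,
        "tf_list": gene_ids(design.n_genes)[: design.n_tfs],
    }


# ---------------------------------------------------------------------------
# Writers (all outputs carry a provenance comment line)
# ---------------------------------------------------------------------------

def _header(design: SyntheticDesign) -> str:
    return f"# design_hash={design.hash()} seed={design.seed}\n"


def write_counts_tsv(df: pd.DataFrame, path: str | Path, design: SyntheticDesign) -> None:
    with open(path, "w") as fh:
        fh.write(_header(design))
        df.to_csv(fh, sep="\t")


def write_interactome_tsv(g: nx.Graph, path: str | Path, design: SyntheticDesign) -> None:
    with open(path, "w") as fh:
        fh.write(_header(design))
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def write_truth_json(truth: GroundTruth, path: str | Path, design: SyntheticDesign) -> None:
    payload = json.loads(truth.to_json())
    payload["_provenance"] = {"design_hash": design.hash(), "seed": design.seed}
    Path(path).write_text(json.dumps(payload, indent=1))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
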