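"""End-to-end orchestration: DE overlap -> disrupted network -> GRN shift -> enrichment.

A :class:`PipelineConfig` names the inputs (either precomputed DE tables or
count matrices for the stand-in caller, an interactome edge list, a TF list,
per-condition expression matrices, and optionally a GMT collection) and the
thresholds.  ``run_pipeline`` executes the stages in order, writes per-stage
artifacts stamped with the config hash, and returns a combined report.
``run_demo`` generates a full synthetic study first, so the whole pipeline
runs with no external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import de_overlap, disrupted, enrichment, grn, synthetic
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Either ``de_table1``/``de_table2`` (edgeR-style TSVs) or
    ``counts1``/``counts2`` (count TSVs scored by the stand-in caller) must
    be provided for the overlap stage.  ``expr_before``/``expr_after`` are
    normalized expression matrices for the two GRN conditions.
    """

    output_dir: str = "crpcnet_out"
    de_table1: str | None = None
    de_table2: str | None = None
    counts1: str | None = None
    counts2: str | None = None
    interactome: str | None = None
    tf_list: str | None = None
    expr_before: str | None = None
    expr_after: str | None = None
    gmt: str | None = None
    id_mapping: str | None = None
    fdr_threshold: float = 0.05
    require_concordant_sign: bool = False
    hub_degree_cutoff: int = disrupted.DEFAULT_HUB_CUTOFF
    n_trees: int = grn.DEFAULT_N_TREES
    importance_threshold: float | None = None  # None -> 2 / #TFs
    top_k: int = 10
    seed: int = 0
    correction: str = "BH"
    force_include: list[str] = field(default_factory=list)
    log2_transform: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigurationError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")
        if self.importance_threshold is not None and self.importance_threshold < 0:
            raise ConfigurationError("importance_threshold must be >= 0")
        if self.n_trees < 1 or self.top_k < 1 or self.hub_degree_cutoff < 1:
            raise ConfigurationError("n_trees, top_k and hub_degree_cutoff must be >= 1")
        if self.correction not in enrichment.CORRECTIONS:
            raise ConfigurationError(f"correction must be one of {sorted(enrichment.CORRECTIONS)}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(stray)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise ConfigurationError(f"no {what} configured")
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"{what} file not found: {p}")
    return p


def _read_matrix(path: Path, current_hash: str | None = None) -> pd.DataFrame:
    if current_hash is not None:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# config_hash=") and first.strip() != f"# config_hash={current_hash}":
            logger.warning(
                "%s was produced by a different pipeline config (%s); re-using it here",
                path, first.strip().split("=", 1)[1],
            )
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def _condition_labels(columns) -> list[str]:
    # sample columns are named <condition>_<replicate>
    return [c.split("_", 1)[0] for c in columns]


def _stamp(path: Path, config_hash: str) -> None:
    text = path.read_text()
    path.write_text(f"# config_hash={config_hash}\n{text}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the combined report dict.

    A stage failure aborts the run with the stage name in the exception and
    leaves a FAILED marker next to the partial artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    report: dict = {
        "provenance": {
            "config": asdict(config),
            "config_hash": chash,
            "seed": config.seed,
            "crpcnet_version": __version__,
            "python": sys.version.split()[0],
        }
    }
    stage = "setup"
    try:
        # ---- stage 1: DE tables and overlap -------------------------------
        stage = "de_overlap"
        if config.de_table1 and config.de_table2:
            t1 = de_overlap.read_de_table(_require(config.de_table1, "DE table 1"))
            t2 = de_overlap.read_de_table(_require(config.de_table2, "DE table 2"))
        elif config.counts1 and config.counts2:
            c1 = _read_matrix(_require(config.counts1, "counts matrix 1"), chash)
            c2 = _read_matrix(_require(config.counts2, "counts matrix 2"), chash)
            t1 = de_overlap.call_de_standin(c1, _condition_labels(c1.columns),
                                            config.fdr_threshold)
            t2 = de_overlap.call_de_standin(c2, _condition_labels(c2.columns),
                                            config.fdr_threshold)
        else:
            raise ConfigurationError(
                "configure either de_table1/de_table2 or counts1/counts2"
            )
        common = de_overlap.common_de(
            t1, t2, config.fdr_threshold, config.require_concordant_sign
        )
        universe = de_overlap.tested_universe(t1, t2)
        sig1 = de_overlap.significant_genes(t1, config.fdr_threshold) & universe
        sig2 = de_overlap.significant_genes(t2, config.fdr_threshold) & universe
        overlap = de_overlap.overlap_test(len(universe), sig1, sig2)
        (out / "overlap.json").write_text(overlap.to_json())
        synthetic.write_gene_list(common, out / "common_genes.tsv")
        _stamp(out / "overlap.json", chash)
        _stamp(out / "common_genes.tsv", chash)
        report["overlap"] = json.loads(overlap.to_json())
        report["n_common_de"] = len(common)

        de_either = sorted(
            (de_overlap.significant_genes(t1, config.fdr_threshold)
             | de_overlap.significant_genes(t2, config.fdr_threshold))
        )

        # ---- stage 2: disrupted network -----------------------------------
        if config.interactome:
            stage = "disrupted_network"
            g = disrupted.load_interactome(
                _require(config.interactome, "interactome"), config.hub_degree_cutoff
            )
            query = list(common)
            if config.id_mapping:
                mapping = disrupted.read_id_mapping(_require(config.id_mapping, "id mapping"))
                query = disrupted.apply_id_mapping(query, mapping)
                de_either = disrupted.apply_id_mapping(de_either, mapping)
            net = disrupted.build_disrupted(
                g, query, de_either=de_either, force_include=config.force_include
            )
            disrupted.write_network(
                net, out / "disrupted_edges.tsv", out / "disrupted.graphml",
                out / "disrupted_stats.json",
            )
            _stamp(out / "disrupted_edges.tsv", chash)
            _stamp(out / "disrupted_stats.json", chash)
            report["disrupted_network"] = net.stats

        # ---- stage 3: GRN inference + influence shift ---------------------
        if config.expr_before and config.expr_after and config.tf_list:
            stage = "grn_influence"
            tfs = [
                line.strip()
                for line in _require(config.tf_list, "TF list").read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
            nets = {}
            for label, path in (("before", config.expr_before), ("after", config.expr_after)):
                expr = _read_matrix(_require(path, f"expression matrix ({label})"), chash)
                if config.log2_transform:
                    import numpy as np
                    expr = np.log2(expr + 1.0)
                nets[label] = grn.infer_grn(
                    expr, tfs, n_trees=config.n_trees,
                    importance_threshold=config.importance_threshold,
                    seed=config.seed, condition_label=label,
                )
                grn.write_edges(nets[label], out / f"grn_edges_{label}.tsv")
                _stamp(out / f"grn_edges_{label}.tsv", chash)
            shift = grn.influence_shift(nets["before"], nets["after"], top_k=config.top_k)
            grn.write_shift_table(shift, out / "influence_shift.tsv")
            _stamp(out / "influence_shift.tsv", chash)
            grn.plot_influence_shift(shift, out / "influence_shift.png")
            grn.write_run_metadata(
                out / "grn_metadata.json", seed=config.seed, n_trees=config.n_trees,
                importance_threshold=nets["after"].importance_threshold, config_hash=chash,
            )
            report["influence_shift"] = shift.to_dict(orient="records")

        # ---- stage 4: enrichment ------------------------------------------
        if config.gmt:
            stage = "enrichment"
            collection = enrichment.read_gene_sets(_require(config.gmt, "GMT file"))
            if common:
                table = enrichment.enrich(common, collection, universe, config.correction)
                enrichment.write_enrichment(table, out / "enrichment_common.tsv")
                _stamp(out / "enrichment_common.tsv", chash)
                report["enrichment_common"] = table.head(20).to_dict(orient="records")
            counts = {
                "dataset1": enrichment.pathway_hit_counts(t1, collection, config.fdr_threshold),
                "dataset2": enrichment.pathway_hit_counts(t2, collection, config.fdr_threshold),
            }
            (out / "pathway_hit_counts.json").write_text(json.dumps(counts, indent=1))
            report["pathway_hit_counts"] = counts
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1))
    (out / "summary.txt").write_text(_summary(report))
    return report


def _summary(report: dict) -> str:
    lines = [f"crpcnet {__version__} run (config {report['provenance']['config_hash']})"]
    if "overlap" in report:
        ov = report["overlap"]
        lines.append(
            f"DE overlap: {ov['overlap_size']} genes shared "
            f"(|set1|={ov['set1_size']}, |set2|={ov['set2_size']}, "
            f"N={ov['universe_size']}, hypergeometric p={ov['p_hypergeometric']:.3g})"
        )
        lines.append(f"Common DE genes (after sign filter if enabled): {report['n_common_de']}")
    if "disrupted_network" in report:
        s = report["disrupted_network"]
        lines.append(
            f"Disrupted network: {s['n_nodes']} proteins, {s['n_edges']} interactions; "
            f"{s['frac_de']:.0%} with DE evidence"
        )
    if "influence_shift" in report:
        lines.append("Top TFs by increased influence:")
        for row in report["influence_shift"][:10]:
            lines.append(
                f"  {row['tf']}: {row['network_size_before']} -> "
                f"{row['network_size_after']} (Δ{row['increased_influence']:+d})"
            )
    if "enrichment_common" in report:
        lines.append("Top enriched sets (common DE genes):")
        for row in report["enrichment_common"][:5]:
            lines.append(
                f"  {row['set_name']}: {row['overlap_count']}/{row['set_size_in_universe']} "
                f"genes, adj p={row['p_adjusted']:.3g}"
            )
    return "\n".join(lines) + "\n"


def run_demo(
    output_dir: str | Path,
    design: synthetic.SyntheticDesign | None = None,
    n_trees: int = 100,
) -> dict:
    """Generate a full synthetic study and run the whole pipeline on it.

    ``n_trees`` defaults below the production setting so the demo finishes in
    about a minute on one core.
    """
    design = design or synthetic.SyntheticDesign()
    out = Path(output_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    data = synthetic.generate_all(design)
    synthetic.write_counts_tsv(data["counts1"], inputs / "counts1.tsv", design)
    synthetic.write_counts_tsv(data["counts2"], inputs / "counts2.tsv", design)
    synthetic.write_interactome_tsv(data["interactome"], inputs / "interactome.tsv", design)
    synthetic.write_counts_tsv(data["grn_matrices"]["A"], inputs / "expr_before.tsv", design)
    synthetic.write_counts_tsv(data["grn_matrices"]["B"], inputs / "expr_after.tsv", design)
    synthetic.write_gene_list(data["tf_list"], inputs / "tf_list.txt")
    synthetic.write_truth_json(data["truth"], inputs / "truth.json", design)
    _write_demo_gmt(data, inputs / "sets.gmt")

    config = PipelineConfig(
        output_dir=str(out),
        counts1=str(inputs / "counts1.tsv"),
        counts2=str(inputs / "counts2.tsv"),
        interactome=str(inputs / "interactome.tsv"),
        tf_list=str(inputs / "tf_list.txt"),
        expr_before=str(inputs / "expr_before.tsv"),
        expr_after=str(inputs / "expr_after.tsv"),
        gmt=str(inputs / "sets.gmt"),
        hub_degree_cutoff=design.hub_degree // 2,
        n_trees=n_trees,
        seed=design.seed,
    )
    return run_pipeline(config)


def _write_demo_gmt(data: dict, path: Path) -> None:
    """Three fixture sets: the true shared-DE genes, a decoy, and the TFs."""
    truth = data["truth"]
    genes = list(data["counts1"].index)
    decoy = [g for g in genes if g not in truth.shared_de][:30]
    with open(path, "w") as fh:
        fh.write("shared_de_truth\tsynthetic\t" + "\t".join(sorted(truth.shared_de)) + "\n")
        fh.write("decoy_set\tsynthetic\t" + "\t".join(decoy) + "\n")
        fh.write("tf_panel\tsynthetic\t" + "\t".join(data["tf_list"]) + "\n")
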