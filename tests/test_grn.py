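"""Regulatory-network inference and the influence-shift statistic."""

import numpy as np
import pandas as pd
import pytest

from crpcnet.errors import ConfigurationError, DataError
from crpcnet.grn import (
    default_importance_threshold,
    infer_grn,
    influence_shift,
    influence_table,
    network_size,
    threshold_sweep,
)

# Published per-receptor network sizes (before, after) used as worked examples:
# the human-tumour contrast (hormone naive -> resistant) and the cell-line
# contrast (androgen-sensitive -> androgen-independent).
TUMOUR_SIZES = {
    "PGR": (28, 114), "ESRRA": (2, 77), "PPARD": (2, 65), "THRB": (32, 95),
    "ESR2": (29, 67), "NR2F6": (4, 37), "NR4A2": (5, 35), "ESRRG": (21, 41),
    "RXRG": (7, 24), "NR1I3": (26, 39),
}
CELL_LINE_SIZES = {
    "PGR": (1, 53), "RXRA": (3, 52), "RARG": (2, 44), "RORA": (0, 30),
    "NR4A3": (1, 29), "NR5A2": (0, 27), "ESR2": (0, 23), "VDR": (18, 41),
    "NR2C1": (0, 22), "ESRRG": (22, 42),
}


def _toy_expression(seed=0, n_tfs=20, n_samples=50, noise=0.0, weight=3.0):
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i}" for i in range(n_tfs)]
    x = rng.normal(size=(n_tfs, n_samples))
    y = weight * x[0] + (rng.normal(0, noise, n_samples) if noise else 0.0)
    expr = pd.DataFrame(
        np.vstack([x, y]), index=tfs + ["TARGET"],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return expr, tfs


class TestInferGrn:
    def test_noiseless_regulator_dominates_with_all_feature_splits(self):
        expr, tfs = _toy_expression()
        net = infer_grn(expr, tfs, n_trees=100, seed=1, max_features=1.0)
        assert net.importances.loc["TF0", "TARGET"] > 0.9

    def test_noiseless_regulator_top_ranked_under_sqrt_splits(self):
        expr, tfs = _toy_expression()
        net = infer_grn(expr, tfs, n_trees=100, seed=1)
        assert net.importances["TARGET"].idxmax() == "TF0"

    def test_tf_never_predicts_itself(self):
        expr, tfs = _toy_expression()
        net = infer_grn(expr, tfs, n_trees=20, seed=0)
        for tf in tfs:
            assert net.importances.loc[tf, tf] == 0.0
        edges = net.edges()
        assert not ((edges["tf"] == edges["target"]).any())

    def test_importances_normalized_per_target(self):
        expr, tfs = _toy_expression(noise=0.5)
        net = infer_grn(expr, tfs, n_trees=50, seed=2)
        sums = net.importances.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_zero_variance_genes_dropped(self):
        expr, tfs = _toy_expression()
        expr.loc["FLAT"] = 1.0
        net = infer_grn(expr, tfs, n_trees=20, seed=0)
        assert "FLAT" not in net.importances.columns

    def test_deterministic_under_seed(self):
        expr, tfs = _toy_expression(noise=0.5)
        n1 = infer_grn(expr, tfs, n_trees=30, seed=5)
        n2 = infer_grn(expr, tfs, n_trees=30, seed=5)
        pd.testing.assert_frame_equal(n1.importances, n2.importances)

    def test_too_few_samples_rejected(self):
        expr, tfs = _toy_expression(n_samples=2)
        with pytest.raises(DataError, match="3 samples"):
            infer_grn(expr, tfs)

    def test_empty_tf_list_rejected(self):
        expr, _ = _toy_expression()
        with pytest.raises(ConfigurationError, match="empty"):
            infer_grn(expr, [])

    def test_unknown_tf_rejected(self):
        expr, tfs = _toy_expression()
        with pytest.raises(ConfigurationError, match="NOPE"):
            infer_grn(expr, tfs + ["NOPE"])

    def test_default_threshold_is_twice_uniform(self):
        expr, tfs = _toy_expression()
        net = infer_grn(expr, tfs, n_trees=20, seed=0)
        assert net.importance_threshold == pytest.approx(2 / 20)
        assert default_importance_threshold(48) == pytest.approx(2 / 48)


class TestNetworkSize:
    def _net(self, threshold):
        expr, tfs = _toy_expression(noise=0.3)
        return infer_grn(expr, tfs, n_trees=30, seed=1,
                         importance_threshold=threshold), tfs

    def test_zero_threshold_counts_all_modelled_targets(self):
        net, tfs = self._net(0.0)
        # every target except TF0 itself receives some importance from TF0
        assert network_size(net, "TF0") == net.importances.shape[1] - 1

    def test_huge_threshold_gives_zero(self):
        net, _ = self._net(2.0)
        assert network_size(net, "TF3") == 0

    def test_unknown_tf_rejected(self):
        net, _ = self._net(0.1)
        with pytest.raises(ConfigurationError, match="unknown TF"):
            network_size(net, "NOPE")


class TestInfluenceShift:
    def test_tumour_worked_example_pgr(self):
        table = influence_table({t: b for t, (b, a) in TUMOUR_SIZES.items()},
                                {t: a for t, (b, a) in TUMOUR_SIZES.items()})
        pgr = table[table["tf"] == "PGR"].iloc[0]
        assert pgr["increased_influence"] == 86
        assert table.iloc[0]["tf"] == "PGR"  # largest gain of all receptors

    def test_cell_line_worked_example_pgr(self):
        table = influence_table({t: b for t, (b, a) in CELL_LINE_SIZES.items()},
                                {t: a for t, (b, a) in CELL_LINE_SIZES.items()})
        pgr = table[table["tf"] == "PGR"].iloc[0]
        assert pgr["increased_influence"] == 52
        assert table.iloc[0]["tf"] == "PGR"

    def test_published_rankings_reproduced_by_tie_break(self):
        """Descending shift with lexicographic ties reproduces both published
        top-ten orderings exactly."""
        tumour = influence_table({t: b for t, (b, a) in TUMOUR_SIZES.items()},
                                 {t: a for t, (b, a) in TUMOUR_SIZES.items()}, top_k=10)
        assert list(tumour["tf"]) == ["PGR", "ESRRA", "PPARD", "THRB", "ESR2",
                                      "NR2F6", "NR4A2", "ESRRG", "RXRG", "NR1I3"]
        cell = influence_table({t: b for t, (b, a) in CELL_LINE_SIZES.items()},
                               {t: a for t, (b, a) in CELL_LINE_SIZES.items()}, top_k=10)
        assert list(cell["tf"]) == ["PGR", "RXRA", "RARG", "RORA", "NR4A3",
                                    "NR5A2", "ESR2", "VDR", "NR2C1", "ESRRG"]

    def test_identical_networks_give_zero_shift(self):
        expr, tfs = _toy_expression(noise=0.3)
        net = infer_grn(expr, tfs, n_trees=30, seed=1)
        table = influence_shift(net, net)
        assert (table["increased_influence"] == 0).all()

    def test_antisymmetric(self):
        expr, tfs = _toy_expression(noise=0.3)
        n1 = infer_grn(expr, tfs, n_trees=30, seed=1)
        expr2 = expr.sample(frac=1.0, axis=1, random_state=3)
        n2 = infer_grn(expr2, tfs, n_trees=30, seed=9)
        fwd = influence_shift(n1, n2).set_index("tf")
        rev = influence_shift(n2, n1).set_index("tf").reindex(fwd.index)
        assert (fwd["increased_influence"] == -rev["increased_influence"]).all()

    def test_missing_tf_subset_rejected(self):
        expr, tfs = _toy_expression()
        net = infer_grn(expr, tfs, n_trees=10, seed=0)
        with pytest.raises(ConfigurationError, match="GHOST"):
            influence_shift(net, net, tf_subset=["GHOST"])

    def test_top_k_truncates(self):
        table = influence_table({t: b for t, (b, a) in TUMOUR_SIZES.items()},
                                {t: a for t, (b, a) in TUMOUR_SIZES.items()}, top_k=3)
        assert len(table) == 3

    def test_stability_report_perfect_agreement_on_strong_signal(self):
        """With a single dominant regulator, the top of the shift ranking is
        identical across seeds."""
        from crpcnet.grn import stability_report

        rng = np.random.default_rng(4)
        tfs = [f"TF{i}" for i in range(5)]
        x = rng.normal(size=(5, 40))
        before = pd.DataFrame(
            np.vstack([x, rng.normal(size=(3, 40))]),
            index=tfs + ["T1", "T2", "T3"],
            columns=[f"s{i}" for i in range(40)],
        )
        after = before.copy()
        after.loc[["T1", "T2", "T3"]] = 2.0 * x[0] + rng.normal(0, 0.2, (3, 40))
        report = stability_report(before, after, tfs, seeds=range(5), n_trees=30)
        assert report["agreement_fraction"] == 1.0
        assert report["modal_top"][0] == "TF0"

    def test_threshold_sweep_monotone_in_threshold(self):
        expr, tfs = _toy_expression(noise=0.3)
        net = infer_grn(expr, tfs, n_trees=30, seed=1)
        sweep = threshold_sweep(net, net, [0.0, 0.05, 0.1, 0.5], tf="TF0")
        assert sweep["network_size_before"].is_monotonic_decreasing
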