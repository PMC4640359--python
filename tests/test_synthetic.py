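"""The synthetic generators: determinism, forced structure, and realism checks."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crpcnet.de_overlap import call_de_standin, significant_genes
from crpcnet.disrupted import load_interactome
from crpcnet.errors import ConfigurationError
from crpcnet.synthetic import (
    SyntheticDesign,
    de_assignment,
    generate_counts,
    generate_interactome,
    generate_regulatory_truth,
    write_interactome_tsv,
)


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(frac_shared_de=0.2, frac_de_dataset1=0.1), "frac_shared_de"),
            (dict(n_tfs=200, n_genes=100, interactome_nodes=300), "n_tfs"),
            (dict(frac_de_dataset1=1.5), "frac_de_dataset1"),
            (dict(nb_dispersion=-1), "nb_dispersion"),
            (dict(n_genes=0), "n_genes"),
            (dict(tf_out_degree_range=(2, 500)), "tf_out_degree_range"),
            (dict(interactome_nodes=100, hub_degree=150), "interactome_nodes"),
        ],
    )
    def test_invalid_design_names_offending_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SyntheticDesign(**kwargs)


class TestCounts:
    def test_identical_seed_gives_byte_identical_counts(self):
        d = SyntheticDesign(seed=11)
        df1, t1 = generate_counts(d, 1)
        df2, t2 = generate_counts(d, 1)
        pd.testing.assert_frame_equal(df1, df2)
        assert t1.de_genes_1 == t2.de_genes_1

    def test_no_de_requested_gives_empty_truth(self):
        d = SyntheticDesign(frac_de_dataset1=0, frac_shared_de=0, seed=1)
        _, truth = generate_counts(d, 1)
        assert truth.de_genes_1 == set()

    def test_shared_de_size_forced_by_fractions(self):
        d = SyntheticDesign(n_genes=1000, frac_de_dataset1=0.1,
                            frac_de_dataset2=0.1, frac_shared_de=0.05, seed=3)
        _, truth = generate_counts(d, 1)
        assert len(truth.shared_de) == 50
        assert truth.shared_de == truth.de_genes_1 & truth.de_genes_2

    def test_shared_genes_concordant_sign_across_datasets(self):
        d = SyntheticDesign(n_genes=500, seed=5)
        lfc1, lfc2, shared = de_assignment(d)
        assert shared == set(lfc1) & set(lfc2)
        for g in shared:
            assert np.sign(lfc1[g]) == np.sign(lfc2[g])

    def test_no_all_zero_rows(self):
        d = SyntheticDesign(n_genes=300, nb_dispersion=2.0, seed=2)
        df, _ = generate_counts(d, 1)
        assert (df.sum(axis=1) > 0).all()

    def test_standin_caller_recovers_true_de(self):
        """Power check: at log2FC ~ 2 and n=5/condition the stand-in caller
        finds >= 80 % of true DE genes at FDR < 0.05 (Monte-Carlo)."""
        recalls = []
        for seed in range(1, 21):
            d = SyntheticDesign(n_genes=1000, n_samples_per_condition=5,
                                mean_log_fc=2.0, nb_dispersion=0.1, seed=seed)
            counts, truth = generate_counts(d, 1)
            table = call_de_standin(counts, [c.split("_")[0] for c in counts.columns])
            sig = significant_genes(table, 0.05)
            recalls.append(len(sig & truth.de_genes_1) / len(truth.de_genes_1))
        assert np.mean(recalls) >= 0.8


class TestInteractome:
    def test_exactly_one_mega_hub(self):
        d = SyntheticDesign(interactome_nodes=100, hub_degree=50, seed=4)
        g, hub = generate_interactome(d)
        big = [v for v, deg in g.degree if deg >= 50]
        assert big == [hub]

    def test_round_trips_through_loader(self, tmp_path):
        d = SyntheticDesign(seed=9)
        g, _ = generate_interactome(d)
        path = tmp_path / "net.tsv"
        write_interactome_tsv(g, path, d)
        g2 = load_interactome(path, hub_degree_cutoff=10 ** 6)
        assert set(g2.nodes) == set(g.nodes)
        assert {frozenset(e) for e in g2.edges} == {frozenset(e) for e in g.edges}

    def test_degree_distribution_heavy_tailed(self):
        for seed in range(1, 11):
            d = SyntheticDesign(interactome_nodes=1000, seed=seed)
            g, _ = generate_interactome(d)
            degs = np.array([deg for _, deg in g.degree])
            assert degs.max() / np.median(degs) > 5

    def test_simple_and_connected(self):
        for seed in (1, 2, 3):
            d = SyntheticDesign(seed=seed)
            g, _ = generate_interactome(d)
            assert nx.number_of_selfloops(g) == 0
            lcc = max(nx.connected_components(g), key=len)
            assert len(lcc) / g.number_of_nodes() >= 0.9


class TestRegulatoryTruth:
    def test_gainer_delta_forced_by_construction(self):
        d = SyntheticDesign(gainer_targets=(2, 40), seed=6)
        _, truth = generate_regulatory_truth(d)
        gainer_edges = [e for e in truth.true_edges if e[0] == truth.gainer_tf]
        n_a = sum(1 for _, _, wa, _ in gainer_edges if wa != 0)
        n_b = sum(1 for _, _, _, wb in gainer_edges if wb != 0)
        assert (n_a, n_b) == (2, 40)
        assert n_b - n_a == 38

    def test_noiseless_targets_are_exact_linear_functions(self):
        d = SyntheticDesign(n_genes=50, n_tfs=5, n_samples_per_condition=10,
                            regulatory_noise_sd=0.0, tf_out_degree_range=(1, 5),
                            gainer_targets=(1, 5), interactome_nodes=100,
                            hub_degree=20, seed=8)
        mats, truth = generate_regulatory_truth(d)
        for cond, wi in (("A", 2), ("B", 3)):
            expr = mats[cond]
            by_target = {}
            for tf, t, wa, wb in truth.true_edges:
                w = (wa, wb)[wi - 2]
                if w != 0:
                    by_target.setdefault(t, []).append((tf, w))
            for target, regs in by_target.items():
                expected = sum(w * expr.loc[tf] for tf, w in regs)
                np.testing.assert_allclose(expr.loc[target], expected, atol=1e-9)

    def test_matrices_deterministic_under_seed(self):
        d = SyntheticDesign(seed=12)
        m1, _ = generate_regulatory_truth(d)
        m2, _ = generate_regulatory_truth(d)
        pd.testing.assert_frame_equal(m1["A"], m2["A"])
        pd.testing.assert_frame_equal(m1["B"], m2["B"])
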