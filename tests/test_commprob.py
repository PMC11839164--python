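import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import synocross as sx
from synocross.errors import SynocrossError, ValidationError
from conftest import toy_two_cluster_dataset
from oracles import tensor_oracle, trimean_oracle


class TestTrimean:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 2, 2, 2], 2.0),
            ([0, 1, 2, 3, 4], 2.0),
            ([0, 0, 0, 0, 10], 0.0),  # <25% expressing cells contribute zero
        ],
    )
    def test_known_values(self, values, expected):
        assert sx.trimean(values) == pytest.approx(expected, abs=1e-15)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            sx.trimean([])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_within_sample_range_and_order_invariant(self, values):
        t = sx.trimean(values)
        assert min(values) - 1e-9 <= t <= max(values) + 1e-9
        assert sx.trimean(list(reversed(values))) == pytest.approx(t, abs=1e-9)


class TestHillProbability:
    def test_zero_ligand_gives_zero(self):
        assert sx.hill_probability(0.0, 3.7, 0.5) == 0.0

    def test_half_saturation(self):
        assert sx.hill_probability(2.0, 0.25, 0.5) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert sx.hill_probability(1.0, 1.0, 0.5) == pytest.approx(2.0 / 3.0)

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0, 5, 100)
        for r in (0.1, 1.0, 4.0):
            p = [sx.hill_probability(l, r, 0.5) for l in grid]
            assert all(b >= a for a, b in zip(p, p[1:]))
            q = [sx.hill_probability(r, l, 0.5) for l in grid]
            assert all(b >= a for a, b in zip(q, q[1:]))


def constant_dataset(n_cells_a=12, n_cells_b=12, value=3.0):
    x = np.full((n_cells_a + n_cells_b, 2), value)
    obs = pd.DataFrame(
        {
            "cluster": ["A"] * n_cells_a + ["B"] * n_cells_b,
            "condition": "Sham",
        },
        index=[f"c{i}" for i in range(n_cells_a + n_cells_b)],
    )
    return sx.make_dataset(x, obs, ["g1", "g2"])


class TestClusterSummaries:
    def test_small_cluster_flagged_ineligible(self):
        adata = constant_dataset(n_cells_a=5, n_cells_b=15)
        summary = sx.cluster_summaries(adata, "Sham", sx.PipelineConfig())
        assert not summary.eligible["A"]
        assert summary.eligible["B"]

    def test_constant_expression_summary(self):
        adata = constant_dataset(value=3.0)
        summary = sx.cluster_summaries(adata, "Sham", sx.PipelineConfig())
        assert summary.values.loc["A", "g1"] == pytest.approx(3.0)

    def test_matches_bruteforce_trimean(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(1.0, 1.0, size=(50, 20))
        obs = pd.DataFrame(
            {"cluster": ["A"] * 25 + ["B"] * 25, "condition": "Sham"},
            index=[f"c{i}" for i in range(50)],
        )
        adata = sx.make_dataset(x, obs, [f"g{j}" for j in range(20)])
        summary = sx.cluster_summaries(adata, "Sham", sx.PipelineConfig())
        for cl, rows in (("A", x[:25]), ("B", x[25:])):
            for j in range(20):
                assert summary.values.loc[cl, f"g{j}"] == pytest.approx(
                    trimean_oracle(rows[:, j]), abs=1e-12
                )

    def test_absent_condition_rejected(self):
        adata = constant_dataset()
        with pytest.raises(ValidationError, match="condition"):
            sx.cluster_summaries(adata, "ACLR7", sx.PipelineConfig())


class TestComplexLevel:
    def summary(self, values):
        return sx.ClusterSummaryMatrix(
            condition="Sham",
            values=pd.DataFrame([values], index=["A"]),
            counts=pd.Series({"A": 20}),
            eligible=pd.Series({"A": True}),
        )

    def test_single_subunit_identity(self):
        s = self.summary({"g1": 1.7})
        assert sx.complex_level(s, ["g1"], "A") == pytest.approx(1.7)

    def test_geometric_mean(self):
        s = self.summary({"g1": 4.0, "g2": 1.0})
        assert sx.complex_level(s, ["g1", "g2"], "A") == pytest.approx(2.0)

    def test_zero_subunit_kills_complex(self):
        s = self.summary({"g1": 4.0, "g2": 0.0})
        assert sx.complex_level(s, ["g1", "g2"], "A") == 0.0

    def test_unknown_gene_rejected(self):
        s = self.summary({"g1": 1.0})
        with pytest.raises(ValidationError, match="unknown genes"):
            sx.complex_level(s, ["gX"], "A")


class TestCommunicationTensor:
    def test_unexpressed_ligand_gives_zero_tensor(self):
        adata, db, cmap = toy_two_cluster_dataset(ligand_value=0.0)
        tensor = sx.communication_tensor(adata, db, "Sham", cmap, sx.PipelineConfig())
        assert np.all(tensor.prob == 0.0)

    def test_compartment_restricted_expression_blocks_reverse_direction(self):
        # ligand only in the stromal cluster, receptor only in the immune
        # cluster: any immune-sender / stromal-receiver entry must be zero
        adata, db, cmap = toy_two_cluster_dataset()
        tensor = sx.communication_tensor(adata, db, "Sham", cmap, sx.PipelineConfig())
        b, a = tensor.clusters.index("B"), tensor.clusters.index("A")
        assert tensor.prob[b, a, 0] == 0.0
        assert tensor.prob[b, b, 0] == 0.0

    def test_hand_composed_probability(self):
        # trimean 1 x trimean 1 with kh=0.5 -> P = 2/3 on a 20-cell toy
        adata, db, cmap = toy_two_cluster_dataset()
        tensor = sx.communication_tensor(adata, db, "Sham", cmap, sx.PipelineConfig())
        a, b = tensor.clusters.index("A"), tensor.clusters.index("B")
        assert tensor.prob[a, b, 0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_no_eligible_cluster_in_compartment_names_it(self):
        adata, db, cmap = toy_two_cluster_dataset(n_per_cluster=10)
        cfg = sx.PipelineConfig(min_cells=11)
        with pytest.raises(SynocrossError, match="stromal"):
            sx.communication_tensor(adata, db, "Sham", cmap, cfg)

    def test_unbound_database_rejected(self):
        adata, _, cmap = toy_two_cluster_dataset()
        db = sx.LRDatabase((sx.LRInteraction("x", "P", ("Nope",), ("Rg",)),))
        with pytest.raises(ValidationError, match="Nope"):
            sx.communication_tensor(adata, db, "Sham", cmap, sx.PipelineConfig())

    def test_monotone_in_single_cell_ligand_expression(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(1.0, 1.0, size=(40, 4))
        obs = pd.DataFrame(
            {"cluster": ["A"] * 20 + ["B"] * 20, "condition": "Sham"},
            index=[f"c{i}" for i in range(40)],
        )
        genes = ["Lg", "Rg", "g2", "g3"]
        cmap = sx.CompartmentMap({"A": "stromal", "B": "immune"})
        db = sx.LRDatabase((sx.LRInteraction("Lg__Rg", "P", ("Lg",), ("Rg",)),))
        cfg = sx.PipelineConfig(n_perm=1)
        base = sx.communication_tensor(
            sx.make_dataset(x, obs, genes), db, "Sham", cmap, cfg
        )
        for bump in (0.1, 1.0, 10.0):
            x2 = x.copy()
            x2[3, 0] += bump  # cell 3 is in cluster A
            bumped = sx.communication_tensor(
                sx.make_dataset(x2, obs, genes), db, "Sham", cmap, cfg
            )
            a = base.clusters.index("A")
            assert np.all(bumped.prob[a] >= base.prob[a] - 1e-15)


class TestPermutationSignificance:
    def test_constant_expression_gives_p_one(self):
        adata, db, cmap = toy_two_cluster_dataset(ligand_value=0.0, receptor_value=0.0)
        adata.X = adata.X.toarray() * 0 + 2.0  # every gene constant everywhere
        pvals = sx.permutation_significance(adata, db, "Sham", sx.PipelineConfig())
        assert np.all(pvals == 1.0)

    def test_planted_signal_is_significant(self, small_simulated):
        adata, db, cmap, _ = small_simulated
        cfg = sx.PipelineConfig(seed=11)
        tensor = sx.communication_tensor(adata, db, "ACLR7", cmap, cfg)
        s = tensor.clusters.index("Fibro")
        r = tensor.clusters.index("Mac")
        k = tensor.interaction_ids.index("Csf1__Csf1r")
        assert tensor.pval[s, r, k] <= 0.05

    def test_seeded_determinism(self, small_simulated):
        adata, db, cmap, _ = small_simulated
        cfg = sx.PipelineConfig(seed=3)
        p1 = sx.permutation_significance(adata, db, "Sham", cfg)
        p2 = sx.permutation_significance(adata, db, "Sham", cfg)
        assert np.array_equal(p1, p2)

    def test_invariant_to_gene_column_order(self, small_simulated):
        adata, db, cmap, _ = small_simulated
        cfg = sx.PipelineConfig(seed=3, n_perm=20)
        p1 = sx.permutation_significance(adata, db, "Sham", cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(adata.n_vars)
        shuffled = adata[:, perm].copy()
        p2 = sx.permutation_significance(shuffled, db, "Sham", cfg)
        assert np.array_equal(p1, p2)

    def test_min_cells_masking_isolates_ineligible_cluster(self):
        # dropping an ineligible cluster entirely must not move any
        # unmasked tensor entry
        rng = np.random.default_rng(8)
        n_a, n_b, n_tiny = 20, 20, 4
        x = rng.gamma(1.0, 1.0, size=(n_a + n_b + n_tiny, 3))
        obs = pd.DataFrame(
            {
                "cluster": ["A"] * n_a + ["B"] * n_b + ["Tiny"] * n_tiny,
                "condition": "Sham",
            },
            index=[f"c{i}" for i in range(n_a + n_b + n_tiny)],
        )
        genes = ["Lg", "Rg", "g2"]
        db = sx.LRDatabase((sx.LRInteraction("Lg__Rg", "P", ("Lg",), ("Rg",)),))
        cmap = sx.CompartmentMap({"A": "stromal", "B": "immune", "Tiny": "immune"})
        cfg = sx.PipelineConfig(seed=5, n_perm=50)
        full = sx.communication_tensor(sx.make_dataset(x, obs, genes), db, "Sham", cmap, cfg)
        reduced = sx.communication_tensor(
            sx.make_dataset(x[: n_a + n_b], obs.iloc[: n_a + n_b], genes),
            db,
            "Sham",
            sx.CompartmentMap({"A": "stromal", "B": "immune"}),
            cfg,
        )
        keep = [full.clusters.index("A"), full.clusters.index("B")]
        np.testing.assert_array_equal(full.prob[np.ix_(keep, keep)], reduced.prob)
        np.testing.assert_array_equal(full.pval[np.ix_(keep, keep)], reduced.pval)
        tiny = full.clusters.index("Tiny")
        assert np.all(full.prob[tiny] == 0.0) and np.all(full.prob[:, tiny] == 0.0)
        assert np.all(full.pval[tiny] == 1.0)

    def test_matches_bruteforce_oracle_small(self):
        cfg = sx.SynthConfig(
            seed=21,
            clusters=(
                sx.ClusterSpec("Fibro", "stromal", 12),
                sx.ClusterSpec("Mac", "immune", 12),
            ),
            n_genes=40,
            n_decoys=4,
            planted=(
                sx.PlantedSignal(
                    "CSF", ("Csf1",), ("Csf1r",), "Fibro", "Mac", ("ACLR7",), 6.0
                ),
            ),
        )
        adata, db, cmap, _ = sx.simulate_dataset(cfg)
        pc = sx.PipelineConfig(seed=21, n_perm=20)
        tensor = sx.communication_tensor(adata, db, "ACLR7", cmap, pc)
        prob_o, pval_o = tensor_oracle(adata, db, "ACLR7", pc)
        np.testing.assert_allclose(tensor.prob, prob_o, atol=1e-12)
        np.testing.assert_array_equal(tensor.pval, pval_o)
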