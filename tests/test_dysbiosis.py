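import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

import microhi as mh
from conftest import random_table


def bc_oracle(a, b):
    return float(np.abs(a - b).sum() / (a + b).sum())


def upgma_heights_oracle(matrix):
    """Naive agglomeration recomputing every cluster distance from the
    original matrix (definition of average linkage), not via updates."""
    n = matrix.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([matrix[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        frame = pd.DataFrame({"a": [0.4, 0.6], "b": [0.4, 0.6]}, index=["t1", "t2"])
        dm = mh.bray_curtis_matrix(mh.AbundanceTable(frame))
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_distance_one(self):
        frame = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["t1", "t2"])
        dm = mh.bray_curtis_matrix(mh.AbundanceTable(frame))
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        frame = pd.DataFrame({"a": [0.6, 0.4], "b": [0.2, 0.8]}, index=["t1", "t2"])
        dm = mh.bray_curtis_matrix(mh.AbundanceTable(frame))
        assert dm.values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_matches_elementwise_oracle_on_random_tables(self, rng):
        for _ in range(20):
            table = random_table(rng, int(rng.integers(2, 11)), int(rng.integers(2, 9)))
            dm = mh.bray_curtis_matrix(table)
            v = table.values
            for i in range(len(table.samples)):
                for j in range(len(table.samples)):
                    assert dm.values[i, j] == pytest.approx(
                        bc_oracle(v[:, i], v[:, j]), abs=1e-12
                    )

    def test_requires_two_samples(self):
        frame = pd.DataFrame({"a": [1.0]}, index=["t1"])
        with pytest.raises(mh.ValidationError):
            mh.bray_curtis_matrix(mh.AbundanceTable(frame))


class TestAverageLinkage:
    def test_three_sample_hand_agglomeration(self):
        dm = mh.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 0.1, 0.8], [0.1, 0.0, 0.8], [0.8, 0.8, 0.0]]),
        )
        tree = mh.average_linkage_tree(dm)
        assert tree.linkage[0, 2] == pytest.approx(0.1)
        assert sorted(tree.linkage[0, :2]) == [0, 1]
        assert tree.linkage[1, 2] == pytest.approx(0.8)

    def test_two_samples_merge_at_their_distance(self):
        dm = mh.DistanceMatrix(["A", "B"], np.array([[0.0, 0.37], [0.37, 0.0]]))
        tree = mh.average_linkage_tree(dm)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(0.37)

    def test_all_equal_distances_resolved_lexicographically(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = mh.average_linkage_tree(mh.DistanceMatrix(list("ABCD"), d))
        # first merge is the smallest pair (0,1); then (2,3); then roots
        assert (tree.linkage[0, :2] == [0, 1]).all()
        assert (tree.linkage[1, :2] == [2, 3]).all()

    def test_merge_heights_non_decreasing(self, rng):
        for _ in range(10):
            table = random_table(rng, 6, 8)
            tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
            assert (np.diff(tree.merge_heights) >= -1e-12).all()

    def test_heights_match_naive_oracle(self, rng):
        for _ in range(10):
            table = random_table(rng, int(rng.integers(2, 11)), int(rng.integers(3, 9)))
            dm = mh.bray_curtis_matrix(table)
            tree = mh.average_linkage_tree(dm)
            expected = upgma_heights_oracle(dm.values)
            assert np.abs(tree.merge_heights - expected).max() < 1e-12

    def test_agrees_with_scipy_average_linkage(self, rng):
        table = random_table(rng, 8, 10)
        dm = mh.bray_curtis_matrix(table)
        ours = mh.average_linkage_tree(dm).merge_heights
        theirs = linkage(dm.values[np.triu_indices(10, 1)], method="average")[:, 2]
        assert np.abs(ours - theirs).max() < 1e-10

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(mh.ValidationError):
            mh.DistanceMatrix(["A", "B"], np.array([[0.0, 0.2], [0.3, 0.0]]))

    def test_newick_export_contains_all_leaves(self, rng):
        table = random_table(rng, 5, 4)
        tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        newick = tree.to_newick()
        for leaf in table.samples:
            assert leaf in newick


def make_meta(samples, species, ecotype):
    return [
        mh.SampleMetadata(
            sample_id=s, source="gut", species=sp, ecotype=ec, site="S1", year=2022
        )
        for s, sp, ec in zip(samples, species, ecotype)
    ]


def displaced_fixture(rng, n_a=10, n_b=10):
    """Species A cluster, species B cluster, and one A sample sitting
    squarely inside B's branch."""
    base_a = np.array([0.7, 0.1, 0.1, 0.1])
    base_b = np.array([0.1, 0.1, 0.1, 0.7])
    cols, species = {}, []
    for i in range(n_a):
        cols[f"a{i}"] = rng.dirichlet(base_a * 200)
        species.append("A")
    for i in range(n_b):
        cols[f"b{i}"] = rng.dirichlet(base_b * 200)
        species.append("B")
    cols["stray"] = rng.dirichlet(base_b * 200)
    species.append("A")
    frame = pd.DataFrame(cols, index=[f"t{k}" for k in range(4)])
    table = mh.AbundanceTable.from_dataframe(frame)
    meta = make_meta(list(cols), species, ["carnivorous"] * len(species))
    return table, meta


class TestClassifyDisordered:
    def test_displaced_sample_is_unhealthy(self, rng):
        table, meta = displaced_fixture(rng)
        tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        labels = {l.sample_id: l.status for l in mh.classify_disordered(tree, meta)}
        assert labels["stray"] == "unhealthy"
        assert all(
            status == "healthy" for s, status in labels.items() if s != "stray"
        )

    def test_pure_branches_give_zero_unhealthy(self, rng):
        table, meta = displaced_fixture(rng, n_a=8, n_b=8)
        keep = [s for s in table.samples if s != "stray"]
        table = table.subset(keep)
        meta = [m for m in meta if m.sample_id != "stray"]
        tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        labels = mh.classify_disordered(tree, meta)
        assert all(l.status == "healthy" for l in labels)

    def test_invariant_to_sample_input_order(self, rng):
        table, meta = displaced_fixture(rng)
        order = list(table.samples)
        shuffled = list(order)
        rng.shuffle(shuffled)
        t1 = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        t2 = mh.average_linkage_tree(mh.bray_curtis_matrix(table.subset(shuffled)))
        l1 = {l.sample_id: l.status for l in mh.classify_disordered(t1, meta)}
        l2 = {l.sample_id: l.status for l in mh.classify_disordered(t2, meta)}
        assert l1 == l2

    def test_rare_species_judged_by_ecotype_branch(self, rng):
        # two samples of a rare species nested inside a same-ecotype branch
        base = np.array([0.7, 0.1, 0.1, 0.1])
        cols = {f"a{i}": rng.dirichlet(base * 300) for i in range(8)}
        cols["r0"] = rng.dirichlet(base * 300)
        cols["r1"] = rng.dirichlet(base * 300)
        frame = pd.DataFrame(cols, index=[f"t{k}" for k in range(4)])
        table = mh.AbundanceTable.from_dataframe(frame)
        meta = make_meta(
            list(cols), ["A"] * 8 + ["Rare"] * 2, ["carnivorous"] * 10
        )
        tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        labels = {l.sample_id: l.status for l in mh.classify_disordered(tree, meta)}
        assert labels["r0"] == "healthy" and labels["r1"] == "healthy"

    def test_rejects_water_leaves(self, rng):
        table, meta = displaced_fixture(rng)
        meta[0] = mh.SampleMetadata(
            sample_id=meta[0].sample_id, source="water", site="S1", year=2022
        )
        tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        with pytest.raises(mh.ValidationError, match="non-gut"):
            mh.classify_disordered(tree, meta)

    def test_cut_strategy_also_flags_displaced_sample(self, rng):
        table, meta = displaced_fixture(rng)
        tree = mh.average_linkage_tree(mh.bray_curtis_matrix(table))
        labels = {
            l.sample_id: l.status
            for l in mh.classify_disordered(tree, meta, strategy="cut", cut_q=75)
        }
        assert labels["stray"] == "unhealthy"


def test_multilevel_consensus_is_majority(rng):
    table, meta = displaced_fixture(rng)
    genus = {t: "g0" if t in ("t0", "t1") else "g1" for t in table.taxa}
    tables = {
        "species": table,
        "genus": mh.collapse_taxa(table, genus, "genus"),
    }
    frame = mh.classify_multilevel(tables, meta)
    assert set(frame.columns) == {"species", "genus", "consensus"}
    # two-level tie resolves to healthy; rows with agreement keep the vote
    agree = frame["species"] == frame["genus"]
    assert (frame.loc[agree, "consensus"] == frame.loc[agree, "species"]).all()
    assert (frame.loc[~agree, "consensus"] == "healthy").all()
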