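"""Cross-study linking: harmonization, presence filters, clustering oracle,
progression-cluster assignment."""

import numpy as np
import pandas as pd
import pytest

from arsig import crossdb
from arsig.crossdb import (
    assign_progression_cluster,
    assign_progression_clusters,
    build_concordance_matrix,
    harmonize_identifiers,
    hierarchical_cluster,
    linkage_to_newick,
    presence_filter,
)


def study_table(rows):
    return pd.DataFrame(rows, columns=["study_id", "comparison_class",
                                       "symbol", "value"])


class TestHarmonize:
    def test_case_and_whitespace(self):
        t = study_table([("S1", "androgen_response", "ndrg1 ", 1.0)])
        assert harmonize_identifiers(t).symbol.iloc[0] == "NDRG1"

    def test_alias_map(self):
        t = study_table([("S1", "androgen_response", "MTP18", 1.0)])
        out = harmonize_identifiers(t, alias_map={"MTP18": "MTFP1"})
        assert out.symbol.iloc[0] == "MTFP1"

    def test_duplicates_averaged(self, caplog):
        t = study_table([
            ("S1", "androgen_response", "NDRG1", 2.6),
            ("S1", "androgen_response", "NDRG1", 2.1),
        ])
        out = harmonize_identifiers(t)
        assert len(out) == 1
        assert out.value.iloc[0] == pytest.approx(2.35)

    def test_unknown_class_rejected(self):
        t = study_table([("S1", "whatever", "A", 1.0)])
        with pytest.raises(ValueError):
            harmonize_identifiers(t)


class TestPresenceFilter:
    tables = study_table(
        [(f"S{i}", "androgen_response", "KEEP", 1.0) for i in range(1, 4)]
        + [(f"S{i}", "androgen_response", "DROP", 1.0) for i in range(1, 3)]
        + [("S4", "androgen_response", "OTHER", 1.0),
           ("S5", "androgen_response", "OTHER", 1.0)]
    )

    def test_boundary_inclusive(self):
        kept = presence_filter(["KEEP", "DROP"], self.tables, min_present=3)
        assert kept == ["KEEP"]

    def test_min_zero_retains_all(self):
        kept = presence_filter(["KEEP", "DROP", "ABSENT"], self.tables, 0)
        assert kept == ["KEEP", "DROP", "ABSENT"]

    def test_min_above_study_count_errors(self):
        with pytest.raises(ValueError):
            presence_filter(["KEEP"], self.tables, min_present=6)

    def test_monotone_in_min_present(self):
        for lo in range(0, 5):
            a = set(presence_filter(["KEEP", "DROP", "OTHER"], self.tables, lo))
            b = set(presence_filter(["KEEP", "DROP", "OTHER"], self.tables, lo + 1))
            assert b <= a


def brute_force_average_linkage(mat):
    """Naive agglomeration recomputing all pairwise cluster distances each
    step (unweighted average of leaf-pair correlation distances)."""
    def leaf_dist(i, j):
        xi, xj = mat[i], mat[j]
        r = np.corrcoef(xi, xj)[0, 1]
        return 1.0 - r

    clusters = {i: [i] for i in range(len(mat))}
    merges = []
    next_id = len(mat)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([leaf_dist(i, j)
                             for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a] + clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 1.0],
                            [1.0, 2.0, 3.0, 1.0],
                            [3.0, -1.0, 2.0, 8.0]],
                           index=["A", "B", "C"])
        z, order = hierarchical_cluster(mat)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_anticorrelated_rows_distance_two(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["A", "B"])
        z, _ = hierarchical_cluster(mat)
        assert z[0, 2] == pytest.approx(2.0)

    def test_merge_sequence_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(0, 1, (4, 6))
        z, _ = hierarchical_cluster(pd.DataFrame(mat, index=list("ABCD")))
        expected = brute_force_average_linkage(mat)
        # replay scipy merges into leaf sets
        members = {i: frozenset([i]) for i in range(4)}
        for step, row in enumerate(z):
            a, b = int(row[0]), int(row[1])
            merged = members[a] | members[b]
            members[4 + step] = merged
            exp_set, exp_d = expected[step]
            assert merged == exp_set
            assert row[2] == pytest.approx(exp_d)

    def test_zero_variance_row_gets_max_distance(self, caplog):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [0.2, 0.9, 0.1]], index=["A", "B"])
        z, _ = hierarchical_cluster(mat)
        assert z[0, 2] == pytest.approx(2.0)

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.normal(0, 1, (6, 5)),
                           index=[f"G{i}" for i in range(6)])
        _, o1 = hierarchical_cluster(mat)
        _, o2 = hierarchical_cluster(mat.copy())
        assert o1 == o2

    def test_pairwise_complete_with_missing(self):
        mat = pd.DataFrame([[1.0, 2.0, np.nan, 4.0],
                            [1.0, 2.0, 3.0, 4.0],
                            [np.nan, np.nan, np.nan, np.nan]],
                           index=["A", "B", "EMPTY"])
        with pytest.raises(ValueError):
            hierarchical_cluster(mat.loc[["EMPTY"]])
        z, order = hierarchical_cluster(mat)   # EMPTY dropped
        assert set(order) == {"A", "B"}

    def test_newick_roundtrip_labels(self):
        mat = pd.DataFrame(np.random.default_rng(9).normal(0, 1, (4, 5)),
                           index=list("WXYZ"))
        z, _ = hierarchical_cluster(mat)
        nwk = crossdb.linkage_to_newick(z, list("WXYZ"))
        assert nwk.endswith(";")
        for lab in "WXYZ":
            assert lab in nwk


class TestProgressionClusters:
    @pytest.mark.parametrize("adir,met,expected", [
        ("up", (-1, -1, 1), 3),     # consensus down
        ("down", (1, 1), 1),
        ("down", (-1, -1), 2),
        ("up", (1, 1), 4),
        ("up", (1, -1), "unassigned"),   # tie
        ("up", (), "unassigned"),        # no data
        ("up", (0.05, -0.05, 0.2), 4),   # zero band ignores tiny values
    ])
    def test_mapping(self, adir, met, expected):
        assert assign_progression_cluster(adir, met) == expected

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            assign_progression_cluster("sideways", (1,))

    def test_sign_flip_permutes_clusters(self):
        # flipping every met study's sign maps 1<->2 and 3<->4
        tables = study_table([
            ("M1", "met_vs_primary", "A", 1.0),
            ("M2", "met_vs_primary", "A", 0.8),
            ("M1", "met_vs_primary", "B", -1.0),
            ("M2", "met_vs_primary", "B", -0.8),
        ])
        dirs = pd.Series({"A": "up", "B": "down"})
        before = assign_progression_clusters(dirs, tables).set_index("symbol")
        flipped = tables.assign(value=-tables.value)
        after = assign_progression_clusters(dirs, flipped).set_index("symbol")
        perm = {1: 2, 2: 1, 3: 4, 4: 3}
        for g in ("A", "B"):
            assert after.loc[g, "cluster"] == perm[before.loc[g, "cluster"]]

    def test_invariant_to_study_order(self):
        tables = study_table([
            ("M1", "met_vs_primary", "A", 1.0),
            ("M2", "met_vs_primary", "A", -0.8),
            ("M3", "met_vs_primary", "A", 0.9),
        ])
        dirs = pd.Series({"A": "up"})
        shuffled = tables.iloc[[2, 0, 1]].reset_index(drop=True)
        a = assign_progression_clusters(dirs, tables).cluster.iloc[0]
        b = assign_progression_clusters(dirs, shuffled).cluster.iloc[0]
        assert a == b == 4


def test_concordance_matrix_layout():
    tables = study_table([
        ("T1", "tumor_vs_normal", "A", 1.0),
        ("A1", "androgen_response", "A", 2.0),
        ("A1", "androgen_response", "B", -1.0),
    ])
    mat = build_concordance_matrix(["A", "B"], tables)
    assert list(mat.columns) == ["A1", "T1"]   # androgen block first
    assert np.isnan(mat.loc["B", "T1"])
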