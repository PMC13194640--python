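"""Core signature selection, z-scoring, clustering order, and modules."""

import numpy as np
import pandas as pd
import pytest

from kdsig.errors import ConfigError
from kdsig.signature import (CoreSignature, cluster_gene_order, core_signature,
                             intersect_with_sets, module_condition_means,
                             signature_heatmap, zscore_rows)
from kdsig.io import GeneSetCollection
from kdsig.diffexp import de_table


def _de(pairs):
    """Minimal DE-shaped frame from {gene: log2fc}."""
    idx = pd.Index(list(pairs), name="gene_id")
    return pd.DataFrame({"symbol": [f"sym_{g}" for g in idx],
                         "log2fc": list(pairs.values()),
                         "cell_line": "X"}, index=idx)


class TestCoreSignature:
    def test_boundary_and_direction_semantics(self):
        de1 = _de({"a": 1.2, "b": 1.2, "c": 0.9, "d": 1.0, "e": -2.0})
        de2 = _de({"a": 1.5, "b": -1.5, "c": 1.5, "d": 1.0, "e": -1.1})
        sig = core_signature(de1, de2)
        assert set(sig.gene_ids) == {"a", "d", "e"}  # b discordant, c below threshold
        tab = sig.table
        assert tab.loc["a", "direction"] == "up"
        assert tab.loc["d", "direction"] == "up"  # 1.0 included: inclusive >=
        assert tab.loc["e", "direction"] == "down"
        assert sig.n_up + sig.n_down == len(sig)

    def test_symmetric_in_arguments(self):
        de1 = _de({"a": 1.2, "b": -3.0, "c": 0.2})
        de2 = _de({"a": 2.0, "b": -1.0, "c": 5.0})
        assert set(core_signature(de1, de2).gene_ids) == set(core_signature(de2, de1).gene_ids)

    def test_threshold_monotone_shrinkage(self):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": v for i, v in enumerate(rng.normal(0, 2, 200))}
        genes2 = {f"g{i}": v for i, v in enumerate(rng.normal(0, 2, 200))}
        prev = None
        for thr in (0.5, 1.0, 1.5, 2.5):
            sel = set(core_signature(_de(genes), _de(genes2), thr).gene_ids)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_empty_intersection_rejected(self):
        with pytest.raises(ConfigError):
            core_signature(_de({"a": 1.0}), _de({"b": 1.0}))

    def test_planted_program_recovered(self, planted_expr):
        de1 = de_table(planted_expr, "L1")
        de2 = de_table(planted_expr, "L2")
        sig = core_signature(de1, de2)
        got = set(sig.gene_ids)
        planted_up = {f"UP{i}" for i in range(20)}
        planted_dn = {f"DN{i}" for i in range(20)}
        assert len(got & planted_up) >= 18
        assert len(got & planted_dn) >= 18
        assert "DISC0" not in got  # discordant planted gene never selected
        private = {f"PRIV{i}" for i in range(5)}
        assert not (got & private)


class TestZscoreRows:
    def test_known_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        assert zscore_rows(df).loc["g"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_row_zeroed_with_warning(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_rows(df)
        assert (out.loc["g"] == 0).all()

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 12)))
        z = zscore_rows(df)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-8)

    def test_needs_two_columns(self):
        with pytest.raises(ConfigError):
            zscore_rows(pd.DataFrame([[1.0]]))


def _brute_force_average_linkage(X):
    """Independent UPGMA: returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([np.linalg.norm(X[i] - X[j])
                             for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return sorted(heights)


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        df = pd.DataFrame([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]], index=["a", "b", "c"])
        order = cluster_gene_order(df)
        ia, ic = order.index("a"), order.index("c")
        assert abs(ia - ic) == 1

    def test_close_pair_adjacent(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]], index=["a", "b", "c"])
        order = cluster_gene_order(df)
        assert abs(order.index("a") - order.index("b")) == 1

    def test_merge_heights_match_brute_force(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        Z = linkage(pdist(X), method="average")
        assert np.allclose(sorted(Z[:, 2]), _brute_force_average_linkage(X), atol=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(15, 4)))
        assert cluster_gene_order(df) == cluster_gene_order(df)


class TestModules:
    def test_condition_means_and_order(self, planted_expr):
        mat = module_condition_means(planted_expr, ["SYM_UP0", "SYM_DN0"])
        assert list(mat.columns) == ["L1_NT", "L1_KD1", "L1_KD2",
                                     "L2_NT", "L2_KD1", "L2_KD2"]
        up = mat.loc["SYM_UP0"]
        assert (up[["L1_KD1", "L1_KD2", "L2_KD1", "L2_KD2"]] > 0).all()
        assert (up[["L1_NT", "L2_NT"]] < 0).all()
        dn = mat.loc["SYM_DN0"]
        assert (dn[["L1_KD1", "L1_KD2", "L2_KD1", "L2_KD2"]] < 0).all()

    def test_replicate_averaging(self):
        from kdsig.containers import ExpressionMatrix
        from conftest import make_count_matrix

        cm = make_count_matrix(np.ones((1, 4), dtype=int),
                               lines=["A", "A", "A", "A"],
                               conditions=["NT", "NT", "KD1", "KD1"])
        values = pd.DataFrame([[4.0, 6.0, 1.0, 3.0]], index=pd.Index(["G0"], name="gene_id"),
                              columns=cm.samples.index)
        expr = ExpressionMatrix(values, cm.genes, cm.samples)
        # one gene over two conditions: z-scores of the means (5, 2)
        mat = module_condition_means(expr, ["G0"], by_symbol=False)
        assert mat.shape == (1, 2)
        z = mat.loc["G0"]
        assert z["A_NT"] == pytest.approx(np.sqrt(0.5), rel=1e-9)

    def test_missing_gene_rejected(self, planted_expr):
        with pytest.raises(KeyError):
            module_condition_means(planted_expr, ["NOT_A_SYMBOL"])


class TestIntersectWithSets:
    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        symbols = [f"s{i}" for i in range(100)]
        table = pd.DataFrame({
            "symbol": symbols,
            "direction": rng.choice(["up", "down"], 100),
            "log2fc_a": 2.0, "log2fc_b": 2.0,
        }, index=pd.Index([f"g{i}" for i in range(100)], name="gene_id"))
        sig = CoreSignature(table, 1.0)
        sets = GeneSetCollection({
            f"S{k}": ("d", frozenset(rng.choice(symbols, 20, replace=False)))
            for k in range(5)
        })
        sets.sets["EMPTY"] = ("d", frozenset(["nope"]))
        out = intersect_with_sets(sig, sets)
        for name in sets.names():
            expected = set(symbols) & set(sets.members(name))
            assert {s for s, _ in out[name]} == expected
        assert out["EMPTY"] == []

    def test_full_signature_returned(self):
        table = pd.DataFrame({"symbol": ["x", "y"], "direction": ["up", "down"],
                              "log2fc_a": [2, -2], "log2fc_b": [2, -2]},
                             index=pd.Index(["g1", "g2"], name="gene_id"))
        sig = CoreSignature(table, 1.0)
        sets = GeneSetCollection({"ALL": ("d", frozenset(["x", "y"]))})
        assert intersect_with_sets(sig, sets)["ALL"] == [("x", "up"), ("y", "down")]


def test_signature_heatmap_rows_standardized(planted_expr):
    de1 = de_table(planted_expr, "L1")
    de2 = de_table(planted_expr, "L2")
    sig = core_signature(de1, de2)
    heat = signature_heatmap(planted_expr, sig)
    assert set(heat.index) == set(sig.gene_ids)
    assert np.allclose(heat.mean(axis=1), 0, atol=1e-8)
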