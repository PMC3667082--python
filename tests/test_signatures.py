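import numpy as np
import pandas as pd
import pytest

from sigconcord import (
    GeneSignature,
    derive_group_signature,
    derive_paired_signature,
    derive_subtype_vs_rest_signature,
    intersect_signatures,
    per_sample_log2fc,
)


def make_expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestGeneSignature:
    def test_up_down_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneSignature("s", {"a"}, {"a"}, {"a", "b"})

    def test_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            GeneSignature("s", {"a"}, set(), {"b"})

    def test_restrict_intersects_all_sets(self):
        sig = GeneSignature("s", {"a", "b"}, {"c"}, {"a", "b", "c", "d"})
        r = sig.restrict({"a", "c", "d"})
        assert r.up == {"a"} and r.down == {"c"} and r.universe == {"a", "c", "d"}

    def test_text_and_json_round_trip(self, tmp_path):
        sig = GeneSignature("s", {"a"}, {"b"}, {"a", "b", "c"}, threshold_log2=0.5)
        sig.save(tmp_path / "sig.txt")
        loaded = GeneSignature.load(tmp_path / "sig.txt", universe=sig.universe,
                                    threshold_log2=0.5)
        assert loaded.up == sig.up and loaded.down == sig.down
        assert GeneSignature.from_dict(sig.to_dict()) == sig


class TestGroupSignature:
    def test_identical_groups_give_empty_signature(self):
        expr = make_expr(np.tile([[5.0, 5.0, 5.0, 5.0]], (4, 1)))
        sig = derive_group_signature(expr, ["s0", "s1"], ["s2", "s3"])
        assert sig.up == frozenset() and sig.down == frozenset()

    def test_boundary_is_inclusive(self):
        # group mean 6.0 vs reference mean 5.0 at tau=1.0 -> up
        expr = make_expr([[6.0, 6.0, 5.0, 5.0]])
        sig = derive_group_signature(expr, ["s0", "s1"], ["s2", "s3"], tau=1.0)
        assert sig.up == {"g0"}

    def test_recovers_planted_up_genes(self, rng):
        # 50 planted up genes at delta=2, sd=0.2, 20 samples/group
        n_genes, n_up = 500, 50
        base = rng.normal(8, 1, n_genes)
        group = base[:, None] + rng.normal(0, 0.2, (n_genes, 20))
        group[:n_up] += 2.0
        ref = base[:, None] + rng.normal(0, 0.2, (n_genes, 20))
        expr = make_expr(np.hstack([group, ref]))
        g_cols, r_cols = expr.columns[:20], expr.columns[20:]
        sig = derive_group_signature(expr, list(g_cols), list(r_cols), tau=1.0)
        # independent oracle: direct mean arithmetic
        diff = expr[g_cols].to_numpy().mean(1) - expr[r_cols].to_numpy().mean(1)
        assert sig.up == set(expr.index[diff >= 1.0])
        assert sig.up == set(expr.index[:n_up])
        assert sig.down == frozenset()

    def test_antisymmetry(self, small_expr):
        a, b = list(small_expr.columns[:5]), list(small_expr.columns[5:])
        ab = derive_group_signature(small_expr, a, b, tau=0.3)
        ba = derive_group_signature(small_expr, b, a, tau=0.3)
        assert ab.up == ba.down and ab.down == ba.up

    @pytest.mark.parametrize("taus", [(0.25, 0.5, 1.0)])
    def test_raising_tau_shrinks_sets(self, small_expr, taus):
        a, b = list(small_expr.columns[:5]), list(small_expr.columns[5:])
        sigs = [derive_group_signature(small_expr, a, b, tau=t) for t in taus]
        for lo, hi in zip(sigs, sigs[1:]):
            assert hi.up <= lo.up and hi.down <= lo.down

    def test_sample_and_gene_order_invariance(self, rng, small_expr):
        a, b = list(small_expr.columns[:5]), list(small_expr.columns[5:])
        sig = derive_group_signature(small_expr, a, b, tau=0.3)
        shuffled = small_expr.iloc[rng.permutation(50), rng.permutation(10)]
        sig2 = derive_group_signature(shuffled, a[::-1], b[::-1], tau=0.3)
        assert sig.up == sig2.up and sig.down == sig2.down

    def test_overlapping_or_empty_groups_rejected(self, small_expr):
        cols = list(small_expr.columns)
        with pytest.raises(ValueError, match="overlap"):
            derive_group_signature(small_expr, cols[:3], cols[2:5])
        with pytest.raises(ValueError, match="empty"):
            derive_group_signature(small_expr, [], cols[:3])


class TestSubtypeVsRest:
    def test_two_identical_subtypes_empty(self):
        expr = make_expr(np.tile([[5.0]], (3, 6)))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
        sig = derive_subtype_vs_rest_signature(expr, labels, "A")
        assert not sig.up and not sig.down

    def test_shifted_gene_appears_only_in_own_up_set(self):
        expr = make_expr(np.zeros((2, 6)) + 5.0)
        expr.iloc[0, :3] += 2.0  # gene g0 up in subtype A
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
        sig_a = derive_subtype_vs_rest_signature(expr, labels, "A")
        sig_b = derive_subtype_vs_rest_signature(expr, labels, "B")
        assert sig_a.up == {"g0"} and "g0" not in sig_b.up
        assert sig_b.down == {"g0"}  # with two subtypes the view is mirrored

    def test_absent_subtype_rejected(self, small_expr):
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=small_expr.columns)
        with pytest.raises(ValueError, match="absent"):
            derive_subtype_vs_rest_signature(small_expr, labels, "Z")

    def test_recovers_planted_markers_on_study(self, default_study):
        st = default_study
        labels = st.subtype_labels
        for name, truth in st.truth.subtype_signatures.items():
            sig = derive_subtype_vs_rest_signature(st.expr_tumor, labels, name, tau=1.0)
            # oracle: direct group-mean arithmetic on the generator's truth
            members = labels.index[labels == name].tolist()
            rest = labels.index[labels != name].tolist()
            diff = (st.expr_tumor[members].mean(1) - st.expr_tumor[rest].mean(1))
            assert sig.up == set(diff.index[diff >= 1.0])
            assert sig.up == truth.up and sig.down == truth.down


class TestPairedSignature:
    @pytest.fixture()
    def paired_expr(self):
        # gene rows engineered for support counting across 4 pairs
        cols = [f"{p}{s}" for p in "abcd" for s in ("+", "-")]
        neg = np.full((3, 4), 5.0)
        pos = neg.copy()
        pos[0] += 2.0            # gene g0 up in all 4 pairs
        pos[1, 0] += 2.0         # gene g1 up in exactly 1 pair
        pos[2, :2] += 2.0        # gene g2 up in exactly 2 pairs
        values = np.empty((3, 8))
        values[:, ::2] = pos
        values[:, 1::2] = neg
        return make_expr(values, samples=cols), [(f"{p}+", f"{p}-") for p in "abcd"]

    def test_consensus_support_rule(self, paired_expr):
        expr, pairs = paired_expr
        per_pair, consensus = derive_paired_signature(expr, pairs, tau=1.0, min_support=2)
        assert len(per_pair) == 4
        assert consensus.up == {"g0", "g2"}  # >=2 of 4 pairs
        assert "g1" not in consensus.up

    def test_conflicting_gene_removed_from_both(self):
        cols = ["a+", "a-", "b+", "b-", "c+", "c-", "d+", "d-"]
        values = np.full((1, 8), 5.0)
        values[0, [0, 2]] += 2.0   # up in pairs a, b
        values[0, [4, 6]] -= 2.0   # down in pairs c, d
        expr = make_expr(values, samples=cols)
        pairs = [("a+", "a-"), ("b+", "b-"), ("c+", "c-"), ("d+", "d-")]
        _, consensus = derive_paired_signature(expr, pairs, tau=1.0, min_support=2)
        assert not consensus.up and not consensus.down

    def test_identical_pair_samples_rejected(self, small_expr):
        with pytest.raises(ValueError, match="identical"):
            derive_paired_signature(small_expr, [("s1", "s1")])


class TestIntersectSignatures:
    def test_intersection_of_up_down_and_universe(self):
        u = {"a", "b", "c", "d"}
        s1 = GeneSignature("x", {"a", "b"}, {"c"}, u)
        s2 = GeneSignature("y", {"b"}, {"c", "d"}, u)
        core = intersect_signatures([s1, s2], name="core")
        assert core.up == {"b"} and core.down == {"c"}


class TestPerSampleLog2FC:
    def test_reference_mean_column_is_zero(self):
        expr = make_expr([[4.0, 6.0, 5.0]])
        fc = per_sample_log2fc(expr, ["s0", "s1"])
        np.testing.assert_allclose(fc.loc["g0"], [-1.0, 1.0, 0.0])

    def test_single_reference_is_simple_difference(self, small_expr):
        fc = per_sample_log2fc(small_expr, ["s0"])
        np.testing.assert_allclose(
            fc.to_numpy(), small_expr.to_numpy() - small_expr[["s0"]].to_numpy()
        )

    def test_elementwise_oracle(self, rng):
        expr = make_expr(rng.normal(8, 1, (20, 8)))
        ref = list(expr.columns[:3])
        fc = per_sample_log2fc(expr, ref)
        for g in expr.index:  # brute-force loop
            ref_mean = sum(expr.loc[g, r] for r in ref) / 3
            for s in expr.columns:
                assert fc.loc[g, s] == pytest.approx(expr.loc[g, s] - ref_mean)

    def test_missing_reference_rejected(self, small_expr):
        with pytest.raises(ValueError, match="not in matrix"):
            per_sample_log2fc(small_expr, ["nope"])
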