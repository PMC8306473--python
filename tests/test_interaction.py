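"""Pair scoring, the gene-role permutation null, and the analysis driver."""

import numpy as np
import pandas as pd
import pytest

import glialink as gl
from glialink import io
from conftest import make_context, study_expression


class TestPairScore:
    def test_symmetry(self):
        assert gl.pair_score([3.5, 3.5], [3.5]) == 3.5

    def test_forced_arithmetic(self):
        assert gl.pair_score([2, 2, 2], [4, 4, 4, 4]) == 3.0

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            lig = rng.normal(size=rng.integers(1, 6))
            rec = rng.normal(size=rng.integers(1, 6))
            expected = (sum(lig) / len(lig) + sum(rec) / len(rec)) / 2
            assert gl.pair_score(lig, rec) == pytest.approx(expected, abs=1e-12)

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gl.pair_score([], [1.0])
        with pytest.raises(ValueError, match="finite"):
            gl.pair_score([np.nan], [1.0])


def enumeration_p(pair, ctx, universe):
    """Independent oracle: exact null fraction over all |U|x|U| role
    assignments (ties counted as extreme)."""
    lig_means = {g: np.mean(ctx.ligand_values.loc[g]) for g in universe}
    rec_means = {g: np.mean(ctx.receptor_values.loc[g]) for g in universe}
    obs = (
        np.mean(ctx.ligand_values.loc[pair[0]])
        + np.mean(ctx.receptor_values.loc[pair[1]])
    ) / 2
    hits = sum(
        (lig_means[l] + rec_means[r]) / 2 >= obs
        for l in universe
        for r in universe
    )
    return hits / len(universe) ** 2, obs


class TestPermutationNull:
    def test_dominant_pair_hits_estimator_floor(self):
        # pair genes sit far above a low-expressed universe
        ctx = make_context(
            {"L": [10.0, 10.0], "u1": [0.1, 0.2], "u2": [0.0, 0.1], "u3": [0.2, 0.1]},
            {"R": [9.0], "u1": [0.1], "u2": [0.2], "u3": [0.0]},
        )
        p, null = gl.permutation_null(("L", "R"), ctx, ["u1", "u2", "u3"], 199, 0)
        assert p == 1.0 / 200
        assert null.shape == (199,)

    def test_constant_universe_ties_give_p_one(self):
        ctx = make_context(
            {g: [2.0, 2.0] for g in "abcd"}, {g: [2.0] for g in "abcd"}
        )
        p, _ = gl.permutation_null(("a", "b"), ctx, list("abcd"), 500, 1)
        assert p == 1.0

    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        universe = [f"u{i}" for i in range(5)]
        ctx = make_context(
            {g: rng.normal(size=3).tolist() for g in universe},
            {g: rng.normal(size=4).tolist() for g in universe},
        )
        n_perm = 10_000
        for pair in [("u0", "u1"), ("u2", "u2"), ("u4", "u3")]:
            q, _ = enumeration_p(pair, ctx, universe)
            p, _ = gl.permutation_null(pair, ctx, universe, n_perm, 7)
            expected = (1 + n_perm * q) / (1 + n_perm)
            tol = 3 * np.sqrt(q * (1 - q) * n_perm) / (1 + n_perm)
            assert abs(p - expected) <= tol + 1e-12

    def test_p_granularity(self):
        rng = np.random.default_rng(8)
        universe = [f"u{i}" for i in range(6)]
        ctx = make_context(
            {g: rng.normal(size=2).tolist() for g in universe},
            {g: rng.normal(size=2).tolist() for g in universe},
        )
        n_perm = 40
        p, _ = gl.permutation_null(("u0", "u1"), ctx, universe, n_perm, 2)
        assert 0 < p <= 1
        assert (p * (n_perm + 1)) == pytest.approx(round(p * (n_perm + 1)))

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        universe = [f"u{i}" for i in range(4)]
        ctx = make_context(
            {g: rng.normal(size=2).tolist() for g in universe},
            {g: rng.normal(size=2).tolist() for g in universe},
        )
        out1 = gl.permutation_null(("u0", "u1"), ctx, universe, 100, 42)
        out2 = gl.permutation_null(("u0", "u1"), ctx, universe, 100, 42)
        assert out1[0] == out2[0]
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_small_universe_and_missing_gene_errors(self):
        ctx = make_context({"a": [1.0], "b": [2.0]}, {"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match=">= 2"):
            gl.permutation_null(("a", "b"), ctx, ["a"], 10, 0)
        with pytest.raises(gl.MissingGeneError):
            gl.permutation_null(("zz", "b"), ctx, ["a", "b"], 10, 0)


@pytest.fixture(scope="module")
def analysis_inputs():
    cfg = gl.SimulationConfig(
        n_genes=400, n_de_up=20, n_de_down=10, n_lr_pairs=50, n_active_pairs=2,
        seed=21,
    )
    counts, ann, pairs, truth = gl.simulate_study(cfg)
    opc_expr, mg_expr = study_expression(counts, ann)
    return opc_expr, mg_expr, pairs, truth


class TestRunInteractionAnalysis:
    def test_single_pair_single_context_matches_pair_score(self, analysis_inputs):
        opc_expr, mg_expr, pairs, _ = analysis_inputs
        one = gl.LRPairTable(pairs.pairs.iloc[[0]].reset_index(drop=True))
        res = gl.run_interaction_analysis(
            opc_expr, mg_expr, one, contexts=[("WT", "St", "EAE")],
            n_perm=50, seed=1,
        )
        assert len(res.table) == 1
        row = res.table.iloc[0]
        ctx = gl.build_context(opc_expr, mg_expr, "WT", "St", "EAE")
        expected = gl.pair_score(
            ctx.ligand_values.loc[row.ligand], ctx.receptor_values.loc[row.receptor]
        )
        assert row.score == pytest.approx(expected, abs=1e-12)
        assert row.score == pytest.approx((row.ligand_mean + row.receptor_mean) / 2)

    def test_rows_sorted_and_complete(self, analysis_inputs):
        opc_expr, mg_expr, pairs, _ = analysis_inputs
        res = gl.run_interaction_analysis(
            opc_expr, mg_expr, pairs, n_perm=20, seed=2
        )
        # 4 OPC groups x 2 microglia conditions
        assert res.table.context.nunique() == 8
        assert len(res.table) == 8 * len(pairs)
        for _, sub in res.table.groupby("context"):
            assert (sub.score.diff().dropna() <= 1e-12).all()

    def test_determinism(self, analysis_inputs):
        opc_expr, mg_expr, pairs, _ = analysis_inputs
        kwargs = dict(contexts=[("KO", "St", "naive")], n_perm=100, seed=33)
        r1 = gl.run_interaction_analysis(opc_expr, mg_expr, pairs, **kwargs)
        r2 = gl.run_interaction_analysis(opc_expr, mg_expr, pairs, **kwargs)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_translation_equivariance(self, analysis_inputs):
        opc_expr, mg_expr, pairs, _ = analysis_inputs
        shift = 3.25
        opc2 = gl.ExpressionMatrix(
            opc_expr.values + shift, transform=opc_expr.transform,
            pseudocount=opc_expr.pseudocount, metadata=opc_expr.metadata,
        )
        mg2 = gl.ExpressionMatrix(
            mg_expr.values + shift, transform=mg_expr.transform,
            pseudocount=mg_expr.pseudocount, metadata=mg_expr.metadata,
        )
        kwargs = dict(contexts=[("WT", "NS", "naive")], n_perm=200, seed=4)
        base = gl.run_interaction_analysis(opc_expr, mg_expr, pairs, **kwargs)
        moved = gl.run_interaction_analysis(opc2, mg2, pairs, **kwargs)
        np.testing.assert_allclose(
            moved.table.score, base.table.score + shift, rtol=0, atol=1e-10
        )
        np.testing.assert_array_equal(moved.table.p_value, base.table.p_value)

    def test_planted_pair_tops_stimulated_context(self, analysis_inputs):
        opc_expr, mg_expr, pairs, truth = analysis_inputs
        res = gl.run_interaction_analysis(
            opc_expr, mg_expr, pairs, contexts=[("WT", "St", "EAE")],
            n_perm=100, seed=5,
        )
        top = res.top_pairs().iloc[0]
        assert (top.ligand, top.receptor) in truth.active_pairs
        assert top.p_value <= 0.05

    def test_missing_pair_gene_skipped_with_reason(self, analysis_inputs):
        opc_expr, mg_expr, pairs, _ = analysis_inputs
        extra = pd.concat(
            [pairs.pairs, pd.DataFrame({"ligand": ["nope"], "receptor": ["nor"],
                                        "name": ["nope_nor"]})],
            ignore_index=True,
        )
        res = gl.run_interaction_analysis(
            opc_expr, mg_expr, gl.LRPairTable(extra),
            contexts=[("WT", "NS", "naive")], n_perm=10, seed=6,
        )
        assert len(res.skipped) == 1
        assert "nope" in res.skipped.iloc[0].reason
        assert len(res.table) == len(pairs)

    def test_input_validation(self, analysis_inputs):
        opc_expr, mg_expr, pairs, _ = analysis_inputs
        with pytest.raises(ValueError, match="empty"):
            gl.run_interaction_analysis(
                opc_expr, mg_expr,
                gl.LRPairTable(pd.DataFrame(columns=["ligand", "receptor"])),
            )
        linear = gl.ExpressionMatrix(
            np.exp2(opc_expr.values), transform="FPKM", metadata=opc_expr.metadata
        )
        with pytest.raises(ValueError, match="log"):
            gl.run_interaction_analysis(linear, mg_expr, pairs)


class TestDotplotExport:
    def table(self):
        return pd.DataFrame(
            {
                "context": ["c1", "c1"],
                "pair": ["A_B", "C_D"],
                "score": [2.0, 2.0],
                "p_value": [0.01, 0.1],
            }
        )

    def test_neg_log10_sizes(self):
        out = gl.export_dotplot_data(self.table())
        assert out.loc[out.pair == "C_D", "neg_log10_p"].iloc[0] == pytest.approx(1.0)
        # equal scores, lower p -> strictly larger circle
        sizes = out.set_index("pair")["neg_log10_p"]
        assert sizes["A_B"] > sizes["C_D"]

    def test_round_trip_exact(self, tmp_path):
        out = gl.export_dotplot_data(self.table())
        path = tmp_path / "dotplot.tsv"
        io.write_table(out, path)
        back = io.read_table(path)
        pd.testing.assert_frame_equal(back, out)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gl.export_dotplot_data(pd.DataFrame(columns=["context", "pair"]))
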