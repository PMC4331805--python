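import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gammaln

from lncgba.expression_io import ExpressionMatrix
from lncgba.coexpression import (
    CoexpressionNetwork,
    CoexpressionNetworkBuilder,
    adjust_and_filter,
    all_pairs,
    pearson_pvalue,
    pearson_r,
)


def matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"c{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df)


def t_two_sided_by_integration(t_obs: float, df: int) -> float:
    """Independent oracle: numerically integrate the t density."""
    log_norm = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    def density(x):
        return np.exp(log_norm - (df + 1) / 2 * np.log1p(x * x / df))
    upper, _ = quad(density, abs(t_obs), np.inf)
    return 2.0 * upper


class TestPearsonR:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3, 4), (2, 4, 6, 8), 1.0),
            ((1, 2, 3, 4), (8, 6, 4, 2), -1.0),
            # hand computation: cov terms sum to 1, each sd is sqrt(2)
            ((1, 2, 3), (1, 3, 2), 0.5),
        ],
    )
    def test_exact_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-15)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            pearson_r((1, 1, 1), (1, 2, 3))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson_r((1, 2), (3, 4))

    @given(
        x=st.lists(st.floats(-100, 100), min_size=4, max_size=12, unique=True),
        a=st.floats(0.01, 50),
        b=st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_affine_invariance(self, x, a, b):
        rng = np.random.default_rng(42)
        y = rng.normal(size=len(x))
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_r(a * np.asarray(x) + b, y) == pytest.approx(r, abs=1e-9)


class TestPearsonPvalue:
    def test_null_center(self):
        assert pearson_pvalue(0.0, 10) == 1.0

    def test_degenerate_bounds(self):
        assert pearson_pvalue(1.0, 19) == 0.0
        assert pearson_pvalue(-1.0, 5) == 0.0

    def test_against_integration_oracle(self):
        r, n = 0.9, 19
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        expected = t_two_sided_by_integration(t, n - 2)
        assert pearson_pvalue(r, n) == pytest.approx(expected, rel=1e-8)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_pvalue(0.5, 2)

    def test_monotone_in_abs_r_and_n(self):
        ps = [pearson_pvalue(r, 19) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        pn = [pearson_pvalue(0.6, n) for n in (5, 10, 19, 40)]
        assert all(a > b for a, b in zip(pn, pn[1:]))


class TestAllPairs:
    def test_cardinality(self):
        lnc = matrix({"L1": [1, 2, 3, 5], "L2": [4, 1, 2, 2]})
        coding = matrix({"G1": [1, 0, 2, 4], "G2": [5, 4, 3, 1],
                         "G3": [2, 2, 1, 0]})
        pairs = all_pairs(lnc, coding)
        assert len(pairs) == 6
        assert list(pairs["lncrna_id"])[:3] == ["L1"] * 3

    def test_zero_variance_pairs_dropped(self):
        lnc = matrix({"L1": [1, 2, 3, 5], "L2": [4, 1, 2, 2]})
        coding = matrix({"G1": [1, 0, 2, 4], "G2": [3, 3, 3, 3]})
        pairs = all_pairs(lnc, coding)
        assert len(pairs) == 2
        assert set(pairs["coding_id"]) == {"G1"}

    def test_identical_profiles_give_r_one(self):
        lnc = matrix({"L1": [1, 2, 3, 5]})
        coding = matrix({"G1": [1, 2, 3, 5]})
        pairs = all_pairs(lnc, coding)
        assert pairs.loc[0, "r"] == 1.0
        assert pairs.loc[0, "p_raw"] == 0.0

    def test_condition_mismatch_rejected(self):
        lnc = matrix({"L1": [1, 2, 3]})
        coding = matrix({"G1": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="conditions"):
            all_pairs(lnc, coding)

    def test_block_size_does_not_change_results(self):
        rng = np.random.default_rng(3)
        lnc = matrix({f"L{i}": rng.uniform(0, 10, 8).tolist() for i in range(9)})
        coding = matrix(
            {f"G{i}": rng.uniform(0, 10, 8).tolist() for i in range(7)}
        )
        reference = all_pairs(lnc, coding, block_size=256)
        for block_size in (1, 2, 4):
            out = all_pairs(lnc, coding, block_size=block_size)
            pd.testing.assert_frame_equal(out, reference)

    def test_agrees_with_scalar_functions(self):
        rng = np.random.default_rng(11)
        lnc = matrix({"L1": rng.uniform(0, 10, 10).tolist()})
        coding = matrix({"G1": rng.uniform(0, 10, 10).tolist()})
        pairs = all_pairs(lnc, coding)
        r = pearson_r(lnc.values[0], coding.values[0])
        assert pairs.loc[0, "r"] == pytest.approx(r, abs=1e-12)
        assert pairs.loc[0, "p_raw"] == pytest.approx(
            pearson_pvalue(r, 10), rel=1e-10
        )


def bh_oracle(pvals):
    """Brute-force BH step-up: sort, scale by m/rank, cumulative min."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    scaled = [pvals[order[k]] * m / (k + 1) for k in range(m)]
    for k in range(m - 2, -1, -1):
        scaled[k] = min(scaled[k], scaled[k + 1])
    out = np.empty(m)
    out[order] = np.minimum(scaled, 1.0)
    return out


class TestAdjustAndFilter:
    def make_pairs(self, rs, ps):
        return pd.DataFrame(
            {
                "lncrna_id": [f"L{i}" for i in range(len(rs))],
                "coding_id": [f"G{i}" for i in range(len(rs))],
                "r": rs,
                "p_raw": ps,
            }
        )

    def test_null_pairs_give_empty_network(self):
        pairs = self.make_pairs([0.0] * 4, [1.0] * 4)
        net = adjust_and_filter(pairs, n_conditions=10)
        assert len(net) == 0

    def test_perfect_pair_retained(self):
        net = adjust_and_filter(self.make_pairs([1.0], [0.0]), n_conditions=10)
        assert len(net) == 1
        assert net.edges.loc[0, "p_adj"] == 0.0

    def test_bh_adjustment_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(size=10)
        pairs = self.make_pairs([0.95] * 10, ps.tolist())
        net = adjust_and_filter(pairs, n_conditions=19, alpha=1.0 - 1e-12)
        expected = bh_oracle(ps)
        got = net.edges.set_index("lncrna_id")["p_adj"]
        for i in range(10):
            assert got[f"L{i}"] == pytest.approx(expected[i], rel=1e-12)

    def test_strict_inequalities(self):
        # |r| exactly at the cutoff and p_adj exactly at alpha are excluded:
        # BH on (0.001, 0.05) adjusts to (0.002, 0.05)
        pairs = self.make_pairs([0.9, 0.95], [0.001, 0.05])
        net = adjust_and_filter(pairs, n_conditions=19)
        assert len(net) == 0

    def test_filter_is_anti_monotone(self):
        rng = np.random.default_rng(8)
        pairs = self.make_pairs(
            rng.uniform(-1, 1, size=50).tolist(),
            rng.uniform(size=50).tolist(),
        )
        loose = adjust_and_filter(pairs, 19, r_cutoff=0.3, alpha=0.9)
        tight = adjust_and_filter(pairs, 19, r_cutoff=0.6, alpha=0.5)
        loose_keys = set(zip(loose.edges["lncrna_id"], loose.edges["coding_id"]))
        tight_keys = set(zip(tight.edges["lncrna_id"], tight.edges["coding_id"]))
        assert tight_keys <= loose_keys


class TestNetwork:
    def test_coexpressed_set_and_unknown_lncrna(self):
        edges = pd.DataFrame(
            {
                "lncrna_id": ["L1", "L1", "L1", "L2"],
                "coding_id": ["G1", "G2", "G3", "G1"],
                "r": [0.95] * 4,
                "p_raw": [1e-8] * 4,
                "p_adj": [1e-6] * 4,
            }
        )
        net = CoexpressionNetwork(edges, n_conditions=19)
        assert net.coexpressed_set("L1") == {"G1", "G2", "G3"}
        assert net.coexpressed_set("nope") == set()

    def test_duplicate_edge_rejected(self):
        edges = pd.DataFrame(
            {
                "lncrna_id": ["L1", "L1"],
                "coding_id": ["G1", "G1"],
                "r": [0.95, 0.96],
                "p_raw": [1e-8, 1e-9],
                "p_adj": [1e-6, 1e-7],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            CoexpressionNetwork(edges, n_conditions=19)

    def test_tsv_round_trip(self, tmp_path, network):
        path = tmp_path / "net.tsv"
        network.to_tsv(path)
        back = CoexpressionNetwork.from_tsv(path, network.n_conditions)
        pd.testing.assert_frame_equal(back.edges, network.edges)


class TestBuilderEstimator:
    def test_fitted_attributes_and_params(self, bundle, network):
        builder = CoexpressionNetworkBuilder(r_cutoff=0.8)
        assert builder.get_params()["r_cutoff"] == 0.8
        builder.set_params(r_cutoff=0.9)
        from lncgba.expression_io import split_by_biotype
        lnc, coding = split_by_biotype(bundle.expression, bundle.catalog)
        builder.fit(lnc, coding)
        assert builder.n_pairs_tested_ == lnc.n_genes * coding.n_genes
        assert builder.n_conditions_ == 19
        pd.testing.assert_frame_equal(builder.network_.edges, network.edges)

    def test_transform_maps_lncrnas_to_sets(self, bundle, network):
        from lncgba.expression_io import split_by_biotype
        lnc, coding = split_by_biotype(bundle.expression, bundle.catalog)
        builder = CoexpressionNetworkBuilder().fit(lnc, coding)
        lnc_id = bundle.truth.modules[0].lncrna_ids[0]
        sets = builder.transform([lnc_id])
        assert sets[lnc_id] == network.coexpressed_set(lnc_id)
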