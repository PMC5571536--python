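import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from reversom import (
    ConfigurationError,
    DomainError,
    InsufficientReplicationError,
    benjamini_hochberg,
    call_degs,
    extract_deg_set,
)
from .conftest import make_two_group_matrix


def bh_bruteforce(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j)/j, input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_all_equal_inputs_stay_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3] * 7), [0.3] * 7)

    def test_single_value_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        q = benjamini_hochberg(p)
        np.testing.assert_allclose(q, bh_bruteforce(p), rtol=0, atol=1e-12)
        sm_q = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, sm_q, rtol=0, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_monotone_and_never_below_input(self, p_list):
        p = np.array(p_list)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        # monotone: smaller p never gets a larger q
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            benjamini_hochberg(bad)


class TestCallDegs:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, size=(20, 4))
        matrix = make_two_group_matrix(vals, vals.copy())
        result = call_degs(matrix, "T", "ref", "alt")
        tab = result.table
        np.testing.assert_allclose(tab["p_value"], 1.0)
        np.testing.assert_allclose(tab["log2_fold_change"], 0.0)
        assert not tab["significant"].any()
        assert (tab["direction"] == "none").all()

    def test_invariant_to_column_and_row_order(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(4, 0.5, size=(30, 6))
        alt = rng.normal(4.5, 0.5, size=(30, 6))
        matrix = make_two_group_matrix(ref, alt)
        base = call_degs(matrix, "T", "ref", "alt").table

        perm_cols = rng.permutation(matrix.values.columns)
        perm_rows = rng.permutation(matrix.values.index)
        from reversom import ExpressionMatrix

        shuffled = ExpressionMatrix(
            values=matrix.values.loc[perm_rows, perm_cols],
            metadata=matrix.metadata.loc[perm_cols],
        )
        again = call_degs(shuffled, "T", "ref", "alt").table
        np.testing.assert_allclose(
            base.loc[again.index, "p_value"], again["p_value"], rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            base.loc[again.index, "log2_fold_change"],
            again["log2_fold_change"],
            rtol=0,
            atol=1e-12,
        )

    def test_q_never_below_p_and_significance_gate(self, sim_default):
        _, matrix, _ = sim_default
        result = call_degs(matrix, "Glom", "db/+", "db/db")
        tab = result.table
        assert (tab["q_value"] >= tab["p_value"] - 1e-15).all()
        assert ((tab["q_value"] < 0.05) == tab["significant"]).all()

    def test_unknown_labels_rejected(self, tiny_matrix):
        with pytest.raises(ConfigurationError, match="tissue"):
            call_degs(tiny_matrix, "kidney", "ctrl", "case")
        with pytest.raises(ConfigurationError, match="group"):
            call_degs(tiny_matrix, "SCN", "ctrl", "treated")

    def test_insufficient_replication_rejected(self, tiny_matrix):
        import pandas as pd

        from reversom import ExpressionMatrix

        # drop one 'case' sample -> only one replicate left
        keep = ["s1", "s2", "s3"]
        small = ExpressionMatrix(
            values=tiny_matrix.values[keep],
            metadata=tiny_matrix.metadata.loc[keep],
        )
        with pytest.raises(InsufficientReplicationError, match="case"):
            call_degs(small, "SCN", "ctrl", "case")


class TestExtractDegSet:
    def test_signs_match_directions(self):
        rng = np.random.default_rng(2)
        n = 200
        ref = rng.normal(5, 0.2, size=(n, 6))
        alt = ref.copy()
        alt[:40] += 2.0   # up-regulated
        alt[40:60] -= 2.0  # down-regulated
        matrix = make_two_group_matrix(ref, alt)
        result = call_degs(matrix, "T", "ref", "alt")
        deg = extract_deg_set(result)
        assert len(deg) == result.n_significant
        tab = result.table
        for gene, sign in deg.members.items():
            assert sign == (1 if tab.loc[gene, "log2_fold_change"] > 0 else -1)
            assert tab.loc[gene, "direction"] == ("up" if sign > 0 else "down")

    def test_empty_when_nothing_significant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, size=(50, 4))
        matrix = make_two_group_matrix(vals, rng.normal(5, 1, size=(50, 4)))
        result = call_degs(matrix, "T", "ref", "alt")
        deg = extract_deg_set(result)
        assert len(deg) == int(result.table["significant"].sum())
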