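"""Unit tests for PSM filtering, normalization, inference, and rollup."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import apcscreen as apc
from apcscreen.quant import DegenerateInputError, base_protein_id

from conftest import make_psm_table


class TestColumnNormalize:
    def test_equal_totals_is_fixed_point(self):
        psms = make_psm_table([[1.0, 2.0], [3.0, 2.0]])
        out = apc.column_normalize(psms)
        pd.testing.assert_frame_equal(out, psms)

    def test_two_psm_worked_example(self):
        # totals [200, 100], mean 150 -> factors 0.75 and 1.5
        psms = make_psm_table([[120.0, 40.0], [80.0, 60.0]])
        out = apc.column_normalize(psms)
        np.testing.assert_allclose(out["ch1"], [90.0, 60.0])
        np.testing.assert_allclose(out["ch2"], [60.0, 90.0])
        np.testing.assert_allclose(out[["ch1", "ch2"]].sum(), [150.0, 150.0])

    def test_single_psm(self):
        psms = make_psm_table([[2.0, 4.0]])
        out = apc.column_normalize(psms)
        np.testing.assert_allclose(out[["ch1", "ch2"]].to_numpy(), [[3.0, 3.0]])

    def test_zero_total_channel_named_in_error(self):
        psms = make_psm_table([[1.0, 0.0]])
        with pytest.raises(DegenerateInputError, match="ch2"):
            apc.column_normalize(psms)

    @given(st.integers(0, 2**32 - 1))
    def test_totals_equal_after_normalization(self, seed):
        rng = np.random.default_rng(seed)
        psms = make_psm_table(rng.lognormal(3, 1, size=(8, 5)))
        totals = apc.column_normalize(psms)[[f"ch{k}" for k in range(1, 6)]].sum()
        np.testing.assert_allclose(totals, totals.mean(), rtol=1e-12)


class TestFilterLowSn:
    @pytest.mark.parametrize(
        "row_sum,kept",
        [(99.9, False), (100.0, True), (150.0, True)],
        ids=["just_below", "exact_boundary", "above"],
    )
    def test_summed_sn_boundary(self, row_sum, kept):
        psms = make_psm_table([[row_sum / 2, row_sum / 2]])
        out = apc.filter_low_sn(psms)
        assert (len(out) == 1) is kept

    def test_empty_table(self):
        psms = make_psm_table(np.empty((0, 3)))
        assert apc.filter_low_sn(psms).empty


class TestProteinProbability:
    def test_product_rule(self):
        assert apc.protein_probability([0.9, 0.8]) == pytest.approx(0.72)

    def test_single_peptide_identity(self):
        assert apc.protein_probability([0.37]) == pytest.approx(0.37)

    def test_log_space_matches_closed_form_for_many_peptides(self):
        p = apc.protein_probability([0.99] * 100)
        assert p == pytest.approx(np.exp(100 * np.log(0.99)), rel=1e-12)
        assert p == pytest.approx(0.366, abs=5e-4)

    def test_best_posterior_per_distinct_peptide(self):
        psms = pd.DataFrame(
            {"peptide": ["AAA", "AAA", "BBB"], "posterior": [0.5, 0.9, 0.8]}
        )
        assert apc.protein_probability(psms) == pytest.approx(0.9 * 0.8)

    def test_zero_posterior_flags_zero(self):
        assert apc.protein_probability([0.9, 0.0]) == 0.0


def _sweep_oracle(picked: pd.DataFrame, fdr_target: float) -> tuple[dict, set]:
    """Brute-force q-values by sweeping every score cutoff over an
    already-picked (best-per-pair) table."""
    cutoffs = sorted(set(picked["score"]))
    q = {}
    for _, row in picked.iterrows():
        fdrs = []
        for c in cutoffs:
            if c <= row["score"]:
                at = picked[picked["score"] >= c]
                n_t = (~at["is_decoy"]).sum()
                n_d = at["is_decoy"].sum()
                fdrs.append(min(1.0, n_d / n_t) if n_t else 1.0)
        q[row["protein"]] = min(fdrs)
    accepted = {
        r["protein"]
        for _, r in picked.iterrows()
        if not r["is_decoy"] and q[r["protein"]] <= fdr_target
    }
    return q, accepted


class TestPickedFdr:
    def test_worked_example(self):
        scores = pd.DataFrame(
            {
                "protein": ["A", "B", "C", "decoy_A", "decoy_B", "decoy_C"],
                "score": [0.99, 0.95, 0.60, 0.50, 0.97, 0.55],
            }
        )
        out = apc.picked_protein_fdr(scores, 0.01)
        # picking keeps A(t, .99), B(d, .97), C(t, .60)
        assert set(out["protein"]) == {"A", "decoy_B", "C"}
        by = out.set_index("protein")
        assert by.loc["A", "q_value"] == pytest.approx(0.0)
        assert by.loc["decoy_B", "q_value"] == pytest.approx(0.5)
        assert by.loc["C", "q_value"] == pytest.approx(0.5)
        assert set(out.loc[out["accepted"], "protein"]) == {"A"}

    def test_no_surviving_decoys_accepts_all_targets(self):
        scores = pd.DataFrame(
            {"protein": ["A", "B", "decoy_A"], "score": [0.9, 0.5, 0.1]}
        )
        out = apc.picked_protein_fdr(scores, 0.01)
        assert set(out.loc[out["accepted"], "protein"]) == {"A", "B"}

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            apc.picked_protein_fdr(pd.DataFrame({"protein": ["A"], "score": [1.0]}), 0.0)

    @given(st.integers(0, 2**32 - 1))
    def test_acceptance_monotone_in_fdr_target(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        prots = [f"P{i}" for i in range(n)] + [f"decoy_P{i}" for i in range(n)]
        scores = pd.DataFrame({"protein": prots, "score": rng.random(2 * n)})
        acc = {}
        for target in (0.01, 0.05, 0.25):
            out = apc.picked_protein_fdr(scores, target)
            acc[target] = set(out.loc[out["accepted"], "protein"])
        assert acc[0.01] <= acc[0.05] <= acc[0.25]

    @given(st.integers(0, 2**32 - 1))
    def test_q_values_match_threshold_sweep(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        prots = [f"P{i}" for i in range(n)] + [f"decoy_P{i}" for i in range(n)]
        scores = pd.DataFrame(
            {"protein": prots, "score": rng.integers(0, 15, size=2 * n) / 10.0}
        )
        out = apc.picked_protein_fdr(scores, 0.05)
        q, accepted = _sweep_oracle(out[["protein", "is_decoy", "score"]], 0.05)
        for _, row in out.iterrows():
            assert row["q_value"] == pytest.approx(q[row["protein"]])
        assert set(out.loc[out["accepted"], "protein"]) == accepted


def exhaustive_min_cover(pep_sets):
    """Oracle: smallest protein set covering all peptides, lexicographic ties."""
    proteins = sorted(set().union(*pep_sets))
    for size in range(1, len(proteins) + 1):
        for combo in itertools.combinations(proteins, size):
            if all(s & set(combo) for s in pep_sets):
                return set(combo)
    return set(proteins)


class TestParsimony:
    def test_worked_example(self):
        psms = make_psm_table(
            np.ones((4, 2)),
            peptides=["p1", "p2", "p3", "p4"],
            proteins=["X;Y", "X", "Y;Z", "Z"],
        )
        assignment, retained = apc.parsimony_collapse(psms)
        assert retained == {"X", "Z"}
        assert assignment == {"p1": "X", "p2": "X", "p3": "Z", "p4": "Z"}

    def test_unique_peptides_identity(self):
        psms = make_psm_table(
            np.ones((3, 2)), peptides=["a", "b", "c"], proteins=["A", "B", "C"]
        )
        assignment, retained = apc.parsimony_collapse(psms)
        assert retained == {"A", "B", "C"}

    def test_identical_peptide_sets_lexicographic_tiebreak(self):
        psms = make_psm_table(
            np.ones((2, 2)), peptides=["a", "b"], proteins=["B;A", "A;B"]
        )
        _, retained = apc.parsimony_collapse(psms)
        assert retained == {"A"}

    @given(st.integers(0, 2**32 - 1))
    def test_matches_exhaustive_set_cover(self, seed):
        rng = np.random.default_rng(seed)
        n_prot = int(rng.integers(2, 8))
        n_pep = int(rng.integers(1, 8))
        prots = [f"P{i}" for i in range(n_prot)]
        pep_sets = [
            set(rng.choice(prots, size=int(rng.integers(1, min(4, n_prot) + 1)),
                           replace=False))
            for _ in range(n_pep)
        ]
        psms = make_psm_table(
            np.ones((n_pep, 2)),
            peptides=[f"pep{i}" for i in range(n_pep)],
            proteins=[";".join(sorted(s)) for s in pep_sets],
        )
        _, retained = apc.parsimony_collapse(psms)
        oracle = exhaustive_min_cover(pep_sets)
        assert len(retained) == len(oracle)
        assert all(s & retained for s in pep_sets)


class TestRollup:
    def test_proportionality(self):
        psms = make_psm_table([[2.0, 3.0, 5.0]])
        ra = apc.rollup_to_ra(psms)
        np.testing.assert_allclose(
            ra[["ra_ch1", "ra_ch2", "ra_ch3"]].to_numpy(), [[20.0, 30.0, 50.0]]
        )

    def test_three_vs_three_worked_example(self):
        psms = make_psm_table([[1, 1, 1, 2, 2, 2]])
        ra = apc.rollup_to_ra(psms)
        expected = np.array([100 / 9] * 3 + [200 / 9] * 3)
        np.testing.assert_allclose(ra.iloc[0, 2:].to_numpy(dtype=float), expected)

    @given(st.integers(0, 2**32 - 1))
    def test_sums_to_100_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3, 1, size=(6, 4))
        peptides = [f"pep{i}" for i in range(6)]
        proteins = [f"P{i % 2}" for i in range(6)]
        psms = make_psm_table(values, peptides=peptides, proteins=proteins)
        ra = apc.rollup_to_ra(psms)
        sums = ra[[c for c in ra.columns if c.startswith("ra_")]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)
        scaled = apc.rollup_to_ra(
            make_psm_table(values * 137.0, peptides=peptides, proteins=proteins)
        )
        pd.testing.assert_frame_equal(ra, scaled)

    def test_distinct_peptide_count(self):
        psms = make_psm_table(
            np.ones((3, 2)), peptides=["a", "a", "b"], proteins=["P1"] * 3
        )
        assert apc.rollup_to_ra(psms)["n_peptides"].tolist() == [2]


class TestQuantifyChain:
    def test_decoys_never_quantified(self, small_dataset):
        psms, _ = small_dataset
        ra = apc.quantify(psms)
        assert not ra["protein"].map(lambda p: p == base_protein_id(p)).eq(False).any()
        assert not ra["protein"].str.startswith("decoy_").any()

    def test_empty_input_gives_empty_output(self):
        assert apc.quantify(pd.DataFrame()).empty

    def test_q_values_within_target(self, small_dataset):
        psms, _ = small_dataset
        ra = apc.quantify(psms, fdr_target=0.01)
        assert (ra["q_value"] <= 0.01).all()
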