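"""Instrument selection: cis filter, clumping, two-study split, F and specificity filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from proteomr.instruments import (
    build_instrument_set,
    cross_protein_pleiotropy_filter,
    f_statistic,
    filter_weak_instruments,
    ld_clump,
    resolve_aptamers,
    select_cis_variants,
    split_sample_effects,
)
from proteomr.ld import LDMatrix
from proteomr.types import InstrumentSet, TrialProteinEffect
from tests.conftest import make_variants


class TestCisSelection:
    def test_window_boundary_is_closed(self):
        df = make_variants([{"pos": 1000 - 500, "p": 1e-9},
                            {"variant_id": "v2", "pos": 1000 - 501, "p": 1e-9}])
        out = select_cis_variants(df, "1", 1000, 2000, cis_window_bp=500, p_threshold=5e-8)
        assert list(out["variant_id"]) == ["v1"]

    def test_threshold_is_strict(self):
        df = make_variants([{"pos": 1500, "p": 5e-8},
                            {"variant_id": "v2", "pos": 1500, "p": 4.9999e-8}])
        out = select_cis_variants(df, "1", 1000, 2000, 500)
        assert list(out["variant_id"]) == ["v2"]

    def test_matches_brute_force_scan(self, rng):
        rows = [{"variant_id": f"v{i}", "chr": str(rng.choice(["1", "2"])),
                 "pos": int(rng.integers(0, 10_000)), "p": float(10 ** -rng.uniform(2, 12))}
                for i in range(10)]
        df = make_variants(rows)
        out = select_cis_variants(df, "1", 4000, 6000, 1000, 5e-8)
        expected = {r["variant_id"] for r in rows
                    if r["chr"] == "1" and 3000 <= r["pos"] <= 7000 and r["p"] < 5e-8}
        assert set(out["variant_id"]) == expected


def _ld(ids, pairs):
    n = len(ids)
    mat = np.zeros((n, n))
    np.fill_diagonal(mat, 1.0)
    idx = {v: i for i, v in enumerate(ids)}
    for a, b, r2 in pairs:
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r2
    return LDMatrix(ids, mat)


class TestClumping:
    def test_correlated_pair_keeps_smaller_p(self):
        df = make_variants([{"variant_id": "a", "pos": 100, "p": 1e-10},
                            {"variant_id": "b", "pos": 200, "p": 1e-9}])
        ld = _ld(["a", "b"], [("a", "b", 0.5)])
        out = ld_clump(df, ld, 0.001, 10_000)
        assert list(out["variant_id"]) == ["a"]

    def test_r2_threshold_strict_below_kept(self):
        df = make_variants([{"variant_id": "a", "pos": 100, "p": 1e-10},
                            {"variant_id": "b", "pos": 200, "p": 1e-9}])
        ld = _ld(["a", "b"], [("a", "b", 0.0005)])
        out = ld_clump(df, ld, 0.001, 10_000)
        assert set(out["variant_id"]) == {"a", "b"}

    def test_outside_window_not_pruned(self):
        df = make_variants([{"variant_id": "a", "pos": 0, "p": 1e-10},
                            {"variant_id": "b", "pos": 10_000_001, "p": 1e-9}])
        ld = _ld(["a", "b"], [("a", "b", 0.9)])
        out = ld_clump(df, ld, 0.001, 10_000)
        assert set(out["variant_id"]) == {"a", "b"}

    def test_matches_exhaustive_greedy_oracle(self, rng):
        # independent oracle: repeatedly take the best remaining p, discard conflicts
        ids = [f"v{i}" for i in range(6)]
        rows = [{"variant_id": v, "pos": 100 * i,
                 "p": float(10 ** -rng.uniform(8, 15))} for i, v in enumerate(ids)]
        mat = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                mat[i, j] = mat[j, i] = rng.choice([0.0, 0.002, 0.5, 0.9])
        np.fill_diagonal(mat, 1.0)
        ld = LDMatrix(ids, mat)
        df = make_variants(rows)

        remaining = sorted(rows, key=lambda r: (r["p"], r["pos"], r["variant_id"]))
        oracle = []
        while remaining:
            best = remaining.pop(0)
            oracle.append(best["variant_id"])
            remaining = [r for r in remaining
                         if ld.get(r["variant_id"], best["variant_id"]) < 0.001]
        out = ld_clump(df, ld, 0.001, 10_000)
        assert set(out["variant_id"]) == set(oracle)

    def test_invariant_to_input_row_order(self, rng):
        rows = [{"variant_id": f"v{i}", "pos": 100 * i, "p": float(10 ** -rng.uniform(8, 15))}
                for i in range(8)]
        ids = [r["variant_id"] for r in rows]
        mat = np.full((8, 8), 0.3)
        np.fill_diagonal(mat, 1.0)
        ld = LDMatrix(ids, mat)
        df = make_variants(rows)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = ld_clump(df, ld, 0.001, 10_000)
        b = ld_clump(shuffled, ld, 0.001, 10_000)
        pd.testing.assert_frame_equal(a, b)

    def test_retained_pairwise_r2_below_threshold(self, rng):
        rows = [{"variant_id": f"v{i}", "pos": 10 * i, "p": float(10 ** -rng.uniform(8, 15))}
                for i in range(8)]
        ids = [r["variant_id"] for r in rows]
        mat = rng.uniform(0, 0.01, (8, 8))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        ld = LDMatrix(ids, mat)
        out = ld_clump(make_variants(rows), ld, 0.005, 10_000)
        kept = list(out["variant_id"])
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.get(a, b) < 0.005


class TestSplitSampleEffects:
    def test_estimation_effects_replace_discovery(self):
        disc = make_variants([{"beta": 0.9, "se": 0.05}])
        est = make_variants([{"beta": 0.4, "se": 0.02}])
        out, dropped = split_sample_effects(disc, est)
        assert out["beta"].iloc[0] == pytest.approx(0.4)
        assert dropped.empty

    def test_absent_variant_dropped_and_logged(self):
        disc = make_variants([{"variant_id": "a"}, {"variant_id": "b"}])
        est = make_variants([{"variant_id": "a"}])
        out, dropped = split_sample_effects(disc, est)
        assert list(out["variant_id"]) == ["a"]
        assert list(dropped["variant_id"]) == ["b"]

    def test_swapped_alleles_in_estimation_are_flipped(self):
        disc = make_variants([{"ea": "A", "oa": "G", "beta": 0.5}])
        est = make_variants([{"ea": "G", "oa": "A", "beta": 0.5, "eaf": 0.3}])
        out, _ = split_sample_effects(disc, est)
        assert out["beta"].iloc[0] == pytest.approx(-0.5)
        assert out["eaf"].iloc[0] == pytest.approx(0.7)

    def test_winners_curse_removed_by_split(self, rng):
        # variants selected at genome-wide significance in a noisy discovery
        # study overestimate their effects; the estimation-study betas do not
        true_beta, se_disc, se_est = 0.3, 0.06, 0.03
        reps, sel_disc, sel_est = 1000, [], []
        zcrit = norm.isf(5e-8 / 2)
        for _ in range(reps):
            bd = true_beta + rng.normal(0, se_disc)
            if abs(bd / se_disc) < zcrit:
                continue
            sel_disc.append(bd)
            sel_est.append(true_beta + rng.normal(0, se_est))
        assert len(sel_disc) > 100
        assert np.mean(sel_disc) > true_beta + 0.01      # upward bias in discovery
        assert abs(np.mean(sel_est) - true_beta) < 3 * se_est / np.sqrt(len(sel_est))


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.2, 0.1, 4.0),
        (0.0, 0.5, 0.0),
        (0.057, 0.0049, (0.057 / 0.0049) ** 2),  # ~135.3
    ])
    def test_squared_wald_z(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected, rel=1e-12)

    def test_weak_instrument_boundary_f_equal_threshold_kept(self):
        pairs = pd.DataFrame({
            "variant_id": ["a", "b", "c"],
            "beta_exp": [np.sqrt(9.9) * 0.1, np.sqrt(10.0) * 0.1, np.sqrt(135.0) * 0.1],
            "se_exp": [0.1, 0.1, 0.1], "p_exp": [1e-8] * 3, "eaf_exp": [0.3] * 3,
            "n_exp": [1000] * 3,
        })
        iset = InstrumentSet(protein="X", pairs=pairs)
        out = filter_weak_instruments(iset, f_min=10.0)
        assert list(out.pairs["variant_id"]) == ["b", "c"]
        assert (out.f_statistics >= 10.0).all()

    def test_all_weak_yields_empty_set_with_provenance(self):
        pairs = pd.DataFrame({"variant_id": ["a"], "beta_exp": [0.01], "se_exp": [0.1],
                              "p_exp": [0.5], "eaf_exp": [0.3], "n_exp": [100]})
        out = filter_weak_instruments(InstrumentSet(protein="X", pairs=pairs))
        assert len(out) == 0
        assert out.provenance[-1]["n_in"] == 1 and out.provenance[-1]["n_out"] == 0


class TestPleiotropyFilter:
    def _iset(self, p_exp):
        pairs = pd.DataFrame({"variant_id": ["a"], "beta_exp": [0.5], "se_exp": [0.05],
                              "p_exp": [p_exp], "eaf_exp": [0.3], "n_exp": [1000]})
        return InstrumentSet(protein="X", pairs=pairs)

    def test_target_strongest_retained(self, variants_factory):
        others = {"X": make_variants([{"variant_id": "a", "p": 1e-12}]),
                  "Y": make_variants([{"variant_id": "a", "p": 1e-9}])}
        out = cross_protein_pleiotropy_filter(self._iset(1e-12), others)
        assert len(out) == 1

    def test_other_protein_stronger_removed(self):
        others = {"X": make_variants([{"variant_id": "a", "p": 1e-9}]),
                  "Y": make_variants([{"variant_id": "a", "p": 1e-12}])}
        out = cross_protein_pleiotropy_filter(self._iset(1e-9), others)
        assert len(out) == 0

    def test_equal_pvalues_tie_retained(self):
        others = {"X": make_variants([{"variant_id": "a", "p": 1e-9}]),
                  "Y": make_variants([{"variant_id": "a", "p": 1e-9}])}
        out = cross_protein_pleiotropy_filter(self._iset(1e-9), others)
        assert len(out) == 1


class TestAptamerResolution:
    def test_lowest_discovery_p_wins_ties_by_seq_id(self):
        t1 = TrialProteinEffect("U1", "GENE", "2000_5", 0.1)
        t2 = TrialProteinEffect("U1", "GENE", "1000_1", 0.2)
        stats = {"2000_5": make_variants([{"p": 1e-20}]),
                 "1000_1": make_variants([{"p": 1e-10}])}
        assert resolve_aptamers([t1, t2], stats)[0].seq_id == "2000_5"
        tie = {"2000_5": make_variants([{"p": 1e-10}]),
               "1000_1": make_variants([{"p": 1e-10}])}
        assert resolve_aptamers([t1, t2], tie)[0].seq_id == "1000_1"


class TestBuildInstrumentSet:
    def test_provenance_conservation_and_determinism(self, rng):
        from proteomr.simulate import SimulationScenario, simulate_ld, simulate_pqtl_studies

        sc = SimulationScenario(n_proteins=3, seed=11)
        disc, est, truth = simulate_pqtl_studies(sc)
        ld = simulate_ld(sc, truth)
        sets = []
        for _ in range(2):
            iset = build_instrument_set("P001", disc["P001"], est["P001"], "1",
                                        1_000_000, 1_100_000, ld,
                                        all_protein_stats=disc)
            for rec in iset.provenance:
                assert rec["n_in"] >= rec["n_out"] >= 0
            sets.append(iset)
        pd.testing.assert_frame_equal(sets[0].pairs, sets[1].pairs)
        assert sets[0].provenance == sets[1].provenance
        assert (sets[0].f_statistics >= 10.0).all()
        summary = sets[0].f_summary()
        assert summary["min"] >= 10.0
        assert summary["min"] <= summary["mean"] <= summary["total"]
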