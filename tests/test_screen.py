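"""Hit-calling mathematics: median/MAD, bands, FDR, categories, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from gtscreen import screen as scr
from tests.conftest import constructed_plate


def sort_based_mad_oracle(values):
    """Naive sort-based median and median-of-absolute-deviations."""
    x = sorted(values)
    n = len(x)
    med = x[n // 2] if n % 2 else (x[n // 2 - 1] + x[n // 2]) / 2.0
    devs = sorted(abs(v - med) for v in x)
    mad = devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2.0
    return med, mad


class TestPlateMad:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10, 12, 14, 100], (13.0, 2.0)),
            ([5, 7, 9], (7.0, 2.0)),
            ([4.0] * 10, (4.0, 0.0)),
        ],
    )
    def test_hand_cases(self, counts, expected):
        assert scr.plate_mad(counts) == expected

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            scr.plate_mad([5.0])

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(3, 385))
            counts = rng.normal(1000, 200, size=n)
            assert scr.plate_mad(counts) == sort_based_mad_oracle(counts)


class TestCallHits:
    def test_band_by_hand(self):
        # plate median 13, MAD 2, k=3 -> band [7, 19]; quadruplet mean 20
        # is hyper at +3.5 MAD, mean 6 is hypo, everything else none
        layout, meas = constructed_plate(n_compound_wells=160, n_controls=0,
                                         base=13.0, spread=2.0)
        _, stats = scr.call_hits(meas, layout)
        assert stats.iloc[0]["median"] == 13.0 and stats.iloc[0]["mad"] == 2.0
        m = meas.copy()
        w1 = layout[layout.compound_id == "CPD01"]["well"]
        w2 = layout[layout.compound_id == "CPD02"]["well"]
        m.loc[m.well.isin(w1), "cell_count"] = 20.0
        m.loc[m.well.isin(w2), "cell_count"] = 6.0
        table, _ = scr.call_hits(m, layout)
        t = table.set_index(["compound_id", "sex"])
        assert t.loc[("CPD01", "male"), "direction"] == "hyper"
        assert t.loc[("CPD01", "male"), "deviation_mads"] == pytest.approx(3.5)
        assert t.loc[("CPD02", "male"), "direction"] == "hypo"
        null_dirs = t.drop(index=["CPD01", "CPD02"], level=0)["direction"]
        assert (null_dirs == "none").all()

    def test_inclusive_boundary(self):
        # 160 compound wells at 990/1010 + 160 controls at 1000:
        # median 1000, MAD 5, anchored against the 4-well replacement below
        layout, meas = constructed_plate(n_compound_wells=160, n_controls=160,
                                         base=1000.0, spread=10.0)
        wells = layout[layout.compound_id == "CPD01"]["well"]
        meas.loc[meas.well.isin(wells), "cell_count"] = 1015.0  # exactly +3 MAD
        incl, _ = scr.call_hits(meas, layout, inclusive=True)
        strict, _ = scr.call_hits(meas, layout, inclusive=False)
        i = incl.set_index(["compound_id", "sex"])
        s = strict.set_index(["compound_id", "sex"])
        assert i.loc[("CPD01", "male"), "direction"] == "hyper"
        assert s.loc[("CPD01", "male"), "direction"] == "none"

    def test_degenerate_plate_no_calls(self):
        layout, meas = constructed_plate(n_compound_wells=16, n_controls=0,
                                         base=500.0, spread=0.0)
        table, stats = scr.call_hits(meas, layout)
        assert stats["degenerate"].all()
        assert (table["direction"] == "none").all()
        assert table["deviation_mads"].isna().all()

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_affine_invariance(self, seed):
        # shifting all counts by +c or scaling by m > 0 preserves directions
        rng = np.random.default_rng(seed)
        layout, meas = constructed_plate(n_compound_wells=160, n_controls=16)
        meas = meas.copy()
        meas["cell_count"] = rng.lognormal(np.log(1500), 0.4, size=len(meas))
        base, _ = scr.call_hits(meas, layout)
        c, m = rng.uniform(10, 500), rng.uniform(0.2, 5.0)
        shifted = meas.assign(cell_count=meas["cell_count"] + c)
        scaled = meas.assign(cell_count=meas["cell_count"] * m)
        for variant in (shifted, scaled):
            table, _ = scr.call_hits(variant, layout)
            assert list(table["direction"]) == list(base["direction"])

    def test_permutation_invariance(self, small_layout, small_screen):
        meas, _ = small_screen
        base, _ = scr.call_hits(meas, small_layout)
        shuffled = meas.sample(frac=1.0, random_state=5).reset_index(drop=True)
        table, _ = scr.call_hits(shuffled, small_layout)
        pd.testing.assert_frame_equal(table, base)


class TestControlFdr:
    def test_fractions(self):
        layout, meas = constructed_plate(n_compound_wells=160, n_controls=8)
        ctrl_wells = layout[layout.role == "control"]["well"].tolist()
        meas.loc[meas.well == ctrl_wells[0], "cell_count"] = 2000.0
        fdr = scr.control_fdr(meas, layout)
        assert fdr.n_controls == 8
        assert fdr.fdr_hyper_percent == pytest.approx(12.5)
        assert fdr.fdr_hypo_percent == 0.0

    def test_no_controls_error(self):
        layout, meas = constructed_plate(n_compound_wells=160, n_controls=0)
        with pytest.raises(ValueError):
            scr.control_fdr(meas, layout)

    def test_null_rate_matches_noise_model(self, small_layout):
        # pure-null screen: pooled control flag rate should be binomially
        # compatible with the lognormal noise model's tail mass outside
        # the 3 MAD band (Monte-Carlo theory oracle)
        from gtscreen import simulate
        from gtscreen.simulate import GrowthParams

        growth = GrowthParams(count_cv=0.08)
        flagged = total = 0
        for seed in range(12):
            meas = simulate.simulate_screen_counts(small_layout, {}, growth, seed=seed)
            fdr = scr.control_fdr(meas, small_layout)
            flagged += fdr.n_hyper_flagged + fdr.n_hypo_flagged
            total += fdr.n_controls
        rng = np.random.default_rng(0)
        sigma = np.sqrt(np.log1p(0.08**2))
        draws = np.exp(rng.normal(-sigma**2 / 2, sigma, size=200_000))
        med = np.median(draws)
        mad = np.median(np.abs(draws - med))
        p_theory = np.mean(np.abs(draws - med) >= 3 * mad)
        se = np.sqrt(p_theory * (1 - p_theory) / total)
        assert abs(flagged / total - p_theory) < max(4 * se, 0.02)


class TestCategorize:
    @pytest.mark.parametrize(
        "direction, shift, expected",
        [
            ("hypo", -4.1, "C1"),
            ("hyper", -3.2, "C2"),
            ("hypo", -0.4, "C3"),
            ("hyper", 0.2, "C3"),
            ("none", -5.0, "not_a_hit"),
        ],
    )
    def test_rules(self, direction, shift, expected):
        table = pd.DataFrame(
            [{
                "compound_id": "X", "sex": "male", "plate_id": "P1",
                "mean_count": 10.0, "mean_nuclear_area": 100.0 + 10.0 * shift,
                "deviation_mads": 4.0 if direction == "hyper" else -4.0,
                "direction": direction,
            }]
        )
        size_stats = pd.DataFrame(
            [{"plate_id": "P1", "sex": "male", "median": 100.0, "mad": 10.0,
              "n_wells_used": 100, "degenerate": False}]
        )
        out = scr.categorize_hits(table, size_stats)
        assert out["category"].iloc[0] == expected

    def test_enlarged_flag(self):
        table = pd.DataFrame(
            [{"compound_id": "X", "sex": "male", "plate_id": "P1",
              "mean_count": 10.0, "mean_nuclear_area": 150.0,
              "deviation_mads": 4.0, "direction": "hyper"}]
        )
        size_stats = pd.DataFrame(
            [{"plate_id": "P1", "sex": "male", "median": 100.0, "mad": 10.0,
              "n_wells_used": 100, "degenerate": False}]
        )
        out = scr.categorize_hits(table, size_stats)
        assert out["category"].iloc[0] == "C3" and out["size_enlarged"].iloc[0]


class TestVennAndConcordance:
    def test_set_algebra(self):
        parts = scr.venn_partition({"A", "B", "C"}, {"B", "D"})
        assert parts == {"male_only": {"A", "C"}, "female_only": {"D"},
                         "both": {"B"}}
        same = scr.venn_partition({"A"}, {"A"})
        assert same["both"] == {"A"} and not same["male_only"]
        solo = scr.venn_partition({"A", "B"}, set())
        assert solo["male_only"] == {"A", "B"}

    def _table(self, directions):
        return pd.DataFrame(
            [{"compound_id": c, "sex": "male", "direction": d}
             for c, d in directions.items()]
        )

    def test_identical_screens_fully_repeat(self):
        t = self._table({"A": "hyper", "B": "hypo", "C": "hypo"})
        n_rep, n_test, _ = scr.concordance(t, t.copy())
        assert (n_rep, n_test) == (3, 3)

    def test_opposite_directions_never_repeat(self):
        a = self._table({"A": "hyper", "B": "hypo"})
        b = self._table({"A": "hypo", "B": "hyper"})
        n_rep, n_test, _ = scr.concordance(a, b)
        assert (n_rep, n_test) == (0, 2)

    def test_absent_compound_excluded(self):
        a = self._table({"A": "hyper", "B": "hypo"})
        b = self._table({"A": "hyper"})
        n_rep, n_test, _ = scr.concordance(a, b, compounds=["A", "B"])
        assert (n_rep, n_test) == (1, 1)


def brute_force_fisher(table):
    """Two-sided Fisher p by full enumeration over margin-consistent tables."""
    from fractions import Fraction
    from math import comb

    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_known_tables(self):
        assert scr.fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0
        assert scr.fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1, abs=1e-15)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            scr.fisher_exact_2x2([[1, -1], [2, 3]])

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_enumeration_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2)).tolist()
            if sum(map(sum, t)) == 0:
                continue
            p = scr.fisher_exact_2x2(t)
            assert p == pytest.approx(brute_force_fisher(t), abs=1e-12)
            assert p == pytest.approx(sps.fisher_exact(t)[1], abs=1e-9)


class TestFamilyEnrichment:
    def test_planted_family_most_enriched(self):
        annotation = {f"C{i}": ("F" if i < 10 else "G") for i in range(100)}
        hits = {f"C{i}" for i in range(10)} | {"C50"}
        table = scr.family_enrichment(hits, annotation)
        enriched = table[table.label == "enriched"]
        assert enriched.iloc[0]["family"] == "F"
        assert enriched.iloc[0]["p"] < 1e-6

    def test_tie_rule_and_single_family(self):
        annotation = {f"C{i}": "F" for i in range(10)}
        table = scr.family_enrichment({"C0", "C1"}, annotation)
        assert table["p"].iloc[0] == 1.0
        # hit fraction equals global fraction exactly -> not strictly
        # greater -> disenriched by the tie rule
        assert table["label"].iloc[0] == "disenriched"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            scr.family_enrichment({"A"}, {})
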