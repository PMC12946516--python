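"""Rank tests, contingency tests, BH adjustment and the comparison tables."""

import numpy as np
import pandas as pd
import pytest

from homeobias.compare import (
    StatisticsError,
    bh_adjust,
    compare_global,
    compare_per_region,
    kruskal_wallis,
    proportion_test,
    rank_sum,
)


class TestKruskalWallis:
    def test_identical_groups_give_p_one(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_separated_groups_match_hand_ranked_formula(self):
        # ranks 1..6; H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2 = 3.857...
        h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        n, r1, r2, rbar = 6, 2.0, 5.0, 3.5
        expect = 12 / (n * (n + 1)) * (3 * (r1 - rbar) ** 2 + 3 * (r2 - rbar) ** 2)
        assert h == pytest.approx(expect)

    def test_null_rejection_rate_calibrated(self, rng):
        rej = sum(
            kruskal_wallis(*(rng.normal(size=20) for _ in range(3)))[1] < 0.05
            for _ in range(1000)
        )
        assert 0.035 <= rej / 1000 <= 0.065

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(StatisticsError):
            kruskal_wallis([1, 2, 3])


class TestRankSum:
    def test_identical_groups(self):
        _, p = rank_sum([1, 2, 3] * 10, [1, 2, 3] * 10)
        assert p == pytest.approx(1.0)

    def test_exact_small_sample(self):
        # all mass of one group below the other: p = 2/C(4,2) = 1/3
        _, p = rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_empty_group_rejected(self):
        with pytest.raises(StatisticsError):
            rank_sum([], [1])

    def test_power_at_large_shift(self, rng):
        hits = sum(
            rank_sum(rng.normal(0, 1, 200), rng.normal(1, 1, 200))[1] < 0.05
            for _ in range(100)
        )
        assert hits == 100

    def test_two_group_kw_equals_rank_sum_p(self, rng):
        a, b = rng.normal(size=500), rng.normal(0.05, 1, 500)
        _, p_kw = kruskal_wallis(a, b)
        _, p_rs = rank_sum(a, b)
        assert p_kw == pytest.approx(p_rs, abs=1e-6)


class TestProportionTest:
    def test_equal_rates_give_zero_chi2(self):
        chi2, p = proportion_test(50, 100, 50, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_2x2(self):
        # O = [[10,90],[30,70]], E = [[20,80],[20,80]] -> chi2 = 12.5
        chi2, _ = proportion_test(np.array([[10, 90], [30, 70]]))
        assert chi2 == pytest.approx(12.5)

    def test_identical_category_distributions(self):
        chi2, p = proportion_test(np.array([[30, 20, 10], [60, 40, 20]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_degenerate_table(self):
        assert proportion_test(np.array([[0, 0], [0, 5]]))[1] == 1.0


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 5), [0.3] * 5)

    def test_order_preserved_and_bounded(self, rng):
        # step-up BH: adjusted >= raw, capped at 1, largest p unchanged,
        # and the adjusted values respect the order of the raw ones
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        assert adj[np.argmax(p)] == pytest.approx(p.max())
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _toy_metrics(rng, n_dyads=300, n_sra=50, tpm_shift=1.0):
    """Minimal metric tables with n_sra rearranged dyads."""
    n = n_dyads
    label_d = np.array(["non_rearranged"] * (n - n_sra) + ["rearranged"] * n_sra)
    dyads = pd.DataFrame({
        "dyad_id": [f"d{i}" for i in range(n)],
        "label": label_d,
        "region_id": [None] * (n - n_sra) + ["SRA01"] * n_sra,
        "heb": rng.normal(size=n),
        "hphb": rng.normal(size=n),
        "dominance": rng.choice(["balanced", "M_dominant", "U_dominant"], n, p=[0.8, 0.1, 0.1]),
    })
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(2 * n)],
        "label": np.repeat(label_d, 2),
        "region_id": np.repeat(dyads["region_id"], 2),
        "global_tpm": rng.lognormal(2, 1, 2 * n) * np.repeat(
            np.where(label_d == "rearranged", tpm_shift, 1.0), 2
        ),
        "expressed": rng.random(2 * n) < 0.9,
        "summit_fe": rng.uniform(1, 10, 2 * n),
        "peak": rng.random(2 * n) < 0.7,
    })
    return genes, dyads


class TestCompareGlobal:
    def test_all_seven_metrics_reported(self, rng):
        genes, dyads = _toy_metrics(rng)
        out = compare_global(genes, dyads)
        assert len(out) == 7
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_missing_rearranged_group_errors(self, rng):
        genes, dyads = _toy_metrics(rng, n_sra=0)
        with pytest.raises(StatisticsError, match="HEB"):
            compare_global(genes, dyads)

    def test_kw_on_category_codes_mode(self, rng):
        genes, dyads = _toy_metrics(rng)
        out = compare_global(genes, dyads, categorical_test="kw_codes")
        assert len(out) == 7
        with pytest.raises(ValueError):
            compare_global(genes, dyads, categorical_test="bogus")

    def test_planted_tpm_shift_detected(self, rng):
        genes, dyads = _toy_metrics(rng, n_dyads=1000, n_sra=200, tpm_shift=0.5)
        out = compare_global(genes, dyads).set_index("metric")
        assert out.loc["TPM", "significant"]
        assert out.loc["TPM", "direction"] == "down"
        assert not out.loc["HEB", "significant"]


class TestComparePerRegion:
    def test_thirteen_regions_give_thirteen_adjusted_ps(self, rng):
        genes, dyads = _toy_metrics(rng, n_dyads=1300, n_sra=650)
        regions = [f"SRA{i:02d}" for i in range(13)]
        dyads.loc[dyads.label == "rearranged", "region_id"] = np.repeat(regions, 50)
        genes["region_id"] = np.repeat(dyads["region_id"], 2).to_numpy()
        out = compare_per_region(genes, dyads)
        heb = out[out.metric == "HEB"]
        assert len(heb) == 13
        assert set(heb["scope"]) == set(regions)

    def test_small_region_flagged_low_n(self, rng):
        genes, dyads = _toy_metrics(rng, n_dyads=300, n_sra=3)
        out = compare_per_region(genes, dyads)
        assert out["low_n"].all()
        assert len(out[out.metric == "TPM"]) == 1
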