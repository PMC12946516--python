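"""FE areas, gene profiles, HPHB and peak-presence calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeobias.chromatin import fe_area, gene_profile, hphb, peak_presence
from homeobias.io import GeneModel, PeakSet, SignalTrack


def track_of(*intervals):
    return SignalTrack(pd.DataFrame(
        [(c, s, e, v) for c, s, e, v in intervals],
        columns=["chrom", "start", "end", "value"],
    ))


GENE = GeneModel("g", "M", "1M", 10_000, 11_000, "+", 10_000)


class TestFeArea:
    def test_rectangle(self):
        track = track_of(("1M", 10_000, 11_000, 2.0))
        assert fe_area(track, GENE) == pytest.approx(2000.0)

    def test_zero_track(self):
        assert fe_area(track_of(("9U", 0, 10, 1.0)), GENE) == 0.0

    def test_abutting_intervals_sum(self):
        track = track_of(("1M", 10_000, 10_500, 1.0), ("1M", 10_500, 11_000, 3.0))
        assert fe_area(track, GENE) == pytest.approx(2000.0)

    def test_additive_over_split_intervals(self):
        one = track_of(("1M", 9_000, 12_000, 1.5))
        split = track_of(("1M", 9_000, 10_000, 1.5), ("1M", 10_000, 12_000, 1.5))
        assert fe_area(one, GENE) == pytest.approx(fe_area(split, GENE))


class TestGeneProfile:
    def test_constant_track_gives_constant_bins(self):
        track = track_of(("1M", 0, 1_000_000, 2.0))
        values, weights = gene_profile(track, GENE)
        np.testing.assert_allclose(values, 2.0)
        assert weights.sum() == pytest.approx(4000 + 1000)

    def test_body_and_flanks_separate(self):
        track = track_of(("1M", 10_000, 11_000, 3.0))
        values, _ = gene_profile(track, GENE, flank=2000, flank_bin=20)
        n_flank = 100
        np.testing.assert_allclose(values[:n_flank], 0.0)
        np.testing.assert_allclose(values[n_flank:-n_flank], 3.0)
        np.testing.assert_allclose(values[-n_flank:], 0.0)

    def test_minus_strand_profile_is_reversed(self):
        track = track_of(("1M", 8_000, 10_500, 1.0), ("1M", 10_500, 13_000, 4.0))
        plus = GeneModel("p", "M", "1M", 10_000, 11_000, "+", 10_000)
        minus = GeneModel("m", "M", "1M", 10_000, 11_000, "-", 10_999)
        vp, _ = gene_profile(track, plus)
        vm, _ = gene_profile(track, minus)
        np.testing.assert_allclose(vm, vp[::-1])

    def test_flank_truncated_at_chromosome_start(self):
        track = track_of(("1M", 0, 5_000, 2.0))
        gene = GeneModel("g", "M", "1M", 500, 1_500, "+", 500)
        _, weights = gene_profile(track, gene, flank=2000, flank_bin=20)
        assert weights.sum() == pytest.approx(500 + 1000 + 2000)

    def test_short_gene_uses_one_bin_per_bp(self):
        track = track_of(("1M", 0, 1_000_000, 1.0))
        gene = GeneModel("g", "M", "1M", 100, 130, "+", 100)
        values, _ = gene_profile(track, gene, body_bins=100)
        assert len(values) == 100 + 30 + 100  # 30 body bins


class TestHphb:
    def test_worked_examples(self):
        assert hphb(100, 100) == 0.0
        assert hphb(200, 50) == pytest.approx(2.0, abs=1e-6)
        assert hphb(0, 100) == pytest.approx(np.log2(1e-6 / (100 + 1e-6)), abs=1e-6)

    @settings(max_examples=200, deadline=None)
    @given(a=st.floats(0, 1e6, allow_nan=False), b=st.floats(0, 1e6, allow_nan=False))
    def test_antisymmetry(self, a, b):
        assert hphb(a, b) == pytest.approx(-hphb(b, a), abs=1e-9)


class TestPeakPresence:
    def peaks(self, *rows):
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def test_peak_in_window(self):
        g = GeneModel("g", "M", "1M", 9_000, 12_000, "+", 10_000)
        assert peak_presence(self.peaks(("1M", 9_800, 9_900)), g)

    def test_half_open_boundary_excluded(self):
        g = GeneModel("g", "M", "1M", 9_000, 12_000, "+", 10_000)
        # peak ends exactly where the window begins: no overlap
        assert not peak_presence(self.peaks(("1M", 9_400, 9_500)), g)
        assert peak_presence(self.peaks(("1M", 9_400, 9_501)), g)

    def test_no_peaks_on_chromosome(self):
        g = GeneModel("g", "M", "1M", 9_000, 12_000, "+", 10_000)
        assert not peak_presence(self.peaks(("2M", 9_800, 9_900)), g)

    def test_downstream_mode_is_strand_aware(self):
        gplus = GeneModel("g", "M", "1M", 9_000, 12_000, "+", 10_000)
        gminus = GeneModel("h", "M", "1M", 9_000, 12_000, "-", 10_500)
        down = self.peaks(("1M", 10_100, 10_200))  # right of both starts
        up = self.peaks(("1M", 9_400, 9_600))
        assert peak_presence(down, gplus, mode="downstream")
        assert not peak_presence(up, gplus, mode="downstream")
        # downstream of a '-' gene extends leftward
        assert peak_presence(down, gminus, mode="downstream")
        assert not peak_presence(self.peaks(("1M", 10_700, 10_800)), gminus,
                                 mode="downstream")


class TestPlantedChromatinSignal:
    def test_equal_planted_signal_gives_near_zero_hphb(self):
        from homeobias.chromatin import dyad_chromatin_table, gene_chromatin_table
        from homeobias.simulate import SimConfig, simulate_all

        # exact 50:50 splits and no ratio wobble -> identical dyad signal
        cfg = SimConfig(
            n_dyads=400, seed=31, dominance_mixture=(1.0, 0, 0),
            split_concentration=None, ratio_noise_sd=0.0, silencing_prob=0.0,
            sra_fraction=0.0,
        )
        d = simulate_all(cfg)
        gtab = gene_chromatin_table(d.tracks, d.peaks, d.truth.genes)
        dtab = dyad_chromatin_table(gtab, d.truth.dyads)
        assert dtab["hphb"].abs().mean() < 0.1

    def test_silenced_gene_has_background_area_only(self):
        from homeobias.chromatin import gene_chromatin_table
        from homeobias.simulate import SimConfig, simulate_all

        cfg = SimConfig(n_dyads=200, seed=32, silencing_prob=0.3)
        d = simulate_all(cfg)
        gtab = gene_chromatin_table(d.tracks, d.peaks, d.truth.genes).set_index("gene_id")
        genes = d.truth.genes.set_index("gene_id")
        silenced = genes[genes["true_silenced"].astype(bool)]
        for gid, row in silenced.head(20).iterrows():
            span = (row.end - row.start) + 4000  # background FE = 1 throughout
            assert gtab.loc[gid, "fe_area"] == pytest.approx(span, rel=1e-6)
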