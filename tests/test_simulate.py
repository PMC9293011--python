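"""Source panels, haplotype-copying admixture, and degradation transforms."""

import numpy as np
import pytest

import admixdate as ad
from admixdate.errors import SimulationError


def hudson_fst(h1, h2):
    """Hudson's pairwise FST estimator from two haplotype panels (oracle)."""
    p1, p2 = h1.mean(axis=0), h2.mean(axis=0)
    n1, n2 = h1.shape[0], h2.shape[0]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return num[keep].mean() / den[keep].mean()


class TestSourcePanels:
    def test_emitted_divergence_matches_requested_fst(self):
        p1, p2 = ad.make_source_panels(10_000, 60, 0.15, [1.0, 1.0], seed=31)
        assert hudson_fst(p1.haplotypes, p2.haplotypes) == pytest.approx(0.15, abs=0.03)

    def test_low_fst_limit_gives_similar_panels(self):
        # Hudson's estimator removes finite-panel sampling noise, so it tracks
        # the generating divergence even as fst -> 0
        p1, p2 = ad.make_source_panels(5_000, 60, 0.002, [1.0], seed=32)
        q1, q2 = ad.make_source_panels(5_000, 60, 0.3, [1.0], seed=32)
        assert hudson_fst(p1.haplotypes, p2.haplotypes) == pytest.approx(0.002, abs=0.01)
        diff_low = np.abs(p1.haplotypes.mean(0) - p2.haplotypes.mean(0)).mean()
        diff_high = np.abs(q1.haplotypes.mean(0) - q2.haplotypes.mean(0)).mean()
        assert diff_low < diff_high / 3

    def test_fixed_seed_is_reproducible(self):
        a = ad.make_source_panels(500, 10, 0.15, [0.5, 0.8], seed=33)
        b = ad.make_source_panels(500, 10, 0.15, [0.5, 0.8], seed=33)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.haplotypes, pb.haplotypes)
            assert pa.snp.equals(pb.snp)

    def test_markers_apportioned_by_length_and_sorted(self):
        p1, _ = ad.make_source_panels(3_000, 6, 0.15, [0.2, 0.6], seed=34)
        per_chrom = p1.snp.groupby("chrom", sort=False).size()
        assert per_chrom["1"] == pytest.approx(750, abs=1)
        assert per_chrom["2"] == pytest.approx(2250, abs=1)
        for _, grp in p1.snp.groupby("chrom", sort=False):
            assert grp["gpos"].is_monotonic_increasing

    def test_fst_out_of_range(self):
        with pytest.raises(SimulationError, match="fst"):
            ad.make_source_panels(100, 6, 1.5, [0.5], seed=1)


class TestSimulateAdmixed:
    def test_alpha_one_copies_only_source_one(self):
        p1, p2 = ad.make_source_panels(2_000, 30, 0.15, [1.0], seed=35)
        spec = ad.AdmixtureSpec(alpha=1.0, t=10, n_individuals=3, seed=36)
        gm, truth = ad.simulate_admixed(p1, p2, spec)
        assert truth.ancestry_fraction("source_1") == 1.0
        # every copied window exists verbatim in the source_1 panel: check a
        # genotype-level consequence — markers fixed in panel 1 are fixed in targets
        fixed = p1.haplotypes.mean(axis=0) == 1.0
        assert np.all(gm.calls[:, fixed] == 2)

    def test_recombination_count_matches_analytic_expectation(self):
        # t = 1, one chromosome of 1 M: expected switches = sum(1 - e^(-2g))
        p1, p2 = ad.make_source_panels(1_000, 400, 0.15, [1.0], seed=37)
        spec = ad.AdmixtureSpec(alpha=0.5, t=1, n_individuals=150, seed=38)
        _, truth = ad.simulate_admixed(p1, p2, spec)
        gaps = np.diff(np.sort(p1.snp["gpos"].to_numpy()))
        expected = np.sum(1.0 - np.exp(-2.0 * gaps))
        switches = [len(per["1"]) - 1 for per in truth.segments]
        assert np.mean(switches) == pytest.approx(expected, abs=0.3)
        assert expected == pytest.approx(2.0, abs=0.1)  # dense-marker limit

    def test_realized_ancestry_fraction(self):
        p1, p2 = ad.make_source_panels(5_000, 80, 0.15, [1.0] * 4, seed=39)
        spec = ad.AdmixtureSpec(alpha=0.2, t=10, n_individuals=10, seed=40)
        _, truth = ad.simulate_admixed(p1, p2, spec)
        assert truth.ancestry_fraction("source_1") == pytest.approx(0.2, abs=0.05)

    def test_tracts_shorten_with_older_admixture(self):
        p1, p2 = ad.make_source_panels(4_000, 400, 0.15, [1.0] * 2, seed=41)
        lengths = {}
        for t in (10, 100):
            spec = ad.AdmixtureSpec(alpha=0.5, t=t, n_individuals=5, seed=42)
            _, truth = ad.simulate_admixed(p1, p2, spec)
            lengths[t] = truth.mean_tract_length()
        assert lengths[100] < lengths[10]

    def test_truth_segments_tile_each_chromosome(self):
        p1, p2 = ad.make_source_panels(2_000, 60, 0.15, [0.8, 1.2], seed=43)
        spec = ad.AdmixtureSpec(alpha=0.3, t=25, n_individuals=4, seed=44)
        _, truth = ad.simulate_admixed(p1, p2, spec)
        gpos = p1.snp.groupby("chrom", sort=False)["gpos"]
        first, last = gpos.min(), gpos.max()
        for per_chrom in truth.segments:
            for chrom, segs in per_chrom.items():
                assert segs[0][0] == pytest.approx(first[chrom])
                assert segs[-1][1] == pytest.approx(last[chrom])
                for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
                    assert e0 == pytest.approx(s1)  # no gaps, no overlaps
                    assert s0 <= e0

    def test_determinism(self):
        p1, p2 = ad.make_source_panels(1_000, 30, 0.15, [1.0], seed=45)
        spec = ad.AdmixtureSpec(alpha=0.3, t=15, n_individuals=3, seed=46)
        gm1, _ = ad.simulate_admixed(p1, p2, spec)
        gm2, _ = ad.simulate_admixed(p1, p2, spec)
        assert np.array_equal(gm1.calls, gm2.calls)

    def test_panel_too_small_for_n(self):
        p1, p2 = ad.make_source_panels(500, 10, 0.15, [1.0], seed=47)
        spec = ad.AdmixtureSpec(alpha=0.5, t=5, n_individuals=5, seed=48)
        with pytest.raises(SimulationError, match="need more than 10"):
            ad.simulate_admixed(p1, p2, spec)

    def test_pool_exhaustion_mid_chromosome(self):
        p1, p2 = ad.make_source_panels(2_000, 14, 0.15, [1.5], seed=49)
        spec = ad.AdmixtureSpec(alpha=0.5, t=300, n_individuals=2, seed=50)
        with pytest.raises(SimulationError, match="exhausted"):
            ad.simulate_admixed(p1, p2, spec)

    def test_t_zero_rejected(self):
        with pytest.raises(SimulationError, match="t must be"):
            ad.AdmixtureSpec(alpha=0.5, t=0, n_individuals=1, seed=1)


class TestMultiway:
    def test_single_event_reduces_to_two_way(self):
        p1, p2, p3 = ad.make_source_panels(1_000, 30, 0.15, [1.0], seed=51, n_panels=3)
        spec = ad.AdmixtureSpec(alpha=0.3, t=12, n_individuals=3, seed=52)
        gm_direct, _ = ad.simulate_admixed(p1, p2, spec)
        gm_multi, truth = ad.simulate_multiway([p1, p2], [spec])
        assert np.array_equal(gm_direct.calls, gm_multi.calls)
        assert truth.labels == [p1.label, p2.label]

    def test_full_replacement_by_third_panel(self):
        p1, p2, p3 = ad.make_source_panels(1_000, 40, 0.15, [1.0], seed=53, n_panels=3)
        ev1 = ad.AdmixtureSpec(alpha=0.5, t=50, n_individuals=8, seed=54)
        ev2 = ad.AdmixtureSpec(alpha=0.0, t=10, n_individuals=3, seed=55)  # all from panel 3
        _, truth = ad.simulate_multiway([p1, p2, p3], [ev1, ev2])
        assert truth.ancestry_fraction(2) == 1.0

    def test_three_way_fractions(self):
        p1, p2, p3 = ad.make_source_panels(3_000, 90, 0.15, [1.0] * 3, seed=56, n_panels=3)
        ev1 = ad.AdmixtureSpec(alpha=0.5, t=60, n_individuals=20, seed=57)
        ev2 = ad.AdmixtureSpec(alpha=2 / 3, t=10, n_individuals=6, seed=58)
        _, truth = ad.simulate_multiway([p1, p2, p3], [ev1, ev2])
        for lid in range(3):
            assert truth.ancestry_fraction(lid) == pytest.approx(1 / 3, abs=0.09)

    def test_panel_event_count_mismatch(self):
        p1, p2 = ad.make_source_panels(100, 10, 0.15, [0.5], seed=59)
        with pytest.raises(SimulationError, match="k\\+1 panels"):
            ad.simulate_multiway([p1, p2], [])


class TestDegradation:
    def _gm(self, seed=60):
        p1, p2 = ad.make_source_panels(10_000, 30, 0.15, [1.0], seed=seed)
        spec = ad.AdmixtureSpec(alpha=0.3, t=10, n_individuals=5, seed=seed + 1)
        gm, _ = ad.simulate_admixed(p1, p2, spec)
        return gm

    def test_pseudo_haploidize_splits_hets_evenly(self):
        gm = self._gm()
        het = gm.calls == 1
        assert het.sum() > 2_000
        ph = ad.pseudo_haploidize(gm, seed=61)
        assert ph.ploidy_mode == "pseudo_haploid"
        assert not (ph.calls == 1).any()
        frac_to_two = (ph.calls[het] == 2).mean()
        assert frac_to_two == pytest.approx(0.5, abs=0.02)
        assert np.array_equal(ph.calls[~het], gm.calls[~het])

    def test_pseudo_haploidize_identity_without_hets(self):
        gm = self._gm()
        gm.calls[gm.calls == 1] = 0
        ph = ad.pseudo_haploidize(gm, seed=62)
        assert np.array_equal(ph.calls, gm.calls)

    def test_pseudo_haploidize_reproducible(self):
        gm = self._gm()
        a = ad.pseudo_haploidize(gm, seed=63)
        b = ad.pseudo_haploidize(gm, seed=63)
        assert np.array_equal(a.calls, b.calls)

    def test_mask_missing_rate_zero_is_identity(self):
        gm = self._gm()
        assert np.array_equal(ad.mask_missing(gm, 0.0, seed=64).calls, gm.calls)

    def test_mask_missing_hits_requested_rate(self):
        gm = self._gm()
        masked = ad.mask_missing(gm, 0.6, seed=65)
        assert (masked.calls == 9).mean() == pytest.approx(0.6, abs=0.02)

    def test_mask_rate_out_of_range(self):
        with pytest.raises(SimulationError, match="rate"):
            ad.mask_missing(self._gm(), 1.0, seed=66)


def test_truth_track_text_round_figures(tmp_path):
    p1, p2 = ad.make_source_panels(500, 20, 0.15, [0.5], seed=67)
    spec = ad.AdmixtureSpec(alpha=0.4, t=8, n_individuals=2, seed=68)
    _, truth = ad.simulate_admixed(p1, p2, spec)
    out = tmp_path / "truth.txt"
    truth.to_text(out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    n_segs = sum(len(s) for per in truth.segments for s in per.values())
    assert len(lines) == n_segs
    first = lines[0].split("\t")
    assert first[1] == "1" and first[4] in ("source_1", "source_2")
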