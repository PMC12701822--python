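"""Generator correctness: placement, contact model, ChIP model, truth record."""


import numpy as np
import pytest

from dsbchrom import (
    CutSiteSet,
    SimulationParams,
    expected_chip_tracks,
    expected_contact_matrix,
    make_sites,
    simulate_chip_pair,
    simulate_contact_pair,
)


class TestMakeSites:
    def test_deterministic_given_seed(self):
        p = SimulationParams(genome=[("chr1", 10_000_000)], seed=5)
        a = make_sites(p, 1, 1_000_000)
        b = make_sites(p, 1, 1_000_000)
        assert a[0].sites == b[0].sites
        assert a[1] == b[1]

    def test_infeasible_packing_raises(self):
        p = SimulationParams(genome=[("chr1", 10_000_000)], seed=0)
        with pytest.raises(ValueError, match="cannot place"):
            make_sites(p, 4, 3_000_000)

    def test_126_sites_pairwise_separation_exhaustive(self):
        p = SimulationParams(
            genome=[("chr1", 200_000_000), ("chr2", 200_000_000)], seed=7
        )
        min_sep = 2_000_000
        sites, boundaries = make_sites(p, 126, min_sep)
        assert len(sites) == 126
        assert len({s[2] for s in sites}) == 126  # unique ranks
        by_chrom = {}
        for chrom, pos, _ in sites:
            by_chrom.setdefault(chrom, []).append(pos)
        for chrom, positions in by_chrom.items():
            length = p.chrom_length(chrom)
            for i, a in enumerate(positions):
                assert 2_000_000 <= a < length - 2_000_000
                for b in positions[i + 1 :]:
                    assert abs(a - b) >= min_sep

    def test_boundaries_are_tad_edges(self):
        p = SimulationParams(genome=[("chr1", 5_000_000)], tad_size=1_000_000, seed=0)
        _, boundaries = make_sites(p, 1, 1_000_000, edge_margin=1_000_000)
        assert boundaries == [("chr1", i * 1_000_000) for i in range(1, 5)]


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"sigma_n": 300_000.0},  # sigma_n >= sigma_b
            {"phi": 1.5},
            {"f_cut": 0.0},
            {"m_tad": 0.5},
            {"k_stripe": -1.0},
            {"genome": [("chr1", 0)]},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)


class TestContactModel:
    def test_null_perturbation_expected_matrices_identical(self):
        p = SimulationParams(
            genome=[("chr1", 8_000_000)], contact_bin_size=100_000,
            k_stripe=0.0, f_cut=1.0, seed=1,
        )
        sites = CutSiteSet([("chr1", 4_000_000, 1)])
        et = expected_contact_matrix(p, sites, "chr1", treated=True)
        eu = expected_contact_matrix(p, sites, "chr1", treated=False)
        np.testing.assert_array_equal(et, eu)

    def test_distance_decay_closed_form(self):
        # alpha=1, s0=bin, no TAD structure: E(2s)/E(s) = ((2s+s0)/(s+s0))^-1
        bin_size = 100_000
        p = SimulationParams(
            genome=[("chr1", 20_000_000)], contact_bin_size=bin_size,
            alpha=1.0, s0=float(bin_size), m_tad=1.0, f_bnd=1.0,
            tad_size=100_000_000, seed=0,
        )
        sites = CutSiteSet([])
        e = expected_contact_matrix(p, sites, "chr1", treated=False)
        for k in (3, 10, 40):
            s = k * bin_size
            expected_ratio = ((2 * s + bin_size) / (s + bin_size)) ** -1.0
            assert e[0, 2 * k] / e[0, k] == pytest.approx(expected_ratio, rel=1e-12)

    def test_sampled_matrix_exactly_symmetric(self):
        p = SimulationParams(
            genome=[("chr1", 10_000_000)], contact_bin_size=100_000, seed=2
        )
        sites = CutSiteSet([("chr1", 5_000_000, 1)])
        treated, untreated, _ = simulate_contact_pair(p, sites)
        for cmap in (treated["chr1"], untreated["chr1"]):
            np.testing.assert_array_equal(cmap.matrix, cmap.matrix.T)

    def test_stripe_strictly_increases_with_k_stripe(self):
        sites = CutSiteSet([("chr1", 5_000_000, 1)])
        means = []
        for k in (0.0, 1.0, 2.0, 4.0):
            p = SimulationParams(
                genome=[("chr1", 10_000_000)], contact_bin_size=100_000,
                k_stripe=k, f_cut=1.0, seed=0,
            )
            e = expected_contact_matrix(p, sites, "chr1", treated=True)
            c = 50  # cut bin
            stripe = np.concatenate([e[c, :c], e[c, c + 1 :]])
            means.append(stripe.mean())
        assert np.all(np.diff(means) > 0)

    def test_stripe_log2_excess_matches_expected_matrix_oracle(self):
        p = SimulationParams(
            genome=[("chr1", 12_000_000)], contact_bin_size=100_000,
            k_stripe=2.0, f_cut=1.0, stripe_extent=1_000_000,
            m_tad=1.0, f_bnd=1.0, tad_size=100_000_000, seed=0,
        )
        sites = CutSiteSet([("chr1", 6_000_000, 1)])
        et = expected_contact_matrix(p, sites, "chr1", treated=True)
        eu = expected_contact_matrix(p, sites, "chr1", treated=False)
        c = 60
        # brute-force average of the analytic means over stripe bins within
        # the stripe extent vs off-stripe bins at the same separations
        stripe_ratio, off_ratio = [], []
        for j in range(et.shape[0]):
            d = abs(j - c)
            if 0 < d <= 10:
                stripe_ratio.append(np.log2(et[c, j] / eu[c, j]))
        for i in range(et.shape[0]):
            for j in range(et.shape[0]):
                d = abs(i - j)
                if 0 < d <= 10 and i != c and j != c:
                    off_ratio.append(np.log2(et[i, j] / eu[i, j]))
        assert np.mean(stripe_ratio) > np.mean(off_ratio) + 0.5
        assert np.mean(off_ratio) == pytest.approx(0.0, abs=1e-12)

    def test_cut_site_outside_genome_names_site(self):
        p = SimulationParams(genome=[("chr1", 1_000_000)], seed=0)
        sites = CutSiteSet([("chr1", 2_000_000, 1)])
        with pytest.raises(ValueError, match="chr1:2000000"):
            simulate_contact_pair(p, sites)

    def test_partial_trailing_bin_flagged(self):
        p = SimulationParams(
            genome=[("chr1", 1_050_000)], contact_bin_size=100_000, seed=0
        )
        sites = CutSiteSet([("chr1", 500_000, 1)])
        treated, _, _ = simulate_contact_pair(p, sites)
        assert treated["chr1"].metadata["partial_last_bin"] == "True"


class TestChipModel:
    def test_phi_zero_strand_tracks_identical(self):
        p = SimulationParams(genome=[("chr1", 4_000_000)], phi=0.0, seed=0)
        sites = CutSiteSet([("chr1", 2_000_000, 1)])
        exp = expected_chip_tracks(p, sites, "chr1")
        np.testing.assert_array_equal(exp["treated_fwd"], exp["treated_rev"])

    def test_no_signal_equal_expected_totals(self):
        p = SimulationParams(
            genome=[("chr1", 4_000_000)], narrow_amplitude=0.0,
            broad_amplitude=0.0, seed=0,
        )
        sites = CutSiteSet([("chr1", 2_000_000, 1)])
        exp = expected_chip_tracks(p, sites, "chr1")
        t = exp["treated_fwd"].sum() + exp["treated_rev"].sum()
        u = exp["untreated_fwd"].sum() + exp["untreated_rev"].sum()
        assert t == pytest.approx(u, rel=1e-12)
        assert t == pytest.approx(p.chip_background() * p.n_chip_bins("chr1"))

    def test_read_conservation_closed_form(self):
        # expected treated total = b*nbins + sum(A_n + A_b) per site
        p = SimulationParams(genome=[("chr1", 10_000_000)], seed=0)
        sites = CutSiteSet([("chr1", 4_000_000, 1), ("chr1", 7_000_000, 2)])
        exp = expected_chip_tracks(p, sites, "chr1")
        total = exp["treated_fwd"].sum() + exp["treated_rev"].sum()
        closed = p.chip_background() * p.n_chip_bins("chr1") + 2 * (
            p.narrow_amplitude + p.broad_amplitude
        )
        # Gaussian mass beyond the chromosome ends is the only discrepancy
        assert total == pytest.approx(closed, rel=1e-3)

    def test_asymmetry_polarity_convention(self):
        # forward excess on the right (telomeric) side within the resection span
        p = SimulationParams(genome=[("chr1", 4_000_000)], phi=0.8, seed=0)
        sites = CutSiteSet([("chr1", 2_000_000, 1)])
        exp = expected_chip_tracks(p, sites, "chr1")
        asym = exp["treated_fwd"] - exp["treated_rev"]
        bsz = p.chip_bin_size
        right = slice((2_000_000 + bsz) // bsz, (2_000_000 + 900) // bsz)
        left = slice((2_000_000 - 900) // bsz, (2_000_000 - bsz) // bsz)
        assert np.all(asym[right] > 0)
        assert np.all(asym[left] < 0)

    def test_boundary_truncation_zeroes_broad_beyond_first_boundary(self):
        p = SimulationParams(
            genome=[("chr1", 4_000_000)], tad_size=1_000_000,
            narrow_amplitude=0.0, truncate_at_boundaries=True, seed=0,
        )
        # narrow amplitude 0 isolates the broad component
        sites = CutSiteSet([("chr1", 2_500_000, 1)])
        exp = expected_chip_tracks(p, sites, "chr1")
        total = exp["treated_fwd"] + exp["treated_rev"]
        b = p.chip_background()
        bsz = p.chip_bin_size
        # boundaries flanking the cut at 2 Mb and 3 Mb
        assert np.all(total[: 2_000_000 // bsz] == pytest.approx(b))
        assert np.all(total[3_000_000 // bsz + 1 :] == pytest.approx(b))
        inside = total[2_100_000 // bsz : 2_900_000 // bsz]
        assert np.all(inside > b)

    def test_overlapping_sites_warn(self):
        p = SimulationParams(genome=[("chr1", 4_000_000)], sigma_b=250_000.0, seed=0)
        sites = CutSiteSet([("chr1", 2_000_000, 1), ("chr1", 2_300_000, 2)])
        _, _, truth = simulate_chip_pair(p, sites)
        assert any("superpose" in w for w in truth.warnings)


class TestTruthRoundTrip:
    def test_yaml_roundtrip_regenerates_bit_identical(self, tmp_path):
        p = SimulationParams(genome=[("chr1", 6_000_000)], contact_bin_size=100_000, seed=11)
        sites = CutSiteSet([("chr1", 3_000_000, 1)])
        treated, _, truth = simulate_contact_pair(p, sites)
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        reread = type(truth).from_yaml(path)
        assert reread.params == truth.params
        assert reread.sites == truth.sites
        assert reread.boundaries == truth.boundaries
        treated2, _, _ = simulate_contact_pair(reread.params, reread.cut_sites)
        np.testing.assert_array_equal(treated["chr1"].matrix, treated2["chr1"].matrix)

    def test_chip_regeneration_deterministic(self, chip_pair, small_params, small_sites):
        treated, _, _ = chip_pair
        sites, boundaries = small_sites
        treated2, _, _ = simulate_chip_pair(small_params, sites, boundaries)
        np.testing.assert_array_equal(
            treated["chr1"].forward, treated2["chr1"].forward
        )
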