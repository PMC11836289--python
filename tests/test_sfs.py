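"""Frequency-spectrum statistics: hand values, identities, oracles, null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocevo import sfs
from vocevo.sfs import FrequencySpectrum

from conftest import random_spectrum


# ---------------------------------------------------------------------------
# independent literal transcription of Tajima's formulas (oracle)
# ---------------------------------------------------------------------------


def tajima_d_literal(n, xi):
    """Straight transcription of the 1989 formulas, kept deliberately
    separate from the library implementation."""
    S = sum(xi)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    k_hat = sum(2.0 * i * (n - i) * xi[i - 1] for i in range(1, n)) / (n * (n - 1))
    return (k_hat - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------


def make_sites(totals, derived=None):
    derived = derived or [1] * len(totals)
    return pd.DataFrame({"position": range(1, len(totals) + 1),
                         "derived_count": derived, "total_count": totals})


class TestSiteFiltering:
    def test_total_count_cutoff_is_inclusive(self):
        sites = make_sites([150, 200, 500])
        assert len(sfs.filter_sites(sites, 200)) == 2

    def test_empty_input_gives_empty_output(self):
        assert len(sfs.filter_sites(make_sites([]), 200)) == 0

    def test_zero_cutoff_is_identity(self):
        sites = make_sites([10, 20, 30])
        pd.testing.assert_frame_equal(sfs.filter_sites(sites, 0), sites)

    def test_order_preserved(self):
        sites = make_sites([500, 150, 300, 250])
        out = sfs.filter_sites(sites, 200)
        assert list(out["total_count"]) == [500, 300, 250]


class TestProjection:
    def test_no_projection_needed(self):
        spec = sfs.build_sfs(make_sites([10], derived=[5]), 10)
        assert spec.xi[4] == pytest.approx(1.0)
        assert spec.S == pytest.approx(1.0)

    def test_monomorphic_site_contributes_nothing(self):
        spec = sfs.build_sfs(make_sites([10], derived=[0]), 10)
        assert spec.S == 0

    def test_hypergeometric_weights_by_hand(self):
        # 2 derived of 6 projected to 4: P(j of 4 drawn are derived)
        # P(1) = C(2,1)C(4,3)/C(6,4) = 8/15, P(2) = C(2,2)C(4,2)/C(6,4) = 6/15
        spec = sfs.build_sfs(make_sites([6], derived=[2]), 4)
        assert spec.xi[0] == pytest.approx(8 / 15)
        assert spec.xi[1] == pytest.approx(6 / 15)
        assert spec.xi[2] == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(ValueError, match="total_count < n_project"):
            sfs.build_sfs(make_sites([6, 3], derived=[2, 1]), 4)

    def test_projection_mass_bounded_by_site_count(self):
        sites = make_sites([50, 60, 70], derived=[10, 30, 1])
        spec = sfs.build_sfs(sites, 20)
        assert spec.S <= 3.0 + 1e-12


class TestThetaEstimators:
    def test_watterson_hand_values(self):
        assert sfs.theta_watterson(
            FrequencySpectrum.from_counts(4, {1: 3})) == pytest.approx(
                3 / (1 + 0.5 + 1 / 3))
        assert sfs.theta_watterson(
            FrequencySpectrum(2, np.array([5.0]))) == pytest.approx(5.0)
        assert sfs.theta_watterson(
            FrequencySpectrum(6, np.zeros(5))) == 0.0

    def test_pi_hand_values(self):
        assert sfs.theta_pi(FrequencySpectrum.from_counts(
            4, {1: 2, 2: 1})) == pytest.approx(20 / 12)
        assert sfs.theta_pi(FrequencySpectrum.from_counts(
            4, {3: 1})) == pytest.approx(0.5)

    def test_theta_h_and_fay_wu_hand_values(self):
        spec = FrequencySpectrum.from_counts(4, {3: 1})
        assert sfs.theta_h(spec) == pytest.approx(1.5)
        assert sfs.fay_wu_h(spec) == pytest.approx(-1.0)

    def test_all_singletons_give_positive_h(self):
        spec = FrequencySpectrum.from_counts(10, {1: 7})
        assert sfs.theta_h(spec) == pytest.approx(2 * 7 / (10 * 9))
        assert sfs.fay_wu_h(spec) > 0

    def test_theta_l_hand_value(self):
        assert sfs.theta_l(FrequencySpectrum.from_counts(
            4, {3: 1})) == pytest.approx(1.0)

    def test_folded_spectrum_rejected(self):
        spec = FrequencySpectrum(6, np.ones(5), folded=True)
        for fn in (sfs.theta_h, sfs.theta_l, sfs.normalized_h_and_e):
            with pytest.raises(ValueError, match="folded"):
                fn(spec)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_pi_plus_h_equals_twice_l(self, seed):
        spec = random_spectrum(np.random.default_rng(seed))
        lhs = sfs.theta_pi(spec) + sfs.theta_h(spec)
        assert lhs == pytest.approx(2 * sfs.theta_l(spec), abs=1e-10)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        # at n = 4, w_pi for class 2 is 8/12 = 2/3; choose xi so that
        # theta_pi = S/a1 exactly: solve on classes {1, 2}
        n = 4
        a1 = 1 + 0.5 + 1 / 3
        # xi1 * 1/2 + xi2 * 2/3 = (xi1 + xi2)/a1 ; xi1 = 2 -> xi2 = 6/7
        xi2 = (2 / a1 - 1.0) / (2 / 3 - 1 / a1)
        spec = FrequencySpectrum(n, np.array([2.0, xi2, 0.0]))
        assert sfs.tajimas_d(spec) == pytest.approx(0.0, abs=1e-12)

    def test_matches_literal_transcription_on_random_spectra(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            spec = random_spectrum(rng)
            expected = tajima_d_literal(spec.n, list(spec.xi))
            assert sfs.tajimas_d(spec) == pytest.approx(expected, abs=1e-10)

    def test_undefined_below_two_sites(self):
        with pytest.raises(ValueError, match="undefined"):
            sfs.tajimas_d(FrequencySpectrum.from_counts(6, {1: 1}))

    def test_singleton_spectrum_attains_minimum(self):
        spec = FrequencySpectrum.from_counts(10, {1: 10})
        assert sfs.tajimas_d(spec) == pytest.approx(sfs.tajimas_d_min(spec))
        assert sfs.normalized_d(spec) == pytest.approx(1.0)

    def test_d_never_below_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            spec = random_spectrum(rng)
            assert sfs.tajimas_d(spec) >= sfs.tajimas_d_min(spec) - 1e-12

    def test_minimum_is_negative(self):
        spec = FrequencySpectrum.from_counts(12, {3: 4, 6: 2})
        assert sfs.tajimas_d_min(spec) < 0


class TestNormalizedHE:
    def test_h_norm_zero_when_pi_equals_l(self):
        # at n = 4, sum_i xi_i i (n - 2i) = 0 makes theta_pi = theta_L:
        # classes {1, 3} with xi = (3, 0, 1)
        spec = FrequencySpectrum(4, np.array([3.0, 0.0, 1.0]))
        h_norm, _ = sfs.normalized_h_and_e(spec)
        assert h_norm == pytest.approx(0.0, abs=1e-12)

    def test_e_zero_when_l_equals_w(self):
        # solve xi on classes {1, 3} at n = 4 so theta_L = theta_W
        a1 = 1 + 0.5 + 1 / 3
        # x/3 + y = (x + y)/a1 with x = 3 -> y
        y = 3 * (1 / a1 - 1 / 3) / (1 - 1 / a1)
        spec = FrequencySpectrum(4, np.array([3.0, 0.0, y]))
        _, e = sfs.normalized_h_and_e(spec)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_neutral_means_are_small(self, neutral_ensemble):
        assert abs(neutral_ensemble.H_norm.mean()) < 0.15
        assert abs(neutral_ensemble.D.mean()) < 0.15


class TestNeutralNull:
    def test_reproducible_given_seed(self):
        a = sfs.simulate_neutral_sfs(8, 12, 50, seed=5)
        b = sfs.simulate_neutral_sfs(8, 12, 50, seed=5)
        np.testing.assert_array_equal(a.D, b.D)
        np.testing.assert_array_equal(a.H_raw, b.H_raw)

    def test_class_lengths_match_msprime_oracle(self):
        """Dual-route check: Kingman class branch lengths and the fixed-S
        conditional mean of raw H agree with an msprime-based simulation."""
        msprime = pytest.importorskip("msprime")
        n, S, reps = 10, 20, 800
        rng = np.random.default_rng(21)
        i = np.arange(1, n)
        w_pi = 2.0 * i * (n - i) / (n * (n - 1))
        w_h = 2.0 * i**2 / (n * (n - 1))
        h_oracle = []
        for ts in msprime.sim_ancestry(samples=n, ploidy=1,
                                       population_size=0.5,
                                       num_replicates=reps, random_seed=17):
            tree = ts.first()
            L = np.zeros(n)
            for u in tree.nodes():
                if tree.parent(u) != -1:
                    L[tree.num_samples(u)] += tree.branch_length(u)
            xi = rng.multinomial(S, L[1:] / L[1:].sum())
            h_oracle.append(w_pi @ xi - w_h @ xi)
        ens = sfs.simulate_neutral_sfs(n, S, 3000, seed=9)
        # conditioning on S biases raw H positive; both routes must agree
        se = np.std(h_oracle) / np.sqrt(len(h_oracle))
        assert ens.H_raw.mean() == pytest.approx(np.mean(h_oracle),
                                                 abs=5 * se + 0.05)


class TestDHTest:
    def test_neutral_observations_have_central_p(self, neutral_ensemble):
        from vocevo.synthetic import gen_sfs
        ps = [sfs.dh_test(gen_sfs(20, 30, seed=s), neutral_ensemble).p_D
              for s in range(120)]
        # p_D of neutral observations is approximately uniform
        assert 0.35 < np.median(ps) < 0.65

    def test_smoothing_floor(self, neutral_ensemble):
        # an observation below every replicate gets p = 1/(n_reps + 1)
        spec = FrequencySpectrum.from_counts(20, {1: 30})  # all singletons
        res = sfs.dh_test(spec, neutral_ensemble)
        assert res.p_D == pytest.approx(1 / (neutral_ensemble.n_reps + 1))

    def test_mismatched_null_rejected(self, neutral_ensemble):
        spec = FrequencySpectrum.from_counts(20, {1: 10})  # S = 10 != 30
        with pytest.raises(ValueError, match="does not match"):
            sfs.dh_test(spec, neutral_ensemble)

    def test_sweep_spectra_get_smaller_joint_p(self, neutral_ensemble):
        from vocevo.synthetic import gen_sfs
        p_neu = [sfs.dh_test(gen_sfs(20, 30, seed=s),
                             neutral_ensemble).p_joint for s in range(60)]
        p_swp = [sfs.dh_test(gen_sfs(20, 30, "sweep", 0.6, seed=s + 500),
                             neutral_ensemble).p_joint for s in range(60)]
        assert np.median(p_swp) < np.median(p_neu)


class TestMafCI:
    def test_all_zero_mafs(self):
        assert sfs.maf_ci_upper(np.zeros(50), n_boot=1000, seed=0) == 0.0

    def test_constant_maf_degenerate_bootstrap(self):
        assert sfs.maf_ci_upper(np.full(30, 0.01), n_boot=1000,
                                seed=0) == pytest.approx(0.01)

    def test_agrees_with_large_replicate_oracle(self):
        rng = np.random.default_rng(3)
        mafs = np.clip(np.abs(np.where(rng.random(1000) < 0.8,
                                       rng.normal(0.001, 0.001, 1000),
                                       rng.normal(0.02, 0.01, 1000))),
                       0, 0.5)
        fast = sfs.maf_ci_upper(mafs, n_boot=2000, seed=1)
        oracle = sfs.maf_ci_upper(mafs, n_boot=20_000, seed=99)
        assert fast == pytest.approx(oracle, rel=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sfs.maf_ci_upper([], n_boot=1000)


class TestScaledSelection:
    def test_zero_and_negative(self):
        assert sfs.popscale_coefficient(0.0, 1e4) == 0.0
        assert sfs.popscale_coefficient(-0.001, 1e4) == -20.0

    def test_human_scale(self):
        # s = 8.2e-4 with Ne ~ 11,600 gives a strongly selected S near 19
        assert sfs.popscale_coefficient(0.00082, 11_585) == pytest.approx(
            19.0, rel=0.01)


class TestIngestion:
    def test_vcf_ac_an_roundtrip(self, tmp_path):
        vcf = tmp_path / "mini.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr14\t100\t.\tA\tG\t.\tPASS\tAC=3;AN=250\n"
            "chr14\t200\t.\tC\tT\t.\tPASS\tAC=100;AN=180\n")
        sites = sfs.sites_from_vcf(vcf)
        assert list(sites["derived_count"]) == [3, 100]
        assert list(sites["total_count"]) == [250, 180]
        assert sites["maf"].iloc[0] == pytest.approx(3 / 250)
        assert sites["maf"].iloc[1] == pytest.approx(80 / 180)

    def test_tsv_minor_count_alias(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("position\tminor_count\ttotal_count\n1\t5\t300\n")
        sites = sfs.sites_from_tsv(p)
        assert sites["derived_count"].iloc[0] == 5

    def test_selection_scan_end_to_end(self):
        rng = np.random.default_rng(0)
        sites = pd.DataFrame({
            "position": np.arange(60),
            "derived_count": rng.integers(1, 40, 60),
            "total_count": rng.integers(210, 400, 60),
        })
        res = sfs.selection_scan(sites, min_total=200, n_project=20)
        assert res.n_sites_used == 60
        assert res.theta_pi + res.theta_h == pytest.approx(2 * res.theta_l)
        assert res.D >= res.D_min
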