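"""Clustering-based and direct dd-cfDNA estimation."""

import numpy as np
import pytest

from ddcfdna import (
    AlleleCountTable,
    AltRatioProfile,
    EstimationError,
    GenotypeTable,
    SimulationConfig,
    alt_ratio_profile,
    direct_dd,
    estimate_with_pre,
    estimate_without_pre,
    k_for_relatedness,
    lin_ccc,
    simulate_pair_genotypes,
    simulate_spikein,
)
from ddcfdna.direct import DirectEstimationError


def profile_from_ratios(ratios: dict[str, float], depth: int = 10000) -> AltRatioProfile:
    counts = {s: (depth - int(round(r * depth)), int(round(r * depth))) for s, r in ratios.items()}
    return alt_ratio_profile(AlleleCountTable("analytic", counts))


def analytic_mixture_profiles(f: float, seed: int = 3, n_snps: int = 300):
    """Noise-free pre/post profiles for a simulated unrelated genotype pair."""
    config = SimulationConfig(n_snps=n_snps, seed=seed, error_rate=0.0)
    rec, don = simulate_pair_genotypes(config)
    pre = profile_from_ratios({s: rec.rows[s] / 2 for s in rec.rows})
    post = profile_from_ratios(
        {s: (1 - f) * rec.rows[s] / 2 + f * don.rows[s] / 2 for s in rec.rows}
    )
    return rec, don, pre, post


class TestEstimateWithPre:
    def test_identical_pre_and_post_gives_zero(self, spikein_profiles):
        est = estimate_with_pre(spikein_profiles[0.0], spikein_profiles[0.0])
        assert est.combined == 0.0
        assert "no-donor-signal" in est.flags

    def test_recovers_simulated_fraction(self, spikein_profiles):
        est = estimate_with_pre(spikein_profiles[0.0], spikein_profiles[0.05])
        assert est.combined == pytest.approx(0.05, abs=0.01)
        assert est.aa_component is not None and est.bb_component is not None
        assert est.combined == pytest.approx(
            np.mean([est.aa_component, est.bb_component])
        )

    def test_noise_free_is_monotonic_in_f(self):
        estimates = []
        for f in [0.0, 0.05, 0.1, 0.2, 0.3, 0.4]:
            _, _, pre, post = analytic_mixture_profiles(f)
            estimates.append(estimate_with_pre(pre, post).combined)
        assert all(b > a for a, b in zip(estimates, estimates[1:]))
        assert estimates[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_symmetry_between_groups(self):
        """AA-side shifts go up, BB-side shifts go down; magnitudes agree on
        noise-free data, so each group alone recovers f."""
        _, _, pre, post = analytic_mixture_profiles(0.08)
        est = estimate_with_pre(pre, post)
        assert est.aa_component == pytest.approx(0.08, abs=1e-3)
        assert est.bb_component == pytest.approx(0.08, abs=1e-3)

    def test_parent_child_uses_two_clusters(self):
        config = SimulationConfig(relatedness="parent_child", seed=17,
                                  mixture_fractions=(0.0, 0.05))
        ds = simulate_spikein(config)
        est = estimate_with_pre(
            alt_ratio_profile(ds.baseline),
            alt_ratio_profile(ds.counts[0.05]),
            relatedness="parent_child",
        )
        assert k_for_relatedness("parent_child") == 2
        assert est.bb.clusters is None or est.bb.clusters.k == 2
        assert est.combined == pytest.approx(0.05, abs=0.012)

    def test_both_groups_unusable_raises(self):
        counts = AlleleCountTable("x", {f"s{i}": (50, 50) for i in range(20)})
        profile = alt_ratio_profile(counts)  # everything heterozygous
        with pytest.raises(EstimationError):
            estimate_with_pre(profile, profile)


class TestEstimateWithoutPre:
    def test_recovers_simulated_fraction(self, spikein_profiles):
        est = estimate_without_pre(spikein_profiles[0.05])
        assert est.combined == pytest.approx(0.05, abs=0.012)

    def test_zero_fraction_near_zero(self, spikein_profiles):
        est = estimate_without_pre(spikein_profiles[0.0])
        assert est.combined == pytest.approx(0.0, abs=0.004)

    def test_high_fraction_flagged_low_confidence(self):
        config = SimulationConfig(seed=23, mixture_fractions=(0.27,))
        ds = simulate_spikein(config)
        est = estimate_without_pre(alt_ratio_profile(ds.counts[0.27]))
        assert "low-confidence->10%" in est.flags


class TestDirectEstimator:
    def _post(self, ratios):
        return profile_from_ratios(ratios)

    def test_opposite_homozygous_donor(self):
        rec = GenotypeTable("recipient", {"s1": 0})
        don = GenotypeTable("donor", {"s1": 2})
        res = direct_dd(rec, don, self._post({"s1": 0.05}))
        assert res.fraction == pytest.approx(0.05)

    def test_heterozygous_donor_doubles(self):
        rec = GenotypeTable("recipient", {"s1": 0})
        don = GenotypeTable("donor", {"s1": 1})
        res = direct_dd(rec, don, self._post({"s1": 0.025}))
        assert res.fraction == pytest.approx(0.05)

    def test_mirrored_decrease_for_hom_alt_recipient(self):
        rec = GenotypeTable("recipient", {"s1": 2})
        don = GenotypeTable("donor", {"s1": 0})
        res = direct_dd(rec, don, self._post({"s1": 0.95}))
        assert res.fraction == pytest.approx(0.05)

    def test_measured_baseline_preferred_over_ideal(self):
        rec = GenotypeTable("recipient", {"s1": 0})
        don = GenotypeTable("donor", {"s1": 2})
        pre = self._post({"s1": 0.01})  # measured baseline above ideal 0
        res = direct_dd(rec, don, self._post({"s1": 0.06}), pre)
        assert res.fraction == pytest.approx(0.05)

    def test_negative_contributions_not_clipped(self):
        rec = GenotypeTable("recipient", {"s1": 0, "s2": 0})
        don = GenotypeTable("donor", {"s1": 2, "s2": 2})
        res = direct_dd(rec, don, self._post({"s1": 0.0, "s2": 0.0}),
                        self._post({"s1": 0.01, "s2": 0.02}))
        assert res.fraction < 0

    def test_no_informative_snp_raises(self):
        rec = GenotypeTable("recipient", {"s1": 1, "s2": 0})
        don = GenotypeTable("donor", {"s1": 2, "s2": 0})
        with pytest.raises(DirectEstimationError):
            direct_dd(rec, don, self._post({"s1": 0.5, "s2": 0.0}))

    def test_exact_on_noise_free_mixtures(self):
        for f in [0.0, 0.03, 0.27]:
            rec, don, pre, post = analytic_mixture_profiles(f)
            res = direct_dd(rec, don, post, pre)
            assert res.fraction == pytest.approx(f, abs=1e-3)

    def test_within_binomial_error_on_simulated_counts(self, spikein, spikein_profiles):
        f = 0.05
        res = direct_dd(spikein.recipient, spikein.donor,
                        spikein_profiles[f], spikein_profiles[0.0])
        # per-SNP contribution noise ~ sqrt(2 p q / depth); mean over n_inf SNPs
        se = np.sqrt(2 * f * (1 - f) / 3000) / np.sqrt(res.n_informative)
        assert abs(res.fraction - f) <= 3 * se + 3e-4

    def test_concordance_with_cluster_estimator(self):
        fracs = (0.0, 0.01, 0.03, 0.05, 0.10, 0.27)
        config = SimulationConfig(mixture_fractions=fracs, seed=7)
        ds = simulate_spikein(config)
        from ddcfdna import alt_ratio_profile

        pre = alt_ratio_profile(ds.baseline)
        direct_vals, cluster_vals = [], []
        for f in fracs:
            post = alt_ratio_profile(ds.counts[f])
            direct_vals.append(direct_dd(ds.recipient, ds.donor, post, pre).fraction)
            cluster_vals.append(estimate_with_pre(pre, post).combined)
        assert lin_ccc(direct_vals, cluster_vals) > 0.98
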