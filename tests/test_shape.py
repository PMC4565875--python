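import math

import numpy as np
import pytest

from isofine import (
    ChemicalFormula,
    averagine_formula,
    bin_distribution,
    cross_entropy,
    entropy,
    kl_divergence,
    normality_report,
    render_profile,
)
from isofine.constants import FWHM_PER_SIGMA
from isofine.errors import (
    BinningError,
    DegenerateRangeError,
    DomainError,
)
from isofine.shape import fwhm_to_sigma


class TestRenderProfile:
    def test_single_stick_area_and_apex(self):
        spec = render_profile([(100.0, 1.0)], fwhm=0.5)
        assert spec.area() == pytest.approx(1.0, abs=1e-6)
        assert spec.peak_mass() == pytest.approx(100.0, abs=0.5 / 20)

    def test_area_conserved_for_stick_sets(self):
        sticks = [(100.0, 0.2), (101.0, 0.5), (102.0, 0.3)]
        for fwhm in (0.01, 0.3, 5.0):
            assert render_profile(sticks, fwhm=fwhm).area() == pytest.approx(
                1.0, abs=1e-6
            )

    def test_two_sticks_resolved_vs_merged(self):
        delta = 1.0
        sticks = [(100.0, 0.5), (100.0 + delta, 0.5)]
        resolved = render_profile(sticks, fwhm=delta / 2)
        merged = render_profile(sticks, fwhm=2 * delta)

        def n_maxima(spec):
            y = spec.intensity
            return int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])))

        assert n_maxima(resolved) == 2
        assert n_maxima(merged) == 1

    def test_resolving_power_sets_fwhm_per_stick(self):
        spec = render_profile([(1000.0, 1.0)], resolving_power=1000.0,
                              grid_step=0.002)
        # FWHM = 1 Da -> sigma ~ 0.4247 Da; check half-maximum crossing
        half = spec.intensity.max() / 2
        above = spec.mass_grid[spec.intensity >= half]
        assert above[-1] - above[0] == pytest.approx(1.0, abs=0.01)

    def test_fwhm_sigma_conversion(self):
        assert fwhm_to_sigma(586.0) == pytest.approx(249.0, abs=1.0)
        assert FWHM_PER_SIGMA == pytest.approx(2 * math.sqrt(2 * math.log(2)), rel=1e-12)

    def test_insufficient_grid_rejected(self):
        with pytest.raises(DomainError):
            render_profile([(100.0, 1.0)], fwhm=1.0, mass_min=99.0, mass_max=101.0)

    def test_requires_exactly_one_resolution_spec(self):
        with pytest.raises(DomainError):
            render_profile([(100.0, 1.0)])
        with pytest.raises(DomainError):
            render_profile([(100.0, 1.0)], fwhm=1.0, resolving_power=10.0)


class TestBinDistribution:
    def test_point_mass_pseudocount_arithmetic(self):
        # all weight W on one point, 2 bins: fractions (W+1, 1)/(W+2)
        W = 10.0
        b = bin_distribution([1.0], [W], n_bins=2, bin_range=(0.0, 2.0))
        assert b.mass_fraction == pytest.approx([1.0 / (W + 2), (W + 1) / (W + 2)])

    def test_uniform_weights_equal_fractions(self):
        b = bin_distribution([0.5, 1.5, 2.5, 3.5], [1, 1, 1, 1], n_bins=4,
                             bin_range=(0.0, 4.0))
        assert b.mass_fraction == pytest.approx([0.25] * 4)

    def test_fractions_sum_to_one_and_positive(self):
        rng = np.random.default_rng(0)
        b = bin_distribution(rng.normal(size=100), rng.random(100), n_bins=50)
        assert math.fsum(b.mass_fraction) == pytest.approx(1.0, abs=1e-12)
        assert np.all(b.mass_fraction > 0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            bin_distribution([1.0, 1.0], [1.0, 1.0], n_bins=2)

    def test_shared_range_gives_identical_edges(self):
        p = bin_distribution([0.0, 1.0], [1, 1], n_bins=10, bin_range=(0.0, 2.0))
        q = bin_distribution([0.5, 2.0], [1, 1], n_bins=10, bin_range=(0.0, 2.0))
        assert np.array_equal(p.bin_edges, q.bin_edges)


class TestDivergences:
    def _binned(self, fractions):
        from isofine.shape import BinnedDistribution

        fractions = np.asarray(fractions, dtype=float)
        edges = np.linspace(0, 1, len(fractions) + 1)
        return BinnedDistribution(edges, fractions, True)

    def test_identical_distributions_have_zero_divergence(self):
        p = self._binned([0.25, 0.75])
        assert kl_divergence(p, p) == 0.0

    def test_two_bin_hand_value(self):
        p = self._binned([0.5, 0.5])
        q = self._binned([0.25, 0.75])
        expected = 0.5 * math.log(2) + 0.5 * math.log(2.0 / 3.0)
        assert kl_divergence(p, q) == pytest.approx(expected, rel=1e-12)

    def test_cross_entropy_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pf = rng.random(20) + 1e-3
            qf = rng.random(20) + 1e-3
            p = self._binned(pf / pf.sum())
            q = self._binned(qf / qf.sum())
            assert cross_entropy(p, q) - entropy(p) == pytest.approx(
                kl_divergence(p, q), abs=1e-12
            )
            assert kl_divergence(p, q) >= 0

    def test_mismatched_edges_rejected(self):
        p = self._binned([0.5, 0.5])
        q = self._binned([0.2, 0.3, 0.5])
        with pytest.raises(BinningError):
            kl_divergence(p, q)


class TestNormalityReport:
    def test_divergence_nonnegative_and_identity(self):
        rep = normality_report(averagine_formula(50), min_prob=1e-6, n_bins=200)
        assert rep.kl_divergence >= 0
        assert rep.cross_entropy - rep.entropy == pytest.approx(
            rep.kl_divergence, abs=1e-12
        )

    def test_single_fine_peak_variant_undefined(self):
        with pytest.raises(DegenerateRangeError):
            normality_report(ChemicalFormula({"C": 5}), j=1)

    def test_divergence_decreases_with_size(self):
        kls = [
            normality_report(averagine_formula(nu), min_prob=1e-5).kl_divergence
            for nu in (100, 400)
        ]
        assert kls[0] > kls[1] > 0

    def test_sampling_mode_reproducible(self):
        f = averagine_formula(100)
        a = normality_report(f, seed=11, n_samples=2000)
        b = normality_report(f, seed=11, n_samples=2000)
        assert a.kl_divergence == b.kl_divergence
        c = normality_report(f, seed=12, n_samples=2000)
        assert c.kl_divergence != a.kl_divergence
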