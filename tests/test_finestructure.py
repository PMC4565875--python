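import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isofine import (
    ChemicalFormula,
    aggregated_distribution,
    averagine_formula,
    count_fine_peaks,
    enumerate_fine_peaks,
    max_spread,
    mean_spacing,
    monoisotopic_mass,
    peak_probability,
    sample_ions,
)
from isofine.errors import DomainError, UndefinedSpacingError
from oracle import brute_force_stats


class TestEnumerate:
    def test_chnos_j1_has_five_substitutions(self, chnos_small):
        fs = enumerate_fine_peaks(chnos_small, 1)
        assert len(fs) == 5
        # each peak is a single heavy substitution
        for p in fs.peaks:
            heavies = {
                k: v for k, v in p.isotope_counts.items()
                if k not in {("C", 12), ("H", 1), ("N", 14), ("O", 16), ("S", 32)}
            }
            assert sum(heavies.values()) == 1
        assert fs.captured == pytest.approx(fs.q_j, rel=1e-12)

    def test_j0_single_monoisotopic_peak(self, chnos_small, table):
        fs = enumerate_fine_peaks(chnos_small, 0)
        assert len(fs) == 1
        expected = 1.0
        for el, n in chnos_small:
            expected *= table[el][0].abundance ** n
        assert fs.peaks[0].probability == pytest.approx(expected, rel=1e-12)
        assert fs.peaks[0].mass == pytest.approx(
            monoisotopic_mass(chnos_small), rel=1e-12
        )

    def test_unattainable_j_gives_empty_structure(self):
        fs = enumerate_fine_peaks(ChemicalFormula({"C": 2}), 5)
        assert len(fs) == 0 and fs.q_j == 0.0

    def test_probabilities_sum_to_q_j(self, chnos_small):
        agg = aggregated_distribution(chnos_small)
        for j in (1, 2, 3):
            fs = enumerate_fine_peaks(chnos_small, j, min_prob=0.0)
            idx = np.searchsorted(agg.j, j)
            assert fs.captured == pytest.approx(float(agg.q[idx]), rel=1e-9)

    def test_min_prob_prunes_but_keeps_top_peaks(self, chnos_small):
        full = enumerate_fine_peaks(chnos_small, 2, min_prob=0.0)
        pruned = enumerate_fine_peaks(chnos_small, 2, min_prob=0.05)
        assert 0 < len(pruned) < len(full)
        kept = {tuple(sorted(p.isotope_counts.items())) for p in pruned.peaks}
        for p in full.peaks:
            if p.probability >= 0.05 * full.q_j:
                assert tuple(sorted(p.isotope_counts.items())) in kept
        assert pruned.captured <= full.captured

    def test_peaks_sorted_by_descending_probability(self, chnos_small):
        fs = enumerate_fine_peaks(chnos_small, 2)
        probs = fs.probabilities()
        assert np.all(np.diff(probs) <= 0)

    def test_worked_isotopologue_probability(self):
        """The printed 213x13C 3x2H 21x15N 2x17O 12x18O 1x33S 7x34S peak of
        the 4000-unit poly-averagine has multinomial probability ~8e-7."""
        f = averagine_formula(4000)
        p = peak_probability(
            f,
            {("C", 13): 213, ("H", 2): 3, ("N", 15): 21, ("O", 17): 2,
             ("O", 18): 12, ("S", 33): 1, ("S", 34): 7},
        )
        assert p == pytest.approx(8e-7, rel=0.05)

    def test_peak_probability_matches_enumeration(self, chnos_small):
        fs = enumerate_fine_peaks(chnos_small, 2)
        for peak in fs.peaks:
            heavy = {
                k: v
                for k, v in peak.isotope_counts.items()
                if k not in {("C", 12), ("H", 1), ("N", 14), ("O", 16), ("S", 32)}
            }
            assert peak_probability(chnos_small, heavy) == pytest.approx(
                peak.probability, rel=1e-12
            )


class TestCount:
    @pytest.mark.parametrize("j, expected", [(0, 1), (1, 5), (2, 17)])
    def test_chnos_counts(self, chnos_small, j, expected):
        assert count_fine_peaks(chnos_small, j) == expected

    def test_count_matches_enumeration_small(self, oracle_table):
        for counts in [{"C": 2, "H": 2, "N": 2, "O": 2, "S": 2},
                       {"S": 3}, {"O": 4, "S": 1}, {"C": 1, "S": 2}]:
            variants, *_ = brute_force_stats(counts, oracle_table)
            f = ChemicalFormula(counts)
            for j, ref in variants.items():
                assert count_fine_peaks(f, j) == ref.n_peaks

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S"]),
            st.integers(min_value=1, max_value=30),
            min_size=1,
        ),
        st.sampled_from(["C", "H", "N", "O", "S"]),
        st.integers(min_value=0, max_value=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_nondecreasing_in_atom_counts(self, counts, el, j):
        f1 = ChemicalFormula(counts)
        bigger = dict(counts)
        bigger[el] = bigger.get(el, 0) + 1
        f2 = ChemicalFormula(bigger)
        assert count_fine_peaks(f2, j) >= count_fine_peaks(f1, j)

    def test_averagine_2000_j142_count_fast_and_in_range(self):
        import time

        f = averagine_formula(2000)
        t0 = time.time()
        n = count_fine_peaks(f, 142)
        assert time.time() - t0 < 1.0
        assert 1e10 <= n <= 3e10


class TestSpread:
    def test_universal_unit_value(self, table):
        mu2h = table.mass_per_neutron("H", 1)
        mu15n = table.mass_per_neutron("N", 1)
        assert max_spread(ChemicalFormula({"C": 1, "H": 1, "N": 1}), 1) == (
            pytest.approx(mu2h - mu15n, rel=1e-12)
        )
        assert mu2h - mu15n == pytest.approx(0.00924, abs=1e-5)

    def test_j0_spread_is_zero(self, chnos_small):
        assert max_spread(chnos_small, 0) == 0.0
        assert max_spread(chnos_small, 0, mode="bounded") == 0.0

    def test_bounded_below_universal_without_h_and_n(self):
        f = ChemicalFormula({"C": 10, "O": 5})
        assert max_spread(f, 2, mode="bounded") < max_spread(f, 2, mode="universal")

    def test_bounded_equals_universal_when_enough_h_and_n(self, chnos_small):
        # j <= min(#H, #N) = 2
        for j in (1, 2):
            assert max_spread(chnos_small, j, mode="bounded") == pytest.approx(
                max_spread(chnos_small, j, mode="universal"), rel=1e-12
            )

    def test_bounded_matches_brute_force(self, oracle_table):
        for counts in [{"C": 2, "H": 2, "N": 2, "O": 2, "S": 2},
                       {"C": 3, "O": 3}, {"H": 2, "S": 2}]:
            variants, *_ = brute_force_stats(counts, oracle_table)
            f = ChemicalFormula(counts)
            for j, ref in variants.items():
                got = max_spread(f, j, mode="bounded") if j > 0 else 0.0
                assert got == pytest.approx(
                    ref.max_mass - ref.min_mass, rel=1e-9, abs=1e-15
                )


class TestSpacing:
    def test_direct_ratio(self, chnos_small):
        expected = max_spread(chnos_small, 1) / 5
        assert mean_spacing(chnos_small, 1) == pytest.approx(expected, rel=1e-12)

    def test_k_sigma_zero_width(self, chnos_small):
        assert mean_spacing(chnos_small, 1, width_mode="k_sigma", k=0.0) == 0.0

    def test_single_peak_undefined(self):
        with pytest.raises(UndefinedSpacingError):
            mean_spacing(ChemicalFormula({"C": 5}), 1)

    def test_averagine_2000_conservative_estimate_order(self):
        """Spread-based spacing of the j=142 variant lands at 1e-11..1e-10 Da,
        consistent with the printed conservative estimate."""
        sp = mean_spacing(averagine_formula(2000), 142)
        assert 1e-11 < sp < 1e-10


class TestSampleIons:
    def test_uniform_occupancy_printed_example(self):
        rep = sample_ions(n_peaks=2_000_000, n_ions=200_000, seed=0)
        assert rep.mean_occupancy == 0.1
        assert rep.counts.sum() == 200_000

    def test_zero_ions(self):
        rep = sample_ions(n_peaks=10, n_ions=0, seed=0)
        assert rep.occupied_fraction == 0.0

    def test_seed_determinism(self, chnos_small):
        fs = enumerate_fine_peaks(chnos_small, 1)
        a = sample_ions(fine=fs, n_ions=1000, seed=42)
        b = sample_ions(fine=fs, n_ions=1000, seed=42)
        assert np.array_equal(a.counts, b.counts)
        c = sample_ions(fine=fs, n_ions=1000, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_requires_a_source(self):
        with pytest.raises(DomainError):
            sample_ions(n_ions=5, seed=0)
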