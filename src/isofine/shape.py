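"""Peak-shape rendering and divergence-from-normality analysis.

A stick spectrum rendered at finite resolving power is the sum of Gaussian
kernels of unit-probability area; divergence from normality of a fine
structure is measured by discretizing both the enumerated fine peaks and the
matching normal onto a shared histogram (with pseudo-counts) and computing
entropy, cross-entropy and the Kullback-Leibler divergence
D_KL(P||Q) = sum_i ln(P_i/Q_i) P_i, which satisfies H(P,Q) = H(P) + D_KL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem import ChemicalFormula
from .constants import FWHM_PER_SIGMA
from .errors import BinningError, DegenerateRangeError, DomainError
from .isotopes import DEFAULT_TABLE, IsotopeTable


@dataclass(frozen=True)
class ProfileSpectrum:
    """Profile rendering of a stick spectrum on a uniform mass grid.

    ``intensity`` is probability density per Da; trapezoidal area equals the
    total stick probability (1 for a normalized stick set).
    """

    mass_grid: np.ndarray
    intensity: np.ndarray

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.mass_grid))

    def peak_mass(self) -> float:
        return float(self.mass_grid[int(np.argmax(self.intensity))])


@dataclass(frozen=True)
class BinnedDistribution:
    """Histogram over uniform bins, pseudo-counted and normalized."""

    bin_edges: np.ndarray
    mass_fraction: np.ndarray
    pseudo_count_applied: bool

    @property
    def n_bins(self) -> int:
        return len(self.mass_fraction)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> standard deviation (factor 2*sqrt(2 ln 2))."""
    return fwhm / FWHM_PER_SIGMA


def render_profile(
    sticks: list[tuple[float, float]],
    fwhm: float | None = None,
    resolving_power: float | None = None,
    grid_step: float | None = None,
    mass_min: float | None = None,
    mass_max: float | None = None,
) -> ProfileSpectrum:
    """Render sticks (mass, probability) as a sum of Gaussians.

    Give either an absolute ``fwhm`` (Da) or a ``resolving_power`` R, in
    which case each stick uses FWHM = mass / R at its own mass.  The grid
    must cover every stick by at least 5 FWHM on each side; when bounds are
    omitted, such a grid is built automatically.
    """
    if not sticks:
        raise DomainError("at least one stick required")
    if (fwhm is None) == (resolving_power is None):
        raise DomainError("give exactly one of fwhm or resolving_power")
    masses = np.array([s[0] for s in sticks], dtype=float)
    probs = np.array([s[1] for s in sticks], dtype=float)
    if fwhm is not None:
        if fwhm <= 0:
            raise DomainError("fwhm must be positive")
        fwhms = np.full_like(masses, fwhm)
    else:
        if resolving_power <= 0:
            raise DomainError("resolving power must be positive")
        fwhms = masses / resolving_power
    sigmas = fwhms / FWHM_PER_SIGMA

    lo_req = float(np.min(masses - 5 * fwhms))
    hi_req = float(np.max(masses + 5 * fwhms))
    lo = lo_req if mass_min is None else mass_min
    hi = hi_req if mass_max is None else mass_max
    if lo > lo_req or hi < hi_req:
        raise DomainError(
            f"grid [{lo}, {hi}] does not cover sticks +/- 5 FWHM "
            f"([{lo_req}, {hi_req}])"
        )
    step = grid_step if grid_step is not None else float(np.min(fwhms)) / 20.0
    grid = np.arange(lo, hi + step, step)
    intensity = np.zeros_like(grid)
    for m, p, s in zip(masses, probs, sigmas):
        intensity += p * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    return ProfileSpectrum(mass_grid=grid, intensity=intensity)


def bin_distribution(
    masses,
    weights,
    n_bins: int = 1000,
    pseudo_count: float = 1.0,
    bin_range: tuple[float, float] | None = None,
) -> BinnedDistribution:
    """Histogram weighted masses into equal-width bins with pseudo-counts.

    The range defaults to [min, max] of the input; pass ``bin_range`` to
    share edges between two distributions.  ``pseudo_count`` is added to
    every bin's accumulated weight before normalization, so every fraction
    is strictly positive.
    """
    masses = np.asarray(masses, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if masses.size == 0:
        raise DomainError("at least one point required")
    if n_bins < 2:
        raise DomainError("n_bins must be >= 2")
    lo, hi = bin_range if bin_range is not None else (masses.min(), masses.max())
    if hi <= lo:
        raise DegenerateRangeError(f"zero-width mass range [{lo}, {hi}]")
    counts, edges = np.histogram(masses, bins=n_bins, range=(lo, hi), weights=weights)
    counts = counts + pseudo_count
    return BinnedDistribution(
        bin_edges=edges,
        mass_fraction=counts / counts.sum(),
        pseudo_count_applied=pseudo_count > 0,
    )


def _check_compatible(p: BinnedDistribution, q: BinnedDistribution):
    if p.n_bins != q.n_bins or not np.allclose(p.bin_edges, q.bin_edges):
        raise BinningError("distributions are binned on different edges")


def entropy(p: BinnedDistribution) -> float:
    """Shannon entropy H(P) in nats (0 log 0 = 0)."""
    f = p.mass_fraction
    nz = f > 0
    return float(-np.sum(f[nz] * np.log(f[nz])))


def cross_entropy(p: BinnedDistribution, q: BinnedDistribution) -> float:
    """H(P, Q) = -sum_i P_i ln Q_i, in nats."""
    _check_compatible(p, q)
    if np.any(q.mass_fraction <= 0):
        raise DomainError("Q must be strictly positive (apply pseudo-counts)")
    nz = p.mass_fraction > 0
    return float(-np.sum(p.mass_fraction[nz] * np.log(q.mass_fraction[nz])))


def kl_divergence(p: BinnedDistribution, q: BinnedDistribution) -> float:
    """D_KL(P||Q) = sum_i ln(P_i/Q_i) P_i, in nats."""
    return cross_entropy(p, q) - entropy(p)


@dataclass(frozen=True)
class NormalityReport:
    """Entropy / cross-entropy / KL divergence of a fine structure vs the
    moment-matched normal, plus the inputs that produced them."""

    formula: str
    j: int
    entropy: float
    cross_entropy: float
    kl_divergence: float
    n_bins: int
    n_peaks: int
    captured: float


def normality_report(
    formula: ChemicalFormula,
    table: IsotopeTable = DEFAULT_TABLE,
    j: int | None = None,
    min_prob: float = 1e-5,
    n_bins: int = 1000,
    pseudo_count: float = 1.0,
    count_scale: float = 1e6,
    seed: int | None = None,
    n_samples: int | None = None,
) -> NormalityReport:
    """How far the fine structure of variant *j* is from a normal law.

    P is the enumerated fine structure of variant *j* (default: the most
    abundant one), Q a normal with the variant's center mass and variance,
    both discretized onto the same ``n_bins`` equal-width bins spanning P's
    support extended by one bin width, with ``pseudo_count`` added per bin.
    Probabilities are scaled to pseudo-sample counts of total ``count_scale``
    before pseudo-counting.  Passing ``seed`` and ``n_samples`` switches P to
    a random sample drawn from the fine distribution (the sampling protocol
    of replicate-based studies) instead of exact weights.
    """
    from .finestructure import enumerate_fine_peaks
    from .moments import aggregated_distribution

    agg = aggregated_distribution(formula, table)
    if j is None:
        j = agg.most_abundant()
    idx = agg._loc(j)
    mu, var = float(agg.center_mass[idx]), float(agg.variance[idx])
    fine = enumerate_fine_peaks(formula, j, table, min_prob=min_prob)
    if len(fine) == 0:
        raise DomainError(f"variant j={j} has no enumerable fine peaks")
    masses = fine.masses()
    probs = fine.probabilities()
    lo, hi = masses.min(), masses.max()
    if hi <= lo:
        raise DegenerateRangeError(
            f"variant j={j} is a single fine peak: divergence undefined"
        )
    width = (hi - lo) / n_bins
    rng_lo, rng_hi = lo - width, hi + width

    if seed is not None and n_samples is not None:
        rng = np.random.default_rng(seed)
        draws = rng.choice(masses, size=n_samples, p=probs / probs.sum())
        p_binned = bin_distribution(
            draws, np.full(n_samples, count_scale / n_samples),
            n_bins=n_bins, pseudo_count=pseudo_count, bin_range=(rng_lo, rng_hi),
        )
    else:
        p_binned = bin_distribution(
            masses, probs / probs.sum() * count_scale,
            n_bins=n_bins, pseudo_count=pseudo_count, bin_range=(rng_lo, rng_hi),
        )
    edges = p_binned.bin_edges
    cdf = stats.norm.cdf(edges, loc=mu, scale=math.sqrt(var))
    q_weights = np.diff(cdf)
    q_weights = q_weights / q_weights.sum() * count_scale
    centers = 0.5 * (edges[:-1] + edges[1:])
    q_binned = bin_distribution(
        centers, q_weights, n_bins=n_bins, pseudo_count=pseudo_count,
        bin_range=(rng_lo, rng_hi),
    )
    h = entropy(p_binned)
    ce = cross_entropy(p_binned, q_binned)
    return NormalityReport(
        formula=str(formula),
        j=j,
        entropy=h,
        cross_entropy=ce,
        kl_divergence=ce - h,
        n_bins=n_bins,
        n_peaks=len(fine),
        captured=fine.captured,
    )
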