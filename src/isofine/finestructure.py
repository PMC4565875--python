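"""Explicit isotopic fine structure of an aggregated variant.

Four complementary views of the same combinatorial object:

* :func:`enumerate_fine_peaks` — branch-and-bound enumeration of the
  isotopologues (mass, multinomial probability) making up one aggregated
  variant, pruned by an exact remaining-probability-mass bound;
* :func:`count_fine_peaks` — exact big-integer count of those isotopologues,
  a bounded money-exchange problem over the heavy-isotope neutron
  "denominations" ({13C,2H,15N,17O,18O,33S,34S,36S} = {1,1,1,1,2,1,2,4});
* :func:`max_spread` / :func:`mean_spacing` — extreme fine-variant masses
  and the average mass gap per fine peak;
* :func:`sample_ions` — finite-ion-count occupancy of the fine peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma

import numpy as np

from .chem import ChemicalFormula, monoisotopic_mass
from .errors import DomainError, UndefinedSpacingError
from .isotopes import DEFAULT_TABLE, IsotopeTable

NEG_INF = float("-inf")


@dataclass(frozen=True)
class FinePeak:
    """One isotopologue: heavy-isotope counts, mass and probability.

    ``isotope_counts`` maps (element, nominal nucleon number) to the atom
    count for every isotope, light ones included.
    """

    isotope_counts: dict[tuple[str, int], int]
    mass: float
    probability: float
    neutron_total: int

    def label(self) -> str:
        """Compact heavy-isotope composition, e.g. ``"13C:213 2H:3"``."""
        parts = []
        for (el, nominal), n in self.isotope_counts.items():
            parts.append(f"{nominal}{el}:{n}")
        return " ".join(parts)


@dataclass(frozen=True)
class FineStructure:
    """Fine peaks of one aggregated variant, sorted by descending probability."""

    peaks: list[FinePeak]
    j: int
    truncation_threshold: float
    captured: float
    q_j: float

    def __len__(self) -> int:
        return len(self.peaks)

    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.peaks])

    def probabilities(self) -> np.ndarray:
        return np.array([p.probability for p in self.peaks])


@dataclass(frozen=True)
class OccupancyReport:
    """Ion-counting statistics of a multinomial draw over fine peaks."""

    n_ions: int
    n_peaks: int
    mean_occupancy: float
    occupied_fraction: float
    seed: int
    counts: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# shared element-level helpers


def _element_compositions(recs, n_atoms: int, t: int):
    """All heavy-isotope count vectors of one element summing to t neutrons.

    Yields ``(h, logp)`` where ``h`` is a tuple over the heavy isotopes (in
    table order) with sum(h_i * offset_i) = t and sum(h_i) <= n_atoms, and
    ``logp`` the log multinomial probability of that composition.
    """
    heavy = recs[1:]
    offs = [r.neutron_offset for r in heavy]
    log_a = [math.log(r.abundance) for r in heavy]
    log_a0 = math.log(recs[0].abundance)
    base = lgamma(n_atoms + 1)

    def rec(i, rem, used, h, lp):
        if i == len(heavy):
            if rem == 0:
                yield tuple(h), base + lp - lgamma(n_atoms - used + 1) + (
                    n_atoms - used
                ) * log_a0
            return
        d = offs[i]
        hmax = min(rem // d, n_atoms - used)
        for k in range(hmax + 1):
            h.append(k)
            yield from rec(
                i + 1, rem - k * d, used + k, h, lp + k * log_a[i] - lgamma(k + 1)
            )
            h.pop()

    yield from rec(0, t, 0, [], 0.0)


def _q_polynomial(
    formula: ChemicalFormula, table: IsotopeTable, jmax: int
) -> list[np.ndarray]:
    """Suffix aggregated probabilities.

    Returns per element position i the vector q_i[r] = probability that
    elements i.. contribute exactly r extra neutrons (degree <= jmax); the
    last entry is the delta polynomial [1].
    """
    elems = list(formula)
    suffix = [np.zeros(jmax + 1)]
    suffix[0][0] = 1.0
    for el, n in reversed(elems):
        recs = table[el]
        atom = np.zeros(jmax + 1)
        for r in recs:
            if r.neutron_offset <= jmax:
                atom[r.neutron_offset] += r.abundance
        block = None
        b = atom
        m = n
        while m:
            if m & 1:
                block = b if block is None else np.convolve(block, b)[: jmax + 1]
            m >>= 1
            if m:
                b = np.convolve(b, b)[: jmax + 1]
        suffix.insert(0, np.convolve(suffix[0], block)[: jmax + 1])
    return suffix


def peak_probability(
    formula: ChemicalFormula,
    heavy_counts: dict[tuple[str, int], int],
    table: IsotopeTable = DEFAULT_TABLE,
) -> float:
    """Multinomial probability of one explicit isotopologue.

    ``heavy_counts`` maps (element, nominal nucleon number) of heavy isotopes
    to their atom counts; unspecified atoms are the light isotope.
    """
    logp = 0.0
    for el, n in formula:
        recs = table[el]
        base_nominal = round(recs[0].mass)
        hs = [heavy_counts.get((el, base_nominal + r.neutron_offset), 0) for r in recs[1:]]
        used = sum(hs)
        if used > n:
            raise DomainError(f"element {el}: heavy-isotope counts exceed atom count")
        logp += lgamma(n + 1) - lgamma(n - used + 1) + (n - used) * math.log(
            recs[0].abundance
        )
        for h, r in zip(hs, recs[1:]):
            logp += h * math.log(r.abundance) - lgamma(h + 1)
    return math.exp(logp)


def enumerate_fine_peaks(
    formula: ChemicalFormula,
    j: int,
    table: IsotopeTable = DEFAULT_TABLE,
    min_prob: float = 0.0,
    max_peaks: int | None = None,
) -> FineStructure:
    """Enumerate the isotopologues of aggregated variant *j*.

    ``min_prob`` is relative to the variant's total probability q_j: peaks
    with p_jk < min_prob * q_j are pruned.  Subtrees are cut with the exact
    bound p_partial * q_suffix(remaining neutrons), where q_suffix is the
    aggregated probability of the not-yet-assigned elements, so no retained
    peak is ever missed.  ``captured`` reports the retained probability mass.
    """
    if j < 0:
        raise DomainError("j must be >= 0")
    if not (0.0 <= min_prob < 1.0):
        raise DomainError("min_prob must be in [0, 1)")
    elems = list(formula)
    suffix = _q_polynomial(formula, table, j)
    q_j = float(suffix[0][j]) if j < len(suffix[0]) else 0.0
    if q_j <= 0.0:
        return FineStructure(peaks=[], j=j, truncation_threshold=min_prob,
                             captured=0.0, q_j=0.0)
    threshold = min_prob * q_j
    log_threshold = math.log(threshold) if threshold > 0 else NEG_INF

    mono = monoisotopic_mass(formula, table)
    # lazy per-(element, t) composition cache
    comp_cache: dict[tuple[int, int], list] = {}

    def compositions(i: int, t: int):
        key = (i, t)
        if key not in comp_cache:
            el, n = elems[i]
            comp_cache[key] = list(_element_compositions(table[el], n, t))
        return comp_cache[key]

    log_qsuf = [np.where(s > 0, np.log(np.maximum(s, 1e-320)), NEG_INF) for s in suffix]

    peaks: list[tuple[float, float, tuple]] = []  # (logp, dmass, flat heavy counts)
    state: list[tuple] = [None] * len(elems)
    heavy_dm = [
        [r.mass - table[el][0].mass for r in table[el][1:]] for el, _ in elems
    ]

    def dfs(i: int, rem: int, lp: float, dm: float):
        if i == len(elems):
            if rem == 0:
                peaks.append((lp, dm, tuple(state)))
            return
        for t in range(min(rem, _max_neutrons(table[elems[i][0]], elems[i][1])), -1, -1):
            for h, hlp in compositions(i, t):
                nlp = lp + hlp
                if nlp + log_qsuf[i + 1][rem - t] < log_threshold:
                    continue
                state[i] = h
                dfs(i + 1, rem - t,
                    nlp, dm + sum(k * w for k, w in zip(h, heavy_dm[i])))
        state[i] = None

    dfs(0, j, 0.0, 0.0)

    records = []
    for lp, dm, flat in sorted(peaks, key=lambda r: -r[0]):
        p = math.exp(lp)
        if p < threshold:
            continue
        counts: dict[tuple[str, int], int] = {}
        for (el, n), h in zip(elems, flat):
            recs = table[el]
            base_nominal = round(recs[0].mass)
            counts[(el, base_nominal)] = n - sum(h)
            for k, r in zip(h, recs[1:]):
                if k:
                    counts[(el, base_nominal + r.neutron_offset)] = k
        records.append(FinePeak(counts, mono + dm, p, j))
    if max_peaks is not None:
        records = records[:max_peaks]
    captured = float(sum(p.probability for p in records))
    return FineStructure(
        peaks=records, j=j, truncation_threshold=min_prob, captured=captured, q_j=q_j
    )


def _max_neutrons(recs, n_atoms: int) -> int:
    return n_atoms * recs[-1].neutron_offset


# ---------------------------------------------------------------------------
# exact counting (bounded money exchange)


def _element_count_poly(recs, n_atoms: int, jmax: int) -> list[int]:
    """c[t] = number of heavy-isotope count vectors of one element with
    t extra neutrons, honoring the joint bound sum(h) <= n_atoms.  Exact
    big-integer DP over (neutrons, atoms used); atoms used <= t since every
    denomination is >= 1 neutron."""
    smax = min(n_atoms, jmax)
    # dp[t][s] over heavy isotopes processed so far
    dp = [[0] * (smax + 1) for _ in range(jmax + 1)]
    dp[0][0] = 1
    for r in recs[1:]:
        d = r.neutron_offset
        new = [[0] * (smax + 1) for _ in range(jmax + 1)]
        for t in range(jmax + 1):
            row = dp[t]
            for s in range(min(t, smax) + 1):
                v = row[s]
                if not v:
                    continue
                h = 0
                while True:
                    tt = t + h * d
                    ss = s + h
                    if tt > jmax or ss > smax:
                        break
                    new[tt][ss] += v
                    h += 1
        dp = new
    return [sum(dp[t]) for t in range(jmax + 1)]


def count_fine_peaks(
    formula: ChemicalFormula, j: int, table: IsotopeTable = DEFAULT_TABLE
) -> int:
    """Exact number of distinct isotopologues in aggregated variant *j*.

    Bounded money-exchange count: per element a bounded-composition
    polynomial in the neutron variable, convolved across elements with
    arbitrary-precision integers.
    """
    if j < 0:
        raise DomainError("j must be >= 0")
    result = [1] + [0] * j
    for el, n in formula:
        poly = _element_count_poly(table[el], n, j)
        new = [0] * (j + 1)
        for a, ca in enumerate(result):
            if not ca:
                continue
            for b in range(j + 1 - a):
                cb = poly[b]
                if cb:
                    new[a + b] += ca * cb
        result = new
    return result[j]


# ---------------------------------------------------------------------------
# spread and spacing


def _extreme_mass_poly(recs, n_atoms: int, jmax: int, sign: float) -> list[float]:
    """best[t] = max (sign=+1) or min (sign=-1) heavy-isotope mass offset of
    one element contributing t neutrons (NEG_INF where infeasible)."""
    smax = min(n_atoms, jmax)
    dp = [[NEG_INF] * (smax + 1) for _ in range(jmax + 1)]
    dp[0][0] = 0.0
    base = recs[0].mass
    for r in recs[1:]:
        d = r.neutron_offset
        w = (r.mass - base) * sign
        new = [[NEG_INF] * (smax + 1) for _ in range(jmax + 1)]
        for t in range(jmax + 1):
            for s in range(min(t, smax) + 1):
                v = dp[t][s]
                if v == NEG_INF:
                    continue
                h = 0
                while True:
                    tt = t + h * d
                    ss = s + h
                    if tt > jmax or ss > smax:
                        break
                    cand = v + h * w
                    if cand > new[tt][ss]:
                        new[tt][ss] = cand
                    h += 1
        dp = new
    return [max(dp[t]) for t in range(jmax + 1)]


def _extreme_mass(formula, table, j, sign) -> float:
    best = [0.0] + [NEG_INF] * j
    for el, n in formula:
        poly = _extreme_mass_poly(table[el], n, j, sign)
        new = [NEG_INF] * (j + 1)
        for a in range(j + 1):
            if best[a] == NEG_INF:
                continue
            for b in range(j + 1 - a):
                if poly[b] == NEG_INF:
                    continue
                cand = best[a] + poly[b]
                if cand > new[a + b]:
                    new[a + b] = cand
        best = new
    return best[j] * sign


def max_spread(
    formula: ChemicalFormula,
    j: int,
    table: IsotopeTable = DEFAULT_TABLE,
    mode: str = "universal",
) -> float:
    """Maximum mass spread of aggregated variant *j*, Da.

    ``mode="universal"`` gives the universal upper bound j * (mu_2H - mu_15N)
    (deuterium carries the largest mass per extra neutron, 15N the
    smallest).  ``mode="bounded"`` returns the exact max - min fine-variant
    mass under the formula's atom-count constraints; it equals the universal bound
    whenever j <= min(#H, #N).
    """
    if j < 0:
        raise DomainError("j must be >= 0")
    if j == 0:
        return 0.0
    if mode == "universal":
        mu_2h = table.mass_per_neutron("H", 1)
        mu_15n = table.mass_per_neutron("N", 1)
        return j * (mu_2h - mu_15n)
    if mode == "bounded":
        hi = _extreme_mass(formula, table, j, +1.0)
        lo = _extreme_mass(formula, table, j, -1.0)
        if hi == NEG_INF or lo == NEG_INF or hi < lo:
            raise DomainError(f"variant j={j} unattainable for {formula}")
        return hi - lo
    raise DomainError(f"unknown spread mode {mode!r}")


def mean_spacing(
    formula: ChemicalFormula,
    j: int,
    table: IsotopeTable = DEFAULT_TABLE,
    width_mode: str = "spread",
    k: float | None = None,
    sigma: float | None = None,
) -> float:
    """Average mass gap per fine peak of variant *j*, Da.

    ``width_mode="spread"`` divides the universal maximum spread by the
    exact fine-peak count; ``width_mode="k_sigma"`` uses a width of k
    fine-structure standard deviations instead (sigma may be passed to avoid
    recomputing the aggregated distribution).
    """
    n = count_fine_peaks(formula, j, table)
    if n < 2:
        raise UndefinedSpacingError(f"variant j={j} has {n} fine peak(s)")
    if width_mode == "spread":
        width = max_spread(formula, j, table, mode="universal")
    elif width_mode == "k_sigma":
        if k is None:
            raise DomainError("k required for width_mode='k_sigma'")
        if sigma is None:
            from .moments import aggregated_distribution

            sigma = aggregated_distribution(formula, table).sigma(j)
        width = k * sigma
    else:
        raise DomainError(f"unknown width_mode {width_mode!r}")
    return width / n


# ---------------------------------------------------------------------------
# ion-counting statistics


def sample_ions(
    fine: FineStructure | None = None,
    n_peaks: int | None = None,
    n_ions: int = 0,
    seed: int = 0,
) -> OccupancyReport:
    """Multinomial draw of *n_ions* over fine-structure peaks.

    Pass either an enumerated :class:`FineStructure` (peak probabilities are
    renormalized over the retained peaks) or ``n_peaks`` for equal-abundance
    peaks.  Reproducible for a fixed seed.
    """
    if n_ions < 0:
        raise DomainError("n_ions must be >= 0")
    if fine is not None:
        pvals = fine.probabilities()
        total = pvals.sum()
        if total <= 0:
            raise DomainError("fine structure has no probability mass")
        pvals = pvals / total
    elif n_peaks is not None:
        if n_peaks < 1:
            raise DomainError("n_peaks must be >= 1")
        pvals = np.full(n_peaks, 1.0 / n_peaks)
    else:
        raise DomainError("provide a FineStructure or n_peaks")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_ions, pvals)
    n = len(pvals)
    return OccupancyReport(
        n_ions=n_ions,
        n_peaks=n,
        mean_occupancy=n_ions / n,
        occupied_fraction=float(np.count_nonzero(counts)) / n,
        seed=seed,
        counts=counts,
    )
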