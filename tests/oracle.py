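"""Brute-force isotopologue enumeration used as an independent oracle.

Everything here is computed by exhaustively listing every isotopologue of a
(small) molecule and summing directly — no generating functions, no dynamic
programming — so it exercises none of the code paths it is used to check.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass


def _compositions(n: int, k: int):
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _multinomial(n: int, ks) -> float:
    out = math.factorial(n)
    for k in ks:
        out //= math.factorial(k)
    return float(out)


def enumerate_isotopologues(formula: dict[str, int], table: dict[str, list]):
    """Yield (j, mass, probability, key) over every isotopologue.

    ``table`` maps element -> list of (mass, abundance, neutron_offset)
    tuples; ``key`` is the full isotope-count assignment (hashable).
    """
    per_element = []
    for el, n in formula.items():
        isotopes = table[el]
        options = []
        for comp in _compositions(n, len(isotopes)):
            p = _multinomial(n, comp)
            mass = 0.0
            j = 0
            for k, (m, a, d) in zip(comp, isotopes):
                p *= a**k
                mass += k * m
                j += k * d
            options.append((j, mass, p, (el, comp)))
        per_element.append(options)
    for combo in itertools.product(*per_element):
        j = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        p = 1.0
        for c in combo:
            p *= c[2]
        yield j, mass, p, tuple(c[3] for c in combo)


@dataclass
class VariantStats:
    q: float
    center_mass: float
    variance: float
    entropy: float
    n_peaks: int
    min_mass: float
    max_mass: float


def brute_force_stats(formula: dict[str, int], table: dict[str, list]):
    """Per-variant statistics plus totals, all from exhaustive enumeration."""
    by_j: dict[int, list] = defaultdict(list)
    for j, mass, p, _key in enumerate_isotopologues(formula, table):
        by_j[j].append((mass, p))

    variants: dict[int, VariantStats] = {}
    total_var_acc = []
    total_entropy = 0.0
    # grand mean: straight weighted mean over all isotopologues
    grand_mean = math.fsum(m * p for peaks in by_j.values() for m, p in peaks)
    for j, peaks in sorted(by_j.items()):
        q = math.fsum(p for _m, p in peaks)
        mean = math.fsum(m * p for m, p in peaks) / q
        var = math.fsum(p * (m - mean) ** 2 for m, p in peaks) / q
        ent = -math.fsum((p / q) * math.log(p / q) for _m, p in peaks)
        variants[j] = VariantStats(
            q=q,
            center_mass=mean,
            variance=var,
            entropy=ent,
            n_peaks=len(peaks),
            min_mass=min(m for m, _p in peaks),
            max_mass=max(m for m, _p in peaks),
        )
        total_var_acc.extend(peaks)
        total_entropy += -math.fsum(p * math.log(p) for _m, p in peaks)
    total_variance = math.fsum(
        p * (m - grand_mean) ** 2 for m, p in total_var_acc
    )
    return variants, total_variance, total_entropy, grand_mean
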