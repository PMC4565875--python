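# Methods

## Scope and objects

`isofine` characterizes the isotope pattern of a molecule C_vH_wN_xO_yS_z
(extensible to any element present in the isotope table) at two levels:

- **aggregated variants** — all isotopologues with the same number *j* of
  neutrons above the monoisotopic species; adjacent variants are spaced by
  ~1.003 Da;
- **fine structure** — the individual isotopologues inside one variant.
  Two fine peaks are distinct if and only if some element's isotope count
  differs; an isotopologue is therefore a *lumped multinomial outcome*, not
  a labeled assignment of isotopes to atoms.

## Isotope table

The packaged table (`isofine/data/isotopes.tsv`) pins the NIST *Atomic
Weights and Isotopic Compositions* values of the mid-2000s (AME2003 masses,
IUPAC 1997/2001 representative abundances): C 0.9893/0.0107,
H 0.999885/0.000115, N 0.99632/0.00368, O 0.99757/0.00038/0.00205,
S 0.9493/0.0076/0.0429/0.0002. This is the elemental table used by the
classic polynomial isotope-pattern calculators, and it is the set under
which the package's reference results hold simultaneously (bovine serum
albumin's mode at j = 42 *and* the 4000-unit poly-averagine's mode at
j = 277 with modal probability 0.023). The current CIAAW revision shifts
the poly-averagine mode to 276 — the two modal probabilities differ by only
0.13 %, so the mode is genuinely sensitive at the fourth abundance digit.
Any element can be overridden per run (`IsotopeTable.with_element`, or a
user table file via `load_table`); abundances must sum to 1 within 1e-9.

## Generating-function moments

For each element, a single atom is the polynomial `Σ_i a_i I^(d_i)` over its
isotopes (abundance `a_i`, neutron offset `d_i`). The molecule's aggregated
distribution is the product of per-element powers, computed by repeated
squaring with truncation to a j-window. Alongside the probability
coefficient `S0_j = Σ_k p_jk`, the same Cauchy products propagate
`S1_j = Σ p·δm`, `S2_j = Σ p·δm²` (mass moments) and
`SL_j = Σ p·(−log p)` (entropy numerator), giving per variant

    E(m_j)   = mono + j·ρ + S1_j/S0_j
    Var(m_j) = S2_j/S0_j − (S1_j/S0_j)²
    H(j)     = SL_j/S0_j + log S0_j         (natural log; nats)

Three numerical choices matter:

1. **Affine mass centering.** Accumulating raw masses (~10⁵ Da) would lose
   ~10 digits in the `E(m²) − E(m)²` cancellation. Masses are therefore
   carried as offsets from the reference `monoisotopic + j·ρ`, with ρ the
   molecule's abundance-weighted mean mass per extra neutron, so all
   accumulated magnitudes are of the order of the fine-structure spread.
   Correctness (rather than line-by-line algebra against any particular
   derivation) is established by exhaustive-enumeration oracles in the test
   suite.
2. **Extended precision.** Even centered, deep-tail variants lose up to ~8
   digits in the variance cancellation, so the moment convolutions run in
   80-bit `long double`; results are returned as float64. Against exhaustive
   enumeration over every CHNOS formula with ≤ 12 atoms the worst relative
   error of q, E(m_j) and Var(m_j) is then below 1e-9 (variance additionally
   floored at 1e-18 Da² where the exact value is zero).
3. **Lumped entropy.** `−log p` of a fine peak contains the multinomial
   coefficient, so it is *not* additive over atoms; squaring a single-atom
   polynomial would compute the entropy of atom-labeled outcomes (an
   overestimate). Each element's `SL` series is instead built by direct
   enumeration of its isotope-count compositions, vectorized over the first
   heavy isotope; `−log p` *is* additive across elements, where the ordinary
   convolution applies. Entropy is reported in nats (`unit="bits"`
   converts); a variant consisting of one fine peak has H = 0 exactly.

**j-window and coverage.** The window defaults to the closed-form neutron-
count mean ± 12 envelope standard deviations (clipped to the attainable
maximum, expanded if the coverage target is missed, overridable via
`j_window`). Coverage is the captured probability; the default target is
1 − 1e-12. The comparison allows an explicit round-off floor of
2.5e-17·N_atoms: repeated products of ~N probability polynomials drift the
total by about that much regardless of the window, so demanding more would
never terminate for >100 kDa molecules.

**Decompositions.** With `q̄_j = q_j/coverage` and `m̄` the closed-form
average mass,

    total variance = Σ_j q̄_j Var(m_j)  +  Σ_j q̄_j (E(m_j) − m̄)²
    total entropy  = Σ_j q̄_j H(j)      +  (−Σ_j q̄_j log q̄_j)

The variance total equals `Σ_e n_e·Var_e(isotope mass)` (independent atoms);
the entropy total equals the entropy of the complete isotopologue
distribution. Because the between-variance weights tail variants by
(j − mean)², the decomposition functions default to a tighter coverage
target (1 − 1e-15) than plain `aggregated_distribution`; both identities
then hold to < 1e-11 relative error on the exhaustive oracle set and to
~1e-12 at 450 kDa.

## Fine-structure counting, enumeration, spread

**Counting.** The number of fine peaks of variant *j* is a bounded
money-exchange count: per element, a polynomial `c_e[t]` = number of
heavy-isotope count vectors with `Σ h_i d_i = t` under the joint bound
`Σ h_i ≤ n_e` (big-integer DP over (neutrons, atoms-used); atoms-used ≤ t
since every denomination is ≥ 1), convolved across elements. Exact at any
size; the 222 kDa poly-averagine's j = 142 variant counts 1.96e10 peaks in
~10 ms.

**Enumeration.** Depth-first over elements; per element the isotope-count
compositions for a given neutron share, with log-domain multinomial
probabilities (`lgamma`). Pruning uses the *exact* remaining mass: a partial
assignment with probability p and r neutrons left is cut when
`p · q_suffix(r) < min_prob · q_j`, where `q_suffix` is the aggregated
distribution of the not-yet-assigned elements. No retained peak can be
missed, and the explored node count is bounded by ~1/min_prob. Peak masses
are assembled from heavy-isotope mass offsets added to the monoisotopic
mass, avoiding large-number cancellation. `captured` reports the retained
probability mass; with `min_prob = 0` it equals q_j to 1e-9 relative.

**Spread.** `max_spread(mode="universal")` returns the universal bound
`j·(μ₂H − μ₁₅N)` ≈ j × 9.24 mDa (deuterium adds the most mass per neutron,
¹⁵N the least). `mode="bounded"` returns the exact max − min fine-variant
mass via a max-plus DP per element (neutrons × atoms-used) convolved across
elements — exact under atom-count constraints, unlike a greedy ratio
heuristic, and equal to the universal bound whenever j ≤ min(#H, #N).
`mean_spacing` divides either width (`spread`, or `k_sigma` with a free
multiplier k of the fine-structure σ) by the exact peak count; no specific
published spacing convention is baked in.

**Ion counting.** `sample_ions` draws a multinomial over peak probabilities
(or uniform peaks) with a seeded `numpy.random.Generator`, whose multinomial
implementation performs sequential binomial chaining and is memory-safe at
≥10⁶ categories. 200,000 ions over 2×10⁶ equal peaks give mean occupancy
exactly 0.1 and an occupied fraction ≈ 1 − e^(−0.1) ≈ 9.5 %.

## Resolution limits

**Overlap onset.** Pinned linear models predict the most-abundant-variant
variance from mass: proteins `Var = 1.503e-6 + 3.077e-9·m` (an OLS fit over
~58,000 UniProt proteins; pinned constants, not refit at runtime — the
source data set is external), DNA `1.68e-9·m`, intact virus `2.4e-9·m`
(average of the two). `overlap_onset_mass` inverts the model at a σ
threshold (default 0.5 Da, where 1-Da-spaced variants overlap heavily):
≈ 81.25 MDa for proteins. Self-consistency: variances computed directly for
20–450 kDa poly-averagines fit a line whose slope is within ~2 % of the
pinned protein slope (the acceptance suite allows 15 %).

**Thermorelativistic blur.** An isolated ion's internal energy fluctuates
with `σ_E = √(k_B T² C)`; via E = mc² this is a mass uncertainty
`Δm = σ_E/c²` that no analyser can remove. The heat capacity is modeled as
`C = dof_per_atom · N_atoms · k_B` with defaults `dof_per_atom = 3/2`
(equipartition) and T = 300 K — explicit `ThermoConfig` knobs, chosen
because they reproduce the reference value Δm = 6.00e-9 Da (9.98e-36 kg)
for the 31,147-atom poly-averagine to ~0.2 %. Δm scales as √N_atoms and
linearly in T. For the HIV1 capsid only the σ ≈ 0.32 Da prediction at
~34 MDa is reproduced; its published abundance shift depends on an
unpublished capsid composition and is not a package target.

## Shape and normality

`render_profile` renders sticks as unit-area Gaussians (FWHM absolute or
m/R per stick; FWHM = 2√(2 ln 2)·σ), on a grid covering every stick ± 5
FWHM; trapezoidal area is conserved to 1e-6. `bin_distribution` histograms
weighted masses into equal-width bins and adds a pseudo-count to every bin
before normalizing, so cross-entropy and `D_KL(P‖Q) = Σ ln(P_i/Q_i)P_i` are
finite; `H(P,Q) = H(P) + D_KL(P‖Q)` holds to 1e-12 by construction.

`normality_report` builds P from the *deterministically enumerated* fine
structure of a variant (default: most abundant; probabilities above
`min_prob·q_j`, default 1e-5) and Q from a normal with that variant's
center mass and variance, discretized on the same 1000 bins spanning P's
support ± one bin width; both are scaled to pseudo-counts totalling
`count_scale` (default 1e6) before the per-bin pseudo-count of 1.
Determinism makes the divergence reproducible run to run; a seeded sampling
mode (`seed`, `n_samples`) mimics replicate-based protocols and their
run-to-run spread. Across poly-averagines of 100, 400 and 1600 units the
divergence from normality falls monotonically (≈3.9 → 0.91 → 0.020 nats
under the defaults): large fine structures Gaussianize.

## Synthetic data

Poly-averagines are the package's own synthetic molecule family: element
counts are `n_units` times the averagine stoichiometry
C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇, rounded half-up per element
independently (validated by the printed 2000- and 4000-unit formulas).
They emulate the *average elemental composition* of peptides, proteins and
protomer-built capsids; they do not model post-translational modifications,
non-CHNOS heteroatoms, adducts or charge states, so tests passing on
poly-averagines say nothing about, e.g., metalloproteins or nucleic acids
(DNA enters only through the pinned variance scaling). The `fixtures` CLI
command materializes them with small enumerated fine structures.

## Known limitations

- Formula dialect: no parentheses, charges, adducts or isotope labels;
  m/z conversion is out of scope.
- The aggregated-distribution coverage cannot exceed 1 − ~2.5e-17·N_atoms
  (floating-point drift floor); decomposition identities degrade gracefully
  (~1e-12 at 450 kDa, ~3e-12 at 1 MDa).
- Enumeration cost grows as ~1/min_prob; exhaustive (min_prob = 0)
  enumeration is only sensible below ~10⁶ peaks.
- The linear variance models are extrapolations when applied far outside
  the mass range of their source fits; the virus scaling is a stated
  average, not a fit.
- Entropy-vs-thermorelativistic-limit coupling is reported side by side
  (`resolvability_report`) but no quantitative relationship is modeled.
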