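# Methods

This note records the model assumptions, the defaults that matter, and
the design choices made where the method leaves room, in the order the
pipeline uses them.

## Hydrogen-bond collective variable

The degree of folding is monitored by a continuous count of native
backbone hydrogen bonds.  Each donor–acceptor pair (amide N to carbonyl
O, heavy atoms only — hydrogens are never used) contributes

    f(r) = (1 − x^n) / (1 − x^m),   x = (r − d0)/r0,

evaluated through the equivalent geometric-sum form, which is finite and
continuous at x = 1 (value n/m).  Defaults: r0 = 2.5 Å, d0 = 0, n = 8,
m = 12.  These are the conventional rational-switch settings for
hydrogen-bond counting in biased sampling; the exact functional form used
in any given production study varies, so all four parameters are
explicit configuration, never constants.  The switch decays only
algebraically (x^(n−m)), so a "broken" bond at 100·r0 still contributes
~10⁻⁸; tests and state definitions account for that tail.

Pairs carry a group label (`beta`, `alpha1`, `alpha2`).  The biased CV ξ
may be the β-sheet count only, with the extended variable ξ′ = β + α
used at analysis time — this matters when the bias is built on the sheet
but helix melting must still enter the free energy.  Pair selectors
match residue number + atom name only, so one pair list serves all
point mutants that keep their backbone.

The packaged BPTI-like pair list has 8 β + 3 α₁ + 5 α₂ pairs, so ξ spans
0…16 with the folded state near 14 and a molten-globule unfolded state
near 4.

## Well-tempered metadynamics

Bias: V_G(s,t) = Σ hills w_t′ · exp(−(s−s(t′))²/2δ²), with tempered
heights w_t′ = w·exp(−V_G(s(t′),t′)/k_B ΔT).  Defaults: w = 1 kJ/mol,
δ = 1 CV unit (of order one hydrogen bond; the toy runs use δ = 0.3 on
their narrower landscapes), deposition period τ_G = 20 ps (a 10 ps
preset is equally valid; the period is configuration).  ΔT defaults to
5700 K, i.e. biasing factor (T+ΔT)/T = 20 at T = 300 K, an energy scale
R·ΔT of the order of one hydrogen-bond barrier.  The untempered limit is
a flag (all heights exactly w), not ΔT = 0, which is rejected.

Multi-walker construction follows a staged schedule: equilibration
(8 ns), bias construction (22 ns) with an altruistic exchange every
2 ns, collection at frozen bias afterwards.  The exchange rule is

    V_i' = (1−α)·V_i + α·[w·V_i + (1−w)·mean_j V_j],

with (α, w) ramping (0,1) → (1/4,1) → (1/2,1) → (3/4,1) → (1,1/2) over
the construction stages.  The precise combination formula used by
altruistic-sharing implementations is not uniquely fixed in the
literature we follow; this convex rule is the package's default and the
hook is pluggable.  The stage-table "w" is read as the sharing weight,
not a hill-height rescale.  After the last construction stage the walker
biases are averaged point-wise and frozen for collection.

Bias evaluation caches hills on a uniform grid (0.1 CV units) with the
cached values asserted exact on nodes; free energies from the frozen
bias use F(s)−F(s₀) = −(T+ΔT)/ΔT·ΔV_G and are independent of the
irrelevant additive constant.  For presentation the grid can be smoothed
by a least-squares quartic inside a fit range (default 0.5–15.5 CV
units) continued linearly outside with matching slope (C¹).

### Toy sampler

The only dynamics shipped is overdamped Langevin in CV space:
s ← s − μ·(F′+V_G′)·dt + √(2k_B T μ dt)·η, μ = 1/(mass·friction),
Euler–Maruyama.  Only the bias/staging/reweighting logic is under test,
not integrator accuracy, so the simplest stable scheme is the right
one.  Defaults friction 10 ps⁻¹, dt 0.01 ps, reflecting walls at the
edge of the (analytic, confining) landscape's domain.  Runs are bitwise
reproducible from the seed.

## Maximal-constrained-entropy reweighting

Frames enter with multiplicity 1 (a multiplicity column is supported for
pre-aggregated histograms).  For target mean s the tilt parameter λ
solves ⟨ξ⟩_λ = s; since d⟨ξ⟩/dλ = −Var_λ(ξ) < 0 the map is strictly
monotone and a bracketed root-find (geometric expansion from [−1, 1],
then Brent) converges globally.  Residual tolerance: 10⁻¹⁰·range(ξ).
All tilted sums go through max-shifted log-sum-exp — λ·ξ reaches
hundreds near the support edges.  Targets outside the open support hull
are refused (no tilt can reach them); profile grids skip such points
with a warning.

G(s) = ⟨Ū⟩_λ − T_eff·k_B·S̄_c with S̄_c = ln Z_λ + λs.  The
identification of S̄_c and T_eff with thermodynamic entropy and
temperature is empirical, so T_eff is explicit configuration (default
300 K, the simulation temperature).  Per-point uncertainty is
leave-one-walker-out jackknife by default (walker labels come with the
frames); walker bootstrap is available.  How error bars are best
propagated through this construction is genuinely open; the jackknife is
a documented, conservative choice.

ΔΔG = [G_X(s_unf)−G_X(s_fold)] − [G_0(s_unf)−G_0(s_fold)], positive =
stabilizing.  Both the MEC route and the direct-from-bias route are
reported when a bias grid is available, because they can legitimately
disagree when the biased CV misses slow degrees of freedom — that
disagreement is diagnostic, not an error.

## Mean-field MM/PBSA energy

The five intramolecular terms (stretch, bend, torsion, van der Waals,
Coulomb) are consumed as inputs: the package's contribution is the
statistical machinery, not a force field, and any engine (or the
synthetic generator) can supply consistent term tables.

Nonpolar: G_np = Σᵢ σᵢ·SASAᵢ with Shrake–Rupley areas on a deterministic
golden-spiral point set (default 960 points, probe 1.4 Å).  σ defaults
to a single 0.0226 kJ/mol/Å² value with a per-atom-name override table;
published per-group σ sets vary and are configuration.

Polar: linearized Poisson–Boltzmann on a uniform lattice, 7-point
stencil, trilinear charge assignment, Dirichlet boundaries from the
Debye–Hückel superposition, red–black SOR (ω from the grid dimension,
relative residual 10⁻⁶, iteration guard).  Face permittivities are
harmonic averages over 4 sub-samples of each internode segment; a binary
node assignment makes the effective cavity radius jump with grid
alignment and destroys monotone grid convergence, while the segment
average restores it (Born-ion error 2.9% → 0.8% → 0.2% at 0.8/0.4/0.2 Å
in the acceptance run).  The self-energy of the spread charges cancels
by subtracting a second solve with uniform solute permittivity and no
salt, so no analytic grid-self-energy correction is needed at this
tolerance.  Dielectric cavity: van-der-Waals union (an inflation option
exists); defaults ε_in = 1, ε_out = 80, κ = 0 (κ configurable for salted
environments).  The solute must sit ≥ 5 Å inside the box.

## Synthetic ground truth

The ensemble generator emulates the *structure* of real metastatistics —
a deliberately non-flat, bimodal CV distribution (sharp folded peak at
14, broad unfolded peak at 4, integer support 0…16), per-frame energies
Ū(ξ) plus Gaussian noise (σ_E = 2 kJ/mol default), round-robin walker
labels, 10⁵ frames over 10 walkers — while its free-energy curve G*(s)
is computable exactly from the discrete proposal by an independent
closed-form tilt calculation.  Recovery is exact in the σ_E → 0, n → ∞
limit by construction: with the default linear energy model the
energetic part of G* is exactly a·s and the entropic part is fixed by
the shared proposal, which is how `make_variant_pair` injects an exact
ΔΔG gap (shifting the slope by gap/(s_unf − s_fold)).

What the generator does *not* emulate: time correlation within walkers
(frames are i.i.d., so jackknife errors are optimistic relative to
correlated MD), energy–CV coupling beyond the stated Ū(ξ), and any real
force-field energetics.  Passing tests therefore validate the
estimators and their bookkeeping, not the physical accuracy of a
production study.

Toy peptides place backbone N/O atoms so every listed pair is either
fully formed (~0.8 Å effective separation, switch ≈ 1) or fully broken
(> 8 Å), with small seeded jitter; charges/radii carry simple fixed
defaults.  They exist to exercise the CV and PBSA plumbing end to end.

## Problem sizes and tolerances used in validation

The validation suite runs at desk scale: 10⁵-frame ensembles (100
seeded replicates for the ΔΔG sign-recovery rate), a 10⁶-step toy
well-tempered run (convergence criterion: RMSD of V_G + ΔT/(T+ΔT)·F
below 0.5 k_BT over the sampled region; reweighted well populations
within the Monte-Carlo error of the correlated sample, ±0.1), Born-ion
agreement within 5% at 0.4 Å spacing with monotone refinement, SASA
within 1% at 960 points, tilt-vs-brute-force agreement to 10⁻⁷ per
component on ≤ 12-frame ensembles, and the closed-form/direct cross
entropy identity to 10⁻⁹ on every solve.  Production-scale explicit-
solvent campaigns (tens of ns across 90 walkers per variant) are out of
scope for this package's own validation.

## Known limitations

- Single scalar constraint only; no multi-CV maximum-entropy variant.
- Strictly post-processing: the modulation never feeds back into the
  sampler.
- No nonlinear PB, no molecular (reentrant) surface, no solute
  vibrational entropy, no explicit ions.
- No periodic-boundary handling in the CV: solute coordinates are
  assumed whole.
- The pipeline predicts the sign (and a model magnitude) of ΔΔG; it
  does not model the magnitude of melting-temperature shifts or
  circular-dichroism observables.
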