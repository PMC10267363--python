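# metamec

Estimating how a single-point mutation changes the thermal stability of a
small, water-soluble protein — the sign (and magnitude) of the unfolding
free-energy change ΔΔG, which tracks the sign of the melting-temperature
shift ΔT_m — from biased atomistic sampling.

The toolkit implements the statistical machinery around three ideas:

1. **Well-tempered multiple-walker metadynamics** over a hydrogen-bond
   collective variable ξ(q) (a switched count of native backbone N···O
   contacts, grouped into β-sheet and α-helix sets).  The bias
   V_G(ξ, t) is a history-dependent sum of Gaussians whose heights shrink
   as exp(−V_G/k_B ΔT); at convergence

       V_G(s) = −ΔT/(T+ΔT) · F(s) + C,

   so free-energy differences follow directly from the frozen bias,
   F(s) − F(s₀) = −(T+ΔT)/ΔT · [V_G(s) − V_G(s₀)].  A swarm of walkers
   shares its bias through periodic "altruistic" convex combinations and a
   final average.

2. **Maximal-constrained-entropy (MEC) reweighting** of the
   metastatistics P̃ collected at frozen bias.  For each target mean
   ⟨ξ⟩ = s the distribution closest to P̃ (minimum KL divergence) is the
   exponential tilt P_γ = P̃_γ e^(−λξ_γ)/Z_λ, with λ solving the
   constraint.  The free energy at target s is

       G(s) = ⟨Ū⟩_λ − T_eff · k_B · S̄_c(s),   S̄_c = ln Z_λ + λs ≤ 0.

3. **An MM/PBSA mean-field energy** Ū(Q) replacing the (hugely
   fluctuating) total enthalpy: the five intramolecular force-field terms
   (consumed as inputs), a per-atom SASA-linear nonpolar solvation term
   Σᵢ σᵢ·SASAᵢ (Shrake–Rupley areas), and a polar term from a
   finite-difference linearized Poisson–Boltzmann solve (low-dielectric
   solute cavity in a high-dielectric, optionally salted, continuum).

The reported quantity is, for variant X against reference 0,

    ΔΔG = [G_X(s_unf) − G_X(s_fold)] − [G_0(s_unf) − G_0(s_fold)],

positive meaning the mutation stabilizes the fold.  Folded/unfolded
states are picked as the two dominant peaks of the CV distribution
(e.g. s = 14 and s = 4 for a BPTI-like CV spanning 0…16).

No molecular-dynamics engine is included: production sampling is read
from PLUMED-style text tables, and a desk-scale overdamped Langevin
sampler in CV space exercises the full staging, bias bookkeeping and
reweighting on analytic landscapes.

## Worked example

Generate two synthetic metastatistics ensembles whose exact free-energy
curves differ by a known stability gap of 5 kJ/mol, then recover it:

```python
import numpy as np
from metamec import synthetic, mec

ref_spec, var_spec = synthetic.make_variant_pair(gap=5.0, seed=42, n_frames=100_000)
ms_ref = synthetic.sample_metastatistics(ref_spec)
ms_var = synthetic.sample_metastatistics(var_spec)

grid = np.arange(4.0, 14.5, 2.0)
prof_ref = mec.profile(ms_ref, grid, s0=14.0, T_eff=300.0)
prof_var = mec.profile(ms_var, grid, s0=14.0, T_eff=300.0)

value = mec.ddg(prof_var, prof_ref, s_unfolded=4.0, s_folded=14.0)
print(f"ddG(unfold 14 -> 4) = {value:+.2f} kJ/mol")
```

This prints (profiles referenced to the folded state s₀ = 14; the ±
column is the leave-one-walker-out jackknife standard error):

```
  s      G_ref     G_var    +/-
  4.0    30.773    35.742   0.025
  6.0    23.763    27.735   0.021
  8.0    17.185    20.162   0.017
 10.0    10.968    12.952   0.012
 12.0     5.147     6.139   0.006
 14.0     0.000     0.000   0.000
ddG(unfold 14 -> 4) = +4.97 kJ/mol (stabilizing)
```

Unfolding the variant costs ~5 kJ/mol more reversible work than the
reference — the injected gap, recovered within the jackknife error.

The same workflow is scriptable from the shell (`metamec --help`):

```bash
metamec synth ensemble --n 100000 --seed 42 --out wt.dat
metamec mec profile --in wt.dat --s0 14 --grid 4:14:1 --temp 300 --out wt.prof
metamec mec ddg --ref wt.prof --var mut.prof --folded 14 --unfolded 4
metamec pbsa energy --pqr frame.pqr --spacing 0.4 --eps-out 80
metamec ddg run --config run.json --out report.json
```

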