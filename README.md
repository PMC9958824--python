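# isoswell

A two-compartment equilibrium-thermodynamic model of neuron swelling in
which water and ions are **co-transported at fixed stoichiometry**, so that
brain tissue stays isotonic while extracellular space shrinks.  The package
is aimed at cellular/membrane biophysicists studying cytotoxic oedema,
spreading depolarization and cell-volume regulation: it computes the full
isotonic mixing path, the Donnan equilibria it is usually compared against,
and the Gibbs-energy bookkeeping (work of mixing vs osmotic work) of both.

## The model

One litre of tissue is split into interstitial space (volume fraction
α = 0.25 physiologically) and the neuronal interior, separated by a movable
semi-permeable membrane.  Monovalent ions Na⁺, K⁺, Cl⁻ and HCO₃⁻ are
permeant; the impermeant anions A⁻ (charged metabolites and macromolecules)
are confined to their compartment.  Both sides start electro-neutral and
isotonic at 304 mM total.

Each permeant species K crosses the membrane together with water at a
constant *transport concentration* c_K (mM of ion per litre of
co-transported water; negative when ion and water move oppositely, as for
K⁺ through a KCC2-style co-transporter running in reverse).  Under this
mixing rule the concentrations are hyperbolae of the compartment volumes,

    Ko(w) = c_K − (c_K − Ko*)/w,   Ki(y) = c_K − (c_K − Ki*)/y,

with w, y the relative extra-/intracellular volume changes
(y = (1 − wα)/(1 − α)).  The path ends at the volume ω where the impermeant
anions reach equal concentration on both sides; there every permeant species
settles at its volume-weighted mean K_e = αKo* + (1−α)Ki* and all Nernst
potentials vanish.  Because the total transport is isotonic and
electro-neutral, *every* intermediate state is isotonic and electro-neutral
— unlike the Donnan equilibria at intermediate volumes, which carry an
osmotic imbalance of up to ~171 mM (≈0.4 atm of equivalent hydrostatic
pressure by van 't Hoff).

The reversible work retrieved by mixing species K is

    W = RT ∫ ln(Ko/Ki) d(Ko·Vo)
      = RT·[Vo*Ko*lnKo* − wVo*K°lnK° + Vi*Ki*lnKi* − yVi*K°lnK°
            + (C/a_K)ln w + (D/a_K)ln y],

whose last two terms are minus the osmotic (pressure–volume) work the
species does in displacing the membrane.  Energies are reported as densities
in J per litre of tissue.

## Worked example

```python
from isoswell import (load_config, solve_full_equilibrium, solve_donnan,
                      donnan_total_imbalance, path_coefficients, isotonic_work)

cfg = load_config("table1")          # packaged physiological ion table
state = cfg.initial_state()

eq = solve_full_equilibrium(state)
print(round(eq.omega, 4), round(eq.y, 2))
# 0.0243 1.3   -> extracellular space shrinks to 2.4% of the tissue,
#                 neurons swell by 30%
print({k: round(v, 1) for k, v in eq.transport_plan.c.items()})
# {'Na+': 159.0, 'K+': -7.0, 'Cl-': 121.5, 'HCO3-': 30.5, 'A-': 0.0}
#   -> co-transport concentrations; K+ moves against the water flow

sol = solve_donnan(state, 0.25)
print(round(donnan_total_imbalance(sol), 1), round(sol.donnan_potential, 1))
# 171.2 -18.2  -> the Donnan alternative is 171 mM hypertonic inside,
#                 at a common Donnan potential of -18 mV

work = isotonic_work(path_coefficients(state), eq.omega)
print({k: round(v, 1) for k, v in work.mixing.items()}, round(work.total_mixing, 1))
# {'Na+': 138.5, 'K+': 8.6, 'Cl-': 109.4, 'HCO3-': 13.3, 'A-': -0.0} 269.8
#   -> Gibbs energy retrieved along the isotonic path, J per litre of
#      tissue; the impermeant anions do no mixing work (the -0.0 is the
#      exact term cancellation at machine precision)
```

The same computations are available from the shell:

```
isoswell equilibrium            # full-equilibrium table + transport plan
isoswell donnan --alpha-tilde 0.25
isoswell path --grid 0.0243:0.25:0.001 --audit
isoswell energy
isoswell figures                # all curve data (both scenarios) as CSV
```

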