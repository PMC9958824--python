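# Methods

## Model and assumptions

The tissue is a closed system of fixed total volume V = 1 l, partitioned
into an extracellular compartment (initial fraction α) and an intracellular
one, separated by a movable semi-permeable membrane.  Solutions are ideal
and well mixed; bulk electroneutrality holds on both sides; the number of
particles of each ion species is conserved (no sources, sinks or buffering);
divalent ions are excluded (their physiological concentrations are too low
to matter for the energy balance and they require separate pumps).  The
membrane potential is not modelled: it stores a negligible fraction of the
energy held in the concentration gradients and cannot shift the equilibria,
only the (unmodelled) kinetics.  The model has no time axis — it is
equilibrium thermodynamics evaluated along a quasi-static path — so results
apply to processes slow enough for chemical potentials to equilibrate and
fast enough that volume and particle numbers are conserved.

State variables are the extracellular volume fraction (public coordinate
`alpha_tilde`; internally w = α̃/α and y = (1 − α̃)/(1 − α)) and the
per-species concentrations on both sides.  The impermeant anions are a
single species present in *both* compartments (10 mM outside, 134 mM inside
in the default table); the two pools never exchange and change concentration
by volume rescaling alone.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| R | 8.3145 | J mol⁻¹ K⁻¹ | gas constant |
| T | 310 | K | physiological brain temperature |
| F | 96485 | C mol⁻¹ | Faraday constant |
| water molarity | 55.6 | M | sets water-per-solute stoichiometry |
| α | 0.25 | — | physiological extracellular fraction |
| ion table | packaged `table1` | mM | physiological monovalent concentrations |

Concentrations are mM (≡ mol m⁻³), volumes are fractions of the 1-litre
tissue, energies are J per litre of tissue (mM × J mol⁻¹ × 10⁻³).

## Procedures and numerical choices

**Full equilibrium.**  The final relative extracellular volume solves
A⁻ₒ*/w = A⁻ᵢ*(1−α)/(1−wα) in closed form,
w_e = Aₒ*/(αAₒ* + (1−α)Aᵢ*); a solution requires impermeants on both sides
with the inside concentration at least the outside one, otherwise the
bracket (0, 1] is empty and an explicit error names it.  When the impermeant
distribution is already equal (w_e = 1) no transport plan exists (the
endpoint-ratio formula degenerates) and the equilibrium is returned without
one.  Equilibrium concentrations are K_e = αKₒ* + (1−α)Kᵢ*; transport
concentrations c_K = (Kₒ* − wK_e)/(1 − w).  Particle conservation guarantees
the inner-compartment route (Kᵢ*, y) gives the same c_K; the test suite
checks the two routes agree to 1e−12 relative.

**Donnan solve.**  A species of valence z obeys Kₒ/Kᵢ = ρᶻ at a common
ratio ρ; with per-species totals fixed and volumes (α̃, 1−α̃) the
extracellular net charge is strictly monotone in ρ, so the root is unique.
It is found with Brent's method on ln ρ over the bracket [1e−8, 1e8] at
machine tolerance; the inside charge then vanishes by global charge
conservation.  The Donnan potential is (RT/F)·ln ρ, inside minus outside,
with ρ the cation outside/inside ratio (≈ −18 mV at α̃ = 0.25: anion excess
inside makes the interior negative).  Impermeant pools rescale with their
own compartment volume, here and on the path.

**Path evaluation.**  Concentrations follow the hyperbolic laws; the
validity bound is the largest volume at which any concentration crosses
zero (for the default plan ≈ 0.0174, set by the extracellular Cl⁻/Na⁺
depletion — both bind within 0.0002 of each other).  Evaluation below the
bound raises an error naming the offending species rather than clamping,
which would silently corrupt the conservation audits; evaluation below the
full-equilibrium volume ω (physically a super-equilibrium extrapolation,
useful for plotting) is allowed but flagged with a warning category.

**Energies.**  The closed-form work of mixing is evaluated with x·ln x
continued by 0 at x = 0, so the depletion endpoint of variant plans is
admissible; the ratios C/a_K = Vₒ*(c_K − Kₒ*) and D/a_K = Vᵢ*(c_K − Kᵢ*)
are used directly, which stay finite in the impermeant limit c_K → 0 and
avoid the 0·∞ of forming a_K = 1/c_K.  The independent quadrature oracle
integrates RT·ln(Kₒ/Kᵢ) d(KₒVₒ) by composite trapezoid; since KₒVₒ is linear
in w with slope αc_K the integral reduces to a 1-D integral over w
(10⁵ steps by default; agreement with the closed form is tested to 1e−6
relative).  Work to a Donnan endpoint derives a per-volume c_K from the
endpoints; at α̃ = α the transfer is isochoric (w = y = 1) and the volume
terms vanish, so no transport concentration is needed.  The equal-work
volume is found by Brent bisection on (ω, α); the isotonic total is strictly
monotone there, so the crossing is unique.  It evaluates to 0.1158 for the
default table (the conventional rounded statement is "extracellular space
shrinks by 54%", i.e. ≈ 0.115).

**Audits.**  Model-generated states must satisfy |Σout − Σin| and net
charge < 1e−9 mM and per-species particle drift < 1e−9 mmol/l; states
rebuilt from rounded printed tables are audited at 0.1 mM.  Configs are
audited at 1e−6 mM — strict enough to catch a 1 mM typo, loose enough for
two-decimal inputs.

## What the default scenario does and does not represent

The packaged table is a textbook mammalian physiological state, not a
measurement of any one preparation: passing tests show internal consistency
of the thermodynamics (isotonicity, electroneutrality, conservation, energy
identities) and agreement with the closed-form reference values derived from
that table.  They do not show that real neurons follow the path: real tissue
has glia, ion buffering (CO₂/bicarbonate, pH), divalents, channel kinetics
and a membrane potential, none of which are modelled, and the co-transport
stoichiometry is assumed constant on the coarse time-scale of swelling.

## Known limitations

* Valences other than ±1 are accepted by the types and the Donnan solver but
  are untested against reference values; the default table is monovalent.
* No activity coefficients (ideal solutions) and no elastic-membrane energy
  term (membrane-area buffering is assumed).
* The variant-plan comparison (raised Na⁺ transport) has an ambiguous
  integration endpoint: the variant path cannot reach ω because
  extracellular Na⁺ depletes first (at α̃ ≈ 0.043 for c_Na = 179 mM).  The
  work comparison is therefore asserted only as an inequality against the
  full-equilibrium plan's 269.8 J/l.
* Plotting is intentionally out of scope; the `figures` command emits the
  underlying curve tables as CSV, from which any plotting tool can
  reproduce the panels.
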