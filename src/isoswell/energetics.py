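"""Work of mixing, osmotic work, and the van 't Hoff pressure equivalence.

For reversible transport of species *K* at constant transport concentration
c_K, the Gibbs energy retrieved (work of mixing) is

    W = RT * integral( ln(Ko/Ki) d(Ko*Vo) )

taken from the final back to the initial state.  It has the closed form

    W/RT = Vo*Ko*lnKo* - w Vo*K° lnK° + Vi*Ki*lnKi* - y Vi*K° lnK°
           + (C/a_K) ln w + (D/a_K) ln y,

whose first four terms are the decrease in chemical potential energy of the
species and whose last two are minus the osmotic (pressure-volume) work the
species does in displacing the membrane.  All energies are densities in
joule per litre of tissue; concentrations enter in mM and volumes as
fractions of the fixed 1-litre tissue volume, whence the 1e-3 factor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .core import (
    DEFAULT_CONSTANTS,
    ModelError,
    PhysicalConstants,
    TissueState,
    VolumeChange,
)
from .equilibria import (
    TransportPlan,
    solve_donnan,
    solve_full_equilibrium,
    transport_concentration,
)
from .isotonic_path import PathCoefficients, path_coefficients, path_state

__all__ = [
    "EnergyBreakdown",
    "mixing_work_closed",
    "mixing_work_numeric",
    "chemical_energy_decrease",
    "osmotic_work",
    "isotonic_work",
    "isochoric_complete_mixing",
    "work_to_donnan",
    "find_equal_work_volume",
    "vant_hoff_pressure",
    "water_per_ion",
    "WaterStoichiometry",
]


def _xlogx(x: float) -> float:
    """x*ln(x) with the continuous limit 0 at x = 0."""
    if x < 0:
        raise ModelError(f"negative concentration in energy term: {x}")
    return 0.0 if x == 0.0 else x * math.log(x)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-species and total energies (J per litre of tissue) at one endpoint."""

    scenario: str  #: "isotonic" | "donnan" | "isochoric"
    alpha_tilde: float
    mixing: Mapping[str, float]
    osmotic: Mapping[str, float]

    @property
    def total_mixing(self) -> float:
        return sum(self.mixing.values())

    @property
    def total_osmotic(self) -> float:
        return sum(self.osmotic.values())


def mixing_work_closed(
    name: str,
    coeffs: PathCoefficients,
    w: float,
    y: float,
    final_out: float,
    final_in: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Closed-form work of mixing (J/l) done by one species.

    Valid for any leg with constant transport concentration connecting the
    initial state to final concentrations ``final_out``/``final_in`` under
    volume changes ``(w, y)``.  Species transported at c_K = 0 whose
    concentrations change by volume rescaling alone do no mixing work (the
    chemical and osmotic terms cancel).
    """
    if final_out < 0 or final_in < 0:
        raise ModelError(
            f"{name}: final concentrations must be non-negative, got "
            f"({final_out}, {final_in}) mM"
        )
    VolumeChange(w=w, y=y, alpha=coeffs.alpha)  # consistency check
    alpha = coeffs.alpha
    init = coeffs.initial
    terms = (
        alpha * _xlogx(init.conc_out[name])
        - w * alpha * _xlogx(final_out)
        + (1.0 - alpha) * _xlogx(init.conc_in[name])
        - y * (1.0 - alpha) * _xlogx(final_in)
        + coeffs.c_over_a_out(name) * math.log(w)
        + coeffs.c_over_a_in(name) * math.log(y)
    )
    return constants.rt * terms * 1e-3


def chemical_energy_decrease(
    name: str,
    coeffs: PathCoefficients,
    w: float,
    y: float,
    final_out: float,
    final_in: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Decrease in chemical potential energy (J/l) of one species.

    The first four terms of the closed form; equals mixing work plus osmotic
    work done by the species.
    """
    alpha = coeffs.alpha
    init = coeffs.initial
    terms = (
        alpha * _xlogx(init.conc_out[name])
        - w * alpha * _xlogx(final_out)
        + (1.0 - alpha) * _xlogx(init.conc_in[name])
        - y * (1.0 - alpha) * _xlogx(final_in)
    )
    return constants.rt * terms * 1e-3


def osmotic_work(
    name: str,
    coeffs: PathCoefficients,
    w: float,
    y: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Osmotic (pressure-volume) work (J/l) done by one species.

    Sum of the work done by the species' extracellular ions in shrinking
    their compartment and by its intracellular ions in expanding theirs:
    ``-RT*[(C/a_K) ln w + (D/a_K) ln y]``.  The volume-exchange terms
    ``-/+ RT*alpha*(1-w)*c_K`` of the two compartments cancel in the sum and
    the expression holds in the impermeant limit c_K -> 0 as well.
    """
    if w <= 0:
        raise ModelError(f"relative volume w must be > 0, got {w}")
    VolumeChange(w=w, y=y, alpha=coeffs.alpha)
    terms = coeffs.c_over_a_out(name) * math.log(w) + coeffs.c_over_a_in(
        name
    ) * math.log(y)
    return -constants.rt * terms * 1e-3


def mixing_work_numeric(
    name: str,
    coeffs: PathCoefficients,
    alpha_tilde: float,
    n_steps: int = 100_000,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Work of mixing by composite-trapezoid quadrature along the path.

    Independent of the closed form: integrates ``RT ln(Ko/Ki) d(Ko*Vo)``
    directly.  Since ``Ko*Vo`` is linear in w with slope alpha*c_K, the
    integral reduces to ``RT*alpha*c_K * int_w^1 ln(Ko/Ki) dw``.
    """
    if n_steps < 100:
        raise ModelError("quadrature needs at least 100 steps")
    c = coeffs.plan.c[name]
    if c == 0.0:
        return 0.0
    alpha = coeffs.alpha
    w_end = alpha_tilde / alpha
    w = np.linspace(w_end, 1.0, n_steps + 1)
    y = (1.0 - w * alpha) / (1.0 - alpha)
    ko = c - (c - coeffs.initial.conc_out[name]) / w
    ki = c - (c - coeffs.initial.conc_in[name]) / y
    if np.any(ko <= 0) or np.any(ki <= 0):
        raise ModelError(
            f"{name}: non-positive concentration on the quadrature grid; "
            "alpha_tilde lies outside the validity range"
        )
    integrand = np.log(ko / ki)
    return constants.rt * alpha * c * float(np.trapezoid(integrand, w)) * 1e-3


def isotonic_work(
    coeffs: PathCoefficients,
    alpha_tilde: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EnergyBreakdown:
    """Energy breakdown for isotonic mixing from alpha down to ``alpha_tilde``."""
    vol = VolumeChange.from_alpha(coeffs.alpha, alpha_tilde)
    final = path_state(coeffs, alpha_tilde, warn_super_equilibrium=False)
    mixing = {
        s.name: mixing_work_closed(
            s.name,
            coeffs,
            vol.w,
            vol.y,
            final.conc_out[s.name],
            final.conc_in[s.name],
            constants,
        )
        for s in coeffs.initial.species
    }
    osmotic = {
        s.name: osmotic_work(s.name, coeffs, vol.w, vol.y, constants)
        for s in coeffs.initial.species
    }
    return EnergyBreakdown(
        scenario="isotonic", alpha_tilde=alpha_tilde, mixing=mixing, osmotic=osmotic
    )


def isochoric_complete_mixing(
    initial: TissueState,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EnergyBreakdown:
    """Work of complete mixing at constant volume, impermeants included.

    Every species (the impermeant anions as well) equilibrates to its
    volume-weighted mean concentration while the membrane stays put:
    ``W_K = RT*[alpha*Ko*lnKo* + (1-alpha)*Ki*lnKi* - Kbar*lnKbar]*1e-3``
    with ``Kbar = alpha*Ko* + (1-alpha)*Ki*``.  No osmotic work is done.
    """
    alpha = initial.alpha_tilde
    mixing: dict[str, float] = {}
    for s in initial.species:
        ko, ki = initial.conc_out[s.name], initial.conc_in[s.name]
        kbar = alpha * ko + (1.0 - alpha) * ki
        mixing[s.name] = (
            constants.rt
            * (alpha * _xlogx(ko) + (1.0 - alpha) * _xlogx(ki) - _xlogx(kbar))
            * 1e-3
        )
    return EnergyBreakdown(
        scenario="isochoric",
        alpha_tilde=alpha,
        mixing=mixing,
        osmotic={s.name: 0.0 for s in initial.species},
    )


def work_to_donnan(
    initial: TissueState,
    alpha_tilde: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EnergyBreakdown:
    """Energy breakdown for mixing straight to the Donnan equilibrium at
    ``alpha_tilde``.

    A separate transport concentration per species is derived from the
    endpoints for each target volume; at ``alpha_tilde = alpha`` the mixing
    is isochoric (w = y = 1) and the volume terms vanish, so no transport
    concentration is needed.
    """
    alpha = initial.alpha_tilde
    if not 0.0 < alpha_tilde <= alpha:
        raise ModelError(
            f"alpha_tilde = {alpha_tilde} outside (0, alpha = {alpha}]"
        )
    sol = solve_donnan(initial, alpha_tilde, constants)
    vol = VolumeChange.from_alpha(alpha, alpha_tilde)
    if vol.w == 1.0:
        c = {s.name: 0.0 for s in initial.species}  # unused: ln w = ln y = 0
    else:
        c = {
            s.name: (
                transport_concentration(
                    initial.conc_out[s.name], sol.state.conc_out[s.name], vol.w
                )
                if s.permeant
                else 0.0
            )
            for s in initial.species
        }
    coeffs = PathCoefficients(
        initial=initial, plan=TransportPlan(species=initial.species, c=c)
    )
    mixing = {
        s.name: mixing_work_closed(
            s.name,
            coeffs,
            vol.w,
            vol.y,
            sol.state.conc_out[s.name],
            sol.state.conc_in[s.name],
            constants,
        )
        for s in initial.species
    }
    osmotic = {
        s.name: osmotic_work(s.name, coeffs, vol.w, vol.y, constants)
        for s in initial.species
    }
    return EnergyBreakdown(
        scenario="donnan", alpha_tilde=alpha_tilde, mixing=mixing, osmotic=osmotic
    )


def find_equal_work_volume(
    initial: TissueState,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    xtol: float = 1e-12,
) -> float:
    """Extracellular fraction at which the cumulative isotonic work of mixing
    equals the work of isochoric mixing to the Donnan equilibrium at alpha.

    The isotonic total grows monotonically as the extracellular space
    shrinks, so the crossing in (omega, alpha) is unique when it exists.
    """
    eq = solve_full_equilibrium(initial)
    coeffs = path_coefficients(initial)
    w_ref = work_to_donnan(initial, initial.alpha_tilde, constants).total_mixing

    def f(at: float) -> float:
        return isotonic_work(coeffs, at, constants).total_mixing - w_ref

    lo = eq.omega
    hi = initial.alpha_tilde * (1.0 - 1e-12)
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ModelError(
            f"no equal-work volume in (omega = {lo:.4g}, alpha = "
            f"{initial.alpha_tilde:.4g}): endpoint residuals {f_lo:.4g}, "
            f"{f_hi:.4g} J/l"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def vant_hoff_pressure(
    delta_c: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Hydrostatic pressure equivalent of a solute concentration difference.

    van 't Hoff: ``Pi = R*T*delta_c`` with ``delta_c`` in mM (= mol m^-3).
    Returns ``(pascal, mmHg)``.
    """
    pa = constants.rt * delta_c
    return pa, pa / constants.pascal_per_mmHg


@dataclass(frozen=True)
class WaterStoichiometry:
    """Water-per-solute transport ratios of an isotonic plan.

    ``overall`` is the number of water molecules accompanying each
    transported ion for the total membrane transport to be isotonic;
    ``per_species[name]`` is the ratio if *all* water crossed together with
    that single species (``None`` for species with c_K = 0, where the ratio
    is undefined).
    """

    overall: float
    per_species: Mapping[str, float | None]


def water_per_ion(
    plan: TransportPlan, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> WaterStoichiometry:
    """Water:ion stoichiometry implied by the transport concentrations."""
    total = plan.total
    if total <= 0:
        raise ModelError("total transported concentration must be positive")
    water_mm = constants.water_molarity * 1e3  # mM
    overall = water_mm / total
    per_species = {
        name: (water_mm / c if c != 0.0 else None) for name, c in plan.c.items()
    }
    return WaterStoichiometry(overall=overall, per_species=per_species)
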