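"""Full equilibrium and Donnan equilibria of the two-compartment model.

Two distinct end states can be computed from one physiological ion table:

* the *state of full equilibrium* — the tissue volume at which the impermeant
  anions reach the same concentration in the shrunken extracellular space as
  inside the swollen neurons, so that every permeant species can mix
  completely and all Nernst potentials vanish; and
* the *Donnan equilibrium at a prescribed volume* — the passive distribution
  of the permeant ions at a fixed extracellular fraction, where all permeant
  species share one (Donnan) potential but the two sides are generally not
  isotonic.

The full equilibrium also fixes the constant transport concentration c_K at
which each permeant species is co-transported with water along the isotonic
path (c_K < 0 when ion and water move in opposite directions).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy.optimize import brentq

from .core import (
    DEFAULT_CONSTANTS,
    INSIDE,
    OUTSIDE,
    AuditError,
    IonSpec,
    ModelError,
    PhysicalConstants,
    TissueState,
    VolumeChange,
    audit_state,
    particle_totals,
    total_concentration,
)

__all__ = [
    "TransportPlan",
    "FullEquilibrium",
    "DonnanSolution",
    "transport_concentration",
    "solve_full_equilibrium",
    "solve_donnan",
    "donnan_total_imbalance",
]

#: Bracket for the Donnan ratio root search.
_RHO_BRACKET = (1e-8, 1e8)


@dataclass(frozen=True)
class TransportPlan:
    """Constant co-transport concentrations c_K (mM) per species.

    ``c[name]`` is the fixed ratio of moles of species *K* transported to the
    volume of co-transported water, expressed as a concentration; it is 0 for
    impermeant species.  ``a[name] = 1/c`` is the reciprocal water-per-solute
    coefficient (``None`` where c = 0).  An admissible plan transports
    isotonically (sum of c equals the initial total concentration) and
    electro-neutrally (valence-weighted sum of c is zero).
    """

    species: tuple[IonSpec, ...]
    c: Mapping[str, float]

    @property
    def a(self) -> dict[str, float | None]:
        return {
            name: (1.0 / value if value != 0.0 else None)
            for name, value in self.c.items()
        }

    @property
    def total(self) -> float:
        return sum(self.c.values())

    @property
    def charge(self) -> float:
        return sum(s.valence * self.c[s.name] for s in self.species)

    def audit(self, expected_total: float, tol: float = 1e-9) -> None:
        """Verify the plan is isotonic with ``expected_total`` and electro-neutral."""
        if abs(self.total - expected_total) > tol:
            raise AuditError(
                f"transport plan is not isotonic: sum c_K = {self.total:.6f} mM, "
                f"expected {expected_total:.6f} mM"
            )
        if abs(self.charge) > tol:
            raise AuditError(
                f"transport plan is not electro-neutral: sum z*c_K = "
                f"{self.charge:.3e} mM"
            )


def transport_concentration(
    conc_initial: float, conc_final: float, volume_ratio: float
) -> float:
    """c_K from one compartment's endpoint concentrations.

    ``(K* - r*K°)/(1 - r)`` with ``r`` the compartment's relative volume
    change (w outside, y inside).  Particle conservation guarantees the same
    value from either compartment.
    """
    if volume_ratio == 1.0:
        raise ModelError(
            "transport concentration is undefined for an unchanged volume "
            "(volume_ratio = 1)"
        )
    return (conc_initial - volume_ratio * conc_final) / (1.0 - volume_ratio)


@dataclass(frozen=True)
class FullEquilibrium:
    """The state of full equilibrium and the isotonic transport plan to it.

    ``w_e`` is the final extracellular volume relative to its initial value,
    ``omega = w_e*alpha`` the final extracellular fraction of the tissue, and
    ``y`` the neuronal expansion factor.  ``concentrations`` holds the common
    final concentration of every species (equal outside and inside).
    """

    alpha: float
    w_e: float
    omega: float
    y: float
    concentrations: Mapping[str, float]
    transport_plan: TransportPlan | None

    @property
    def state(self) -> TissueState:
        species = self.transport_plan.species if self.transport_plan else ()
        return TissueState(
            species=species,
            alpha_tilde=self.omega,
            conc_out=dict(self.concentrations),
            conc_in=dict(self.concentrations),
        )


def _impermeant_equal_volume(initial: TissueState) -> float:
    """Relative extracellular volume w at which [A]o equals [A]i.

    Closed form of ``A_o*/w = A_i*(1-alpha)/(1-w*alpha)``:
    ``w = A_o*/(alpha*A_o* + (1-alpha)*A_i*)``.
    """
    alpha = initial.alpha_tilde
    a_out = sum(initial.conc_out[s.name] for s in initial.species if not s.permeant)
    a_in = sum(initial.conc_in[s.name] for s in initial.species if not s.permeant)
    if a_out <= 0 or a_in <= 0:
        raise ModelError(
            "full equilibrium requires impermeant species present on both "
            f"sides; got outside {a_out} mM, inside {a_in} mM"
        )
    w = a_out / (alpha * a_out + (1.0 - alpha) * a_in)
    if not 0.0 < w <= 1.0:
        raise ModelError(
            f"no shrinkage solution: impermeant-anion equalisation requires "
            f"w = {w:.6g}, outside the admissible bracket (0, 1]; the inside "
            f"impermeant concentration must be >= the outside one"
        )
    return w


def solve_full_equilibrium(initial: TissueState) -> FullEquilibrium:
    """Construct the state of full equilibrium from a physiological state.

    The final volume is the one at which the impermeant anions acquire the
    same concentration on both sides; there every permeant species settles at
    its volume-weighted mean concentration ``K_e = alpha*Ko* + (1-alpha)*Ki*``
    and the co-transport concentrations follow from the endpoints.  The input
    must be electro-neutral and isotonic (both sides at the same total).
    """
    audit_state(initial, tol=1e-6)
    alpha = initial.alpha_tilde
    w_e = _impermeant_equal_volume(initial)
    vol = VolumeChange.from_alpha(alpha, w_e * alpha)

    conc: dict[str, float] = {}
    for s in initial.species:
        if s.permeant:
            conc[s.name] = (
                alpha * initial.conc_out[s.name]
                + (1.0 - alpha) * initial.conc_in[s.name]
            )
        else:
            conc[s.name] = initial.conc_out[s.name] / w_e

    plan: TransportPlan | None
    if w_e == 1.0:
        # Anion-equalising volume already attained; no co-transport path.
        plan = None
    else:
        c = {
            s.name: (
                transport_concentration(initial.conc_out[s.name], conc[s.name], w_e)
                if s.permeant
                else 0.0
            )
            for s in initial.species
        }
        plan = TransportPlan(species=initial.species, c=c)

    return FullEquilibrium(
        alpha=alpha,
        w_e=w_e,
        omega=w_e * alpha,
        y=vol.y,
        concentrations=conc,
        transport_plan=plan,
    )


@dataclass(frozen=True)
class DonnanSolution:
    """A Donnan equilibrium at a prescribed extracellular fraction.

    ``donnan_ratio`` is the common ratio rho = Ko/Ki of the monovalent
    cations (anions obey the inverse ratio; a species of valence z obeys
    ``Ko/Ki = rho**z``).  ``donnan_potential`` is the inside-minus-outside
    membrane potential (RT/F)*ln(rho), in mV.
    """

    alpha_tilde: float
    donnan_ratio: float
    donnan_potential: float
    state: TissueState


def _donnan_concentrations(
    species: tuple[IonSpec, ...],
    totals: Mapping[str, float],
    impermeant_out: Mapping[str, float],
    alpha_tilde: float,
    rho: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-side concentrations for a trial Donnan ratio.

    Permeant species split their conserved total over the two volumes under
    ``Ko = rho**z * Ki``; impermeant pools rescale with their own volume.
    """
    out: dict[str, float] = {}
    inn: dict[str, float] = {}
    for s in species:
        if s.permeant:
            factor = rho**s.valence
            ki = totals[s.name] / (alpha_tilde * factor + (1.0 - alpha_tilde))
            out[s.name] = factor * ki
            inn[s.name] = ki
        else:
            n_out = impermeant_out[s.name]
            out[s.name] = n_out / alpha_tilde
            inn[s.name] = (totals[s.name] - n_out) / (1.0 - alpha_tilde)
    return out, inn


def solve_donnan(
    initial: TissueState,
    alpha_tilde: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> DonnanSolution:
    """Solve the Donnan equilibrium at extracellular fraction ``alpha_tilde``.

    Particle totals are taken from ``initial``; the impermeant pools stay on
    their own side and rescale with volume.  The Donnan ratio is found by
    driving the extracellular net charge to zero (the intracellular side then
    follows from global charge conservation).  The charge residual is
    monotone in the ratio, so the root in the bracket is unique.
    """
    if not 0.0 < alpha_tilde < 1.0:
        raise ModelError(
            f"alpha_tilde must lie in (0, 1), got {alpha_tilde}"
        )
    totals = particle_totals(initial)
    imp_out = {
        s.name: initial.alpha_tilde * initial.conc_out[s.name]
        for s in initial.species
        if not s.permeant
    }

    def residual(log_rho: float) -> float:
        out, _ = _donnan_concentrations(
            initial.species, totals, imp_out, alpha_tilde, math.exp(log_rho)
        )
        return sum(s.valence * out[s.name] for s in initial.species)

    lo, hi = math.log(_RHO_BRACKET[0]), math.log(_RHO_BRACKET[1])
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        log_rho = lo
    elif r_hi == 0.0:
        log_rho = hi
    elif r_lo * r_hi > 0:
        raise ModelError(
            f"Donnan ratio not bracketed in [{_RHO_BRACKET[0]:g}, "
            f"{_RHO_BRACKET[1]:g}]: charge residuals {r_lo:.3g}, {r_hi:.3g} mM"
        )
    else:
        log_rho = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16)

    rho = math.exp(log_rho)
    out, inn = _donnan_concentrations(
        initial.species, totals, imp_out, alpha_tilde, rho
    )
    state = TissueState(
        species=initial.species,
        alpha_tilde=alpha_tilde,
        conc_out=out,
        conc_in=inn,
    )
    return DonnanSolution(
        alpha_tilde=alpha_tilde,
        donnan_ratio=rho,
        donnan_potential=constants.rt_over_f_mv * math.log(rho),
        state=state,
    )


def donnan_total_imbalance(sol: DonnanSolution) -> float:
    """Inside-minus-outside total solute concentration (mM) of a Donnan state.

    Positive when the impermeant species accumulate solute inside; zero only
    at the volume of full equilibrium (and trivially without impermeants).
    """
    return total_concentration(sol.state, INSIDE) - total_concentration(
        sol.state, OUTSIDE
    )
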