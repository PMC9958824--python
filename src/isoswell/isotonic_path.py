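"""The isotonic mixing path: concentrations, potentials and audits.

When water and ions cross the membrane at fixed transport concentrations
c_K, each species' concentration is a hyperbolic function of its host
compartment's volume:

    Ko(w) = c_K - (c_K - Ko*)/w,      Ki(y) = c_K - (c_K - Ki*)/y,

with w and y the relative extra-/intracellular volume changes.  Impermeant
species rescale with volume only (c_K = 0).  If the transport plan is
isotonic and electro-neutral, every intermediate state is too; the audit
here verifies that numerically on a grid.

The public volume coordinate throughout is the extracellular fraction
``alpha_tilde`` of the tissue (the quantity measured experimentally);
internally ``w = alpha_tilde/alpha``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_CONSTANTS,
    INSIDE,
    OUTSIDE,
    IonSpec,
    ModelError,
    PhysicalConstants,
    TissueState,
    VolumeChange,
    charge_imbalance,
    particle_totals,
    total_concentration,
)
from .equilibria import FullEquilibrium, TransportPlan, solve_full_equilibrium

__all__ = [
    "PathCoefficients",
    "PathRangeError",
    "SuperEquilibriumWarning",
    "ValidityRange",
    "PathAudit",
    "path_coefficients",
    "path_state",
    "validity_range",
    "nernst_potential",
    "interion_slope",
    "audit_path",
]


class PathRangeError(ModelError):
    """Requested volume lies outside the physically admissible range."""


class SuperEquilibriumWarning(UserWarning):
    """The path was evaluated beyond the full-equilibrium volume.

    States below omega are mathematically valid on the hyperbolae but lie
    past the point where mixing is complete; concentration gradients there
    are inverted relative to the physiological ones.
    """


@dataclass(frozen=True)
class PathCoefficients:
    """Integration constants of the hyperbolic concentration-volume laws.

    For a permeant species with water-per-solute coefficient a_K = 1/c_K the
    compartment volumes obey ``Vo = C/(1 - a_K*Ko)`` and
    ``Vi = D/(1 - a_K*Ki)`` with ``C = Vo*(1 - a_K*Ko*)`` and
    ``D = Vi*(1 - a_K*Ki*)``.  The ratios ``C/a_K = Vo*(c_K - Ko*)`` and
    ``D/a_K = Vi*(c_K - Ki*)`` stay finite in the impermeant limit c_K -> 0
    and are the quantities the energetics needs.
    """

    initial: TissueState
    plan: TransportPlan
    omega: float | None = None  #: full-equilibrium volume fraction, if known

    @property
    def alpha(self) -> float:
        return self.initial.alpha_tilde

    def c_over_a_out(self, name: str) -> float:
        """C/a_K (mmol per litre tissue) for the outer compartment."""
        return self.alpha * (self.plan.c[name] - self.initial.conc_out[name])

    def c_over_a_in(self, name: str) -> float:
        """D/a_K for the inner compartment."""
        return (1.0 - self.alpha) * (self.plan.c[name] - self.initial.conc_in[name])

    def hyperbola_constants(self, name: str) -> tuple[float, float]:
        """(C, D) for a permeant species with c_K != 0."""
        a = self.plan.a[name]
        if a is None:
            raise ModelError(
                f"{name} is transported at c_K = 0; its hyperbola degenerates "
                "to pure volume rescaling and C, D are undefined"
            )
        return (
            self.alpha * (1.0 - a * self.initial.conc_out[name]),
            (1.0 - self.alpha) * (1.0 - a * self.initial.conc_in[name]),
        )


def path_coefficients(
    initial: TissueState, plan: TransportPlan | None = None
) -> PathCoefficients:
    """Build path coefficients for ``initial``.

    Without an explicit plan the transport concentrations to the state of
    full equilibrium are used, and the full-equilibrium volume is recorded so
    evaluation beyond it can be flagged.
    """
    if plan is None:
        eq = solve_full_equilibrium(initial)
        if eq.transport_plan is None:
            raise ModelError(
                "initial state is already at full equilibrium; no transport "
                "plan exists"
            )
        return PathCoefficients(initial=initial, plan=eq.transport_plan, omega=eq.omega)
    return PathCoefficients(initial=initial, plan=plan)


def from_equilibrium(eq: FullEquilibrium, initial: TissueState) -> PathCoefficients:
    """Coefficients for the path from ``initial`` to a solved equilibrium."""
    if eq.transport_plan is None:
        raise ModelError("equilibrium carries no transport plan (w_e = 1)")
    return PathCoefficients(initial=initial, plan=eq.transport_plan, omega=eq.omega)


def _species_conc(
    ion: IonSpec, c: float, conc_init: float, ratio: float
) -> float:
    if ion.permeant and c != 0.0:
        return c - (c - conc_init) / ratio
    return conc_init / ratio


def path_state(
    coeffs: PathCoefficients,
    alpha_tilde: float,
    *,
    warn_super_equilibrium: bool = True,
) -> TissueState:
    """Evaluate the isotonic path at extracellular fraction ``alpha_tilde``.

    Raises :class:`PathRangeError`, naming the first offending species, if
    any concentration would go negative; warns (once per call) when
    evaluating beyond the full-equilibrium volume.
    """
    alpha = coeffs.alpha
    if not 0.0 < alpha_tilde <= alpha:
        raise PathRangeError(
            f"alpha_tilde = {alpha_tilde} outside (0, alpha = {alpha}]"
        )
    vol = VolumeChange.from_alpha(alpha, alpha_tilde)
    out: dict[str, float] = {}
    inn: dict[str, float] = {}
    for s in coeffs.initial.species:
        c = coeffs.plan.c[s.name]
        ko = _species_conc(s, c, coeffs.initial.conc_out[s.name], vol.w)
        ki = _species_conc(s, c, coeffs.initial.conc_in[s.name], vol.y)
        for side, value in ((OUTSIDE, ko), (INSIDE, ki)):
            if value < -1e-12:
                raise PathRangeError(
                    f"[{s.name}] {side} would be negative ({value:.4g} mM) at "
                    f"alpha_tilde = {alpha_tilde:.6g}; the path is only valid "
                    f"down to alpha_tilde = {validity_range(coeffs).alpha_min:.6g}"
                )
        out[s.name] = max(ko, 0.0)
        inn[s.name] = max(ki, 0.0)
    if (
        warn_super_equilibrium
        and coeffs.omega is not None
        and alpha_tilde < coeffs.omega - 1e-12
    ):
        warnings.warn(
            f"alpha_tilde = {alpha_tilde:.6g} lies beyond the full-equilibrium "
            f"volume omega = {coeffs.omega:.6g}",
            SuperEquilibriumWarning,
            stacklevel=2,
        )
    return TissueState(
        species=coeffs.initial.species,
        alpha_tilde=alpha_tilde,
        conc_out=out,
        conc_in=inn,
    )


@dataclass(frozen=True)
class ValidityRange:
    """Lower admissible bound of the path coordinate.

    ``species``/``side`` identify the concentration that reaches zero at
    ``alpha_min`` (``None`` when every concentration stays positive down to
    alpha_tilde -> 0).
    """

    alpha_min: float
    species: str | None
    side: str | None

    def __float__(self) -> float:
        return self.alpha_min


def validity_range(coeffs: PathCoefficients) -> ValidityRange:
    """Smallest ``alpha_tilde`` at which all concentrations are non-negative.

    For each permeant species the outer concentration hits zero at
    ``w = (c_K - Ko*)/c_K`` (when that lies in (0, 1)) and the inner one at
    ``y = (c_K - Ki*)/c_K``; the binding constraint is the largest resulting
    ``alpha_tilde``.
    """
    alpha = coeffs.alpha
    best = ValidityRange(alpha_min=0.0, species=None, side=None)
    for s in coeffs.initial.species:
        c = coeffs.plan.c[s.name]
        if not s.permeant or c == 0.0:
            continue  # pure rescaling never changes sign
        # Outer compartment: w shrinks from 1 toward 0.
        w_zero = (c - coeffs.initial.conc_out[s.name]) / c
        if 0.0 < w_zero < 1.0:
            cand = alpha * w_zero
            if cand > best.alpha_min:
                best = ValidityRange(cand, s.name, OUTSIDE)
        # Inner compartment: y grows from 1 toward 1/(1-alpha).
        y_zero = (c - coeffs.initial.conc_in[s.name]) / c
        if y_zero > 1.0:
            cand = 1.0 - y_zero * (1.0 - alpha)
            if cand > best.alpha_min:
                best = ValidityRange(cand, s.name, INSIDE)
    return best


def nernst_potential(
    conc_out: float,
    conc_in: float,
    valence: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Nernst equilibrium potential (mV), inside minus outside.

    ``(RT/zF)*ln(Ko/Ki)``; both concentrations must be strictly positive.
    """
    if conc_out <= 0 or conc_in <= 0:
        raise ModelError(
            f"Nernst potential needs positive concentrations, got "
            f"Ko = {conc_out}, Ki = {conc_in} mM"
        )
    return constants.rt_over_f_mv / valence * math.log(conc_out / conc_in)


def interion_slope(species_x: IonSpec, species_ref: IonSpec) -> float:
    """Slope of [X]o against [ref]o along the isotonic path.

    Both extracellular concentrations are linear in 1/w, so the relation is
    an exact straight line with slope ``(Xo* - Xi*)/(Ro* - Ri*)`` — minus the
    ratio of the magnitudes of the physiological concentration gradients when
    the two gradients point in opposite directions.
    """
    denom = species_ref.conc_out - species_ref.conc_in
    if denom == 0.0:
        raise ModelError(
            f"reference species {species_ref.name} has no concentration "
            "gradient; the slope is undefined"
        )
    return (species_x.conc_out - species_x.conc_in) / denom


@dataclass(frozen=True)
class PathAudit:
    """Worst-case residuals over an evaluated path grid (all in mM)."""

    n_points: int
    alpha_lo: float
    alpha_hi: float
    max_tonicity: float  #: max |total(side) - initial total| over both sides
    max_charge: float
    max_conservation: float  #: max per-species particle drift

    @property
    def max(self) -> float:
        return max(self.max_tonicity, self.max_charge, self.max_conservation)


def audit_path(
    coeffs: PathCoefficients,
    n_points: int,
    alpha_lo: float | None = None,
    alpha_hi: float | None = None,
) -> PathAudit:
    """Audit isotonicity, electroneutrality and conservation on a grid.

    Defaults to the closed interval from the full-equilibrium volume (or the
    validity bound, whichever is larger) up to the physiological alpha.
    """
    if n_points < 2:
        raise ModelError("audit needs at least the two endpoint states")
    alpha = coeffs.alpha
    if alpha_hi is None:
        alpha_hi = alpha
    if alpha_lo is None:
        lo_bound = validity_range(coeffs).alpha_min
        alpha_lo = coeffs.omega if coeffs.omega is not None else lo_bound
        alpha_lo = max(alpha_lo, lo_bound + 1e-12)
    total0 = total_concentration(coeffs.initial, OUTSIDE)
    n0 = particle_totals(coeffs.initial)

    grid = np.linspace(alpha_lo, alpha_hi, n_points)
    max_t = max_q = max_n = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SuperEquilibriumWarning)
        for at in grid:
            st = path_state(coeffs, float(at))
            max_t = max(
                max_t,
                abs(total_concentration(st, OUTSIDE) - total0),
                abs(total_concentration(st, INSIDE) - total0),
            )
            max_q = max(
                max_q,
                abs(charge_imbalance(st, OUTSIDE)),
                abs(charge_imbalance(st, INSIDE)),
            )
            drift = particle_totals(st)
            max_n = max(max_n, max(abs(drift[k] - n0[k]) for k in n0))
    return PathAudit(
        n_points=n_points,
        alpha_lo=float(alpha_lo),
        alpha_hi=float(alpha_hi),
        max_tonicity=max_t,
        max_charge=max_q,
        max_conservation=max_n,
    )
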