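"""Domain types, physical constants and consistency audits.

The model describes one litre of brain tissue split into two well-mixed
compartments — interstitial (extracellular) space and the neuronal interior —
separated by a movable semi-permeable membrane.  A state is a snapshot of the
extracellular volume fraction together with the per-species ion concentrations
on either side.  Three bookkeeping quantities (total solute concentration,
valence-weighted charge, per-species particle content) are the audits every
computed state must satisfy: bulk solutions are electro-neutral, the model
path is isotonic, and the system is closed (no particles enter or leave).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PhysicalConstants",
    "IonSpec",
    "TissueState",
    "VolumeChange",
    "ModelError",
    "AuditError",
    "OUTSIDE",
    "INSIDE",
    "total_concentration",
    "charge_imbalance",
    "particle_totals",
    "state_residuals",
    "audit_state",
    "MODEL_TOL",
    "PRINTED_TOL",
]

#: Absolute tolerance (mM) for states produced by the model itself.
MODEL_TOL = 1e-9
#: Absolute tolerance (mM) for states rebuilt from rounded printed tables.
PRINTED_TOL = 0.1

OUTSIDE = "outside"
INSIDE = "inside"


class ModelError(ValueError):
    """Base class for model-domain errors."""


class AuditError(ModelError):
    """A state failed an electroneutrality/tonicity/conservation audit."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the model.

    Parameters
    ----------
    gas_constant : float
        Universal gas constant R, J mol^-1 K^-1.
    temperature : float
        Absolute temperature T, K (physiological brain temperature).
    faraday : float
        Faraday constant F, C mol^-1.
    water_molarity : float
        Molar concentration of pure water, mol l^-1; sets the
        water-per-solute stoichiometry of isotonic co-transport.
    pascal_per_mmHg : float
        Unit conversion for hydrostatic pressure.
    """

    gas_constant: float = 8.3145
    temperature: float = 310.0
    faraday: float = 96485.0
    water_molarity: float = 55.6
    pascal_per_mmHg: float = 133.322

    def __post_init__(self) -> None:
        for name in (
            "gas_constant",
            "temperature",
            "faraday",
            "water_molarity",
            "pascal_per_mmHg",
        ):
            if getattr(self, name) <= 0:
                raise ModelError(f"physical constant {name!r} must be positive")

    @property
    def rt(self) -> float:
        """R*T in J mol^-1."""
        return self.gas_constant * self.temperature

    @property
    def rt_over_f_mv(self) -> float:
        """RT/F in millivolts."""
        return self.rt / self.faraday * 1e3


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IonSpec:
    """One ion species with its physiological boundary conditions.

    ``conc_out`` / ``conc_in`` are the *initial* (physiological)
    extracellular / intracellular concentrations in mM.  Impermeant species
    (``permeant=False``) never cross the membrane: their two pools change
    concentration by volume rescaling only.
    """

    name: str
    valence: int
    permeant: bool
    conc_out: float
    conc_in: float

    def __post_init__(self) -> None:
        if self.conc_out < 0 or self.conc_in < 0:
            raise ModelError(f"{self.name}: concentrations must be >= 0")
        if self.valence == 0:
            raise ModelError(f"{self.name}: valence must be a nonzero integer")


@dataclass(frozen=True)
class TissueState:
    """A snapshot of the two-compartment system.

    The total tissue volume is fixed at 1 litre; ``alpha_tilde`` is the
    fraction of it taken by extracellular space, so the compartment volumes
    are ``alpha_tilde`` and ``1 - alpha_tilde`` litres.
    """

    species: tuple[IonSpec, ...]
    alpha_tilde: float
    conc_out: Mapping[str, float]
    conc_in: Mapping[str, float]
    total_volume: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_tilde < 1.0:
            raise ModelError(
                f"extracellular volume fraction must lie in (0, 1), "
                f"got {self.alpha_tilde}"
            )
        for ion in self.species:
            for side, table in ((OUTSIDE, self.conc_out), (INSIDE, self.conc_in)):
                if ion.name not in table:
                    raise ModelError(f"missing {side} concentration for {ion.name}")
                if table[ion.name] < -MODEL_TOL:
                    raise ModelError(
                        f"negative {side} concentration for {ion.name}: "
                        f"{table[ion.name]} mM"
                    )

    @classmethod
    def from_specs(cls, species: tuple[IonSpec, ...], alpha: float) -> "TissueState":
        """Initial state: every species at its physiological concentrations."""
        return cls(
            species=tuple(species),
            alpha_tilde=alpha,
            conc_out={s.name: s.conc_out for s in species},
            conc_in={s.name: s.conc_in for s in species},
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def ion(self, name: str) -> IonSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class VolumeChange:
    """Relative compartment volume changes.

    ``w`` is the extracellular volume relative to its initial value, ``y``
    the intracellular one.  Conservation of the total tissue volume ties the
    two together through the initial extracellular fraction ``alpha``:
    ``y = (1 - w*alpha)/(1 - alpha)``.
    """

    w: float
    y: float
    alpha: float

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ModelError(f"relative extracellular volume w must be > 0, got {self.w}")
        expected_y = (1.0 - self.w * self.alpha) / (1.0 - self.alpha)
        if not math.isclose(self.y, expected_y, rel_tol=1e-12, abs_tol=1e-12):
            raise ModelError(
                f"inconsistent volume change: y={self.y} but total-volume "
                f"conservation requires {expected_y}"
            )

    @classmethod
    def from_alpha(cls, alpha: float, alpha_tilde: float) -> "VolumeChange":
        """Volume changes when the extracellular fraction moves alpha -> alpha_tilde."""
        w = alpha_tilde / alpha
        y = (1.0 - alpha_tilde) / (1.0 - alpha)
        return cls(w=w, y=y, alpha=alpha)


def _side_table(state: TissueState, side: str) -> Mapping[str, float]:
    if side == OUTSIDE:
        return state.conc_out
    if side == INSIDE:
        return state.conc_in
    raise ModelError(f"unknown side {side!r}; expected {OUTSIDE!r} or {INSIDE!r}")


def total_concentration(state: TissueState, side: str) -> float:
    """Total solute concentration (mM) on one side of the membrane."""
    table = _side_table(state, side)
    return sum(table[s.name] for s in state.species)


def charge_imbalance(state: TissueState, side: str) -> float:
    """Valence-weighted net charge concentration (mM) on one side.

    Zero for an electro-neutral bulk solution.
    """
    table = _side_table(state, side)
    return sum(s.valence * table[s.name] for s in state.species)


def particle_totals(state: TissueState) -> dict[str, float]:
    """Per-species particle content, mmol per litre of tissue.

    ``alpha_tilde*Ko + (1 - alpha_tilde)*Ki``; conserved along any closed
    mixing path.
    """
    a = state.alpha_tilde
    return {
        s.name: a * state.conc_out[s.name] + (1.0 - a) * state.conc_in[s.name]
        for s in state.species
    }


@dataclass(frozen=True)
class StateResiduals:
    """Audit residuals of one state (all in mM)."""

    tonicity: float  #: |total outside - total inside|
    charge_out: float
    charge_in: float

    @property
    def max(self) -> float:
        return max(self.tonicity, abs(self.charge_out), abs(self.charge_in))


def state_residuals(state: TissueState) -> StateResiduals:
    return StateResiduals(
        tonicity=abs(
            total_concentration(state, OUTSIDE) - total_concentration(state, INSIDE)
        ),
        charge_out=charge_imbalance(state, OUTSIDE),
        charge_in=charge_imbalance(state, INSIDE),
    )


def audit_state(state: TissueState, tol: float = MODEL_TOL) -> StateResiduals:
    """Check electroneutrality of both sides and equality of the totals.

    Raises :class:`AuditError` if any residual exceeds ``tol`` (mM); returns
    the residuals otherwise.
    """
    res = state_residuals(state)
    if res.tonicity > tol:
        raise AuditError(
            f"tonicity audit failed: |total_out - total_in| = "
            f"{res.tonicity:.3e} mM > {tol:g} mM"
        )
    for side, value in ((OUTSIDE, res.charge_out), (INSIDE, res.charge_in)):
        if abs(value) > tol:
            raise AuditError(
                f"electroneutrality audit failed {side}: net charge = "
                f"{value:.3e} mM > {tol:g} mM"
            )
    return res
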