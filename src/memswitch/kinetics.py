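"""Promoter-state kinetics: parameters, induction protocols, closed forms.

Three promoter model variants are supported.

* ``two_state_model1`` — loci switch irreversibly (while hormone is
  present) from inactive to active at rate ``k_A``; active loci load
  Pol II at the constant rate ``k_pol``.
* ``two_state_model2`` — all loci activate essentially immediately
  (``k_A`` set very fast) and the Pol II *attempt* rate grows linearly
  in time, ``alpha * t``; successful loadings are limited by the Pol II
  footprint, a minimum spacing of ``footprint_nt`` nucleotides between
  consecutive elongating polymerases.
* ``memory_switch`` — four states as the product of two independent
  binary coordinates: induced/uninduced (rates ``k_A`` / ``k_minus_A``)
  and memory/default (rates ``k_C`` / ``k_minus_C``).  Induced loci
  load Pol II at ``k_polL`` (default state) or ``k_polH`` (memory
  state); uninduced loci at the basal ``k_polB``.  Hormone makes both
  activation and conversion effectively irreversible; Nup98 is required
  to keep conversion irreversible after hormone withdrawal.

All times are minutes, rates per minute, positions in nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "KineticParams",
    "PromoterModelSpec",
    "ProtocolSegment",
    "InductionProtocol",
    "active_fraction",
    "memory_fraction",
    "effective_loading_rate",
    "mean_production_rate",
    "MODEL1",
    "MODEL2",
    "MEMORY_SWITCH",
]

MODEL1 = "two_state_model1"
MODEL2 = "two_state_model2"
MEMORY_SWITCH = "memory_switch"
_VARIANTS = (MODEL1, MODEL2, MEMORY_SWITCH)

#: k_A used when a model stipulates essentially instantaneous activation.
FAST_K_A = 1000.0


@dataclass
class KineticParams:
    """Rate constants for all promoter model variants.

    Defaults are the fitted values for the ecdysone-induced E74 response
    (memory-switch: k_A = 17e-3/min, k_C = 0.8e-3/min, k_polL = 0.3,
    k_polH = 4.5 Pol II/min; two-state: k_pol = 2.0 Pol II/min,
    alpha = 11.7e-3 Pol II/min^2).  Fields a given variant does not use
    are simply ignored.
    """

    k_A: float = 17e-3  # activation rate (1/min)
    k_minus_A: float = 0.0  # inactivation rate; ~0 while hormone present
    k_C: float = 0.8e-3  # default -> memory conversion rate (1/min)
    k_minus_C: float = 0.0  # memory -> default reversion (Nup98-dependent)
    k_polB: float = 5e-4  # basal loading rate, uninduced states (Pol II/min)
    k_polL: float = 0.3  # loading rate, induced default state
    k_polH: float = 4.5  # loading rate, induced memory state
    k_pol: float = 2.0  # single loading rate for two-state Model 1
    alpha: float = 11.7e-3  # attempt-rate acceleration for Model 2 (min^-2)
    footprint_nt: int = 150  # minimum Pol II spacing s
    elongation_nt_per_min: float = 1500.0  # elongation speed v

    def __post_init__(self) -> None:
        for name in (
            "k_A", "k_minus_A", "k_C", "k_minus_C",
            "k_polB", "k_polL", "k_polH", "k_pol", "alpha",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.footprint_nt < 1:
            raise ValueError("footprint_nt must be >= 1")
        if self.elongation_nt_per_min <= 0:
            raise ValueError("elongation_nt_per_min must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)

    def replace(self, **kwargs) -> "KineticParams":
        d = self.to_dict()
        d.update(kwargs)
        return KineticParams.from_dict(d)


@dataclass(frozen=True)
class PromoterModelSpec:
    """Which promoter model variant to run.

    ``immediate_activation`` forces effectively instantaneous entry into
    the active state (k_A replaced by ``FAST_K_A``); it is implied by
    Model 2.
    """

    variant: str
    immediate_activation: bool = False

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {_VARIANTS}"
            )

    @property
    def activation_is_immediate(self) -> bool:
        return self.immediate_activation or self.variant == MODEL2

    def to_dict(self) -> dict:
        return {"variant": self.variant,
                "immediate_activation": self.immediate_activation}

    @classmethod
    def from_dict(cls, d: dict) -> "PromoterModelSpec":
        return cls(**d)


@dataclass(frozen=True)
class ProtocolSegment:
    duration_min: float
    hormone_present: bool
    nup98_depleted: bool = False
    inhibitor: str = "none"  # one of {"none", "FP", "TPL"}

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("segment duration must be > 0")
        if self.inhibitor not in ("none", "FP", "TPL"):
            raise ValueError("inhibitor must be one of none/FP/TPL")


@dataclass(frozen=True)
class InductionProtocol:
    """Ordered timeline of hormone exposure and perturbations."""

    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration_min(self) -> float:
        return sum(s.duration_min for s in self.segments)

    @classmethod
    def standard(
        cls,
        nup98_depleted: bool = False,
        induction_min: float = 240.0,
        recovery_min: float = 1440.0,
        first_induction_inhibitor: str = "none",
    ) -> "InductionProtocol":
        """4 hr hormone, 24 hr recovery, 4 hr hormone (the memory assay)."""
        return cls((
            ProtocolSegment(induction_min, True, nup98_depleted,
                            first_induction_inhibitor),
            ProtocolSegment(recovery_min, False, nup98_depleted),
            ProtocolSegment(induction_min, True, nup98_depleted),
        ))

    @classmethod
    def single_induction(
        cls, duration_min: float = 240.0, nup98_depleted: bool = False,
        inhibitor: str = "none",
    ) -> "InductionProtocol":
        return cls((ProtocolSegment(duration_min, True, nup98_depleted,
                                    inhibitor),))

    def to_dict(self) -> dict:
        return {"segments": [asdict(s) for s in self.segments]}

    @classmethod
    def from_dict(cls, d: dict) -> "InductionProtocol":
        return cls(tuple(ProtocolSegment(**s) for s in d["segments"]))

    def segment_of_times(self, times_abs) -> np.ndarray:
        """Segment index for each absolute time.

        Boundary convention: a time at a segment boundary belongs to the
        earlier segment, except when the later segment is hormone-on —
        a sample taken exactly at induction start belongs to that
        induction (offset 0).
        """
        times_abs = np.asarray(times_abs, dtype=float)
        starts = np.concatenate([
            [0.0], np.cumsum([s.duration_min for s in self.segments])
        ])
        idx = np.clip(
            np.searchsorted(starts, times_abs, side="right") - 1,
            0, len(self.segments) - 1,
        )
        for i, seg in enumerate(self.segments):
            if i > 0 and not seg.hormone_present:
                on_boundary = times_abs == starts[i]
                idx[on_boundary & (idx == i)] = i - 1
        return idx

    def segment_starts(self) -> np.ndarray:
        return np.concatenate([
            [0.0],
            np.cumsum([s.duration_min for s in self.segments])[:-1],
        ])


# ---------------------------------------------------------------------
# Closed-form occupancies
# ---------------------------------------------------------------------

def active_fraction(k_A: float, t) -> float | np.ndarray:
    """Fraction of loci activated after ``t`` minutes of hormone.

    First-order irreversible kinetics (k_A >> k_-A while hormone is
    present): 1 - exp(-k_A * t).
    """
    t = np.asarray(t, dtype=float) if np.ndim(t) else float(t)
    if k_A < 0 or np.any(np.asarray(t) < 0):
        raise ValueError("k_A and t must be >= 0")
    return -np.expm1(-k_A * t) if np.ndim(t) else -math.expm1(-k_A * t)


def memory_fraction(
    k_C: float, t_since_first_hormone: float, nup98_depleted: bool = False
) -> float:
    """Fraction of loci converted to memory ``t`` minutes after hormone
    was first added.

    Conversion continues after hormone withdrawal (the defining feature
    of the memory state), so the clock runs from the first exposure.
    Under Nup98 depletion the memory state reverts as soon as hormone is
    withdrawn (k_-C >> k_C), so the retained fraction is 0.
    """
    if k_C < 0 or t_since_first_hormone < 0:
        raise ValueError("k_C and t must be >= 0")
    if nup98_depleted:
        return 0.0
    return -math.expm1(-k_C * t_since_first_hormone)


def effective_loading_rate(
    attempt_rate: float, footprint_nt: float, elongation: float
) -> float:
    """Successful Pol II loading rate under footprint exclusion.

    With deterministic elongation at v nt/min, a new polymerase can only
    load s/v minutes after the previous one, so successful loadings form
    a renewal process with mean gap s/v + 1/lambda and rate
    lambda / (1 + lambda*s/v), capped at v/s.
    """
    if attempt_rate < 0 or footprint_nt < 0 or elongation < 0:
        raise ValueError("arguments must be >= 0")
    if attempt_rate == 0:
        return 0.0
    if elongation == 0:
        return 0.0
    return attempt_rate / (1.0 + attempt_rate * footprint_nt / elongation)


def mean_production_rate(
    spec: PromoterModelSpec,
    params: KineticParams,
    t: float,
    f_M0: float = 0.0,
) -> float:
    """Mean mRNA production rate per locus at time ``t`` of a hormone-on
    segment.

    ``f_M0`` is the memory fraction carried over from earlier protocol
    segments (0 for a naive first induction; after recovery it is set by
    :func:`memory_fraction`).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if spec.variant == MODEL1:
        k_A = FAST_K_A if spec.activation_is_immediate else params.k_A
        return params.k_pol * active_fraction(k_A, t)
    if spec.variant == MODEL2:
        return effective_loading_rate(
            params.alpha * t, params.footprint_nt, params.elongation_nt_per_min
        )
    if spec.variant == MEMORY_SWITCH:
        k_A = FAST_K_A if spec.activation_is_immediate else params.k_A
        f_A = active_fraction(k_A, t)
        f_M = 1.0 - (1.0 - f_M0) * math.exp(-params.k_C * t)
        induced = f_M * params.k_polH + (1.0 - f_M) * params.k_polL
        return f_A * induced + (1.0 - f_A) * params.k_polB
    raise ValueError(f"unknown variant {spec.variant!r}")
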