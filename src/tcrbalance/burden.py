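"""Closed-form effector-target balance model for a heterozygous myeloid clone.

The model asks whether antigen-specific effector T cells can, in principle,
keep up with the transformed myeloid compartment implied by a peripheral-blood
variant allele fraction (VAF).  For a heterozygous driver mutation a VAF of
``v`` means a fraction ``2 v`` of myeloid cells carry the mutation, so the
target burden is ``2 (N + M) v`` where ``N`` and ``M`` are the body-wide
neutrophil and monocyte counts.  A fraction ``b`` of the total T-cell pool
``T`` is specific for the mutant antigen, each effector killing serially at a
constant per-kill time ``tau``.  Eradication requires the total killing time
to beat the self-renewal time of the transformed compartment, dominated by
the neutrophil lifetime (6.6 days):

    kills per effector   k = 2 (N + M) v / (b T)
    total kill time      t_total = tau * k
    eradication          t_total <= L_N
    maximal VAF          v_max = L_N * b * T / (2 * tau * (N + M))

This is deliberately static algebra: serial killing at constant ``tau``
against a fixed target pool, with regrowth entering only through the lifetime
criterion.  No ODE or agent-based dynamics are modelled.

Default parameter values are the Sender & Milo whole-body estimates
(N = 6e11, lifetime 6.6 d; M = 1e10, lifetime 3.5 d; T = 7e11).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import DomainError
from .units import parse_duration

__all__ = [
    "BalanceParams",
    "SweepGrid",
    "BFractionEstimate",
    "tumor_burden",
    "effector_pool",
    "kills_per_effector",
    "total_kill_time",
    "is_eradicable",
    "max_controllable_vaf",
    "display_vaf",
    "sweep",
    "estimate_b_from_elispot",
]

SWEEPABLE_FIELDS = ("vaf", "tau", "b")

SweepOutput = Literal["kills", "total_time", "max_vaf"]


class BalanceParams(BaseModel):
    """Constants and variables of the balance model.

    All cell counts are whole-body numbers; lifetimes and ``tau`` are in days.
    ``vaf`` is capped at 0.5: the mutation is heterozygous, so the mutant-cell
    fraction ``2 vaf`` must not exceed 1.
    """

    model_config = ConfigDict(frozen=True)

    N: float = Field(6e11, gt=0, description="neutrophil count (cells)")
    M: float = Field(1e10, gt=0, description="monocyte count (cells)")
    T: float = Field(7e11, gt=0, description="total T-cell count (cells)")
    neutrophil_lifetime: float = Field(6.6, gt=0, description="days")
    # Stored for completeness; the eradication criterion uses only the
    # neutrophil lifetime (the dominant self-renewal time).
    monocyte_lifetime: float = Field(3.5, gt=0, description="days")
    vaf: float = Field(0.40, ge=0, le=0.5, description="variant allele fraction")
    b: float = Field(1e-4, gt=0, le=1, description="specific fraction of T-cell pool")
    tau: float = Field(0.0625, gt=0, description="per-kill time (days)")

    @classmethod
    def with_tau(cls, tau: str | float, **kwargs) -> "BalanceParams":
        """Build params with ``tau`` given as e.g. ``"90 min"`` or ``"4 hours"``."""
        return cls(tau=parse_duration(tau), **kwargs)

    def replace(self, **kwargs) -> "BalanceParams":
        """Return a revalidated copy with the given fields replaced."""
        return BalanceParams(**{**self.model_dump(), **kwargs})


def tumor_burden(params: BalanceParams) -> float:
    """Number of transformed neutrophils + monocytes: ``2 (N + M) vaf``."""
    return 2.0 * (params.N + params.M) * params.vaf


def effector_pool(params: BalanceParams) -> float:
    """Number of antigen-specific T cells: ``b T``."""
    return params.b * params.T


def kills_per_effector(params: BalanceParams) -> float:
    """Kills each specific T cell must perform to clear the burden.

    Returned as a raw float; rounding for display is the caller's concern.
    """
    pool = effector_pool(params)
    if pool <= 0:
        raise DomainError("effector pool is empty (b = 0): kills per effector undefined")
    return tumor_burden(params) / pool


def total_kill_time(params: BalanceParams) -> float:
    """Days needed to clear the burden at ``tau`` days per serial kill."""
    return params.tau * kills_per_effector(params)


def is_eradicable(params: BalanceParams) -> bool:
    """True iff the total kill time beats the neutrophil self-renewal time."""
    return total_kill_time(params) <= params.neutrophil_lifetime


def max_controllable_vaf(params: BalanceParams) -> float:
    """Largest VAF the effectors can eradicate: ``L_N b T / (2 tau (N + M))``.

    The ``vaf`` field of ``params`` is ignored.  The result is *not* clamped:
    values above 0.5 mean any biologically possible VAF is controllable (use
    :func:`display_vaf` to clamp for presentation).
    """
    if params.tau <= 0:
        raise DomainError("tau must be positive to bound the controllable VAF")
    return (
        params.neutrophil_lifetime
        * params.b
        * params.T
        / (2.0 * params.tau * (params.N + params.M))
    )


def display_vaf(vaf: float) -> tuple[float, bool]:
    """Clamp a VAF to the heterozygous bound 0.5 for display.

    Returns ``(clamped_value, was_clamped)``.
    """
    if vaf > 0.5:
        return 0.5, True
    return vaf, False


_OUTPUT_FUNCS = {
    "kills": kills_per_effector,
    "total_time": total_kill_time,
    "max_vaf": max_controllable_vaf,
}


@dataclass
class SweepGrid:
    """A 2-D parameter sweep of one model output.

    ``cell_values[i, j]`` is the output with ``series_name = series_values[i]``
    and ``axis_name = axis_values[j]`` substituted into the base parameters.
    """

    output: str
    axis_name: str
    axis_values: list[float]
    series_name: str
    series_values: list[float]
    cell_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cell_values = np.asarray(self.cell_values, dtype=float)
        expected = (len(self.series_values), len(self.axis_values))
        if self.cell_values.shape != expected:
            raise DomainError(
                f"cell_values shape {self.cell_values.shape} != {expected}"
            )

    def to_frame(self):
        """Tidy long-format table: axis_value, series_value, output_value."""
        import pandas as pd

        rows = [
            (a, s, self.cell_values[i, j])
            for i, s in enumerate(self.series_values)
            for j, a in enumerate(self.axis_values)
        ]
        frame = pd.DataFrame(rows, columns=["axis_value", "series_value", "output_value"])
        frame.insert(0, "series", self.series_name)
        frame.insert(0, "axis", self.axis_name)
        frame.insert(0, "output", self.output)
        return frame


def sweep(
    params: BalanceParams,
    output: SweepOutput,
    axis_name: str,
    axis_values: Sequence[float],
    series_name: str,
    series_values: Sequence[float],
) -> SweepGrid:
    """Evaluate a model output over a grid of two swept parameters.

    Every cell equals the corresponding scalar call with the two values
    substituted; all other fields come from ``params``.
    """
    if output not in _OUTPUT_FUNCS:
        raise DomainError(f"unknown output {output!r}; choose from {sorted(_OUTPUT_FUNCS)}")
    for name in (axis_name, series_name):
        if name not in SWEEPABLE_FIELDS:
            raise DomainError(f"cannot sweep {name!r}; sweepable: {SWEEPABLE_FIELDS}")
    if axis_name == series_name:
        raise DomainError("axis and series must be distinct parameters")
    axis_values = [float(v) for v in axis_values]
    series_values = [float(v) for v in series_values]
    if not axis_values or not series_values:
        raise DomainError("axis_values and series_values must be non-empty")
    if any(b <= a for a, b in zip(axis_values, axis_values[1:])):
        raise DomainError("axis_values must be strictly increasing")

    func = _OUTPUT_FUNCS[output]
    grid = np.empty((len(series_values), len(axis_values)))
    for i, s in enumerate(series_values):
        for j, a in enumerate(axis_values):
            grid[i, j] = func(params.replace(**{series_name: s, axis_name: a}))
    return SweepGrid(
        output=output,
        axis_name=axis_name,
        axis_values=axis_values,
        series_name=series_name,
        series_values=series_values,
        cell_values=grid,
    )


@dataclass(frozen=True)
class BFractionEstimate:
    """Specific-T-cell fraction estimated from an ex vivo ELISPOT.

    ``order_of_magnitude`` is ``10 ** round(log10(raw))``, or ``None`` when
    the raw estimate is zero (the magnitude of zero is undefined and is
    signalled rather than silently reported as 0).
    """

    raw: float
    order_of_magnitude: float | None


def estimate_b_from_elispot(spots: float, assayed_cells: float) -> BFractionEstimate:
    """Estimate ``b`` as responding spots over assayed cells.

    E.g. 45 spot-forming cells among 6e5 assayed PBMC give a raw fraction of
    7.5e-5, i.e. a specific fraction of order 1e-4.
    """
    if assayed_cells <= 0:
        raise DomainError("assayed_cells must be positive")
    if spots < 0:
        raise DomainError("spots must be non-negative")
    if spots > assayed_cells:
        raise DomainError(
            f"spots ({spots}) cannot exceed assayed cells ({assayed_cells})"
        )
    raw = spots / assayed_cells
    if raw == 0:
        return BFractionEstimate(raw=0.0, order_of_magnitude=None)
    return BFractionEstimate(raw=raw, order_of_magnitude=10.0 ** round(math.log10(raw)))
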