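"""ELISPOT normalisation and distribution-free resampling (DFR) positivity calls.

An IFN-gamma ELISPOT plates replicate wells (typically triplicates) of
effector T cells with an antigen stimulus, without stimulus, and — when the
stimulus is itself a cell population — target cells alone.  The normalised
count subtracts the control means from the stimulated mean.  Positivity is
called with the distribution-free resampling test (DFR, after Moodie and
colleagues): a one-sided permutation test of

    H0:  stimulated counts <= multiplier * control counts

on the replicate wells, where multiplier 1 gives the ordinary DFR test and
multiplier 2 the conservative DFR2x variant (antigen wells must exceed twice
the control level).  Control counts are scaled by the multiplier, the scaled
wells are pooled with the stimulated wells, and the test statistic
mean(stimulated) - mean(scaled control) is recomputed over all relabellings.
For small replicate numbers the relabelling set is enumerated exhaustively
(deterministic); otherwise a seeded Monte-Carlo sample of relabellings is
used with an add-one p-value estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "ElispotAssay",
    "NormalizedCount",
    "PositivityCall",
    "normalized_count",
    "dfr_test",
    "read_wells_csv",
    "calls_to_frame",
]

#: Exhaustive enumeration is used when the number of relabellings is at most this.
MAX_EXHAUSTIVE = 1_000_000
DEFAULT_RESAMPLES = 10_000
DEFAULT_SEED = 20230817


@dataclass(frozen=True)
class ElispotAssay:
    """Replicate spot counts for one condition."""

    condition_label: str
    stimulated_counts: tuple[int, ...]
    unstimulated_counts: tuple[int, ...]
    target_alone_counts: tuple[int, ...] | None = None
    cells_per_well: int = 100_000

    def __post_init__(self) -> None:
        arms = {
            "stimulated_counts": self.stimulated_counts,
            "unstimulated_counts": self.unstimulated_counts,
        }
        if self.target_alone_counts is not None:
            arms["target_alone_counts"] = self.target_alone_counts
        for name, counts in arms.items():
            if len(counts) == 0:
                raise DomainError(f"{name} must be non-empty")
            if any(c < 0 for c in counts):
                raise DomainError(f"{name} contains a negative count")
        if self.cells_per_well <= 0:
            raise DomainError("cells_per_well must be positive")


@dataclass(frozen=True)
class NormalizedCount:
    """Background-subtracted spot count.

    ``raw`` keeps the signed value for audit; ``reported`` floors negatives
    to 0, matching standard ELISPOT reporting.
    """

    raw: float
    reported: float


def normalized_count(assay: ElispotAssay) -> NormalizedCount:
    """mean(stimulated) - mean(unstimulated) - mean(target alone, if present)."""
    raw = float(np.mean(assay.stimulated_counts)) - float(np.mean(assay.unstimulated_counts))
    if assay.target_alone_counts is not None:
        raw -= float(np.mean(assay.target_alone_counts))
    return NormalizedCount(raw=raw, reported=max(raw, 0.0))


@dataclass(frozen=True)
class PositivityCall:
    """Outcome of a DFR positivity test for one condition."""

    condition_label: str
    normalized_count: float
    raw_normalized_count: float
    p_value: float
    is_response: bool
    method: Literal["DFR", "DFR2x"]
    mode: Literal["exhaustive", "montecarlo"]


def _permutation_p(
    pooled: np.ndarray,
    n_stim: int,
    observed: float,
    mode: str,
    resamples: int,
    seed: int,
) -> tuple[float, str]:
    n = len(pooled)
    total = math.comb(n, n_stim)
    if mode == "auto":
        mode = "exhaustive" if total <= MAX_EXHAUSTIVE else "montecarlo"
    pooled_sum = pooled.sum()
    # small slack so relabellings tied with the observed statistic count as >=
    eps = 1e-9 * max(1.0, abs(observed))
    if mode == "exhaustive":
        hits = 0
        for idx in combinations(range(n), n_stim):
            stim_mean = pooled[list(idx)].sum() / n_stim
            ctrl_mean = (pooled_sum - stim_mean * n_stim) / (n - n_stim)
            if stim_mean - ctrl_mean >= observed - eps:
                hits += 1
        return hits / total, "exhaustive"
    if mode != "montecarlo":
        raise DomainError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(resamples):
        perm = rng.permutation(pooled)
        stat = perm[:n_stim].mean() - perm[n_stim:].mean()
        if stat >= observed - eps:
            hits += 1
    return (1 + hits) / (1 + resamples), "montecarlo"


def dfr_test(
    assay: ElispotAssay,
    multiplier: int = 2,
    alpha: float = 0.05,
    resamples: int = DEFAULT_RESAMPLES,
    seed: int = DEFAULT_SEED,
    mode: str = "auto",
    control: str = "unstimulated",
) -> PositivityCall:
    """One-sided DFR positivity test of stimulated vs ``multiplier`` x control.

    ``control`` selects the comparison arm (``"unstimulated"`` by default, or
    ``"target_alone"`` for cell-target assays).  ``mode`` forces
    ``"exhaustive"`` or ``"montecarlo"``; ``"auto"`` enumerates whenever the
    relabelling space is small enough (always, for triplicates).
    """
    if multiplier not in (1, 2):
        raise DomainError(f"multiplier must be 1 or 2, got {multiplier}")
    if not (0 < alpha < 1):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    stim = np.asarray(assay.stimulated_counts, dtype=float)
    if control == "unstimulated":
        ctrl = np.asarray(assay.unstimulated_counts, dtype=float)
    elif control == "target_alone":
        if assay.target_alone_counts is None:
            raise DomainError("assay has no target_alone wells")
        ctrl = np.asarray(assay.target_alone_counts, dtype=float)
    else:
        raise DomainError(f"unknown control arm {control!r}")
    if len(stim) < 2 or len(ctrl) < 2:
        raise DomainError("DFR needs at least 2 replicates in each arm")

    scaled_ctrl = multiplier * ctrl
    observed = stim.mean() - scaled_ctrl.mean()
    pooled = np.concatenate([stim, scaled_ctrl])
    p, used_mode = _permutation_p(pooled, len(stim), observed, mode, resamples, seed)

    norm = normalized_count(assay)
    return PositivityCall(
        condition_label=assay.condition_label,
        normalized_count=norm.reported,
        raw_normalized_count=norm.raw,
        p_value=p,
        is_response=bool(p <= alpha + 1e-12),
        method="DFR2x" if multiplier == 2 else "DFR",
        mode=used_mode,
    )


def read_wells_csv(path) -> list[ElispotAssay]:
    """Read well-level counts: columns condition, arm, count[, cells_per_well].

    ``arm`` is one of stimulated / unstimulated / target_alone.
    """
    table = pd.read_csv(path)
    for col in ("condition", "arm", "count"):
        if col not in table.columns:
            raise FormatError(f"wells CSV is missing required column {col!r}")
    assays = []
    for condition, group in table.groupby("condition", sort=True):
        arms = {
            arm: tuple(int(c) for c in sub["count"])
            for arm, sub in group.groupby("arm")
        }
        unknown = set(arms) - {"stimulated", "unstimulated", "target_alone"}
        if unknown:
            raise FormatError(f"unknown arm labels {sorted(unknown)} in condition {condition!r}")
        if "stimulated" not in arms or "unstimulated" not in arms:
            raise FormatError(
                f"condition {condition!r} needs both stimulated and unstimulated wells"
            )
        cells = (
            int(group["cells_per_well"].iloc[0])
            if "cells_per_well" in table.columns
            else 100_000
        )
        assays.append(
            ElispotAssay(
                condition_label=str(condition),
                stimulated_counts=arms["stimulated"],
                unstimulated_counts=arms["unstimulated"],
                target_alone_counts=arms.get("target_alone"),
                cells_per_well=cells,
            )
        )
    return assays


def calls_to_frame(calls: Sequence[PositivityCall]) -> pd.DataFrame:
    """Tidy table of positivity calls, one row per condition."""
    return pd.DataFrame(
        [
            {
                "condition": c.condition_label,
                "normalized_count": c.normalized_count,
                "raw_normalized_count": c.raw_normalized_count,
                "p_value": c.p_value,
                "method": c.method,
                "is_response": c.is_response,
            }
            for c in calls
        ]
    )
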