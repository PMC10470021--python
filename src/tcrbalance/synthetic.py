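"""Synthetic repertoire and assay generators with known ground truth.

The study conditions emulated here are those of a small vaccination cohort:

* bulk bone-marrow repertoires with thousands of clonotypes per chain and a
  heavy-tailed clone-size distribution, sequenced to ~1e6 reads;
* paired baseline / end-of-trial bulk samples whose key sets overlap heavily
  (the repertoire stays "relatively constant"), with rare antigen-specific
  clones spiked into the end-of-trial sample at frequencies of order 0.02%;
* near-monoclonal antigen-enriched cultures where a handful of dominant
  clones carry 69-99% of the reads over a low-frequency background;
* triplicate ELISPOT wells with Poisson counts (background rate, plus an
  effect rate in stimulated wells).

Everything is deterministic given a seed, and each generated sample carries
its ground truth in ``sample.metadata`` so recovery can be tested.

Clone-size laws: ``("power_law", a)`` uses deterministic rank weights
``r ** (-1/(a-1))`` so the rank-frequency slope on log-log axes is exactly
``-1/(a-1)`` (``a`` is the exponent of the clone-size distribution);
``("geometric", p)`` uses ``(1-p) ** (r-1)``.  Randomness enters only
through multinomial read sampling and CDR3 string generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .elispot import ElispotAssay
from .errors import DomainError
from .repertoire import DEFAULT_KEY, Clonotype, RepertoireSample

__all__ = [
    "CloneTemplate",
    "SpikeIn",
    "RepertoireScenario",
    "rank_weights",
    "random_cdr3",
    "make_templates",
    "generate_bulk_sample",
    "generate_paired_timepoints",
    "generate_culture_sample",
    "generate_elispot",
]

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Small fixed V/J catalogues: only identity-key behaviour matters here.
_V_CATALOGUE = {
    "alpha": ("TRAV1-2", "TRAV8-4", "TRAV12-1", "TRAV21", "TRAV29DV5"),
    "beta": ("TRBV2", "TRBV5-1", "TRBV7-9", "TRBV19", "TRBV28"),
}
_J_CATALOGUE = {
    "alpha": ("TRAJ33", "TRAJ42", "TRAJ49"),
    "beta": ("TRBJ1-1", "TRBJ2-1", "TRBJ2-7"),
}


@dataclass(frozen=True)
class CloneTemplate:
    """Identity of a clonotype before any reads are assigned."""

    cdr3_aa: str
    v_call: str | None = None
    j_call: str | None = None

    def to_clonotype(self, locus: str, read_count: int) -> Clonotype:
        return Clonotype(
            locus=locus,
            cdr3_aa=self.cdr3_aa,
            read_count=read_count,
            v_call=self.v_call,
            j_call=self.j_call,
        )


@dataclass(frozen=True)
class SpikeIn:
    """A clone injected at a fixed target frequency."""

    template: CloneTemplate
    frequency: float


@dataclass
class RepertoireScenario:
    """Parameters of one synthetic bulk repertoire.

    CDR3 lengths are uniform on 8-20 amino acids; V/J labels come from a
    small fixed catalogue.
    """

    n_clonotypes: int = 3000
    clone_size_law: tuple = ("power_law", 2.0)
    read_depth: int = 1_000_000
    spike_ins: tuple[SpikeIn, ...] = ()
    retention: float = 0.9
    seed: int = 0
    locus: str = "beta"
    patient_id: str = "P1"

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise DomainError("n_clonotypes must be >= 1")
        if self.read_depth < 1:
            raise DomainError("read_depth must be >= 1")
        if not (0 <= self.retention <= 1):
            raise DomainError("retention must be in [0, 1]")
        total = sum(s.frequency for s in self.spike_ins)
        if any(s.frequency <= 0 for s in self.spike_ins) or total >= 1:
            raise DomainError(
                f"spike frequencies must be positive and sum to < 1 (got {total})"
            )


def rank_weights(clone_size_law: tuple, n: int) -> np.ndarray:
    """Normalised clone weights for ranks 1..n under a size law."""
    name = clone_size_law[0]
    if name == "power_law":
        exponent = float(clone_size_law[1])
        if exponent <= 1:
            raise DomainError("power_law exponent must be > 1")
        slope = 1.0 / (exponent - 1.0)
        w = np.arange(1, n + 1, dtype=float) ** (-slope)
    elif name == "geometric":
        p = float(clone_size_law[1])
        if not (0 < p < 1):
            raise DomainError("geometric p must be in (0, 1)")
        w = (1.0 - p) ** np.arange(n, dtype=float)
    else:
        raise DomainError(f"unknown clone_size_law {name!r}")
    return w / w.sum()


def random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    return "".join(rng.choice(list(_AA_ALPHABET), size=length))


def make_templates(
    rng: np.random.Generator,
    n: int,
    locus: str,
    exclude: set[str] | None = None,
) -> list[CloneTemplate]:
    """``n`` unique clone templates, avoiding CDR3 strings in ``exclude``."""
    seen = set(exclude or ())
    templates: list[CloneTemplate] = []
    while len(templates) < n:
        cdr3 = random_cdr3(rng)
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        templates.append(
            CloneTemplate(
                cdr3_aa=cdr3,
                v_call=str(rng.choice(_V_CATALOGUE[locus])),
                j_call=str(rng.choice(_J_CATALOGUE[locus])),
            )
        )
    return templates


def _sample_from_probs(
    templates: Sequence[CloneTemplate],
    probs: np.ndarray,
    read_depth: int,
    rng: np.random.Generator,
    locus: str,
) -> list[Clonotype]:
    counts = rng.multinomial(read_depth, probs)
    return [
        t.to_clonotype(locus, int(c))
        for t, c in zip(templates, counts)
        if c >= 1
    ]


def generate_bulk_sample(
    scenario: RepertoireScenario,
    sample_kind: str = "end_of_trial_bm",
    rng: np.random.Generator | None = None,
    background: list[CloneTemplate] | None = None,
) -> RepertoireSample:
    """One bulk repertoire: multinomial reads over law weights plus spikes.

    Spike-ins occupy exactly their target probability mass; the background
    weights are scaled to the remainder.  Ground truth (spike frequencies,
    law, seed) lands in ``sample.metadata``.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    spike_total = sum(s.frequency for s in scenario.spike_ins)
    if background is None:
        exclude = {s.template.cdr3_aa for s in scenario.spike_ins}
        background = make_templates(rng, scenario.n_clonotypes, scenario.locus, exclude)
    bg_probs = rank_weights(scenario.clone_size_law, len(background)) * (1 - spike_total)
    templates = [s.template for s in scenario.spike_ins] + list(background)
    probs = np.concatenate([[s.frequency for s in scenario.spike_ins], bg_probs])
    clones = _sample_from_probs(templates, probs, scenario.read_depth, rng, scenario.locus)
    return RepertoireSample(
        patient_id=scenario.patient_id,
        sample_kind=sample_kind,
        locus=scenario.locus,
        clonotypes=clones,
        key_fields=DEFAULT_KEY,
        metadata={
            "generator": "bulk",
            "seed": scenario.seed,
            "clone_size_law": list(scenario.clone_size_law),
            "read_depth": scenario.read_depth,
            "spike_ins": {
                s.template.cdr3_aa: s.frequency for s in scenario.spike_ins
            },
        },
    )


def generate_paired_timepoints(
    scenario: RepertoireScenario,
) -> tuple[RepertoireSample, RepertoireSample]:
    """Paired baseline / end-of-trial bulk samples with partial key overlap.

    A ``retention`` fraction of the baseline clone templates is reused at
    end of trial (keeping their rank weights); the rest are replaced by novel
    templates at the vacated ranks, and reads are resampled.  Spike-ins from
    the scenario enter the end-of-trial sample only — the baseline contains
    none of them.
    """
    rng = np.random.default_rng(scenario.seed)
    spike_cdr3s = {s.template.cdr3_aa for s in scenario.spike_ins}
    pool = make_templates(rng, scenario.n_clonotypes, scenario.locus, spike_cdr3s)

    baseline_scenario = RepertoireScenario(
        **{**scenario.__dict__, "spike_ins": ()}
    )
    baseline = generate_bulk_sample(
        baseline_scenario, sample_kind="baseline_bm", rng=rng, background=pool
    )
    baseline.metadata["generator"] = "paired_baseline"

    n = scenario.n_clonotypes
    n_keep = int(round(scenario.retention * n))
    keep_idx = set(rng.choice(n, size=n_keep, replace=False).tolist())
    existing = {t.cdr3_aa for t in pool} | spike_cdr3s
    novel = iter(make_templates(rng, n - n_keep, scenario.locus, existing))
    end_pool = [t if i in keep_idx else next(novel) for i, t in enumerate(pool)]

    end = generate_bulk_sample(
        scenario, sample_kind="end_of_trial_bm", rng=rng, background=end_pool
    )
    end.metadata.update(
        generator="paired_end_of_trial",
        retention=scenario.retention,
        retained_cdr3s=sorted(pool[i].cdr3_aa for i in keep_idx),
    )
    return baseline, end


def generate_culture_sample(
    dominant_keys: Sequence[CloneTemplate],
    dominant_fraction: float,
    background_n: int,
    read_depth: int = 100_000,
    seed: int = 0,
    locus: str = "beta",
    patient_id: str = "P1",
) -> RepertoireSample:
    """Near-monoclonal antigen-enriched culture.

    The dominant templates share ``dominant_fraction`` of the reads equally;
    ``background_n`` low-frequency clones share the rest equally (each below
    1% whenever ``(1 - dominant_fraction) / background_n < 0.01``).
    """
    if not dominant_keys:
        raise DomainError("need at least one dominant clone")
    if not (0 < dominant_fraction <= 1):
        raise DomainError("dominant_fraction must be in (0, 1]")
    if dominant_fraction < 1 and background_n < 1:
        raise DomainError("background_n must be >= 1 when dominant_fraction < 1")
    rng = np.random.default_rng(seed)
    exclude = {t.cdr3_aa for t in dominant_keys}
    background = make_templates(rng, background_n if dominant_fraction < 1 else 0, locus, exclude)
    templates = list(dominant_keys) + background
    probs = np.concatenate(
        [
            np.full(len(dominant_keys), dominant_fraction / len(dominant_keys)),
            np.full(len(background), (1 - dominant_fraction) / max(len(background), 1)),
        ]
    )
    clones = _sample_from_probs(templates, probs, read_depth, rng, locus)
    return RepertoireSample(
        patient_id=patient_id,
        sample_kind="specific_culture",
        locus=locus,
        clonotypes=clones,
        key_fields=DEFAULT_KEY,
        metadata={
            "generator": "culture",
            "seed": seed,
            "dominant_fraction": dominant_fraction,
            "dominant_cdr3s": [t.cdr3_aa for t in dominant_keys],
        },
    )


def generate_elispot(
    rate_background: float,
    rate_effect: float,
    replicates: int = 3,
    seed: int = 0,
    cells_per_well: int = 100_000,
    condition_label: str = "synthetic",
    with_target_alone: bool = False,
) -> ElispotAssay:
    """Poisson-count assay: stimulated rate = background + effect."""
    if rate_background < 0 or rate_effect < 0:
        raise DomainError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    stim = tuple(int(c) for c in rng.poisson(rate_background + rate_effect, replicates))
    unstim = tuple(int(c) for c in rng.poisson(rate_background, replicates))
    targets = (
        tuple(int(c) for c in rng.poisson(rate_background, replicates))
        if with_target_alone
        else None
    )
    return ElispotAssay(
        condition_label=condition_label,
        stimulated_counts=stim,
        unstimulated_counts=unstim,
        target_alone_counts=targets,
        cells_per_well=cells_per_well,
    )
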