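"""Clonotype tables: ingestion, filtering, tracking and specific-fraction summaries.

Bulk TCR sequencing of a T-cell compartment yields, per chain (alpha or
beta), a table of clonotypes with read counts.  An antigen-enriched culture
sequenced the same way acts as a fingerprint: its high-frequency clonotypes
(>= 1% of the culture by default) are taken to be antigen-specific, and can
be tracked into bulk samples from other timepoints to quantify what fraction
of the bulk repertoire the specific clones occupy.

Filtering rules applied here:

* clonotypes with fewer than 2 reads are discarded (sequencing noise);
* culture clonotypes below 1% frequency are discarded as non-specific
  carry-over (e.g. feeder-cell background).

Clonotype identity is a configurable key over (locus, CDR3, V/J calls);
coarser keys merge rows by summing read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptySampleError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Clonotype",
    "RepertoireSample",
    "TrackingResult",
    "SpecificFractionReport",
    "DEFAULT_KEY",
    "clonotype_key",
    "read_sample",
    "filter_min_reads",
    "specific_clonotype_set",
    "count_clonotypes",
    "top_n_clonotypes",
    "track_clonotypes",
    "specific_fraction_report",
    "format_percent",
]

LOCI = ("alpha", "beta")
SAMPLE_KINDS = ("baseline_bm", "end_of_trial_bm", "specific_culture")

#: Identity-key recipes: tuples of Clonotype field names.
DEFAULT_KEY: tuple[str, ...] = ("locus", "cdr3_aa", "v_call")
KEY_RECIPES = {
    "aa": ("locus", "cdr3_aa"),
    "aa_v": ("locus", "cdr3_aa", "v_call"),
    "nt_vj": ("locus", "cdr3_nt", "v_call", "j_call"),
}

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_LOCUS_ALIASES = {
    "alpha": "alpha",
    "tra": "alpha",
    "a": "alpha",
    "beta": "beta",
    "trb": "beta",
    "b": "beta",
}


def normalize_locus(value: str) -> str:
    try:
        return _LOCUS_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise DomainError(f"unknown locus {value!r}; expected one of {LOCI}") from None


@dataclass(frozen=True)
class Clonotype:
    """One TCR chain rearrangement with its read count."""

    locus: str
    cdr3_aa: str
    read_count: int
    cdr3_nt: str | None = None
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise DomainError(f"locus must be one of {LOCI}, got {self.locus!r}")
        if not self.cdr3_aa:
            raise DomainError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - _AA
        if bad:
            raise DomainError(
                f"cdr3_aa {self.cdr3_aa!r} contains invalid characters {sorted(bad)}"
            )
        if self.read_count < 1:
            raise DomainError(f"read_count must be >= 1, got {self.read_count}")


def clonotype_key(clone: Clonotype, key_fields: Sequence[str] = DEFAULT_KEY) -> tuple:
    """Identity key of a clonotype under a key recipe."""
    return tuple(getattr(clone, f) for f in key_fields)


@dataclass
class RepertoireSample:
    """Clonotypes of one (patient, sample, chain).

    Duplicate identity keys are merged on construction by summing read
    counts.  ``freq_denominator`` overrides the denominator used for
    frequencies; it defaults to the sample's own total reads and is used to
    preserve pre-filter denominators when a filter opts out of
    renormalisation.
    """

    patient_id: str
    sample_kind: str
    locus: str
    clonotypes: list[Clonotype]
    key_fields: tuple[str, ...] = DEFAULT_KEY
    freq_denominator: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS:
            raise DomainError(
                f"sample_kind must be one of {SAMPLE_KINDS}, got {self.sample_kind!r}"
            )
        self.locus = normalize_locus(self.locus)
        merged: dict[tuple, Clonotype] = {}
        for clone in self.clonotypes:
            if clone.locus != self.locus:
                raise DomainError(
                    f"clonotype locus {clone.locus!r} does not match sample locus"
                )
            key = clonotype_key(clone, self.key_fields)
            if key in merged:
                kept = merged[key]
                merged[key] = replace(kept, read_count=kept.read_count + clone.read_count)
            else:
                merged[key] = clone
        if not merged:
            raise EmptySampleError(
                f"sample ({self.patient_id}, {self.sample_kind}, {self.locus}) "
                "has no clonotypes"
            )
        self.clonotypes = list(merged.values())

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clonotypes)

    @property
    def frequencies(self) -> dict[tuple, float]:
        denom = self.freq_denominator or self.total_reads
        return {
            clonotype_key(c, self.key_fields): c.read_count / denom
            for c in self.clonotypes
        }

    def frequency_of(self, key: tuple) -> float:
        """Frequency of an identity key; exactly 0 if absent (no pseudocounts)."""
        return self.frequencies.get(key, 0.0)

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        rows = [
            {
                "locus": c.locus,
                "cdr3_aa": c.cdr3_aa,
                "cdr3_nt": c.cdr3_nt,
                "v_call": c.v_call,
                "j_call": c.j_call,
                "read_count": c.read_count,
                "frequency": freqs[clonotype_key(c, self.key_fields)],
            }
            for c in sorted(
                self.clonotypes, key=lambda c: (-c.read_count, c.cdr3_aa)
            )
        ]
        return pd.DataFrame(rows)


_AIRR_LOCUS_NAMES = {"TRA": "alpha", "TRB": "beta"}


def _clean_count(value) -> int | None:
    try:
        count = int(value)
    except (TypeError, ValueError):
        return None
    return count if count >= 1 else None


def read_sample(
    path,
    dialect: str,
    patient_id: str,
    sample_kind: str,
    locus: str,
    key_fields: Sequence[str] = DEFAULT_KEY,
) -> RepertoireSample:
    """Read one chain's clonotype table from a TSV file.

    ``dialect="airr"`` expects AIRR Rearrangement columns (``junction_aa``,
    ``duplicate_count`` and ``locus``, or a ``v_call`` whose TRA/TRB prefix
    determines the chain).  ``dialect="minimal_tsv"`` expects ``cdr3_aa`` and
    ``reads`` with optional ``v_call``/``j_call``/``cdr3_nt``.  Rows of the
    other chain are ignored (with a logged count); duplicate keys merge.
    """
    locus = normalize_locus(locus)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "airr":
        required = ["junction_aa", "duplicate_count"]
        aa_col, count_col = "junction_aa", "duplicate_count"
        nt_col = "junction"
    elif dialect == "minimal_tsv":
        required = ["cdr3_aa", "reads"]
        aa_col, count_col = "cdr3_aa", "reads"
        nt_col = "cdr3_nt"
    else:
        raise FormatError(f"unknown dialect {dialect!r}; use 'airr' or 'minimal_tsv'")
    for col in required:
        if col not in table.columns:
            raise FormatError(f"{dialect} table is missing required column {col!r}")
    if dialect == "airr" and "locus" not in table.columns and "v_call" not in table.columns:
        raise FormatError("airr table needs a 'locus' or 'v_call' column to determine the chain")

    clones: list[Clonotype] = []
    skipped_locus = 0
    skipped_bad = 0
    for _, row in table.iterrows():
        if dialect == "airr":
            if "locus" in table.columns and pd.notna(row["locus"]):
                row_locus = _AIRR_LOCUS_NAMES.get(str(row["locus"]).upper())
            else:
                v = str(row.get("v_call", "") or "")
                row_locus = _AIRR_LOCUS_NAMES.get(v[:3].upper())
        else:
            row_locus = locus
        if row_locus is None:
            skipped_bad += 1
            continue
        if row_locus != locus:
            skipped_locus += 1
            continue
        count = _clean_count(row[count_col])
        aa = row[aa_col]
        if count is None or pd.isna(aa) or not str(aa):
            skipped_bad += 1
            continue
        clones.append(
            Clonotype(
                locus=locus,
                cdr3_aa=str(aa),
                read_count=count,
                cdr3_nt=(str(row[nt_col]) if nt_col in table.columns and pd.notna(row.get(nt_col)) else None),
                v_call=(str(row["v_call"]) if "v_call" in table.columns and pd.notna(row.get("v_call")) else None),
                j_call=(str(row["j_call"]) if "j_call" in table.columns and pd.notna(row.get("j_call")) else None),
            )
        )
    if skipped_locus:
        logger.info("read_sample(%s): ignored %d rows of the other chain", path, skipped_locus)
    if skipped_bad:
        logger.info("read_sample(%s): skipped %d unusable rows", path, skipped_bad)
    if not clones:
        raise EmptySampleError(f"no usable {locus}-chain rows in {path}")
    return RepertoireSample(
        patient_id=patient_id,
        sample_kind=sample_kind,
        locus=locus,
        clonotypes=clones,
        key_fields=tuple(key_fields),
    )


def write_sample(sample: RepertoireSample, path) -> None:
    """Write a post-filter clonotype table as tidy TSV."""
    sample.to_frame().to_csv(path, sep="\t", index=False)


_LOCUS_TO_AIRR = {"alpha": "TRA", "beta": "TRB"}


def write_airr(sample: RepertoireSample, path) -> None:
    """Write a sample as an AIRR Rearrangement TSV (one row per clonotype)."""
    rows = [
        {
            "locus": _LOCUS_TO_AIRR[sample.locus],
            "junction_aa": c.cdr3_aa,
            "junction": c.cdr3_nt,
            "v_call": c.v_call,
            "j_call": c.j_call,
            "duplicate_count": c.read_count,
        }
        for c in sorted(sample.clonotypes, key=lambda c: (-c.read_count, c.cdr3_aa))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_min_reads(
    sample: RepertoireSample, min_reads: int = 2, renormalize: bool = True
) -> RepertoireSample:
    """Drop clonotypes with fewer than ``min_reads`` reads.

    With ``renormalize=True`` (default) frequencies are recomputed over the
    survivors so they again sum to 1; with ``renormalize=False`` the
    pre-filter denominator is preserved.
    """
    if min_reads < 1:
        raise DomainError(f"min_reads must be >= 1, got {min_reads}")
    survivors = [c for c in sample.clonotypes if c.read_count >= min_reads]
    removed = len(sample.clonotypes) - len(survivors)
    if not survivors:
        raise EmptySampleError(
            f"filter_min_reads(min_reads={min_reads}) removed all "
            f"{len(sample.clonotypes)} clonotypes"
        )
    if removed:
        logger.info(
            "filter_min_reads(%s/%s/%s): removed %d of %d clonotypes below %d reads",
            sample.patient_id, sample.sample_kind, sample.locus,
            removed, len(sample.clonotypes), min_reads,
        )
    denom = None if renormalize else (sample.freq_denominator or sample.total_reads)
    return RepertoireSample(
        patient_id=sample.patient_id,
        sample_kind=sample.sample_kind,
        locus=sample.locus,
        clonotypes=survivors,
        key_fields=sample.key_fields,
        freq_denominator=denom,
        metadata=dict(sample.metadata),
    )


def specific_clonotype_set(
    culture_sample: RepertoireSample, min_fraction: float = 0.01
) -> set[tuple]:
    """Identity keys of culture clonotypes at or above ``min_fraction``.

    Clonotypes strictly below the threshold are discarded as redundant
    non-specific carry-over; a frequency of exactly ``min_fraction`` is kept.
    """
    if culture_sample.sample_kind != "specific_culture":
        raise DomainError(
            "specific_clonotype_set expects a specific_culture sample, got "
            f"{culture_sample.sample_kind!r}"
        )
    if not (0 < min_fraction < 1):
        raise DomainError(f"min_fraction must be in (0, 1), got {min_fraction}")
    keys = {k for k, f in culture_sample.frequencies.items() if f >= min_fraction}
    if not keys:
        logger.warning(
            "specific_clonotype_set: no culture clonotype reaches %.3f%%",
            100 * min_fraction,
        )
    return keys


def count_clonotypes(sample: RepertoireSample) -> int:
    """Number of unique identity keys in the sample."""
    return len(sample.clonotypes)


def top_n_clonotypes(sample: RepertoireSample, n: int = 100) -> list[tuple]:
    """Keys of the ``n`` most frequent clonotypes (all, if fewer exist).

    Ties break deterministically by (read_count desc, cdr3_aa lexicographic).
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    ordered = sorted(sample.clonotypes, key=lambda c: (-c.read_count, c.cdr3_aa))
    return [clonotype_key(c, sample.key_fields) for c in ordered[:n]]


@dataclass
class TrackingResult:
    """Per-clonotype frequency trajectories across an ordered sample list."""

    key_definition: tuple[str, ...]
    clonotype_keys: list[tuple]
    sample_order: list[str]
    frequency_matrix: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            ("|".join(str(p) for p in key), label, self.frequency_matrix[i, j])
            for i, key in enumerate(self.clonotype_keys)
            for j, label in enumerate(self.sample_order)
        ]
        return pd.DataFrame(rows, columns=["clonotype", "sample", "frequency"])


def track_clonotypes(
    keys: Iterable[tuple],
    samples: Sequence[RepertoireSample],
    labels: Sequence[str] | None = None,
) -> TrackingResult:
    """Frequencies of each key in each sample (0 where absent).

    All samples must share patient and locus; the key recipe is taken from
    the first sample and recorded in the result.
    """
    keys = list(keys)
    if not keys:
        raise DomainError("track_clonotypes requires a non-empty key list")
    if not samples:
        raise DomainError("track_clonotypes requires at least one sample")
    loci = {s.locus for s in samples}
    if len(loci) > 1:
        raise DomainError(f"samples mix loci {sorted(loci)}; track one chain at a time")
    patients = {s.patient_id for s in samples}
    if len(patients) > 1:
        raise DomainError(f"samples mix patients {sorted(patients)}")
    recipes = {s.key_fields for s in samples}
    if len(recipes) > 1:
        raise DomainError("samples use different identity-key recipes")
    if labels is None:
        labels = [s.sample_kind for s in samples]
    matrix = np.zeros((len(keys), len(samples)))
    for j, sample in enumerate(samples):
        freqs = sample.frequencies
        for i, key in enumerate(keys):
            matrix[i, j] = freqs.get(key, 0.0)
    n_zero_rows = int((matrix.sum(axis=1) == 0).sum())
    if n_zero_rows:
        logger.warning(
            "track_clonotypes: %d of %d keys absent from every sample",
            n_zero_rows, len(keys),
        )
    return TrackingResult(
        key_definition=samples[0].key_fields,
        clonotype_keys=keys,
        sample_order=list(labels),
        frequency_matrix=matrix,
    )


@dataclass
class SpecificFractionReport:
    """Per-(patient, chain) summary of where the specific clonotypes sit.

    Fractions are summed frequencies of the specific keys in each sample;
    absent keys contribute exactly 0.
    """

    patient_id: str
    locus: str
    n_specific_clonotypes: int
    fraction_in_baseline: float
    fraction_in_end_of_trial: float
    fraction_in_specific_sample: float

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "locus": self.locus,
            "n_specific_clonotypes": self.n_specific_clonotypes,
            "fraction_baseline": format_percent(self.fraction_in_baseline),
            "fraction_end_of_trial": format_percent(self.fraction_in_end_of_trial),
            "fraction_specific_sample": format_percent(self.fraction_in_specific_sample),
        }


def format_percent(fraction: float) -> str:
    """Percentage with 3 decimals and a dot decimal separator, e.g. '0.022%'."""
    return f"{100.0 * fraction:.3f}%"


def specific_fraction_report(
    specific_keys: Iterable[tuple],
    baseline: RepertoireSample,
    end_of_trial: RepertoireSample,
    culture: RepertoireSample,
) -> SpecificFractionReport:
    """Summed frequency of the specific clonotypes in each of three samples."""
    samples = (baseline, end_of_trial, culture)
    patients = {s.patient_id for s in samples}
    loci = {s.locus for s in samples}
    if len(patients) > 1 or len(loci) > 1:
        raise DomainError("the three samples must share patient and locus")
    specific_keys = set(specific_keys)

    def mass(sample: RepertoireSample) -> float:
        freqs = sample.frequencies
        return float(sum(freqs.get(k, 0.0) for k in specific_keys))

    return SpecificFractionReport(
        patient_id=baseline.patient_id,
        locus=baseline.locus,
        n_specific_clonotypes=len(specific_keys),
        fraction_in_baseline=mass(baseline),
        fraction_in_end_of_trial=mass(end_of_trial),
        fraction_in_specific_sample=mass(culture),
    )
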