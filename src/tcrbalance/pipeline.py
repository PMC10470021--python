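"""End-to-end analysis run: repertoires -> filters -> tracking -> reports.

One call to :func:`run_pipeline` produces an immutable run directory with

* post-filter clonotype tables per (patient, chain, sample),
* a cohort specific-fraction report (one row per patient and chain),
* tracking matrices for the top-100 end-of-trial clonotypes and for the
  culture-defined specific clonotypes,
* balance-model sweep CSVs (kills, total kill time, maximal controllable VAF),
* ELISPOT positivity calls,
* a machine-readable ``manifest.json`` (seed, key recipe, thresholds,
  package version, ground truth for simulated cohorts).

Re-running with the same configuration and seed reproduces every CSV byte
for byte; no file content depends on wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import sweep
from .config import RunConfig
from .elispot import calls_to_frame, dfr_test, read_wells_csv
from .errors import ConfigError
from .repertoire import (
    RepertoireSample,
    count_clonotypes,
    filter_min_reads,
    read_sample,
    specific_clonotype_set,
    specific_fraction_report,
    top_n_clonotypes,
    track_clonotypes,
    write_sample,
)
from .synthetic import (
    RepertoireScenario,
    SpikeIn,
    generate_culture_sample,
    generate_elispot,
    generate_paired_timepoints,
    make_templates,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_cohort"]

_KINDS = ("baseline_bm", "end_of_trial_bm", "specific_culture")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:10]


def _chain_seed(base_seed: int, patient_idx: int, locus: str) -> int:
    # distinct, reproducible sub-seed per (patient, chain), kept below 2**31
    offset = patient_idx * 10 + (0 if locus == "alpha" else 1)
    return (base_seed * 1009 + offset) % (2**31)


def simulate_cohort(config: RunConfig) -> tuple[dict, dict]:
    """Generate the synthetic cohort described by ``config.scenario``.

    Returns ``(samples, truth)`` where ``samples[(patient_id, locus)]`` maps
    sample kinds to :class:`RepertoireSample` and ``truth`` records the
    generator's ground truth per (patient, chain).
    """
    sc = config.scenario
    if sc is None:
        raise ConfigError("simulate_cohort needs a scenario in the config")
    samples: dict[tuple[str, str], dict[str, RepertoireSample]] = {}
    truth: dict[str, dict] = {}
    for p in range(sc.n_patients):
        patient_id = f"SIM{p + 1}"
        for locus in sc.loci:
            seed = _chain_seed(config.seed, p, locus)
            rng = np.random.default_rng(seed)
            dominant = make_templates(rng, sc.n_dominant, locus)
            culture = generate_culture_sample(
                dominant,
                dominant_fraction=sc.dominant_fraction,
                background_n=sc.culture_background_n,
                read_depth=sc.culture_read_depth,
                seed=seed + 1,
                locus=locus,
                patient_id=patient_id,
            )
            spiked = p != sc.unspiked_patient and sc.n_spiked > 0
            spikes = ()
            if spiked:
                per_clone = sc.spike_total_frequency / sc.n_spiked
                spikes = tuple(
                    SpikeIn(template=t, frequency=per_clone)
                    for t in dominant[: sc.n_spiked]
                )
            scenario = RepertoireScenario(
                n_clonotypes=sc.n_clonotypes,
                clone_size_law=("power_law", sc.clone_size_exponent),
                read_depth=sc.read_depth,
                spike_ins=spikes,
                retention=sc.retention,
                seed=seed + 2,
                locus=locus,
                patient_id=patient_id,
            )
            baseline, end = generate_paired_timepoints(scenario)
            samples[(patient_id, locus)] = {
                "baseline_bm": baseline,
                "end_of_trial_bm": end,
                "specific_culture": culture,
            }
            truth[f"{patient_id}:{locus}"] = {
                "seed": seed,
                "spike_total_frequency": (sc.spike_total_frequency if spiked else 0.0),
                "spiked_cdr3s": [s.template.cdr3_aa for s in spikes],
                "dominant_cdr3s": [t.cdr3_aa for t in dominant],
                "retention": sc.retention,
            }
    return samples, truth


def _load_cohort(config: RunConfig) -> dict:
    samples: dict[tuple[str, str], dict[str, RepertoireSample]] = {}
    for inp in config.inputs:
        per_kind = {}
        for kind, path in inp.paths().items():
            per_kind[kind] = read_sample(
                path,
                dialect=inp.dialect,
                patient_id=inp.patient_id,
                sample_kind=kind,
                locus=inp.locus,
                key_fields=config.key_fields(),
            )
        samples[(inp.patient_id, inp.locus)] = per_kind
    return samples


def _write_balance_outputs(config: RunConfig, outdir: Path) -> dict:
    bal = config.balance
    base = bal.base_params()
    tau_days = bal.tau_days()
    vaf_axis = bal.vaf_axis
    frames = []
    # kills per effector as a function of VAF, one series per b, per tau grid
    kills = sweep(base, "kills", "vaf", vaf_axis, "b", bal.b_series)
    kills.to_frame().to_csv(outdir / "balance_kills.csv", index=False)
    for label, tau in zip(bal.tau_values, tau_days):
        grid = sweep(base.replace(tau=tau), "total_time", "vaf", vaf_axis, "b", bal.b_series)
        frame = grid.to_frame()
        frame.insert(0, "tau", label)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "balance_total_time.csv", index=False
    )
    maxvaf = sweep(base, "max_vaf", "tau", sorted(tau_days), "b", bal.b_series)
    maxvaf.to_frame().to_csv(outdir / "balance_max_vaf.csv", index=False)
    return {
        "params": base.model_dump(),
        "b_series": bal.b_series,
        "tau_values": bal.tau_values,
    }


def _run_elispot(config: RunConfig, outdir: Path) -> None:
    es = config.elispot
    if es.wells_csv:
        assays = read_wells_csv(es.wells_csv)
    else:
        assays = [
            generate_elispot(
                sim.rate_background,
                sim.rate_effect,
                seed=(config.seed * 97 + i) % (2**31),
                condition_label=sim.label,
            )
            for i, sim in enumerate(es.simulated)
        ]
    calls = [
        dfr_test(a, multiplier=es.multiplier, alpha=es.alpha, resamples=es.resamples)
        for a in assays
    ]
    calls_to_frame(calls).to_csv(outdir / "elispot_calls.csv", index=False)


def run_pipeline(config: RunConfig, run_name: str | None = None) -> Path:
    """Execute the full analysis and return the run directory."""
    if run_name is None:
        stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%S")
        run_name = f"run-{stamp}-{_config_hash(config)}"
    outdir = Path(config.output_dir) / run_name
    if outdir.exists():
        raise ConfigError(f"run directory {outdir} already exists; runs are immutable")
    outdir.mkdir(parents=True)

    truth: dict = {}
    if config.scenario is not None:
        samples, truth = simulate_cohort(config)
    else:
        samples = _load_cohort(config)

    filters = config.filters
    report_rows = []
    stage = "setup"
    try:
        for (patient_id, locus), per_kind in sorted(samples.items()):
            stage = f"filter ({patient_id}, {locus})"
            filtered = {
                kind: filter_min_reads(
                    per_kind[kind], filters.min_reads, renormalize=filters.renormalize
                )
                for kind in _KINDS
            }
            for kind, sample in filtered.items():
                write_sample(sample, outdir / f"clonotypes_{patient_id}_{locus}_{kind}.tsv")

            stage = f"specific set ({patient_id}, {locus})"
            specific = specific_clonotype_set(
                filtered["specific_culture"], filters.min_fraction
            )

            stage = f"tracking ({patient_id}, {locus})"
            ordered = [
                filtered["baseline_bm"],
                filtered["end_of_trial_bm"],
                filtered["specific_culture"],
            ]
            top = top_n_clonotypes(filtered["end_of_trial_bm"], filters.top_n)
            track_clonotypes(top, ordered[:2]).to_long_frame().to_csv(
                outdir / f"tracking_top{filters.top_n}_{patient_id}_{locus}.tsv",
                sep="\t",
                index=False,
            )
            if specific:
                track_clonotypes(sorted(specific), ordered).to_long_frame().to_csv(
                    outdir / f"tracking_specific_{patient_id}_{locus}.tsv",
                    sep="\t",
                    index=False,
                )

            stage = f"report ({patient_id}, {locus})"
            report = specific_fraction_report(
                specific,
                filtered["baseline_bm"],
                filtered["end_of_trial_bm"],
                filtered["specific_culture"],
            )
            row = report.to_row()
            row.update(
                n_clonotypes_baseline=count_clonotypes(filtered["baseline_bm"]),
                n_clonotypes_end_of_trial=count_clonotypes(filtered["end_of_trial_bm"]),
                n_clonotypes_culture=count_clonotypes(filtered["specific_culture"]),
            )
            report_rows.append(row)

        stage = "specific-fraction report"
        pd.DataFrame(report_rows).to_csv(
            outdir / "specific_fraction_report.tsv", sep="\t", index=False
        )

        stage = "balance model"
        balance_info = _write_balance_outputs(config, outdir)

        stage = "elispot"
        _run_elispot(config, outdir)
    except Exception:
        (outdir / "INCOMPLETE").write_text(f"failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    manifest = {
        "package": "tcrbalance",
        "version": __version__,
        "seed": config.seed,
        "key_recipe": list(config.key_fields()),
        "filters": filters.model_dump(),
        "balance": balance_info,
        "elispot": {
            k: v for k, v in config.elispot.model_dump().items() if k != "simulated"
        },
        "ground_truth": truth,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline run complete: %s", outdir)
    return outdir
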