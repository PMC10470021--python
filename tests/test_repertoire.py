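"""Clonotype ingestion, filtering, tracking and specific-fraction summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcrbalance.errors import DomainError, EmptySampleError, FormatError
from tcrbalance.repertoire import (
    DEFAULT_KEY,
    Clonotype,
    RepertoireSample,
    clonotype_key,
    count_clonotypes,
    filter_min_reads,
    format_percent,
    read_sample,
    specific_clonotype_set,
    specific_fraction_report,
    top_n_clonotypes,
    track_clonotypes,
    write_airr,
)

from conftest import make_sample


# ---------------------------------------------------------------- ingestion

def test_minimal_tsv_merges_duplicate_keys(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("cdr3_aa\treads\nCASSLGF\t5\nCASSLGF\t3\nCASRRAF\t2\n")
    sample = read_sample(path, "minimal_tsv", "P1", "baseline_bm", "beta")
    counts = {c.cdr3_aa: c.read_count for c in sample.clonotypes}
    assert counts == {"CASSLGF": 8, "CASRRAF": 2}


def test_airr_reads_only_requested_locus(tmp_path):
    rows = ["locus\tjunction_aa\tv_call\tduplicate_count"]
    rows += [f"TRA\tCA{a}SF\tTRAV1-2\t{n + 2}" for n, a in enumerate("ACDEFGHIKL")]
    rows += [f"TRB\tCW{a}SF\tTRBV2\t{n + 2}" for n, a in enumerate("ACDEFGHIKL")]
    path = tmp_path / "airr.tsv"
    path.write_text("\n".join(rows) + "\n")
    alpha = read_sample(path, "airr", "P1", "baseline_bm", "alpha")
    assert count_clonotypes(alpha) == 10
    assert all(c.locus == "alpha" for c in alpha.clonotypes)


def test_airr_locus_from_v_call_prefix(tmp_path):
    path = tmp_path / "airr.tsv"
    path.write_text(
        "junction_aa\tv_call\tduplicate_count\nCASSLGF\tTRBV2\t4\nCAVSGF\tTRAV1-2\t3\n"
    )
    beta = read_sample(path, "airr", "P1", "baseline_bm", "beta")
    assert [c.cdr3_aa for c in beta.clonotypes] == ["CASSLGF"]


def test_header_only_file_is_empty_sample_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("cdr3_aa\treads\n")
    with pytest.raises(EmptySampleError):
        read_sample(path, "minimal_tsv", "P1", "baseline_bm", "beta")


def test_missing_column_names_the_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("cdr3_aa\nCASSLGF\n")
    with pytest.raises(FormatError, match="reads"):
        read_sample(path, "minimal_tsv", "P1", "baseline_bm", "beta")


def test_airr_round_trip(tmp_path):
    sample = make_sample([9, 4, 2])
    path = tmp_path / "out.tsv"
    write_airr(sample, path)
    back = read_sample(path, "airr", "P1", "end_of_trial_bm", "beta")
    assert back.frequencies == sample.frequencies


def test_clonotype_validation():
    with pytest.raises(DomainError):
        Clonotype(locus="beta", cdr3_aa="CASS*F", read_count=2)
    with pytest.raises(DomainError):
        Clonotype(locus="beta", cdr3_aa="CASSF", read_count=0)
    with pytest.raises(DomainError):
        Clonotype(locus="gamma", cdr3_aa="CASSF", read_count=2)


# ---------------------------------------------------------------- filtering

def test_min_reads_filter_recomputes_frequencies(toy_sample):
    filtered = filter_min_reads(toy_sample, 2)
    freqs = sorted(filtered.frequencies.values())
    assert freqs == pytest.approx([3 / 8, 5 / 8])


def test_min_reads_boundary_read_count_two_retained():
    sample = make_sample([2, 1])
    filtered = filter_min_reads(sample, 2)
    assert [c.read_count for c in filtered.clonotypes] == [2]


def test_min_reads_one_is_identity(toy_sample):
    assert filter_min_reads(toy_sample, 1).frequencies == toy_sample.frequencies


def test_all_removed_raises():
    with pytest.raises(EmptySampleError):
        filter_min_reads(make_sample([1, 1, 1]), 2)


def test_preserved_denominator_mode(toy_sample):
    kept = filter_min_reads(toy_sample, 2, renormalize=False)
    assert sorted(kept.frequencies.values()) == pytest.approx([3 / 9, 5 / 9])
    assert sum(kept.frequencies.values()) < 1


def test_filter_idempotent(toy_sample):
    once = filter_min_reads(toy_sample, 2)
    twice = filter_min_reads(once, 2)
    assert twice.frequencies == once.frequencies


# ------------------------------------------------------- specific clonotypes

def test_specific_set_threshold():
    culture = make_sample([950, 30, 5], kind="specific_culture")  # 0.95/0.03/0.005
    keys = specific_clonotype_set(culture, 0.01)
    assert len(keys) == 2


def test_specific_set_boundary_exactly_one_percent_retained():
    culture = make_sample([99, 1], kind="specific_culture")
    assert len(specific_clonotype_set(culture, 0.01)) == 2


def test_specific_set_may_be_empty():
    culture = make_sample([1] * 200, kind="specific_culture")
    assert specific_clonotype_set(culture, 0.01) == set()


def test_specific_set_requires_culture(toy_sample):
    with pytest.raises(DomainError):
        specific_clonotype_set(toy_sample)


# ------------------------------------------------------------------ summaries

def test_count_clonotypes_merges_before_counting():
    clones = [
        Clonotype(locus="beta", cdr3_aa="CASSLGF", read_count=1) for _ in range(5)
    ] + [Clonotype(locus="beta", cdr3_aa="CASRRAF", read_count=1)]
    sample = RepertoireSample("P1", "baseline_bm", "beta", clones)
    assert count_clonotypes(sample) == 2


def test_top_n_returns_all_when_fewer(toy_sample):
    assert len(top_n_clonotypes(toy_sample, 100)) == 3


def test_top_n_tie_break_lexicographic():
    sample = make_sample([5, 5, 5])
    keys = top_n_clonotypes(sample, 3)
    assert [k[1] for k in keys] == sorted(k[1] for k in keys)


def test_top_one_is_most_frequent():
    sample = make_sample([50, 30, 20])
    (key,) = top_n_clonotypes(sample, 1)
    assert key[1] == "CASSAAF"  # the 50-read clone


def test_top_n_invalid(toy_sample):
    with pytest.raises(DomainError):
        top_n_clonotypes(toy_sample, 0)


# ------------------------------------------------------------------- tracking

def test_tracking_rows_and_absent_zero():
    baseline = make_sample([2, 98], kind="baseline_bm")  # CASSAF at 0.02
    end = make_sample([10], kind="end_of_trial_bm", prefix="CTSS")
    key = clonotype_key(baseline.clonotypes[0])
    result = track_clonotypes([key], [baseline, end])
    assert result.frequency_matrix[0].tolist() == pytest.approx([0.02, 0.0])
    assert result.sample_order == ["baseline_bm", "end_of_trial_bm"]
    assert result.key_definition == DEFAULT_KEY


def test_tracking_column_mass_never_exceeds_one():
    sample = make_sample([5, 3, 2])
    keys = top_n_clonotypes(sample, 3)
    result = track_clonotypes(keys, [sample])
    assert result.frequency_matrix[:, 0].sum() == pytest.approx(1.0)


def test_tracking_validations(toy_sample):
    other = make_sample([4], locus="alpha")
    with pytest.raises(DomainError):
        track_clonotypes([("beta", "CASSAF", None)], [toy_sample, other])
    with pytest.raises(DomainError):
        track_clonotypes([], [toy_sample])
    stranger = make_sample([4], patient="P2")
    with pytest.raises(DomainError):
        track_clonotypes([("beta", "CASSAF", None)], [toy_sample, stranger])


def test_tracking_long_frame_shape(toy_sample):
    keys = top_n_clonotypes(toy_sample, 2)
    frame = track_clonotypes(keys, [toy_sample]).to_long_frame()
    assert list(frame.columns) == ["clonotype", "sample", "frequency"]
    assert len(frame) == 2


# ------------------------------------------------------------------- report

def _trio(spike_reads_end=0):
    culture = make_sample([95, 5], kind="specific_culture", prefix="CSPK")
    baseline = make_sample([600, 400], kind="baseline_bm")
    end_counts = [600, 400]
    end = make_sample(end_counts, kind="end_of_trial_bm")
    if spike_reads_end:
        spike = culture.clonotypes[0]  # CSPKAF, the 95-read dominant clone
        clones = end.clonotypes + [
            Clonotype(locus="beta", cdr3_aa=spike.cdr3_aa, read_count=spike_reads_end)
        ]
        end = RepertoireSample("P1", "end_of_trial_bm", "beta", clones)
    return culture, baseline, end


def test_report_spiked_clone_absent_at_baseline():
    culture, baseline, end = _trio(spike_reads_end=1)
    specific = specific_clonotype_set(culture)
    report = specific_fraction_report(specific, baseline, end, culture)
    assert report.fraction_in_baseline == 0.0
    assert report.fraction_in_end_of_trial == pytest.approx(1 / 1001)
    assert report.fraction_in_specific_sample == pytest.approx(1.0)


def test_report_empty_specific_set_all_zero():
    culture, baseline, end = _trio()
    report = specific_fraction_report(set(), baseline, end, culture)
    assert (
        report.fraction_in_baseline
        == report.fraction_in_end_of_trial
        == report.fraction_in_specific_sample
        == 0.0
    )
    assert report.n_specific_clonotypes == 0


def test_report_percent_formatting():
    assert format_percent(0.00022) == "0.022%"
    assert format_percent(0.0) == "0.000%"
    assert format_percent(0.89011) == "89.011%"


def test_report_requires_matching_patient(toy_sample):
    culture, baseline, end = _trio()
    stranger = make_sample([5], kind="baseline_bm", patient="P9")
    with pytest.raises(DomainError):
        specific_fraction_report(set(), stranger, end, culture)


# ----------------------------------------------------------------- properties

read_count_lists = st.lists(st.integers(1, 500), min_size=1, max_size=40)


@given(read_count_lists)
def test_frequencies_sum_to_one(read_counts):
    sample = make_sample(read_counts)
    assert sum(sample.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
    filtered_counts = [c for c in read_counts if c >= 2]
    if filtered_counts:
        filtered = filter_min_reads(sample, 2)
        assert sum(filtered.frequencies.values()) == pytest.approx(1.0, abs=1e-9)


@given(read_count_lists, st.integers(1, 5))
def test_filter_never_counts_removed_keys(read_counts, min_reads):
    sample = make_sample(read_counts)
    survivors = [c for c in read_counts if c >= min_reads]
    if not survivors:
        with pytest.raises(EmptySampleError):
            filter_min_reads(sample, min_reads)
    else:
        filtered = filter_min_reads(sample, min_reads)
        assert count_clonotypes(filtered) == len(set_idx(read_counts, min_reads))
        assert all(c.read_count >= min_reads for c in filtered.clonotypes)


def set_idx(read_counts, min_reads):
    # distinct CDR3 per index in make_sample, so survivors are positional
    return [i for i, c in enumerate(read_counts) if c >= min_reads]


def test_coarser_key_never_increases_count():
    clones = [
        Clonotype(locus="beta", cdr3_aa="CASSLGF", v_call="TRBV2", read_count=3),
        Clonotype(locus="beta", cdr3_aa="CASSLGF", v_call="TRBV19", read_count=2),
        Clonotype(locus="beta", cdr3_aa="CASRRAF", v_call="TRBV2", read_count=4),
    ]
    fine = RepertoireSample("P1", "baseline_bm", "beta", list(clones),
                            key_fields=("locus", "cdr3_aa", "v_call"))
    coarse = RepertoireSample("P1", "baseline_bm", "beta", list(clones),
                              key_fields=("locus", "cdr3_aa"))
    assert count_clonotypes(coarse) <= count_clonotypes(fine)
    assert count_clonotypes(coarse) == 2
    assert coarse.total_reads == fine.total_reads == 9
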