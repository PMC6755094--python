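"""Threshold-rule substrate callers: decapped intermediates, 3' fragments, cleavage sites."""

import dataclasses
import warnings

import pytest

from parekit.annotation_io import LibraryInfo, ProfileError
from parekit.capsite_calling import CapSiteCall
from parekit.cli_reporting import analyze_dataset
from parekit.degradome_profiles import MaxSeq, NormalizedProfile
from parekit.substrate_calling import (
    Thresholds,
    WTReference,
    call_cleavage_sites,
    call_decapped,
    call_three_prime_fragments,
    intersect_mutants,
    read_calls,
    write_calls,
)
from parekit.synthetic_data import SimulationConfig, simulate_dataset


def _wt_ref(per_rep_abundance, wt_libraries, pseudo_tags=1, tid="t1"):
    profiles = [
        NormalizedProfile(lib.library_id, tid, dict(ab))
        for lib, ab in zip(wt_libraries, per_rep_abundance)
    ]
    return WTReference(profiles, wt_libraries, pseudo_tags=pseudo_tags)


def _cap(tid="t1", position=1):
    offset = position - 1 if position >= 1 else position
    cls = "precise" if offset == 0 else ("within_plus25" if 1 <= offset <= 25 else ("upstream" if offset < 0 else "other"))
    return CapSiteCall(tid, position, offset, cls, 50.0, 2)


# ---------------------------------------------------------------------------
# thresholds and WT reference
# ---------------------------------------------------------------------------

def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(decapped_min_fold=1.0)
    with pytest.raises(ValueError):
        Thresholds(frag_min_abundance=-1.0)
    with pytest.raises(ValueError):
        Thresholds(cleavage_window=-1)


def test_wt_reference_is_replicate_mean(wt_libraries):
    ref = _wt_ref([{10: 4.0}, {10: 6.0}], wt_libraries)
    assert ref.at("t1", 10) == pytest.approx(5.0)


def test_wt_reference_floor_applies_when_mean_below(wt_libraries):
    # floor = mean(1 tag TP20M per replicate) = (2.0 + 0.8) / 2 = 1.4
    ref = _wt_ref([{}, {}], wt_libraries)
    assert ref.floor == pytest.approx(1.4)
    assert ref.at("t1", 10) == pytest.approx(1.4)
    ref2 = _wt_ref([{10: 0.4}, {10: 0.6}], wt_libraries)
    assert ref2.at("t1", 10) == pytest.approx(1.4)  # mean 0.5 < floor


def test_single_tag_floor_in_25M_library():
    lib = LibraryInfo("w1", "WT", "WT", "polyA_plus", 1, 25_000_000)
    ref = WTReference([], [lib], pseudo_tags=1)
    assert ref.floor == pytest.approx(0.8)  # 1 * 2e7 / 2.5e7


def test_wt_reference_absent_transcript_uses_floor(wt_libraries):
    ref = _wt_ref([{1: 3.0}], wt_libraries[:1])
    assert ref.at("unseen", 1) == pytest.approx(ref.floor)


# ---------------------------------------------------------------------------
# decapped caller
# ---------------------------------------------------------------------------

def test_call_decapped_all_criteria_met(wt_libraries):
    maxseqs = {"t1": MaxSeq("mutA_lib", "t1", 1, 60.0, "utr5")}
    ref = _wt_ref([{1: 4.0}, {1: 6.0}], wt_libraries)
    calls, diag = call_decapped(maxseqs, {"t1": _cap()}, ref, Thresholds(), "xrn4-5", "polyA_plus")
    assert len(calls) == 1
    call = calls[0]
    assert call.position == 1
    assert call.fold_change_per_mutant["xrn4-5"] == pytest.approx(12.0)
    assert call.abundance_per_genotype == {"xrn4-5": 60.0, "WT": pytest.approx(5.0)}
    assert diag["n_called"] == 1


def test_call_decapped_below_abundance_threshold(wt_libraries):
    maxseqs = {"t1": MaxSeq("mutA_lib", "t1", 1, 8.0, "utr5")}
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_decapped(maxseqs, {"t1": _cap()}, ref, Thresholds(), "xrn4-5", "polyA_plus")
    assert calls == [] and diag["n_below_abundance"] == 1


def test_call_decapped_requires_exact_cap_match(wt_libraries):
    maxseqs = {"t1": MaxSeq("mutA_lib", "t1", 2, 100.0, "utr5")}  # 1 nt off the cap
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_decapped(maxseqs, {"t1": _cap(position=1)}, ref, Thresholds(), "xrn4-5", "polyA_plus")
    assert calls == [] and diag["n_not_at_cap"] == 1


def test_call_decapped_excludes_transcripts_without_capsite(wt_libraries):
    maxseqs = {"t1": MaxSeq("mutA_lib", "t1", 1, 100.0, "utr5")}
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_decapped(maxseqs, {}, ref, Thresholds(), "xrn4-5", "polyA_plus")
    assert calls == [] and diag["n_no_capsite"] == 1


def test_decapped_diagnostics_account_for_every_input(wt_libraries):
    maxseqs = {
        "t1": MaxSeq("m", "t1", 1, 60.0, "utr5"),   # called
        "t2": MaxSeq("m", "t2", 5, 60.0, "utr5"),   # not at cap
        "t3": MaxSeq("m", "t3", 1, 2.0, "utr5"),    # below abundance
        "t4": MaxSeq("m", "t4", 1, 60.0, "utr5"),   # no capsite
    }
    caps = {t: _cap(t) for t in ("t1", "t2", "t3")}
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_decapped(maxseqs, caps, ref, Thresholds(), "xrn4-5", "polyA_plus")
    assert diag["n_input"] == 4
    assert diag["n_input"] == sum(v for k, v in diag.items() if k != "n_input")
    assert [c.transcript_id for c in calls] == ["t1"]


# ---------------------------------------------------------------------------
# 3' fragment caller
# ---------------------------------------------------------------------------

def test_call_fragments_utr3_maxseq(wt_libraries):
    maxseqs = {"t1": MaxSeq("m", "t1", 450, 40.0, "utr3")}
    ref = _wt_ref([{450: 4.0}, {450: 4.0}], wt_libraries)
    calls, _ = call_three_prime_fragments(maxseqs, {"t1": _cap()}, ref, Thresholds(), "xrn4-5")
    assert len(calls) == 1
    assert calls[0].fold_change_per_mutant["xrn4-5"] == pytest.approx(10.0)
    assert calls[0].call_type == "three_prime_fragment"


def test_fragment_at_cap_is_never_called(wt_libraries):
    # a cap inside the CDS region: MaxSeq there must not be treated as a fragment
    cap = _cap(position=40)
    maxseqs = {"t1": MaxSeq("m", "t1", 40, 500.0, "cds")}
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_three_prime_fragments(maxseqs, {"t1": cap}, ref, Thresholds(), "xrn4-5")
    assert calls == [] and diag["n_at_cap"] == 1


def test_fragment_requires_body_region(wt_libraries):
    maxseqs = {"t1": MaxSeq("m", "t1", 5, 500.0, "utr5")}
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_three_prime_fragments(maxseqs, {"t1": _cap()}, ref, Thresholds(), "xrn4-5")
    assert calls == [] and diag["n_wrong_region"] == 1


def test_fragment_thresholds_are_stricter(wt_libraries):
    # 15 TP20M passes the decapped abundance bar but not the fragment bar (20)
    maxseqs = {"t1": MaxSeq("m", "t1", 450, 15.0, "utr3")}
    ref = _wt_ref([{}, {}], wt_libraries)
    calls, diag = call_three_prime_fragments(maxseqs, {"t1": _cap()}, ref, Thresholds(), "xrn4-5")
    assert calls == [] and diag["n_below_abundance"] == 1


# ---------------------------------------------------------------------------
# cleavage-site caller
# ---------------------------------------------------------------------------

def test_cleavage_window_sum_and_fold(model, wt_libraries):
    profiles = {"t1": NormalizedProfile("m", "t1", {99: 5.0, 100: 8.0, 101: 2.0})}
    ref = _wt_ref([{100: 6.0}, {100: 6.0}], wt_libraries)
    calls, _ = call_cleavage_sites(
        profiles, [("t1", 100)], ref, {"t1": model}, Thresholds(), "xrn4-5", "polyA_plus"
    )
    assert len(calls) == 1
    assert calls[0].abundance_per_genotype["xrn4-5"] == pytest.approx(15.0)
    assert calls[0].fold_change_per_mutant["xrn4-5"] == pytest.approx(2.5)


def test_cleavage_fold_below_threshold(model, wt_libraries):
    profiles = {"t1": NormalizedProfile("m", "t1", {100: 15.0})}
    ref = _wt_ref([{100: 12.0}, {100: 12.0}], wt_libraries)
    calls, diag = call_cleavage_sites(
        profiles, [("t1", 100)], ref, {"t1": model}, Thresholds(), "xrn4-5", "polyA_plus"
    )
    assert calls == [] and diag["n_below_fold"] == 1  # fold 1.25 < 1.5


def test_cleavage_window_zero_is_exact_position(model, wt_libraries):
    profiles = {"t1": NormalizedProfile("m", "t1", {99: 50.0, 100: 12.0})}
    ref = _wt_ref([{}, {}], wt_libraries)
    thresholds = Thresholds(cleavage_window=0)
    calls, _ = call_cleavage_sites(
        profiles, [("t1", 100)], ref, {"t1": model}, thresholds, "xrn4-5", "polyA_plus"
    )
    assert calls[0].abundance_per_genotype["xrn4-5"] == pytest.approx(12.0)


def test_cleavage_site_outside_transcript_names_row(model, wt_libraries):
    ref = _wt_ref([{}, {}], wt_libraries)
    with pytest.raises(ProfileError, match="row 1"):
        call_cleavage_sites(
            {}, [("t1", 100), ("t1", 600)], ref, {"t1": model}, Thresholds(), "xrn4-5", "polyA_plus"
        )


# ---------------------------------------------------------------------------
# intersection across mutants
# ---------------------------------------------------------------------------

def _call(tid, position, call_type="decapped", fraction="polyA_plus", label="xrn4-5"):
    from parekit.substrate_calling import SubstrateCall

    return SubstrateCall(
        transcript_id=tid, call_type=call_type, fraction=fraction, position=position,
        abundance_per_genotype={label: 50.0, "WT": 5.0},
        fold_change_per_mutant={label: 10.0},
        passed_mutants=(label,),
    )


def test_intersect_by_transcript():
    a = [_call("t1", 1), _call("t2", 1)]
    b = [_call("t2", 1, label="xrn4-6"), _call("t3", 1, label="xrn4-6")]
    merged = intersect_mutants(a, b, match="transcript")
    assert [c.transcript_id for c in merged] == ["t2"]
    assert merged[0].passed_mutants == ("xrn4-5", "xrn4-6")
    assert set(merged[0].fold_change_per_mutant) == {"xrn4-5", "xrn4-6"}


def test_intersect_same_site_requires_identical_position():
    a = [_call("t1", 500, call_type="three_prime_fragment")]
    b = [_call("t1", 502, call_type="three_prime_fragment", label="xrn4-6")]
    assert intersect_mutants(a, b, match="same_site") == []
    b_same = [_call("t1", 500, call_type="three_prime_fragment", label="xrn4-6")]
    merged = intersect_mutants(a, b_same, match="same_site")
    assert len(merged) == 1 and merged[0].position == 500


def test_intersect_rejects_mixed_inputs():
    with pytest.raises(ValueError):
        intersect_mutants([_call("t1", 1)], [_call("t1", 1, call_type="cleavage_site")])
    with pytest.raises(ValueError):
        intersect_mutants([_call("t1", 1)], [_call("t1", 1, fraction="polyA_minus")])


def test_calls_table_roundtrip(tmp_path):
    calls = [_call("t1", 1), _call("t2", 7)]
    path = tmp_path / "calls.tsv"
    write_calls(calls, path)
    back = read_calls(path)
    assert [(c.transcript_id, c.position) for c in back] == [("t1", 1), ("t2", 7)]
    assert back[0].abundance_per_genotype["xrn4-5"] == pytest.approx(50.0)
    assert back[0].passed_mutants == ("xrn4-5",)


# ---------------------------------------------------------------------------
# threshold monotonicity
# ---------------------------------------------------------------------------

def _substrate_ids(dataset, thresholds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = analyze_dataset(
            dataset.models, dataset.profiles, dataset.libraries,
            thresholds=thresholds,
            cleavage_sites=list(
                dataset.cleavage_sites[["transcript_id", "position"]].itertuples(index=False, name=None)
            ),
        )
    return {
        key: {(c.transcript_id, c.position) for c in calls}
        for key, calls in result["substrates"].items()
    }


def test_raising_any_threshold_never_adds_a_call():
    dataset = simulate_dataset(SimulationConfig(n_transcripts=60, seed=33))
    base = _substrate_ids(dataset, Thresholds())
    raised_variants = [
        Thresholds(decapped_min_abundance=25.0),
        Thresholds(decapped_min_fold=7.0),
        Thresholds(frag_min_abundance=60.0),
        Thresholds(frag_min_fold=4.0),
        Thresholds(cleavage_min_abundance=40.0),
        Thresholds(cleavage_min_fold=3.0),
    ]
    for thresholds in raised_variants:
        tightened = _substrate_ids(dataset, thresholds)
        for key in base:
            assert tightened.get(key, set()) <= base[key], (key, thresholds)
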