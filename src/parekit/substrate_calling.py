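"""Threshold-rule classification of XRN substrates from degradome profiles.

Three callers, all operating on per-library MaxSeqs or windowed abundances
in the mutant, with fold changes computed against the mean of the two WT
replicate libraries of the same RNA fraction:

* decapped decay intermediates -- the mutant MaxSeq coincides exactly
  (integer equality, no tolerance window) with the transcript's cap site,
  its abundance meets a minimum (default 10 TP20M) and it is at least
  5-fold more abundant than in WT;
* 3' fragments -- the mutant MaxSeq lies in the CDS or 3'UTR away from the
  cap site, with abundance >= 20 TP20M and >= 2-fold change;
* cleavage-site overaccumulation at validated small-RNA-guided cleavage
  positions -- abundance summed over the site +/- 1 nt >= 10 TP20M and
  >= 1.5-fold change.

Per-mutant criteria must pass in each mutant independently; calls common to
both mutants (via :func:`intersect_mutants`) define the substrate sets.
A raw-tag pseudocount floor on the WT denominator makes division by zero
impossible for transcripts with no WT signal at the position.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .annotation_io import (
    LibraryInfo,
    ProfileError,
    ProfileKey,
    TranscriptModel,
    axis_window,
)
from .capsite_calling import CapSiteCall
from .degradome_profiles import TP20M_SCALE, MaxSeq, NormalizedProfile, assign_region

__all__ = [
    "CALL_TYPES",
    "Thresholds",
    "SubstrateCall",
    "WTReference",
    "call_decapped",
    "call_three_prime_fragments",
    "call_cleavage_sites",
    "intersect_mutants",
    "calls_table",
    "write_calls",
    "read_calls",
    "read_cleavage_sites",
]

CALL_TYPES = ("decapped", "three_prime_fragment", "cleavage_site")


@dataclass(frozen=True)
class Thresholds:
    """Abundance and fold-change thresholds for the three callers.

    Defaults are the standard operating point for this analysis:
    decapped >= 10 TP20M and >= 5-fold; 3' fragments >= 20 TP20M and
    >= 2-fold; cleavage sites >= 10 TP20M (summed over +/- 1 nt) and
    >= 1.5-fold.  ``wt_pseudo_tags`` is the raw-tag pseudocount floor
    applied to the WT fold-change denominator.
    """

    decapped_min_abundance: float = 10.0
    decapped_min_fold: float = 5.0
    frag_min_abundance: float = 20.0
    frag_min_fold: float = 2.0
    cleavage_min_abundance: float = 10.0
    cleavage_min_fold: float = 1.5
    cleavage_window: int = 1
    wt_pseudo_tags: int = 1

    def __post_init__(self) -> None:
        for name in ("decapped_min_fold", "frag_min_fold", "cleavage_min_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")
        for name in ("decapped_min_abundance", "frag_min_abundance", "cleavage_min_abundance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cleavage_window < 0:
            raise ValueError("cleavage_window must be >= 0")
        if self.wt_pseudo_tags < 1:
            raise ValueError("wt_pseudo_tags must be >= 1")


@dataclass
class SubstrateCall:
    """A classified decapped intermediate, 3' fragment or cleavage-site event."""

    transcript_id: str
    call_type: str
    fraction: str
    position: int
    abundance_per_genotype: dict[str, float] = field(default_factory=dict)
    fold_change_per_mutant: dict[str, float] = field(default_factory=dict)
    passed_mutants: tuple[str, ...] = ()


class WTReference:
    """Fold-change denominator built from the WT replicate libraries of one fraction.

    The reference at a position is the mean of the replicate TP20M values
    (absent position = 0), floored at the TP20M equivalent of
    ``pseudo_tags`` raw tags (computed per replicate, then averaged).
    """

    def __init__(
        self,
        profiles: Union[Mapping[ProfileKey, NormalizedProfile], Iterable[NormalizedProfile]],
        libraries: Sequence[LibraryInfo],
        pseudo_tags: int = 1,
    ) -> None:
        if not libraries:
            raise ProfileError("WTReference requires at least one WT library")
        self.libraries = list(libraries)
        self.n_replicates = len(self.libraries)
        self.floor = sum(
            pseudo_tags * TP20M_SCALE / lib.total_mapped_tags for lib in self.libraries
        ) / self.n_replicates
        lib_ids = {lib.library_id for lib in self.libraries}
        if isinstance(profiles, Mapping):
            profile_iter: Iterable[NormalizedProfile] = profiles.values()
        else:
            profile_iter = profiles
        self._by_tx: dict[str, list[dict[int, float]]] = {}
        for profile in profile_iter:
            if profile.library_id not in lib_ids:
                raise ProfileError(
                    f"profile from library {profile.library_id!r} does not belong to "
                    f"the WT reference libraries {sorted(lib_ids)}"
                )
            self._by_tx.setdefault(profile.transcript_id, []).append(profile.abundance)

    def raw_mean(self, transcript_id: str, position: int) -> float:
        """Unfloored replicate-mean abundance at a position."""
        total = 0.0
        for abundance in self._by_tx.get(transcript_id, ()):
            total += abundance.get(position, 0.0)
        return total / self.n_replicates

    def at(self, transcript_id: str, position: int) -> float:
        """Floored replicate-mean abundance at a position (never 0)."""
        return max(self.raw_mean(transcript_id, position), self.floor)

    def window_mean(self, transcript_id: str, position: int, halfwidth: int) -> float:
        """Floored replicate-mean of the windowed abundance sum around a position."""
        total = 0.0
        positions = axis_window(position, halfwidth)
        for abundance in self._by_tx.get(transcript_id, ()):
            total += sum(abundance.get(p, 0.0) for p in positions)
        return max(total / self.n_replicates, self.floor)


def _new_diagnostics(keys: Sequence[str]) -> dict[str, int]:
    d = {"n_input": 0, "n_called": 0}
    for key in keys:
        d[key] = 0
    return d


def call_decapped(
    maxseqs: Mapping[str, MaxSeq],
    capsites: Mapping[str, CapSiteCall],
    wt_reference: WTReference,
    thresholds: Thresholds,
    mutant_label: str,
    fraction: str,
) -> tuple[list[SubstrateCall], dict[str, int]]:
    """Call decapped decay intermediates for one mutant library.

    A call is emitted iff (i) the mutant MaxSeq position equals the
    transcript's cap position exactly, (ii) its abundance meets
    ``decapped_min_abundance`` and (iii) the fold change over the WT
    reference at that position meets ``decapped_min_fold``.  Transcripts
    without a cap-site call are not evaluated; every input transcript is
    accounted for in the returned diagnostics tally.
    """
    diagnostics = _new_diagnostics(
        ["n_no_capsite", "n_not_at_cap", "n_below_abundance", "n_below_fold"]
    )
    calls: list[SubstrateCall] = []
    for tid in sorted(maxseqs):
        maxseq = maxseqs[tid]
        diagnostics["n_input"] += 1
        capsite = capsites.get(tid)
        if capsite is None:
            diagnostics["n_no_capsite"] += 1
            continue
        if maxseq.position != capsite.cap_position:
            diagnostics["n_not_at_cap"] += 1
            continue
        if maxseq.abundance < thresholds.decapped_min_abundance:
            diagnostics["n_below_abundance"] += 1
            continue
        wt = wt_reference.at(tid, maxseq.position)
        fold = maxseq.abundance / wt
        if fold < thresholds.decapped_min_fold:
            diagnostics["n_below_fold"] += 1
            continue
        diagnostics["n_called"] += 1
        calls.append(
            SubstrateCall(
                transcript_id=tid,
                call_type="decapped",
                fraction=fraction,
                position=maxseq.position,
                abundance_per_genotype={mutant_label: maxseq.abundance, "WT": wt},
                fold_change_per_mutant={mutant_label: fold},
                passed_mutants=(mutant_label,),
            )
        )
    return calls, diagnostics


def call_three_prime_fragments(
    maxseqs: Mapping[str, MaxSeq],
    capsites: Mapping[str, CapSiteCall],
    wt_reference: WTReference,
    thresholds: Thresholds,
    mutant_label: str,
    fraction: str = "polyA_plus",
) -> tuple[list[SubstrateCall], dict[str, int]]:
    """Call 3' fragments (cleaved decay intermediates) for one mutant library.

    A call requires a MaxSeq in the CDS or 3'UTR that is not the cap
    position, with abundance >= ``frag_min_abundance`` and fold change
    >= ``frag_min_fold``.  The analysis defaults to polyA+ libraries, where
    nearly all 3' fragments are observed.
    """
    diagnostics = _new_diagnostics(
        ["n_no_capsite", "n_wrong_region", "n_at_cap", "n_below_abundance", "n_below_fold"]
    )
    calls: list[SubstrateCall] = []
    for tid in sorted(maxseqs):
        maxseq = maxseqs[tid]
        diagnostics["n_input"] += 1
        capsite = capsites.get(tid)
        if capsite is None:
            diagnostics["n_no_capsite"] += 1
            continue
        if maxseq.region not in ("cds", "utr3"):
            diagnostics["n_wrong_region"] += 1
            continue
        if maxseq.position == capsite.cap_position:
            diagnostics["n_at_cap"] += 1
            continue
        if maxseq.abundance < thresholds.frag_min_abundance:
            diagnostics["n_below_abundance"] += 1
            continue
        wt = wt_reference.at(tid, maxseq.position)
        fold = maxseq.abundance / wt
        if fold < thresholds.frag_min_fold:
            diagnostics["n_below_fold"] += 1
            continue
        diagnostics["n_called"] += 1
        calls.append(
            SubstrateCall(
                transcript_id=tid,
                call_type="three_prime_fragment",
                fraction=fraction,
                position=maxseq.position,
                abundance_per_genotype={mutant_label: maxseq.abundance, "WT": wt},
                fold_change_per_mutant={mutant_label: fold},
                passed_mutants=(mutant_label,),
            )
        )
    return calls, diagnostics


def call_cleavage_sites(
    profiles: Mapping[str, NormalizedProfile],
    cleavage_sites: Iterable[tuple[str, int]],
    wt_reference: WTReference,
    models: Mapping[str, TranscriptModel],
    thresholds: Thresholds,
    mutant_label: str,
    fraction: str,
) -> tuple[list[SubstrateCall], dict[str, int]]:
    """Call overaccumulation at validated cleavage sites for one mutant library.

    ``profiles`` maps transcript_id -> the mutant library's normalized
    profile.  Abundance is the TP20M sum over ``site +/- cleavage_window``
    (the window steps over the nonexistent position 0); the WT reference
    uses the same window.  A site outside its transcript raises an error
    naming the row.
    """
    diagnostics = _new_diagnostics(["n_below_abundance", "n_below_fold"])
    calls: list[SubstrateCall] = []
    w = thresholds.cleavage_window
    for row_index, (tid, site) in enumerate(cleavage_sites):
        model = models.get(tid)
        if model is None:
            raise ProfileError(f"cleavage-site row {row_index}: unknown transcript {tid!r}")
        if not 1 <= site <= model.length:
            raise ProfileError(
                f"cleavage-site row {row_index}: position {site} outside the body "
                f"[1, {model.length}] of transcript {tid}"
            )
        diagnostics["n_input"] += 1
        profile = profiles.get(tid)
        window = [p for p in axis_window(site, w) if model.contains(p)]
        abundance = 0.0
        if profile is not None:
            abundance = sum(profile.abundance.get(p, 0.0) for p in window)
        if abundance < thresholds.cleavage_min_abundance:
            diagnostics["n_below_abundance"] += 1
            continue
        wt = wt_reference.window_mean(tid, site, w)
        fold = abundance / wt
        if fold < thresholds.cleavage_min_fold:
            diagnostics["n_below_fold"] += 1
            continue
        diagnostics["n_called"] += 1
        calls.append(
            SubstrateCall(
                transcript_id=tid,
                call_type="cleavage_site",
                fraction=fraction,
                position=site,
                abundance_per_genotype={mutant_label: abundance, "WT": wt},
                fold_change_per_mutant={mutant_label: fold},
                passed_mutants=(mutant_label,),
            )
        )
    return calls, diagnostics


def intersect_mutants(
    calls_a: Sequence[SubstrateCall],
    calls_b: Sequence[SubstrateCall],
    match: str = "transcript",
) -> list[SubstrateCall]:
    """Intersect per-mutant call sets; only events passing in both survive.

    ``match='transcript'`` intersects by transcript id (appropriate for
    decapped and cleavage-site calls, whose positions are shared by
    construction); ``match='same_site'`` additionally requires the identical
    position in both mutants (3' fragments).  Both inputs must carry the
    same call type and fraction.
    """
    if match not in ("transcript", "same_site"):
        raise ValueError(f"unknown match mode {match!r}")
    types = {c.call_type for c in calls_a} | {c.call_type for c in calls_b}
    fractions = {c.fraction for c in calls_a} | {c.fraction for c in calls_b}
    if len(types) > 1:
        raise ValueError(f"cannot intersect mixed call types {sorted(types)}")
    if len(fractions) > 1:
        raise ValueError(f"cannot intersect mixed fractions {sorted(fractions)}")

    def key(call: SubstrateCall):
        if match == "same_site":
            return (call.transcript_id, call.position)
        return call.transcript_id

    by_key_b = {key(c): c for c in calls_b}
    merged: list[SubstrateCall] = []
    for call_a in calls_a:
        call_b = by_key_b.get(key(call_a))
        if call_b is None:
            continue
        merged.append(
            SubstrateCall(
                transcript_id=call_a.transcript_id,
                call_type=call_a.call_type,
                fraction=call_a.fraction,
                position=call_a.position,
                abundance_per_genotype={
                    **call_a.abundance_per_genotype,
                    **call_b.abundance_per_genotype,
                },
                fold_change_per_mutant={
                    **call_a.fold_change_per_mutant,
                    **call_b.fold_change_per_mutant,
                },
                passed_mutants=tuple(
                    sorted(set(call_a.passed_mutants) | set(call_b.passed_mutants))
                ),
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Tabular serialization of calls
# ---------------------------------------------------------------------------

_CALL_COLUMNS = (
    "transcript_id",
    "call_type",
    "fraction",
    "position",
    "abundances_tp20m",
    "fold_changes",
    "passed_mutants",
)


def _format_map(mapping: Mapping[str, float]) -> str:
    return ";".join(f"{k}={mapping[k]:.6g}" for k in sorted(mapping))


def _parse_map(text: str) -> dict[str, float]:
    result: dict[str, float] = {}
    if text:
        for item in text.split(";"):
            key, _, value = item.partition("=")
            result[key] = float(value)
    return result


def calls_table(calls: Iterable[SubstrateCall]) -> list[dict[str, object]]:
    rows = []
    for c in sorted(calls, key=lambda c: (c.transcript_id, c.position)):
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "call_type": c.call_type,
                "fraction": c.fraction,
                "position": c.position,
                "abundances_tp20m": _format_map(c.abundance_per_genotype),
                "fold_changes": _format_map(c.fold_change_per_mutant),
                "passed_mutants": ",".join(c.passed_mutants),
            }
        )
    return rows


def write_calls(calls: Iterable[SubstrateCall], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CALL_COLUMNS, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in calls_table(calls):
            writer.writerow(row)


def read_calls(path: Union[str, Path]) -> list[SubstrateCall]:
    calls: list[SubstrateCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            calls.append(
                SubstrateCall(
                    transcript_id=row["transcript_id"],
                    call_type=row["call_type"],
                    fraction=row["fraction"],
                    position=int(row["position"]),
                    abundance_per_genotype=_parse_map(row["abundances_tp20m"]),
                    fold_change_per_mutant=_parse_map(row["fold_changes"]),
                    passed_mutants=tuple(
                        m for m in row["passed_mutants"].split(",") if m
                    ),
                )
            )
    return calls


def read_cleavage_sites(path: Union[str, Path]) -> list[tuple[str, int]]:
    """Read a validated-cleavage-site TSV (transcript_id, position[, guide])."""
    sites: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None:
            return sites
        if "transcript_id" not in reader.fieldnames or "position" not in reader.fieldnames:
            raise ProfileError(f"{path}: expected columns transcript_id, position")
        for lineno, row in enumerate(reader, start=2):
            try:
                sites.append((row["transcript_id"], int(row["position"])))
            except (TypeError, ValueError) as exc:
                raise ProfileError(f"{path} line {lineno}: malformed row: {exc}") from exc
    return sites
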