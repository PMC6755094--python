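"""Cap-site calling from C-PARE profiles.

C-PARE sequences the 5' ends of capped RNA after in vitro decapping, so the
dominant C-PARE 5'-end position on a transcript marks its cap site.  Cap
sites are compared with the annotated TSS (transcript position +1) and
classified by offset: ``precise`` (exactly at the annotated TSS),
``within_plus25`` (1-25 nt downstream), ``upstream`` (within the upstream
extension) or ``other`` (>25 nt downstream).

Offset arithmetic skips the nonexistent position 0: a cap at position -8 is
8 nt upstream of the annotated TSS, so its offset is -8 (not -9).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .annotation_io import LibraryInfo, ProfileError, TranscriptModel, axis_to_gapless
from .degradome_profiles import TP20M_SCALE, NormalizedProfile

__all__ = [
    "OFFSET_CLASSES",
    "CapSiteCall",
    "tss_offset",
    "classify_offset",
    "default_min_support",
    "call_cap_sites",
    "capsite_offset_summary",
    "write_capsites",
    "read_capsites",
]

OFFSET_CLASSES = ("precise", "within_plus25", "upstream", "other")


@dataclass(frozen=True)
class CapSiteCall:
    """Per-transcript cap position with its offset class relative to the annotated TSS."""

    transcript_id: str
    cap_position: int
    offset: int
    offset_class: str
    support: float  # TP20M summed across contributing C-PARE libraries
    n_libraries: int

    def __post_init__(self) -> None:
        if self.support <= 0:
            raise ProfileError(f"{self.transcript_id}: cap-site support must be > 0")
        if self.offset_class != classify_offset(self.offset):
            raise ProfileError(
                f"{self.transcript_id}: offset_class {self.offset_class!r} inconsistent "
                f"with offset {self.offset}"
            )


def tss_offset(cap_position: int) -> int:
    """Nt distance from the annotated TSS (+1), stepping over position 0."""
    return axis_to_gapless(cap_position)  # gapless(+1) == 0, so offset == gapless(cap)


def classify_offset(offset: int) -> str:
    if offset == 0:
        return "precise"
    if 1 <= offset <= 25:
        return "within_plus25"
    if offset < 0:
        return "upstream"
    return "other"


def default_min_support(cpare_libraries: Iterable[LibraryInfo], min_tags: int = 5) -> float:
    """TP20M equivalent of ``min_tags`` raw tags in the smallest C-PARE library.

    Prevents single-tag cap calls while keeping the threshold on the
    normalized scale used everywhere else.
    """
    totals = [lib.total_mapped_tags for lib in cpare_libraries]
    if not totals:
        raise ProfileError("no C-PARE libraries supplied for min_support computation")
    return min_tags * TP20M_SCALE / min(totals)


def call_cap_sites(
    cpare_profiles: Iterable[NormalizedProfile],
    models: Mapping[str, TranscriptModel],
    libraries: Optional[Iterable[LibraryInfo]] = None,
    min_support: Optional[float] = None,
    min_support_tags: int = 5,
) -> dict[str, CapSiteCall]:
    """Call one cap site per transcript from summed C-PARE profiles.

    Abundances are summed position-wise across all supplied C-PARE libraries
    (genotypes pooled); the cap position is the summed-profile argmax with
    the 5'-most tie-break.  Calls with support below ``min_support`` are
    dropped.  If ``min_support`` is None it defaults to the TP20M equivalent
    of ``min_support_tags`` raw tags in the smallest supplied library (0 when
    no library metadata is given).

    The result is idempotent and invariant to library ordering.
    """
    libraries = list(libraries) if libraries is not None else None
    if libraries is not None:
        non_cpare = [lib.library_id for lib in libraries if lib.fraction != "cpare"]
        if non_cpare:
            raise ProfileError(f"non-C-PARE libraries passed to call_cap_sites: {non_cpare}")
    if min_support is None:
        min_support = default_min_support(libraries, min_support_tags) if libraries else 0.0

    summed: dict[str, dict[int, float]] = {}
    n_libs: dict[str, set[str]] = {}
    for profile in cpare_profiles:
        tid = profile.transcript_id
        if tid not in models:
            warnings.warn(f"transcript {tid!r} not in annotation; C-PARE profile ignored")
            continue
        if not profile.abundance:
            continue
        bucket = summed.setdefault(tid, {})
        for pos, ab in profile.abundance.items():
            bucket[pos] = bucket.get(pos, 0.0) + ab
        n_libs.setdefault(tid, set()).add(profile.library_id)

    calls: dict[str, CapSiteCall] = {}
    for tid in sorted(summed):
        bucket = summed[tid]
        position, support = min(bucket.items(), key=lambda kv: (-kv[1], kv[0]))
        if support < min_support or support <= 0:
            continue
        offset = tss_offset(position)
        calls[tid] = CapSiteCall(
            transcript_id=tid,
            cap_position=position,
            offset=offset,
            offset_class=classify_offset(offset),
            support=support,
            n_libraries=len(n_libs[tid]),
        )
    return calls


def capsite_offset_summary(calls: Iterable[CapSiteCall]) -> dict[str, int]:
    """Counts per offset class plus the total; classes partition the calls."""
    summary = {cls: 0 for cls in OFFSET_CLASSES}
    total = 0
    for call in calls:
        summary[call.offset_class] += 1
        total += 1
    summary["total"] = total
    return summary


_CAPSITE_COLUMNS = ("transcript_id", "cap_position", "offset", "offset_class", "support_tp20m", "n_libraries")


def write_capsites(calls: Mapping[str, CapSiteCall], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CAPSITE_COLUMNS)
        for tid in sorted(calls):
            c = calls[tid]
            writer.writerow(
                [c.transcript_id, c.cap_position, c.offset, c.offset_class, f"{c.support:.6g}", c.n_libraries]
            )


def read_capsites(path: Union[str, Path]) -> dict[str, CapSiteCall]:
    calls: dict[str, CapSiteCall] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            call = CapSiteCall(
                transcript_id=row["transcript_id"],
                cap_position=int(row["cap_position"]),
                offset=int(row["offset"]),
                offset_class=row["offset_class"],
                support=float(row["support_tp20m"]),
                n_libraries=int(row["n_libraries"]),
            )
            calls[call.transcript_id] = call
    return calls
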