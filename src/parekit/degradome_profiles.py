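"""TP20M normalization, MaxSeq identification and four-region assignment.

Degradome tag counts are normalized to TP20M (tags per 20 million mapped
tags) so abundances are comparable across libraries of different depth.
The single most abundant 5'-end position on a transcript in one library is
its "MaxSeq"; classifying where MaxSeqs fall among four delineated regions
(100 nt upstream extension, 5'UTR, CDS, 3'UTR) summarizes whether decay
intermediates pile up at cap-proximal positions (diagnostic of blocked
5'->3' decay after decapping) or across the transcript body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation_io import (
    DegradomeProfile,
    LibraryInfo,
    ProfileError,
    ProfileKey,
    TranscriptModel,
)

__all__ = [
    "TP20M_SCALE",
    "REGIONS",
    "NormalizedProfile",
    "MaxSeq",
    "normalize_tp20m",
    "normalize_dataset",
    "assign_region",
    "find_maxseq",
    "merge_replicates",
    "maxseq_table",
    "maxseq_region_distribution",
]

TP20M_SCALE = 2.0e7  # tags per 20 million mapped tags

REGIONS = ("upstream", "utr5", "cds", "utr3")


@dataclass
class NormalizedProfile:
    """Sparse position -> TP20M abundance map for one (library, transcript)."""

    library_id: str
    transcript_id: str
    abundance: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MaxSeq:
    """The most abundant degradome 5'-end position on a transcript in one library."""

    library_id: str
    transcript_id: str
    position: int
    abundance: float
    region: str


def normalize_tp20m(profile: DegradomeProfile, library: LibraryInfo) -> NormalizedProfile:
    """Scale raw counts by ``2e7 / total_mapped_tags``; sparse structure preserved.

    The manifest's ``total_mapped_tags`` is the denominator (not the sum of
    profiled counts), matching standard degradome normalization where depth
    includes tags on transcripts outside the analysis set.
    """
    if profile.library_id != library.library_id:
        raise ProfileError(
            f"profile library {profile.library_id!r} does not match "
            f"manifest library {library.library_id!r}"
        )
    scale = TP20M_SCALE / library.total_mapped_tags
    return NormalizedProfile(
        library_id=profile.library_id,
        transcript_id=profile.transcript_id,
        abundance={pos: count * scale for pos, count in profile.counts.items()},
    )


def normalize_dataset(
    profiles: Mapping[ProfileKey, DegradomeProfile],
    libraries: Mapping[str, LibraryInfo],
) -> dict[ProfileKey, NormalizedProfile]:
    """Normalize every profile in a dataset against its manifest entry."""
    normalized: dict[ProfileKey, NormalizedProfile] = {}
    for (lib_id, tid), profile in profiles.items():
        library = libraries.get(lib_id)
        if library is None:
            raise ProfileError(f"library {lib_id!r} missing from manifest")
        normalized[(lib_id, tid)] = normalize_tp20m(profile, library)
    return normalized


def assign_region(position: int, model: TranscriptModel) -> str:
    """Assign a position to one of the four delineated regions.

    ``[-upstream_ext, -1]`` -> upstream; ``[1, utr5_len]`` -> utr5;
    the CDS span -> cds; ``(cds_end, length]`` -> utr3.  A transcript with
    ``utr5_len == 0`` maps position 1 into the CDS (its CDS starts at +1).
    """
    if position == 0 or not model.contains(position):
        raise ProfileError(
            f"position {position} outside the coordinate frame of {model.transcript_id}"
        )
    if position < 0:
        return "upstream"
    if position <= model.utr5_len:
        return "utr5"
    if position <= model.cds_end:
        return "cds"
    return "utr3"


def find_maxseq(profile: NormalizedProfile, model: TranscriptModel) -> Optional[MaxSeq]:
    """Return the argmax position of a normalized profile, or None if empty.

    Ties are broken toward the 5'-most (smallest) position, so the result is
    invariant to the iteration order of the sparse map.
    """
    if profile.transcript_id != model.transcript_id:
        raise ProfileError(
            f"profile transcript {profile.transcript_id!r} does not match "
            f"model {model.transcript_id!r}"
        )
    if not profile.abundance:
        return None
    position, abundance = min(profile.abundance.items(), key=lambda kv: (-kv[1], kv[0]))
    return MaxSeq(
        library_id=profile.library_id,
        transcript_id=profile.transcript_id,
        position=position,
        abundance=abundance,
        region=assign_region(position, model),
    )


def merge_replicates(
    profiles: Sequence[NormalizedProfile], merged_library_id: str
) -> NormalizedProfile:
    """Position-wise sum of TP20M across replicate libraries of one transcript."""
    if not profiles:
        raise ProfileError("cannot merge an empty set of profiles")
    tids = {p.transcript_id for p in profiles}
    if len(tids) != 1:
        raise ProfileError(f"cannot merge profiles from different transcripts: {sorted(tids)}")
    merged: dict[int, float] = {}
    for profile in profiles:
        for pos, ab in profile.abundance.items():
            merged[pos] = merged.get(pos, 0.0) + ab
    return NormalizedProfile(
        library_id=merged_library_id, transcript_id=tids.pop(), abundance=merged
    )


def maxseq_table(maxseqs: Iterable[MaxSeq]) -> pd.DataFrame:
    """Long-format MaxSeq table (one row per library x transcript)."""
    rows = [
        {
            "library_id": m.library_id,
            "transcript_id": m.transcript_id,
            "position": m.position,
            "abundance_tp20m": m.abundance,
            "region": m.region,
        }
        for m in maxseqs
    ]
    df = pd.DataFrame(rows, columns=["library_id", "transcript_id", "position", "abundance_tp20m", "region"])
    return df.sort_values(["library_id", "transcript_id"], kind="stable").reset_index(drop=True)


def maxseq_region_distribution(
    maxseqs: Iterable[MaxSeq],
    expected_libraries: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-library counts and fractions of MaxSeqs in each region.

    Fractions sum to 1 per library.  Libraries listed in
    ``expected_libraries`` but contributing no MaxSeqs are omitted with a
    warning rather than reported as all-zero rows.
    """
    per_lib: dict[str, dict[str, int]] = {}
    for m in maxseqs:
        bucket = per_lib.setdefault(m.library_id, {r: 0 for r in REGIONS})
        bucket[m.region] += 1
    if expected_libraries is not None:
        for lib_id in expected_libraries:
            if lib_id not in per_lib:
                warnings.warn(f"library {lib_id!r} has no MaxSeqs; omitted from distribution")
    rows = []
    for lib_id in sorted(per_lib):
        counts = per_lib[lib_id]
        total = sum(counts.values())
        row: dict[str, object] = {"library_id": lib_id, "n_maxseqs": total}
        for region in REGIONS:
            row[f"n_{region}"] = counts[region]
        for region in REGIONS:
            row[f"frac_{region}"] = counts[region] / total
        rows.append(row)
    columns = (
        ["library_id", "n_maxseqs"]
        + [f"n_{r}" for r in REGIONS]
        + [f"frac_{r}" for r in REGIONS]
    )
    return pd.DataFrame(rows, columns=columns)
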