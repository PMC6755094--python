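"""Readers and writers for transcript models, degradome profiles, manifests and gene lists.

Coordinate convention
---------------------
All degradome positions are transcript-local and 1-based: position ``+1`` is
the annotated transcription start site (TSS), i.e. the cap nucleotide.  Each
transcript model carries a fixed upstream extension (default 100 nt) that
occupies positions ``[-upstream_ext, -1]``, so that mis-annotated cap sites
slightly upstream of the annotated TSS can still be observed.  Position 0
does not exist; the axis jumps from -1 to +1.  This module is the only place
where raw files are parsed, and it enforces the convention at the boundary:
no downstream module ever sees position 0 or a position outside
``[-upstream_ext, -1] U [1, length]``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "UPSTREAM_EXT_DEFAULT",
    "GENOTYPES",
    "FRACTIONS",
    "PARE_FRACTIONS",
    "AnnotationError",
    "ProfileError",
    "TranscriptModel",
    "LibraryInfo",
    "DegradomeProfile",
    "axis_to_gapless",
    "axis_from_gapless",
    "axis_shift",
    "axis_window",
    "read_transcript_models",
    "write_transcript_models",
    "read_manifest",
    "write_manifest",
    "read_profiles",
    "write_profiles",
    "read_gene_list",
    "write_gene_list",
    "profiles_from_alignments",
]

UPSTREAM_EXT_DEFAULT = 100
GENOTYPES = ("WT", "mutantA", "mutantB", "other")
FRACTIONS = ("polyA_plus", "polyA_minus", "cpare")
PARE_FRACTIONS = ("polyA_plus", "polyA_minus")


class AnnotationError(ValueError):
    """Raised for malformed annotation/manifest input."""


class ProfileError(ValueError):
    """Raised for malformed or out-of-convention degradome profile data."""


# ---------------------------------------------------------------------------
# Position axis helpers.  The transcript axis has no position 0, so nt
# arithmetic (offsets, windows) is done on a gapless integer axis where
# ...,-2,-1,1,2,... maps to ...,-2,-1,0,1,...
# ---------------------------------------------------------------------------

def axis_to_gapless(position: int) -> int:
    """Map a transcript position (no 0) onto a gapless integer axis."""
    if position == 0:
        raise ProfileError("position 0 does not exist on the transcript axis")
    return position - 1 if position > 0 else position


def axis_from_gapless(g: int) -> int:
    """Inverse of :func:`axis_to_gapless`."""
    return g + 1 if g >= 0 else g


def axis_shift(position: int, delta: int) -> int:
    """Move ``delta`` nucleotides along the axis, stepping over position 0."""
    return axis_from_gapless(axis_to_gapless(position) + delta)


def axis_window(position: int, halfwidth: int) -> list[int]:
    """All positions within ``halfwidth`` nt of ``position`` (inclusive)."""
    g = axis_to_gapless(position)
    return [axis_from_gapless(g + d) for d in range(-halfwidth, halfwidth + 1)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """Per-transcript coordinate frame: 5'UTR/CDS/3'UTR spans plus upstream extension.

    ``cds_start``/``cds_end`` are 1-based inclusive transcript coordinates.
    The model is validated on construction; the fundamental identity is
    ``utr5_len + (cds_end - cds_start + 1) + utr3_len == length``.
    """

    transcript_id: str
    gene_id: str
    length: int
    utr5_len: int
    cds_start: int
    cds_end: int
    utr3_len: int
    upstream_ext: int = UPSTREAM_EXT_DEFAULT
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"{self.transcript_id}: length must be positive")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise AnnotationError(f"{self.transcript_id}: UTR lengths must be non-negative")
        if self.upstream_ext < 1:
            raise AnnotationError(f"{self.transcript_id}: upstream_ext must be >= 1")
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len <= 0:
            raise AnnotationError(f"{self.transcript_id}: empty CDS span")
        if self.utr5_len + cds_len + self.utr3_len != self.length:
            raise AnnotationError(
                f"{self.transcript_id}: utr5 + CDS + utr3 = "
                f"{self.utr5_len + cds_len + self.utr3_len} != length {self.length}"
            )
        if self.cds_start != self.utr5_len + 1:
            raise AnnotationError(
                f"{self.transcript_id}: cds_start {self.cds_start} != utr5_len + 1"
            )
        if self.cds_end != self.length - self.utr3_len:
            raise AnnotationError(
                f"{self.transcript_id}: cds_end {self.cds_end} != length - utr3_len"
            )

    @property
    def cds_span(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    def contains(self, position: int) -> bool:
        """True if ``position`` is legal for this transcript (0 never is)."""
        return (-self.upstream_ext <= position <= -1) or (1 <= position <= self.length)


@dataclass(frozen=True)
class LibraryInfo:
    """Metadata for one sequencing library.

    ``genotype`` is the structural role (WT / mutantA / mutantB / other);
    ``label`` carries the free-text allele name (e.g. ``xrn4-5``).
    ``total_mapped_tags`` is the library depth used for TP20M normalization
    and may exceed the sum of profiled counts (tags mapping to transcripts
    outside the analysis set still count toward depth).
    """

    library_id: str
    genotype: str
    label: str
    fraction: str
    replicate: int
    total_mapped_tags: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise AnnotationError(
                f"library {self.library_id}: genotype {self.genotype!r} not in {GENOTYPES}"
            )
        if self.fraction not in FRACTIONS:
            raise AnnotationError(
                f"library {self.library_id}: fraction {self.fraction!r} not in {FRACTIONS}"
            )
        if self.replicate < 1:
            raise AnnotationError(f"library {self.library_id}: replicate must be >= 1")
        if self.total_mapped_tags < 1:
            raise AnnotationError(f"library {self.library_id}: total_mapped_tags must be >= 1")


@dataclass
class DegradomeProfile:
    """Sparse position -> raw tag count map for one (library, transcript)."""

    library_id: str
    transcript_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def validate_against(self, model: TranscriptModel) -> None:
        for pos, count in self.counts.items():
            if pos == 0 or not model.contains(pos):
                raise ProfileError(
                    f"library {self.library_id}, transcript {self.transcript_id}: "
                    f"position {pos} outside [-{model.upstream_ext}, -1] U [1, {model.length}]"
                )
            if count < 1:
                raise ProfileError(
                    f"library {self.library_id}, transcript {self.transcript_id}: "
                    f"non-positive count {count} at position {pos}"
                )


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

_MODEL_COLUMNS = (
    "transcript_id",
    "gene_id",
    "length",
    "utr5_len",
    "cds_start",
    "cds_end",
    "utr3_len",
    "biotype",
)


def read_transcript_models(
    source: Union[str, Path], upstream_ext: int = UPSTREAM_EXT_DEFAULT
) -> dict[str, TranscriptModel]:
    """Read transcript models from a GFF3 file or a transcript-model TSV.

    Transcripts violating the coordinate invariants are reported with a
    warning and skipped rather than silently dropped.  Returns an
    insertion-ordered mapping ``transcript_id -> TranscriptModel``.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".gff", ".gff3"} or _looks_like_gff(path):
        return _read_models_gff3(path, upstream_ext)
    return _read_models_table(path, upstream_ext)


def _looks_like_gff(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##gff-version")


def _read_models_table(path: Path, upstream_ext: int) -> dict[str, TranscriptModel]:
    models: dict[str, TranscriptModel] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return models  # empty file -> empty collection
        missing = [c for c in _MODEL_COLUMNS[:-1] if c not in reader.fieldnames]
        if missing:
            raise AnnotationError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            tid = row["transcript_id"]
            try:
                model = TranscriptModel(
                    transcript_id=tid,
                    gene_id=row["gene_id"],
                    length=int(row["length"]),
                    utr5_len=int(row["utr5_len"]),
                    cds_start=int(row["cds_start"]),
                    cds_end=int(row["cds_end"]),
                    utr3_len=int(row["utr3_len"]),
                    upstream_ext=upstream_ext,
                    biotype=row.get("biotype") or "protein_coding",
                )
            except AnnotationError as exc:
                warnings.warn(f"{path} line {lineno}: skipping transcript {tid!r}: {exc}")
                continue
            except (TypeError, ValueError) as exc:
                raise AnnotationError(f"{path} line {lineno}: malformed row: {exc}") from exc
            if tid in models:
                warnings.warn(f"{path} line {lineno}: duplicate transcript {tid!r}; keeping first")
                continue
            models[tid] = model
    return models


def _read_models_gff3(path: Path, upstream_ext: int) -> dict[str, TranscriptModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a mix of exception types
        raise AnnotationError(f"{path}: GFF3 parse error: {exc}") from exc

    models: dict[str, TranscriptModel] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        tid = mrna.id
        gene_id = (mrna.attributes.get("Parent") or mrna.attributes.get("gene_id") or [tid])[0]
        spans = {"five_prime_UTR": 0, "CDS": 0, "three_prime_UTR": 0, "exon": 0}
        for child in db.children(mrna):
            if child.featuretype in spans:
                spans[child.featuretype] += child.end - child.start + 1
        if spans["CDS"] == 0:
            warnings.warn(f"{path}: transcript {tid!r} has no CDS; skipped")
            continue
        length = spans["exon"] or spans["five_prime_UTR"] + spans["CDS"] + spans["three_prime_UTR"]
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                length=length,
                utr5_len=spans["five_prime_UTR"],
                cds_start=spans["five_prime_UTR"] + 1,
                cds_end=length - spans["three_prime_UTR"],
                utr3_len=spans["three_prime_UTR"],
                upstream_ext=upstream_ext,
            )
        except AnnotationError as exc:
            warnings.warn(f"{path}: skipping transcript {tid!r}: {exc}")
            continue
        models[tid] = model
    return models


def write_transcript_models(models: Mapping[str, TranscriptModel], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MODEL_COLUMNS)
        for m in models.values():
            writer.writerow(
                [m.transcript_id, m.gene_id, m.length, m.utr5_len, m.cds_start, m.cds_end, m.utr3_len, m.biotype]
            )


# ---------------------------------------------------------------------------
# Manifest and profiles
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("library_id", "genotype", "label", "fraction", "replicate", "total_mapped_tags")
_PROFILE_COLUMNS = ("library_id", "transcript_id", "position", "count")

ProfileKey = tuple[str, str]  # (library_id, transcript_id)


def read_manifest(path: Union[str, Path]) -> dict[str, LibraryInfo]:
    """Read a library manifest TSV; enforces manifest uniqueness invariants."""
    libraries: dict[str, LibraryInfo] = {}
    seen_keys: set[tuple[str, str, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise AnnotationError(f"{path}: empty manifest")
        missing = [c for c in _MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise AnnotationError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                lib = LibraryInfo(
                    library_id=row["library_id"],
                    genotype=row["genotype"],
                    label=row["label"],
                    fraction=row["fraction"],
                    replicate=int(row["replicate"]),
                    total_mapped_tags=int(row["total_mapped_tags"]),
                )
            except (TypeError, ValueError) as exc:
                raise AnnotationError(f"{path} line {lineno}: {exc}") from exc
            if lib.library_id in libraries:
                raise AnnotationError(f"{path} line {lineno}: duplicate library_id {lib.library_id!r}")
            key = (lib.genotype, lib.fraction, lib.replicate)
            if key in seen_keys:
                raise AnnotationError(
                    f"{path} line {lineno}: duplicate (genotype, fraction, replicate) {key}"
                )
            seen_keys.add(key)
            libraries[lib.library_id] = lib
    return libraries


def write_manifest(libraries: Mapping[str, LibraryInfo], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS)
        for lib in libraries.values():
            writer.writerow(
                [lib.library_id, lib.genotype, lib.label, lib.fraction, lib.replicate, lib.total_mapped_tags]
            )


def read_profiles(
    profile_path: Union[str, Path],
    manifest: Union[str, Path, Mapping[str, LibraryInfo]],
    models: Mapping[str, TranscriptModel],
) -> tuple[dict[ProfileKey, DegradomeProfile], dict[str, LibraryInfo]]:
    """Read a tag-count profile TSV against a manifest and transcript models.

    Duplicate (library, transcript, position) rows are summed.  Rows with an
    unknown library or an out-of-range position raise :class:`ProfileError`
    naming the offending row; rows for transcripts absent from ``models`` are
    skipped with a warning (they cannot be range-checked).
    """
    if isinstance(manifest, (str, Path)):
        libraries = read_manifest(manifest)
    else:
        libraries = dict(manifest)

    counts: dict[ProfileKey, dict[int, int]] = {}
    unknown_tx: set[str] = set()
    with open(profile_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return {}, libraries
        missing = [c for c in _PROFILE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ProfileError(f"{profile_path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            lib_id = row["library_id"]
            if lib_id not in libraries:
                raise ProfileError(
                    f"{profile_path} line {lineno}: unknown library_id {lib_id!r} (not in manifest)"
                )
            tid = row["transcript_id"]
            try:
                position = int(row["position"])
                count = int(row["count"])
            except (TypeError, ValueError) as exc:
                raise ProfileError(f"{profile_path} line {lineno}: malformed row: {exc}") from exc
            model = models.get(tid)
            if model is None:
                if tid not in unknown_tx:
                    warnings.warn(
                        f"{profile_path}: transcript {tid!r} not in annotation; rows skipped"
                    )
                    unknown_tx.add(tid)
                continue
            if position == 0 or not model.contains(position):
                raise ProfileError(
                    f"{profile_path} line {lineno}: transcript {tid}, position {position} "
                    f"outside [-{model.upstream_ext}, -1] U [1, {model.length}]"
                )
            if count < 0:
                raise ProfileError(
                    f"{profile_path} line {lineno}: negative count {count}"
                )
            if count == 0:
                continue  # absent position means zero; never stored
            key = (lib_id, tid)
            bucket = counts.setdefault(key, {})
            bucket[position] = bucket.get(position, 0) + count

    profiles = {
        key: DegradomeProfile(library_id=key[0], transcript_id=key[1], counts=pos_counts)
        for key, pos_counts in counts.items()
    }
    return profiles, libraries


def write_profiles(
    profiles: Mapping[ProfileKey, DegradomeProfile], path: Union[str, Path]
) -> None:
    """Write profiles as a TSV; deterministic (sorted) row order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PROFILE_COLUMNS)
        for lib_id, tid in sorted(profiles):
            profile = profiles[(lib_id, tid)]
            for pos in sorted(profile.counts):
                writer.writerow([lib_id, tid, pos, profile.counts[pos]])


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: Union[str, Path]) -> set[str]:
    """Read one identifier per line; '#' comment lines and blank lines ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line)
    return genes


def write_gene_list(genes: Iterable[str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(set(genes)):
            fh.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# Optional SAM/BAM adapter (transcriptome alignments)
# ---------------------------------------------------------------------------

def profiles_from_alignments(
    alignment_path: Union[str, Path],
    library_id: str,
    models: Mapping[str, TranscriptModel],
    extension_included: bool = True,
) -> dict[ProfileKey, DegradomeProfile]:
    """Build tag-count profiles from coordinate transcriptome alignments.

    Each primary, forward-strand alignment contributes one tag at its
    5'-most aligned base.  If ``extension_included`` the reference sequences
    are assumed to carry the upstream extension, so reference base 0
    corresponds to transcript position ``-upstream_ext``; otherwise reference
    base 0 is transcript position +1.  This adapter is a convenience; the
    primary input path is the tag-count TSV of :func:`read_profiles`.
    """
    import pysam

    counts: dict[ProfileKey, dict[int, int]] = {}
    with pysam.AlignmentFile(str(alignment_path), "r") as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_reverse:
                continue
            tid = read.reference_name
            model = models.get(tid)
            if model is None:
                continue
            if extension_included:
                g = read.reference_start - model.upstream_ext
                position = axis_from_gapless(g)
            else:
                position = read.reference_start + 1
            if not model.contains(position):
                warnings.warn(
                    f"{alignment_path}: read {read.query_name} maps outside the "
                    f"coordinate frame of {tid} (position {position}); skipped"
                )
                continue
            bucket = counts.setdefault((library_id, tid), {})
            bucket[position] = bucket.get(position, 0) + 1
    return {
        key: DegradomeProfile(library_id=key[0], transcript_id=key[1], counts=c)
        for key, c in counts.items()
    }
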