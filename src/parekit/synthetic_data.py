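"""Synthetic degradome datasets with planted ground truth.

Generates a full study layout -- transcript models, PARE profiles for two WT
replicates and two independent mutant alleles in both polyA+ and polyA-
fractions, C-PARE cap-site libraries, a manifest, planted cleavage sites and
a truth table -- so every pipeline stage is testable without external data.

Planted signal per transcript class:

* ``decapped_substrate`` -- a 5'-end peak at the true cap position in every
  PARE library, amplified ``cap_amplification``-fold in both mutants in the
  substrate's routed polyA fraction (decapped intermediates blocked from
  5'->3' decay);
* ``cleavage_target`` -- a peak at a planted small-RNA cleavage site inside
  the CDS, amplified in mutants in polyA+;
* ``nmd_fragment`` -- a 3'UTR peak mimicking an endonucleolytic NMD
  fragment, amplified in mutants in polyA+;
* ``background`` -- only the weak basal cap peak.

All libraries also receive a low exonucleolytic background ladder across the
transcript body (near-Poisson per position, with a gamma-mixed rate giving
negative-binomial overdispersion), and every transcript gets a dominant
C-PARE peak at its true cap.  Counts are reproducible bit-for-bit from the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation_io import (
    DegradomeProfile,
    LibraryInfo,
    ProfileKey,
    TranscriptModel,
    write_manifest,
    write_profiles,
    write_transcript_models,
)
from .degradome_profiles import TP20M_SCALE

__all__ = [
    "CLASSES",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "null_config",
    "simulate_decay_course",
]

CLASSES = ("decapped_substrate", "cleavage_target", "nmd_fragment", "background")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic degradome generator.

    Defaults define the standard scenario: 2000 transcripts, 8-fold
    amplification of decapped cap peaks in both mutant alleles, roughly
    5e5 profiled tags per library, and mild negative-binomial
    overdispersion of peak counts.  Effect folds of exactly 1 construct a
    null dataset (no genotype effect).
    """

    n_transcripts: int = 2000
    # transcript geometry (nt)
    length_min: int = 400
    length_mode: int = 1500
    length_max: int = 4000
    utr5_frac: float = 0.10
    utr3_frac: float = 0.20
    upstream_ext: int = 100
    # planted class mix (fractions of transcripts; remainder is background)
    frac_decapped: float = 0.15
    frac_cleavage: float = 0.05
    frac_nmd: float = 0.05
    # effect sizes (mutant / WT expected peak ratio; 1 = null)
    cap_amplification: float = 8.0
    fragment_amplification: float = 8.0
    cleavage_amplification: float = 6.0
    # routing: probability a decapped substrate shows its effect in polyA-
    p_route_polya_minus: float = 0.6
    # expected raw tags per peak (per library)
    wt_cap_peak_tags: float = 40.0
    basal_cap_peak_tags: float = 2.0
    fragment_peak_tags: float = 8.0
    cleavage_peak_tags: float = 8.0
    cpare_peak_tags: float = 30.0
    # background ladder (expected tags per kb of transcript body)
    background_rate_per_kb: float = 100.0
    cpare_background_rate_per_kb: float = 5.0
    # negative-binomial dispersion (gamma shape; larger = closer to Poisson)
    dispersion: float = 200.0
    # cap-offset mix: P(precise), P(within +25), P(other)
    cap_offset_mix: tuple[float, float, float] = (0.16, 0.35, 0.49)
    # manifest totals = profiled counts * (1 + unprofiled_frac)
    unprofiled_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if not (0 < self.length_min <= self.length_mode <= self.length_max):
            raise ValueError("length distribution requires min <= mode <= max, all positive")
        class_sum = self.frac_decapped + self.frac_cleavage + self.frac_nmd
        for name in ("frac_decapped", "frac_cleavage", "frac_nmd", "p_route_polya_minus"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if class_sum > 1:
            raise ValueError("planted class fractions must sum to <= 1")
        for name in ("cap_amplification", "fragment_amplification", "cleavage_amplification"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if abs(sum(self.cap_offset_mix) - 1.0) > 1e-9:
            raise ValueError("cap_offset_mix probabilities must sum to 1")
        if any(p < 0 for p in self.cap_offset_mix):
            raise ValueError("cap_offset_mix probabilities must be >= 0")
        if self.unprofiled_frac < 0:
            raise ValueError("unprofiled_frac must be >= 0")
        if self.upstream_ext < 1:
            raise ValueError("upstream_ext must be >= 1")


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same scenario with every genotype effect removed (folds = 1)."""
    return replace(
        config,
        cap_amplification=1.0,
        fragment_amplification=1.0,
        cleavage_amplification=1.0,
    )


# library plan: (genotype, label, replicate, fraction)
_LIBRARY_PLAN: tuple[tuple[str, str, int, str], ...] = tuple(
    [
        (genotype, label, rep, fraction)
        for fraction in ("polyA_plus", "polyA_minus")
        for genotype, label, rep in (
            ("WT", "WT", 1),
            ("WT", "WT", 2),
            ("mutantA", "xrn4-5", 1),
            ("mutantB", "xrn4-6", 1),
        )
    ]
    + [("WT", "WT", 1, "cpare"), ("mutantA", "xrn4-5", 1, "cpare")]
)


def _library_id(label: str, fraction: str, replicate: int) -> str:
    return f"{label}_{fraction}_r{replicate}"


@dataclass
class SimulatedDataset:
    """A complete simulated study: inputs for the pipeline plus planted truth."""

    models: dict[str, TranscriptModel]
    libraries: dict[str, LibraryInfo]
    profiles: dict[ProfileKey, DegradomeProfile]
    truth: pd.DataFrame
    cleavage_sites: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Emit the TSV dialects consumed by the I/O layer, plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "models": outdir / "transcript_models.tsv",
            "manifest": outdir / "manifest.tsv",
            "profiles": outdir / "profiles.tsv",
            "truth": outdir / "truth_table.tsv",
            "cleavage_sites": outdir / "cleavage_sites.tsv",
        }
        write_transcript_models(self.models, paths["models"])
        write_manifest(self.libraries, paths["manifest"])
        write_profiles(self.profiles, paths["profiles"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.cleavage_sites.to_csv(paths["cleavage_sites"], sep="\t", index=False)
        return paths


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """One negative-binomial draw with the given mean and gamma-shape dispersion."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _simulate_models(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, TranscriptModel]:
    models: dict[str, TranscriptModel] = {}
    width = len(str(config.n_transcripts))
    for i in range(config.n_transcripts):
        length = int(rng.triangular(config.length_min, config.length_mode, config.length_max))
        utr5 = max(20, int(length * config.utr5_frac * rng.uniform(0.6, 1.4)))
        utr3 = max(60, int(length * config.utr3_frac * rng.uniform(0.6, 1.4)))
        if length - utr5 - utr3 < 90:  # keep a sensible CDS on short transcripts
            utr5 = max(1, int(0.10 * length))
            utr3 = max(1, int(0.20 * length))
        tid = f"TX{i + 1:0{width}d}"
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{i + 1:0{width}d}",
            length=length,
            utr5_len=utr5,
            cds_start=utr5 + 1,
            cds_end=length - utr3,
            utr3_len=utr3,
            upstream_ext=config.upstream_ext,
        )
    return models


def _draw_cap_position(
    model: TranscriptModel, config: SimulationConfig, rng: np.random.Generator
) -> int:
    kind = rng.choice(3, p=np.asarray(config.cap_offset_mix))
    if kind == 0:  # precise: exactly the annotated TSS
        return 1
    if kind == 1:  # within +25 nt downstream
        return int(rng.integers(2, 27))
    # other: upstream of the TSS or far downstream, split evenly
    if rng.random() < 0.5:
        return -int(rng.integers(1, min(60, model.upstream_ext) + 1))
    return int(rng.integers(27, min(100, model.length) + 1))


def _draw_planted_site(
    klass: str, model: TranscriptModel, cap: int, rng: np.random.Generator
) -> Optional[int]:
    if klass == "cleavage_target":
        lo = model.cds_start + 10
        hi = model.cds_end - 10
        if hi <= lo:
            lo, hi = model.cds_start, model.cds_end
        site = int(rng.integers(lo, hi + 1))
    elif klass == "nmd_fragment":
        site = int(rng.integers(model.cds_end + 1, model.length + 1))
    else:
        return None
    if site == cap:  # fragments must not coincide with the cap site
        site = site + 1 if site < model.length else site - 1
    return site


def simulate_dataset(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """Generate a complete degradome study with planted ground truth.

    Fully reproducible: the same config (including seed) yields bit-identical
    profiles, manifest totals and truth table.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    models = _simulate_models(config, rng)

    # class assignment
    p_background = 1.0 - (config.frac_decapped + config.frac_cleavage + config.frac_nmd)
    klasses = rng.choice(
        len(CLASSES),
        size=config.n_transcripts,
        p=[config.frac_decapped, config.frac_cleavage, config.frac_nmd, p_background],
    )

    counts: dict[ProfileKey, dict[int, int]] = {}

    def add(lib_id: str, tid: str, position: int, count: int) -> None:
        if count <= 0:
            return
        bucket = counts.setdefault((lib_id, tid), {})
        bucket[position] = bucket.get(position, 0) + count

    truth_rows: list[dict[str, object]] = []
    cleavage_rows: list[dict[str, object]] = []

    pare_libs = [(g, lab, rep, fr) for g, lab, rep, fr in _LIBRARY_PLAN if fr != "cpare"]
    cpare_libs = [(g, lab, rep, fr) for g, lab, rep, fr in _LIBRARY_PLAN if fr == "cpare"]

    for tid, klass_idx in zip(models, klasses):
        model = models[tid]
        klass = CLASSES[klass_idx]
        cap = _draw_cap_position(model, config, rng)
        site = _draw_planted_site(klass, model, cap, rng)
        routed = None
        if klass == "decapped_substrate":
            routed = "polyA_minus" if rng.random() < config.p_route_polya_minus else "polyA_plus"
        elif klass in ("cleavage_target", "nmd_fragment"):
            routed = "polyA_plus"

        # expected peak tags at the planted positions
        if klass == "decapped_substrate":
            wt_cap_mean = config.wt_cap_peak_tags
        else:
            wt_cap_mean = config.basal_cap_peak_tags
        site_mean = {
            "cleavage_target": config.cleavage_peak_tags,
            "nmd_fragment": config.fragment_peak_tags,
        }.get(klass, 0.0)
        site_fold = {
            "cleavage_target": config.cleavage_amplification,
            "nmd_fragment": config.fragment_amplification,
        }.get(klass, 1.0)

        for genotype, label, rep, fraction in pare_libs:
            lib_id = _library_id(label, fraction, rep)
            # background ladder over the transcript body, gamma-mixed rate
            gamma = rng.gamma(config.dispersion, 1.0 / config.dispersion)
            lam = config.background_rate_per_kb * model.length / 1000.0 * gamma
            n_bg = int(rng.poisson(lam))
            if n_bg:
                for pos in rng.integers(1, model.length + 1, size=n_bg):
                    add(lib_id, tid, int(pos), 1)
            # cap peak
            cap_mean = wt_cap_mean
            if (
                klass == "decapped_substrate"
                and genotype in ("mutantA", "mutantB")
                and fraction == routed
            ):
                cap_mean = wt_cap_mean * config.cap_amplification
            add(lib_id, tid, cap, _nb_count(rng, cap_mean, config.dispersion))
            # planted body site (cleavage / NMD fragment), polyA+ only
            if site is not None and fraction == "polyA_plus":
                mean = site_mean
                if genotype in ("mutantA", "mutantB"):
                    mean = site_mean * site_fold
                add(lib_id, tid, site, _nb_count(rng, mean, config.dispersion))

        # C-PARE: dominant cap peak on every transcript plus a sparse ladder
        for genotype, label, rep, fraction in cpare_libs:
            lib_id = _library_id(label, fraction, rep)
            add(lib_id, tid, cap, _nb_count(rng, config.cpare_peak_tags, config.dispersion))
            lam = config.cpare_background_rate_per_kb * model.length / 1000.0
            n_bg = int(rng.poisson(lam))
            if n_bg:
                for pos in rng.integers(1, model.length + 1, size=n_bg):
                    add(lib_id, tid, int(pos), 1)

        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": model.gene_id,
                "klass": klass,
                "cap_position": cap,
                "planted_site": site if site is not None else pd.NA,
                "routed_fraction": routed if routed is not None else "",
                "wt_peak_tags": wt_cap_mean if klass == "decapped_substrate" else site_mean,
                "mutant_peak_tags": (
                    wt_cap_mean * config.cap_amplification
                    if klass == "decapped_substrate"
                    else site_mean * site_fold
                ),
            }
        )
        if klass == "cleavage_target":
            cleavage_rows.append(
                {"transcript_id": tid, "position": site, "guide": "synthetic-miR"}
            )

    # manifest: totals are profiled counts plus the unprofiled remainder
    libraries: dict[str, LibraryInfo] = {}
    for genotype, label, rep, fraction in _LIBRARY_PLAN:
        lib_id = _library_id(label, fraction, rep)
        profiled = sum(
            sum(c.values()) for (lid, _), c in counts.items() if lid == lib_id
        )
        total = profiled + int(round(config.unprofiled_frac * profiled))
        libraries[lib_id] = LibraryInfo(
            library_id=lib_id,
            genotype=genotype,
            label=label,
            fraction=fraction,
            replicate=rep,
            total_mapped_tags=max(total, 1),
        )

    profiles = {
        key: DegradomeProfile(library_id=key[0], transcript_id=key[1], counts=c)
        for key, c in counts.items()
        if c
    }
    for (lib_id, tid), profile in profiles.items():
        profile.validate_against(models[tid])

    truth = pd.DataFrame(truth_rows)
    # expected mutant TP20M at the planted peak, given realized library depths
    for mutant_label, column in (("xrn4-5", "expected_tp20m_mutantA"), ("xrn4-6", "expected_tp20m_mutantB")):
        scale = {}
        for fraction in ("polyA_plus", "polyA_minus"):
            lib = libraries[_library_id(mutant_label, fraction, 1)]
            scale[fraction] = TP20M_SCALE / lib.total_mapped_tags
        truth[column] = [
            row["mutant_peak_tags"] * scale[row["routed_fraction"]]
            if row["routed_fraction"] in scale
            else float("nan")
            for row in truth_rows
        ]

    cleavage_sites = pd.DataFrame(cleavage_rows, columns=["transcript_id", "position", "guide"])
    return SimulatedDataset(
        models=models,
        libraries=libraries,
        profiles=profiles,
        truth=truth,
        cleavage_sites=cleavage_sites,
        config=config,
    )


def simulate_decay_course(
    k_decay: float,
    timepoints: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0),
    cv: float = 0.05,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[float, float]:
    """Exponential-decay abundances with multiplicative lognormal noise.

    ``abundance(t) = exp(-k t) * eps_t`` where ``eps_t`` is lognormal with
    unit mean and coefficient of variation ``cv`` (``cv = 0`` is noiseless).
    The first timepoint must be 0 so downstream fits can renormalize.
    """
    if k_decay < 0:
        raise ValueError("k_decay must be >= 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    timepoints = tuple(float(t) for t in timepoints)
    if not timepoints or timepoints[0] != 0.0:
        raise ValueError("timepoints must start at 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(timepoints))
    else:
        noise = np.ones(len(timepoints))
    return {
        t: math.exp(-k_decay * t) * float(eps) for t, eps in zip(timepoints, noise)
    }
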