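"""Monte-Carlo set-overlap testing (GeneSect-style).

Tests whether two gene sets drawn from a common universe share more members
than expected by chance.  For each permutation two uniform random subsets of
the universe are drawn, matching the observed set sizes, and their
intersection size recorded; the observed overlap is summarized as a z-score
against the permutation distribution and as an add-one empirical p-value.
Under this null the expected overlap is the hypergeometric mean
``|A| * |B| / N``, which pins the implementation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

__all__ = [
    "OverlapResult",
    "overlap_test",
    "overlap_report",
    "significance_stars",
]


@dataclass(frozen=True)
class OverlapResult:
    """Observed intersection size with its Monte-Carlo null summary."""

    universe_size: int
    size_a: int
    size_b: int
    observed_overlap: int
    perm_mean: float
    perm_sd: float
    z_score: Optional[float]  # undefined (None) when perm_sd == 0
    empirical_p: float
    n_permutations: int
    seed: int


def overlap_test(
    set_a: Set[str],
    set_b: Set[str],
    universe: Set[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Monte-Carlo overlap test of two gene sets within a stated universe.

    Elements of either set outside the universe are dropped with a warning.
    Both sets are re-sampled each permutation (a symmetric null); the
    empirical p-value uses the add-one rule
    ``(1 + #{perm >= observed}) / (n + 1)`` so it is never exactly zero.
    Results are bit-reproducible for a fixed seed.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    universe_list = sorted(universe)
    n = len(universe_list)
    if n == 0:
        raise ValueError("universe must be non-empty")

    dropped_a = set(set_a) - universe
    dropped_b = set(set_b) - universe
    if dropped_a or dropped_b:
        warnings.warn(
            f"dropping elements outside the universe: {len(dropped_a)} from set A, "
            f"{len(dropped_b)} from set B"
        )
    set_a = set(set_a) & universe
    set_b = set(set_b) & universe
    size_a, size_b = len(set_a), len(set_b)
    if size_a > n or size_b > n:
        raise ValueError("set sizes exceed the universe size")
    observed = len(set_a & set_b)

    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_permutations, dtype=np.int64)
    indicator = np.zeros(n, dtype=bool)
    for i in range(n_permutations):
        a_idx = rng.choice(n, size=size_a, replace=False)
        b_idx = rng.choice(n, size=size_b, replace=False)
        indicator[a_idx] = True
        overlaps[i] = int(indicator[b_idx].sum())
        indicator[a_idx] = False

    perm_mean = float(overlaps.mean())
    perm_sd = float(overlaps.std(ddof=1)) if n_permutations > 1 else 0.0
    z_score = (observed - perm_mean) / perm_sd if perm_sd > 0 else None
    empirical_p = (1 + int((overlaps >= observed).sum())) / (n_permutations + 1)

    return OverlapResult(
        universe_size=n,
        size_a=size_a,
        size_b=size_b,
        observed_overlap=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z_score=z_score,
        empirical_p=empirical_p,
        n_permutations=n_permutations,
        seed=seed,
    )


def significance_stars(p: float) -> str:
    """Per-comparison significance stars: '**' for p < 0.01, '***' for p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def overlap_report(
    results: Sequence[OverlapResult],
    labels: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Tabulate overlap results with significance stars (no multiplicity correction)."""
    if labels is None:
        labels = [f"comparison_{i}" for i in range(len(results))]
    labels = list(labels)
    if len(labels) != len(results):
        raise ValueError("labels and results must have equal length")
    rows = []
    for label, r in zip(labels, results):
        rows.append(
            {
                "label": label,
                "universe_size": r.universe_size,
                "size_a": r.size_a,
                "size_b": r.size_b,
                "observed_overlap": r.observed_overlap,
                "perm_mean": r.perm_mean,
                "perm_sd": r.perm_sd,
                "z_score": r.z_score if r.z_score is not None else float("nan"),
                "empirical_p": r.empirical_p,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
                "stars": significance_stars(r.empirical_p),
            }
        )
    return pd.DataFrame(rows)
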