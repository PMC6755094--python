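"""mRNA half-life regression and two small spectrophotometric/qPCR assay formulas.

Half-lives come from transcriptional-shutoff (e.g. cordycepin chase) time
courses: abundances are normalized to t = 0, log-transformed, and fit by
ordinary least squares against time.  The decay rate is the negative slope
and ``t_1/2 = ln(2) / k_decay`` (the familiar 0.693/k; full-precision ln 2
is used in computation).  A transcript whose fitted slope is non-negative
(stable or growing signal) gets an infinite half-life rather than a
negative one.

Also provided: total chlorophyll a+b from OD652/OD665 readings, and the
2^-ddCt method for relative qRT-PCR quantification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitError",
    "DecayFit",
    "fit_decay",
    "fit_decay_table",
    "classify_stabilized",
    "chlorophyll_content",
    "ddct_fold_change",
]

DEFAULT_TIMEPOINTS = (0.0, 15.0, 30.0, 60.0)  # minutes; typical shutoff sampling


class FitError(ValueError):
    """Raised when a decay fit is refused (too few usable points)."""


@dataclass(frozen=True)
class DecayFit:
    """Log-linear decay fit for one transcript in one genotype."""

    transcript_id: str
    genotype: str
    k_decay: float  # per minute
    t_half: float  # minutes; inf when k_decay <= 0
    r_squared: float
    n_points: int
    timepoints: tuple[float, ...]


def fit_decay(
    abundances: Mapping[float, float],
    transcript_id: str = "",
    genotype: str = "",
) -> DecayFit:
    """OLS fit of ln(abundance) on time; k_decay = -slope.

    Abundances are renormalized to the t = 0 value internally, so raw band
    or qPCR intensities may be passed directly.  Points with non-positive
    abundance are excluded (they have no logarithm) with a warning; if fewer
    than three usable points remain the fit is refused with a diagnostic.
    """
    if 0.0 not in {float(t) for t in abundances}:
        raise FitError(f"{transcript_id or 'fit'}: a t=0 abundance is required")
    items = sorted((float(t), float(a)) for t, a in abundances.items())
    a0 = dict(items)[0.0]
    if a0 <= 0:
        raise FitError(f"{transcript_id or 'fit'}: t=0 abundance must be positive")

    used_t: list[float] = []
    used_y: list[float] = []
    for t, a in items:
        if a <= 0:
            warnings.warn(
                f"{transcript_id or 'fit'}: non-positive abundance at t={t:g} excluded"
            )
            continue
        used_t.append(t)
        used_y.append(math.log(a / a0))
    if len(used_t) < 3:
        raise FitError(
            f"{transcript_id or 'fit'}: only {len(used_t)} usable timepoints "
            f"(>= 3 required); fit refused"
        )

    t_arr = np.asarray(used_t)
    y_arr = np.asarray(used_y)
    if np.allclose(y_arr, y_arr[0]):
        # perfectly flat signal: zero decay, and the constant model is exact
        slope, r_squared = 0.0, 1.0
    else:
        result = stats.linregress(t_arr, y_arr)
        slope = float(result.slope)
        r_squared = float(result.rvalue) ** 2

    k_decay = -slope
    t_half = math.log(2) / k_decay if k_decay > 0 else math.inf
    return DecayFit(
        transcript_id=transcript_id,
        genotype=genotype,
        k_decay=k_decay,
        t_half=t_half,
        r_squared=r_squared,
        n_points=len(used_t),
        timepoints=tuple(used_t),
    )


def fit_decay_table(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Fit every (transcript, genotype) group of a long-format time-course table.

    Expects columns transcript_id, genotype, timepoint_min, abundance.
    Groups whose fit is refused are reported with NaN estimates and the
    refusal message in the ``note`` column.
    """
    required = {"transcript_id", "genotype", "timepoint_min", "abundance"}
    missing = required - set(timecourse.columns)
    if missing:
        raise ValueError(f"time-course table missing columns {sorted(missing)}")
    rows = []
    for (tid, genotype), group in timecourse.groupby(["transcript_id", "genotype"], sort=True):
        abundances = dict(zip(group["timepoint_min"].astype(float), group["abundance"].astype(float)))
        try:
            fit = fit_decay(abundances, transcript_id=str(tid), genotype=str(genotype))
            rows.append(
                {
                    "transcript_id": tid,
                    "genotype": genotype,
                    "k_decay_per_min": fit.k_decay,
                    "t_half_min": fit.t_half,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "note": "",
                }
            )
        except FitError as exc:
            rows.append(
                {
                    "transcript_id": tid,
                    "genotype": genotype,
                    "k_decay_per_min": float("nan"),
                    "t_half_min": float("nan"),
                    "r_squared": float("nan"),
                    "n_points": 0,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)


def classify_stabilized(
    fit_reference: Optional[DecayFit],
    fit_test: Optional[DecayFit],
    max_ref_thalf: float = 240.0,
    min_ratio: float = 1.5,
) -> str:
    """Classify a transcript as stabilized in a test condition vs. a reference.

    Only transcripts with a reference half-life of at most ``max_ref_thalf``
    minutes are evaluated (very stable transcripts are excluded -- their
    shutoff time courses are uninformative).  ``stabilized`` means the test
    half-life is at least ``min_ratio`` times the reference half-life.
    Either fit being refused (None) also yields ``excluded``.
    """
    if fit_reference is None or fit_test is None:
        return "excluded"
    if fit_reference.t_half > max_ref_thalf:
        return "excluded"
    ratio = fit_test.t_half / fit_reference.t_half
    return "stabilized" if ratio >= min_ratio else "not_stabilized"


def chlorophyll_content(
    od652: float,
    od665: float,
    dilution_factor: float = 1.0,
    fresh_weight_g: float = 1.0,
    extract_ml: float = 1.0,
) -> tuple[float, float]:
    """Total chlorophyll a+b from methanol-extract absorbances.

    ug/ml = (22.12 * OD652 + 2.71 * OD665) * dilution_factor, and per gram
    fresh weight = ug/ml * extract_ml / fresh_weight_g.  Returns the pair
    (ug_per_ml, ug_per_g_fresh_weight).
    """
    if od652 < 0 or od665 < 0:
        raise ValueError("optical densities must be >= 0")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    if fresh_weight_g <= 0 or extract_ml <= 0:
        raise ValueError("fresh weight and extract volume must be > 0")
    ug_per_ml = (22.12 * od652 + 2.71 * od665) * dilution_factor
    ug_per_g = ug_per_ml * extract_ml / fresh_weight_g
    return ug_per_ml, ug_per_g


def ddct_fold_change(
    ct_target_test: float,
    ct_norm_test: float,
    ct_target_ctrl: float,
    ct_norm_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_norm,test) - (Ct_target,ctrl - Ct_norm,ctrl);
    one cycle of earlier amplification doubles the estimate.
    """
    for value in (ct_target_test, ct_norm_test, ct_target_ctrl, ct_norm_ctrl):
        if not math.isfinite(value):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_norm_test) - (ct_target_ctrl - ct_norm_ctrl)
    return 2.0 ** (-ddct)
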