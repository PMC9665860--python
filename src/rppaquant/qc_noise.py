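"""Per-slide noise quality control from technical replicates.

Technical replicates are repeated dilution series of one common sample
printed across the slide.  They share one true concentration, so the spread
of their estimated log2 concentrations cannot be biological and measures the
slide's random measurement error.  The noise metric is the sample standard
deviation (n-1 denominator) of the replicate estimates, on the same
log2-concentration scale as the sample output, so slides and antibodies are
directly comparable.  The replicate mean expression is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NoiseReport", "compute_noise", "noise_expression_independence"]

#: Flags that disqualify a replicate estimate from the noise metric.
_DISQUALIFYING = {"Saturated", "BelowDetection"}


@dataclass(frozen=True)
class NoiseReport:
    """Per-slide noise metric on the log2-concentration scale."""

    antibody_name: str
    n_replicates: int
    noise_sd: float  #: sample SD of replicate estimates; NaN if n < 2
    replicate_mean: float
    scale: str = "log2-concentration"


def compute_noise(estimates, antibody_name: str = ""):
    """Noise metric from the concentration estimates of replicate series.

    ``estimates`` are :class:`~rppaquant.curve_model.ConcentrationEstimate`
    objects restricted to technical-replicate (``NoiseRep``) series.
    Estimates flagged ``Saturated`` or ``BelowDetection`` sit at the curve's
    asymptotes where position is not identifiable; they are dropped with a
    warning.

    Returns ``(NoiseReport | None, [warning, ...])``: ``None`` when no
    usable replicate remains, a report with ``noise_sd = NaN`` when only one
    does.
    """
    warnings: list[str] = []
    usable = []
    for est in estimates:
        bad = est.flags & _DISQUALIFYING
        if bad:
            warnings.append(
                f"replicate {est.series_id} excluded from noise metric "
                f"(flags: {', '.join(sorted(bad))})"
            )
        elif math.isfinite(est.x):
            usable.append(est.x)

    n = len(usable)
    if n == 0:
        warnings.append("no usable technical replicates; noise metric unavailable")
        return None, warnings
    if n == 1:
        warnings.append(
            "only one usable technical replicate; noise SD undefined (NA)"
        )
        return (
            NoiseReport(antibody_name, 1, float("nan"), float(usable[0])),
            warnings,
        )
    arr = np.asarray(usable)
    return (
        NoiseReport(
            antibody_name,
            n,
            float(np.std(arr, ddof=1)),
            float(np.mean(arr)),
        ),
        warnings,
    )


def noise_expression_independence(reports):
    """Correlation between slide noise and replicate expression level.

    A purely descriptive check across slides of a batch: a low Pearson
    correlation between the noise metric and the replicate mean expression
    supports using one per-slide noise value regardless of expression level.

    Returns ``(r, n, [warning, ...])``; ``r`` is NaN with a warning when
    fewer than 3 valid slide reports exist or either variable has zero
    variance.
    """
    warnings: list[str] = []
    pairs = [
        (rep.noise_sd, rep.replicate_mean)
        for rep in reports
        if rep is not None and math.isfinite(rep.noise_sd) and math.isfinite(rep.replicate_mean)
    ]
    n = len(pairs)
    if n < 3:
        warnings.append(
            f"noise-vs-expression correlation needs >= 3 slides, got {n}"
        )
        return float("nan"), n, warnings
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.append(
            "noise-vs-expression correlation undefined: zero variance"
        )
        return float("nan"), n, warnings
    r, _ = stats.pearsonr(x, y)
    return float(r), n, warnings
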