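"""Spatial bias correction of slide intensities using technical replicates.

Printing, staining and scanning can impose a smooth position-dependent
multiplicative bias on spot intensity across the slide surface.  Because
technical-replicate control spots at a common dilution step should all read
the same, their log2 deviation from the step-wise trimmed mean exposes that
bias.  The deviations are smoothed over the physical grid with a local linear
(loess-style) regression using tricube weights, exponentiated to a
multiplicative surface m(r, c), clamped and median-centered so that the
correction redistributes intensity without changing the slide's overall
level.  Every spot is then divided by m at its position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import stats

from .slide_io import Slide, SlideDesign

__all__ = ["SpatialSurface", "fit_spatial_surface", "apply_spatial_adjustment"]

#: Spot types usable as replicate controls for surface estimation.
DEFAULT_CONTROL_TYPES = frozenset({"NoiseRep", "PosCtrl"})


@dataclass
class SpatialSurface:
    """Multiplicative correction surface over the flattened physical grid."""

    m: np.ndarray  #: (n_rows, n_cols) corrections, median 1, clamped
    span: float
    n_controls_used: int
    control_rmse_before: float  #: RMSE of control log2 deviations pre-correction
    control_rmse_after: float
    warnings: list = field(default_factory=list)

    def correction_at(self, r: int, c: int) -> float:
        """Correction at 1-based physical grid position (r, c)."""
        return float(self.m[r - 1, c - 1])

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.m == 1.0))


def _identity_surface(shape, span, n_controls, warnings):
    return SpatialSurface(
        m=np.ones(shape),
        span=span,
        n_controls_used=n_controls,
        control_rmse_before=float("nan"),
        control_rmse_after=float("nan"),
        warnings=warnings,
    )


def _loess2d(points: np.ndarray, values: np.ndarray, nodes: np.ndarray, span: float) -> np.ndarray:
    """Local linear regression with tricube weights on scattered 2-D points.

    For each query node the nearest ``ceil(span * n)`` control points (at
    least 6, for a stable planar fit) are weighted by tricube distance decay
    and a weighted plane is fitted and evaluated at the node.
    """
    n = len(points)
    k = max(min(n, int(math.ceil(span * n))), min(n, 6))
    out = np.empty(len(nodes))
    for qi, q in enumerate(nodes):
        d = np.hypot(points[:, 0] - q[0], points[:, 1] - q[1])
        idx = np.argpartition(d, k - 1)[:k]
        dk = d[idx]
        dmax = dk.max()
        if dmax <= 0:
            out[qi] = float(np.mean(values[idx]))
            continue
        w = (1.0 - (dk / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        X = np.column_stack([np.ones(k), points[idx, 0] - q[0], points[idx, 1] - q[1]])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], values[idx] * sw, rcond=None)
        out[qi] = coef[0]
    return out


def fit_spatial_surface(
    slide: Slide,
    design: SlideDesign,
    span: float = 0.75,
    min_controls: int = 10,
    clamp: tuple[float, float] = (0.25, 4.0),
    trim: float = 0.1,
    control_types=DEFAULT_CONTROL_TYPES,
    control_dilution_step: int | None = None,
) -> SpatialSurface:
    """Estimate the multiplicative bias surface from replicate control spots.

    Controls are the replicate spots at one common dilution step — by
    default the most concentrated step present, whose intensities carry the
    highest signal-to-noise on the log scale.  Each control's deviation is
    ``log2(observed) - log2(trimmed mean of all controls at that step)``;
    deviations are smoothed over the grid, exponentiated, clamped to
    ``clamp`` and centered to median 1.  With fewer than ``min_controls``
    usable controls an identity surface is returned with a warning;
    controls confined to under a quarter of the grid area attach a coverage
    warning.
    """
    shape = design.grid_shape
    warnings: list[str] = []

    by_step: dict[int, list] = {}
    for rec in slide.records:
        if rec.spot_type in control_types and np.isfinite(rec.net_intensity) and rec.net_intensity > 0:
            by_step.setdefault(rec.dilution_step, []).append(rec)

    points, deltas = [], []
    if by_step:
        step = (
            control_dilution_step
            if control_dilution_step is not None
            else min(by_step)
        )
        recs = by_step.get(step, [])
        if len(recs) >= 3:
            logs = np.log2([r.net_intensity for r in recs])
            center = stats.trim_mean(logs, trim)
            for rec, lv in zip(recs, logs):
                r, c = design.physical_position(rec)
                points.append((r, c))
                deltas.append(lv - center)

    n_controls = len(points)
    if n_controls < min_controls:
        warnings.append(
            f"spatial adjustment skipped: only {n_controls} usable control "
            f"spots (minimum {min_controls}); identity surface returned"
        )
        return _identity_surface(shape, span, n_controls, warnings)

    points = np.asarray(points, dtype=float)
    deltas = np.asarray(deltas, dtype=float)

    bbox_area = np.ptp(points[:, 0]) * np.ptp(points[:, 1])
    if bbox_area < 0.25 * (shape[0] - 1) * (shape[1] - 1):
        warnings.append(
            "control spots cover less than 25% of the grid area; "
            "spatial surface may extrapolate"
        )

    rr, cc = np.meshgrid(
        np.arange(1, shape[0] + 1), np.arange(1, shape[1] + 1), indexing="ij"
    )
    nodes = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    smoothed = _loess2d(points, deltas, nodes, span).reshape(shape)

    m = np.exp2(smoothed)
    m = np.clip(m, clamp[0], clamp[1])
    m = m / np.median(m)

    m_at_controls = np.array(
        [m[int(p[0]) - 1, int(p[1]) - 1] for p in points]
    )
    rmse_before = float(np.sqrt(np.mean(deltas**2)))
    rmse_after = float(np.sqrt(np.mean((deltas - np.log2(m_at_controls)) ** 2)))

    return SpatialSurface(
        m=m,
        span=span,
        n_controls_used=n_controls,
        control_rmse_before=rmse_before,
        control_rmse_after=rmse_after,
        warnings=warnings,
    )


def apply_spatial_adjustment(slide: Slide, surface: SpatialSurface, design: SlideDesign) -> Slide:
    """Divide every spot's net intensity by the surface at its position.

    Raw and background intensities are left untouched; the adjustment is
    recorded in the slide's provenance.  Applying an identity surface
    returns an identical slide.
    """
    if surface.is_identity:
        out = Slide(
            antibody_name=slide.antibody_name,
            records=list(slide.records),
            warnings=list(slide.warnings),
            design=slide.design,
            provenance=slide.provenance + ["spatial: identity surface (no-op)"],
        )
        return out

    new_records = []
    for rec in slide.records:
        r, c = design.physical_position(rec)
        m = surface.correction_at(r, c)
        new_records.append(dc_replace(rec, net_intensity=rec.net_intensity / m))
    return Slide(
        antibody_name=slide.antibody_name,
        records=new_records,
        warnings=list(slide.warnings),
        design=slide.design,
        provenance=slide.provenance
        + [f"spatial: multiplicative surface applied (span={surface.span:g}, "
           f"controls={surface.n_controls_used})"],
    )
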