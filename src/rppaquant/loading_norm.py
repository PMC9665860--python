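"""Protein-loading normalization of the samples x antibodies matrix.

After quantitation, differences in the total protein amount deposited per
sample appear as a sample-specific additive offset on the log2-concentration
scale, shared across antibodies.  Three corrections are offered:

``none``
    Pass-through, for users applying their own downstream correction.
``median_centering``
    Subtract each sample's cross-antibody median, then restore the grand
    median so the matrix keeps its overall level.
``median_polish_loading``
    Tukey two-way median polish; only the fitted row (sample loading)
    effects are removed, antibody (column) effects are retained.  The polish
    is iterated to a fixed point so reapplying the correction is a no-op.

All methods are NA-aware (medians ignore NA; an NA cell stays NA) and
permutation-equivariant in both axes.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConcentrationMatrix",
    "normalize_none",
    "normalize_median_centering",
    "normalize_median_polish_loading",
    "NORMALIZERS",
    "normalize",
]


@dataclass
class ConcentrationMatrix:
    """Samples x antibodies matrix of log2 concentrations (NaN = missing)."""

    values: np.ndarray
    sample_ids: tuple
    antibody_names: tuple
    normalization_applied: str = "none"
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = tuple(self.sample_ids)
        self.antibody_names = tuple(self.antibody_names)
        if self.values.shape != (len(self.sample_ids), len(self.antibody_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.antibody_names)} antibodies"
            )


def normalize_none(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Bit-identical pass-through tagged ``none``."""
    return replace(
        matrix,
        values=matrix.values.copy(),
        normalization_applied="none",
        warnings=list(matrix.warnings),
    )


def _nanmedian(a, axis=None):
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmedian(a, axis=axis)


def normalize_median_centering(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Remove per-sample loading offsets by median centering.

    Each sample row is shifted so its cross-antibody median equals the grand
    median of all per-sample medians; rows that are entirely NA pass through
    with a warning.
    """
    if len(matrix.antibody_names) < 2:
        raise ValueError("median centering needs at least 2 antibodies")
    v = matrix.values.copy()
    row_med = _nanmedian(v, axis=1)
    warnings = list(matrix.warnings)
    all_na = ~np.isfinite(row_med)
    for i in np.flatnonzero(all_na):
        warnings.append(
            f"sample {matrix.sample_ids[i]}: all antibodies NA; row passed through"
        )
    grand = _nanmedian(row_med)
    shift = np.where(all_na, 0.0, row_med - grand)
    v = v - shift[:, None]
    return replace(
        matrix, values=v, normalization_applied="median_centering", warnings=warnings
    )


def _polish_row_effects(v: np.ndarray, max_iter: int, tol: float):
    """Row effects of one converged Tukey median polish (NA-aware).

    Row sweeps come first, so the fitted row effects absorb both the sample
    loading offsets and the shared column-median level; column effects stay
    with the matrix.
    """
    resid = v.copy()
    row = np.zeros(v.shape[0])
    col = np.zeros(v.shape[1])
    converged = False
    for _ in range(max_iter):
        rmed = _nanmedian(resid, axis=1)
        rmed = np.where(np.isfinite(rmed), rmed, 0.0)
        resid -= rmed[:, None]
        row += rmed
        cmed = _nanmedian(resid, axis=0)
        cmed = np.where(np.isfinite(cmed), cmed, 0.0)
        resid -= cmed[None, :]
        col += cmed
        delta = max(np.max(np.abs(rmed)), np.max(np.abs(cmed)))
        if delta < tol:
            converged = True
            break
    return row, converged


def normalize_median_polish_loading(
    matrix: ConcentrationMatrix, max_iter: int = 50, tol: float = 1e-10
) -> ConcentrationMatrix:
    """Remove sample loading effects estimated by two-way median polish.

    Row (sample) effects from a converged median polish are subtracted;
    column (antibody) effects remain in the matrix.  Removal is iterated to
    a fixed point — each pass re-polishes and removes any residual row
    effects — so applying the method twice equals applying it once.
    Non-convergence within the iteration budget returns the last iterate
    with a warning.
    """
    if len(matrix.sample_ids) < 2 or len(matrix.antibody_names) < 2:
        raise ValueError("median polish needs at least 2 samples and 2 antibodies")
    v = matrix.values.copy()
    warnings = list(matrix.warnings)
    converged_outer = False
    for _ in range(max_iter):
        row, _conv_inner = _polish_row_effects(v, max_iter, tol)
        v = v - row[:, None]
        if np.max(np.abs(row)) < tol:
            converged_outer = True
            break
    if not converged_outer:
        warnings.append(
            "median polish did not fully converge; last iterate returned"
        )
    return replace(
        matrix,
        values=v,
        normalization_applied="median_polish_loading",
        warnings=warnings,
    )


NORMALIZERS = {
    "none": normalize_none,
    "median_centering": normalize_median_centering,
    "median_polish_loading": normalize_median_polish_loading,
}


def normalize(matrix: ConcentrationMatrix, method: str) -> ConcentrationMatrix:
    """Apply a registered loading normalization by name."""
    try:
        fn = NORMALIZERS[method]
    except KeyError:
        raise ValueError(
            f"unknown loading normalization {method!r}; "
            f"choose from {sorted(NORMALIZERS)}"
        ) from None
    return fn(matrix)
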