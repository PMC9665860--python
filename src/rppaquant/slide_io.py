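"""Reading, validation and writing of per-antibody RPPA spot quantification files.

An RPPA slide is a grid of printed spots organised as main grids and sub-grids.
Each biological sample (and each control) is printed as a *dilution series*:
several spots of the same lysate at serially decreasing concentrations. One
tab-delimited quantification file per antibody carries, for every spot, its
grid coordinates, the series it belongs to, its spot type, the declared
relative concentration of its dilution step and the scanner intensities.

The slide *design* (grid dimensions, dilution ladder, series roster, spot-type
map) is not supplied separately: it is inferred from the first valid file of a
batch and every subsequent slide is validated against it.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpotRecord",
    "SlideDesign",
    "Slide",
    "Discrepancy",
    "SlideError",
    "REQUIRED_COLUMNS",
    "SPOT_TYPES",
    "read_slide_file",
    "infer_design",
    "validate_against_design",
    "write_outputs",
    "format_number",
]

#: Required header columns of the input dialect, in canonical order.
REQUIRED_COLUMNS = (
    "Order",
    "Main.Row",
    "Main.Col",
    "Sub.Row",
    "Sub.Col",
    "Series.Id",
    "Spot.Type",
    "Dilution",
    "Net.Value",
    "Raw.Value",
    "Background.Value",
)

#: Recognised spot types.  ``NoiseRep`` marks technical-replicate series used
#: for the noise metric and (together with PosCtrl) for spatial adjustment.
SPOT_TYPES = frozenset(
    {"Sample", "PosCtrl", "NegCtrl", "Buffer", "Blank", "NoiseRep"}
)

#: Relative tolerance for agreement of consecutive dilution ratios.
DILUTION_RATIO_RTOL = 1e-6


class SlideError(Exception):
    """Slide-level failure: the slide is skipped, the batch continues."""


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot of a slide."""

    order: int
    main_row: int
    main_col: int
    sub_row: int
    sub_col: int
    series_id: str
    spot_type: str
    dilution: float  #: declared relative concentration of the step (1, 0.5, ...)
    dilution_step: int  #: 1 = most concentrated
    net_intensity: float
    raw_intensity: float
    background_intensity: float

    @property
    def coordinate(self) -> tuple[int, int, int, int]:
        return (self.main_row, self.main_col, self.sub_row, self.sub_col)


@dataclass(frozen=True)
class SlideDesign:
    """Immutable slide layout inferred from the first valid input file."""

    n_main_rows: int
    n_main_cols: int
    n_sub_rows: int
    n_sub_cols: int
    dilution_factor: float  #: ratio f > 1 between consecutive steps
    n_dilution_steps: int  #: D >= 2
    dilution_ladder: tuple[float, ...]  #: declared concentrations, descending
    spot_type_by_position: dict  #: coordinate -> spot_type
    series_roster: tuple  #: (series_id, expected step count) in first occurrence order

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Physical (rows, cols) of the flattened main x sub grid."""
        return (
            self.n_main_rows * self.n_sub_rows,
            self.n_main_cols * self.n_sub_cols,
        )

    def physical_position(self, record: SpotRecord) -> tuple[int, int]:
        """1-based (row, col) on the flattened physical grid."""
        r = (record.main_row - 1) * self.n_sub_rows + record.sub_row
        c = (record.main_col - 1) * self.n_sub_cols + record.sub_col
        return r, c


@dataclass
class Slide:
    """One antibody slide: parsed spot records plus parse-time warnings."""

    antibody_name: str
    records: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    design: SlideDesign | None = None
    provenance: list = field(default_factory=list)


@dataclass(frozen=True)
class Discrepancy:
    """One mismatch between a slide and the inferred batch design."""

    coordinate: tuple
    field: str
    expected: object
    observed: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"at {self.coordinate}: {self.field} expected "
            f"{self.expected!r}, observed {self.observed!r}"
        )


def format_number(value) -> str:
    """Render a numeric value with 6 significant digits, ``NA`` for missing."""
    if value is None:
        return "NA"
    if isinstance(value, float) and not math.isfinite(value):
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    try:
        v = float(value)
    except (TypeError, ValueError):
        return str(value)
    if not math.isfinite(v):
        return "NA"
    return f"{v:.6g}"


def _antibody_name(path: str) -> str:
    return os.path.splitext(os.path.basename(str(path)))[0]


def _assign_dilution_steps(dilutions: pd.Series) -> tuple[np.ndarray, tuple[float, ...]]:
    """Map declared concentrations to 1-based steps (1 = most concentrated)."""
    finite = dilutions[np.isfinite(dilutions)]
    ladder = np.sort(np.unique(finite.to_numpy()))[::-1]
    step_of = {}
    for rank, value in enumerate(ladder, start=1):
        step_of[value] = rank
    steps = np.array(
        [step_of.get(v, 0) if np.isfinite(v) else 0 for v in dilutions], dtype=int
    )
    return steps, tuple(float(v) for v in ladder)


def read_slide_file(path, dialect: dict | None = None) -> Slide:
    """Parse one tab-delimited quantification file into a :class:`Slide`.

    Parameters
    ----------
    path : str or os.PathLike
        Input file.  The antibody name is the file basename minus extension.
    dialect : dict, optional
        Overrides: ``sep`` (default tab), ``encoding`` (default UTF-8).

    Raises
    ------
    SlideError
        Missing required column, duplicate grid coordinate, unreadable or
        unparseable file.  Row-level anomalies (negative intensity,
        unparseable numeric fields) are recorded as warnings on the slide,
        never silently dropped.
    """
    dialect = dialect or {}
    sep = dialect.get("sep", "\t")
    encoding = dialect.get("encoding", "utf-8")
    name = _antibody_name(path)

    try:
        with open(path, "rb") as fh:
            raw = fh.read()
        text = raw.decode(encoding)
    except OSError as exc:
        raise SlideError(f"cannot read file: {exc}") from exc
    except UnicodeDecodeError as exc:
        raise SlideError(f"file is not valid {encoding}: {exc}") from exc

    if not text.strip():
        raise SlideError("file is empty")

    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    except Exception as exc:
        raise SlideError(f"cannot parse file: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SlideError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SlideError("file has a header but no data rows")

    slide = Slide(antibody_name=name)

    int_cols = ("Order", "Main.Row", "Main.Col", "Sub.Row", "Sub.Col")
    num_cols = ("Dilution", "Net.Value", "Raw.Value", "Background.Value")
    parsed = {}
    for col in int_cols + num_cols:
        parsed[col] = pd.to_numeric(df[col], errors="coerce")
        bad = parsed[col].isna() & df[col].notna()
        for idx in df.index[bad]:
            slide.warnings.append(
                f"row {idx + 1}: unparseable value {df.at[idx, col]!r} in column {col}"
            )

    steps, _ladder = _assign_dilution_steps(parsed["Dilution"])

    seen: dict[tuple, int] = {}
    for i in df.index:
        coord_vals = [parsed[c].iloc[i] for c in int_cols[1:]]
        if any(not np.isfinite(v) for v in coord_vals):
            slide.warnings.append(f"row {i + 1}: missing grid coordinate, row kept as-is")
        spot_type = str(df.at[i, "Spot.Type"]).strip()
        if spot_type not in SPOT_TYPES:
            slide.warnings.append(
                f"row {i + 1}: unknown spot type {spot_type!r}"
            )
        net = float(parsed["Net.Value"].iloc[i])
        rawv = float(parsed["Raw.Value"].iloc[i])
        bg = float(parsed["Background.Value"].iloc[i])
        if np.isfinite(net) and net < 0:
            slide.warnings.append(
                f"row {i + 1}: negative net intensity {net:g} retained"
            )
        record = SpotRecord(
            order=int(parsed["Order"].iloc[i]) if np.isfinite(parsed["Order"].iloc[i]) else i + 1,
            main_row=int(coord_vals[0]) if np.isfinite(coord_vals[0]) else -1,
            main_col=int(coord_vals[1]) if np.isfinite(coord_vals[1]) else -1,
            sub_row=int(coord_vals[2]) if np.isfinite(coord_vals[2]) else -1,
            sub_col=int(coord_vals[3]) if np.isfinite(coord_vals[3]) else -1,
            series_id=str(df.at[i, "Series.Id"]).strip(),
            spot_type=spot_type,
            dilution=float(parsed["Dilution"].iloc[i]),
            dilution_step=int(steps[i]),
            net_intensity=net,
            raw_intensity=rawv,
            background_intensity=bg,
        )
        coord = record.coordinate
        if coord in seen:
            raise SlideError(
                f"duplicate grid coordinate {coord} (rows {seen[coord] + 1} and {i + 1})"
            )
        seen[coord] = i
        slide.records.append(record)

    return slide


def infer_design(slide: Slide) -> SlideDesign:
    """Infer the slide design from a parsed slide.

    Grid dimensions are the maxima of the observed coordinates; the number of
    dilution steps D is the maximum step among Sample spots; the dilution
    factor f is the common ratio of consecutive declared concentrations.

    Raises
    ------
    SlideError
        Fewer than 2 dilution steps (one-dot arrays are unsupported: the
        method requires serial dilutions), inconsistent step counts among
        Sample series, or an irregular dilution ladder.
    """
    if not slide.records:
        raise SlideError("cannot infer design from an empty slide")

    n_main_rows = max(r.main_row for r in slide.records)
    n_main_cols = max(r.main_col for r in slide.records)
    n_sub_rows = max(r.sub_row for r in slide.records)
    n_sub_cols = max(r.sub_col for r in slide.records)

    sample_records = [r for r in slide.records if r.spot_type == "Sample"]
    if not sample_records:
        raise SlideError("no Sample spots on slide; cannot infer design")

    dilutions = sorted({r.dilution for r in sample_records if np.isfinite(r.dilution)}, reverse=True)
    n_steps = max(r.dilution_step for r in sample_records)
    if n_steps < 2 or len(dilutions) < 2:
        raise SlideError(
            "fewer than 2 dilution steps: serial dilutions are required "
            "(one-dot format is unsupported)"
        )

    ratios = [dilutions[k] / dilutions[k + 1] for k in range(len(dilutions) - 1)]
    f = ratios[0]
    for r_k in ratios[1:]:
        if abs(r_k - f) > DILUTION_RATIO_RTOL * abs(f):
            raise SlideError(
                f"irregular dilution ladder {dilutions}: consecutive ratios "
                f"{ratios} disagree beyond relative tolerance {DILUTION_RATIO_RTOL:g}"
            )
    if f <= 1:
        raise SlideError(f"dilution factor must exceed 1, got {f:g}")

    # Per-series step-count consistency among Sample series.
    step_counts: dict[str, set] = {}
    for r in sample_records:
        step_counts.setdefault(r.series_id, set()).add(r.dilution_step)
    expected_steps = set(range(1, n_steps + 1))
    offending = sorted(
        sid for sid, steps in step_counts.items() if steps != expected_steps
    )
    if offending:
        raise SlideError(
            "Sample series with inconsistent dilution steps: "
            + ", ".join(offending)
        )

    roster: list[tuple[str, int]] = []
    seen_series: dict[str, int] = {}
    for r in slide.records:
        if r.spot_type == "Blank":
            continue
        seen_series[r.series_id] = seen_series.get(r.series_id, 0) + 1
    for r in slide.records:
        if r.spot_type == "Blank":
            continue
        if r.series_id not in dict(roster):
            roster.append((r.series_id, seen_series[r.series_id]))

    spot_type_by_position = {r.coordinate: r.spot_type for r in slide.records}

    return SlideDesign(
        n_main_rows=n_main_rows,
        n_main_cols=n_main_cols,
        n_sub_rows=n_sub_rows,
        n_sub_cols=n_sub_cols,
        dilution_factor=float(f),
        n_dilution_steps=int(n_steps),
        dilution_ladder=tuple(float(d) for d in dilutions),
        spot_type_by_position=spot_type_by_position,
        series_roster=tuple(roster),
    )


def validate_against_design(slide: Slide, design: SlideDesign) -> list[Discrepancy]:
    """Position-wise comparison of a slide against the batch design.

    Returns an empty list iff coordinates, spot types, series placement and
    the dilution ladder all match the design exactly.
    """
    discrepancies: list[Discrepancy] = []

    own = infer_design(slide)

    for fieldname in ("n_main_rows", "n_main_cols", "n_sub_rows", "n_sub_cols"):
        exp, obs = getattr(design, fieldname), getattr(own, fieldname)
        if exp != obs:
            discrepancies.append(Discrepancy((), fieldname, exp, obs))
    if own.dilution_ladder != design.dilution_ladder:
        discrepancies.append(
            Discrepancy((), "dilution_ladder", design.dilution_ladder, own.dilution_ladder)
        )

    by_coord = {r.coordinate: r for r in slide.records}
    for coord, expected_type in design.spot_type_by_position.items():
        rec = by_coord.get(coord)
        if rec is None:
            discrepancies.append(Discrepancy(coord, "presence", expected_type, None))
            continue
        if rec.spot_type != expected_type:
            discrepancies.append(
                Discrepancy(coord, "spot_type", expected_type, rec.spot_type)
            )
    for coord in by_coord:
        if coord not in design.spot_type_by_position:
            discrepancies.append(
                Discrepancy(coord, "presence", None, by_coord[coord].spot_type)
            )

    # Series placement: compare roster position by position.
    design_series = [sid for sid, _ in design.series_roster]
    own_series = [sid for sid, _ in own.series_roster]
    for k in range(max(len(design_series), len(own_series))):
        exp = design_series[k] if k < len(design_series) else None
        obs = own_series[k] if k < len(own_series) else None
        if exp != obs:
            discrepancies.append(
                Discrepancy((), f"series_roster[{k}]", exp, obs)
            )

    return discrepancies


def _write_table(path: str, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    v if isinstance(v, str) else format_number(v) for v in row
                )
                + "\n"
            )


def write_outputs(results, out_dir) -> list[str]:
    """Write all tabular outputs of a batch and return the file manifest.

    ``results`` is a :class:`rppaquant.pipeline.BatchResult`.  Written files:
    one concentration table per successful slide, the raw and
    loading-normalized samples x antibodies matrices, a per-slide fit summary
    (curve parameters, R^2, noise metric), and a plain-text manifest.  Numbers
    use 6 significant digits; missing values are ``NA``.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: list[str] = []

    for sr in results.slide_results:
        if sr.status != "ok":
            continue
        fname = f"{sr.antibody_name}_concentrations.tsv"
        rows = []
        for est in sr.estimates:
            rows.append(
                [
                    est.series_id,
                    sr.spot_type_of.get(est.series_id, "NA"),
                    est.x,
                    est.se_x,
                    "1" if est.in_fit else "0",
                    ";".join(sorted(est.flags)) if est.flags else "",
                ]
            )
        _write_table(
            os.path.join(out_dir, fname),
            ["Series.Id", "Spot.Type", "Log2Concentration", "SE", "InFit", "Flags"],
            rows,
        )
        manifest.append(fname)

    # Fit summary: one row per slide, including the noise metric.
    fit_rows = []
    for sr in results.slide_results:
        if sr.status != "ok":
            continue
        nr = sr.noise_report
        fit_rows.append(
            [
                sr.antibody_name,
                sr.fit.alpha,
                sr.fit.beta,
                sr.fit.gamma,
                sr.fit.rss,
                sr.fit.r2,
                sr.fit.n_series_used,
                sr.fit.n_spots_used,
                "1" if sr.fit.converged else "0",
                sr.fit.n_iterations,
                nr.noise_sd if nr is not None else None,
                nr.replicate_mean if nr is not None else None,
                nr.n_replicates if nr is not None else 0,
            ]
        )
    _write_table(
        os.path.join(out_dir, "fit_summary.tsv"),
        [
            "Antibody",
            "Alpha",
            "Beta",
            "Gamma",
            "RSS",
            "R2",
            "NSeriesUsed",
            "NSpotsUsed",
            "Converged",
            "NIterations",
            "NoiseSD",
            "ReplicateMean",
            "NReplicates",
        ],
        fit_rows,
    )
    manifest.append("fit_summary.tsv")

    for tag, matrix in (
        ("raw", results.matrix_raw),
        ("normalized", results.matrix_normalized),
    ):
        if matrix is None:
            continue
        fname = f"matrix_{tag}.tsv"
        header = ["Series.Id"] + list(matrix.antibody_names)
        rows = []
        for i, sid in enumerate(matrix.sample_ids):
            rows.append([sid] + [matrix.values[i, j] for j in range(matrix.values.shape[1])])
        _write_table(os.path.join(out_dir, fname), header, rows)
        manifest.append(fname)

    manifest.extend(["errors.txt", "warnings.txt"])
    with open(os.path.join(out_dir, "manifest.txt"), "w", encoding="utf-8") as fh:
        for fname in manifest:
            fh.write(fname + "\n")
    manifest.append("manifest.txt")
    return manifest
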