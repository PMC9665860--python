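"""Batch orchestration: every antibody slide through the full stage chain.

Stage order is fixed: read -> validate -> [spatial] -> curve_fit -> [noise]
-> assemble matrix -> [loading] -> write.  Spatial adjustment and loading
normalization are optional (spatial off by default); curve fitting and the
noise metric are core stages.  Per-slide stages run in parallel across
worker processes; matrix assembly and loading normalization are serial.
A failing slide is recorded in the error log and skipped — it never halts
the batch — and numeric outputs are bit-identical for any worker count.
"""

from __future__ import annotations

import datetime
import glob
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml
from joblib import Parallel, delayed

from . import loading_norm, qc_noise, slide_io, spatial
from .curve_model import FitOptions, fit_supercurve, series_from_slide
from .slide_io import SlideError

__all__ = [
    "RunConfig",
    "BatchResult",
    "SlideResult",
    "Stage",
    "load_config",
    "plan_stages",
    "run_batch",
    "report_errors",
]

_STAGE_ORDER = (
    # name, optional, parallelizable
    ("read", False, True),
    ("validate", False, True),
    ("spatial", True, True),
    ("curve_fit", False, True),
    ("noise", True, True),
    ("assemble_matrix", False, False),
    ("loading", True, False),
    ("write", False, False),
)


@dataclass
class RunConfig:
    """Batch run configuration (mirrors the YAML config file)."""

    input_dir: str = "."
    output_dir: str = "out"
    workers: int = 1
    spatial_enabled: bool = False
    spatial_span: float = 0.75
    spatial_min_controls: int = 10
    spatial_clamp: tuple = (0.25, 4.0)
    noise_enabled: bool = True
    loading_enabled: bool = True
    loading_method: str = "median_centering"
    excluded_series: tuple = ()  #: excluded from curve fitting on every slide
    fit: FitOptions = field(default_factory=FitOptions)
    plots: bool = False
    seed: int = 0  #: for stochastic test harnesses; the pipeline is deterministic


@dataclass(frozen=True)
class Stage:
    name: str
    optional: bool
    parallelizable: bool


@dataclass
class SlideResult:
    """Outcome of one slide's per-slide stages."""

    antibody_name: str
    status: str  #: "ok" | "error"
    fit: object = None
    estimates: list = field(default_factory=list)
    noise_report: object = None
    spot_type_of: dict = field(default_factory=dict)
    surface: object = None
    error: tuple = ()  #: (stage, message) when status == "error"
    warnings: list = field(default_factory=list)  #: (stage, message)
    elapsed_s: float = 0.0


@dataclass
class BatchResult:
    slide_results: list = field(default_factory=list)
    matrix_raw: object = None
    matrix_normalized: object = None
    errors: list = field(default_factory=list)  #: (slide, stage, message)
    warnings: list = field(default_factory=list)
    manifest: list = field(default_factory=list)
    design: object = None

    @property
    def n_ok(self) -> int:
        return sum(1 for s in self.slide_results if s.status == "ok")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise before processing."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    cfg = RunConfig()
    fit_kwargs = {}
    known_stage_flags = {"spatial", "noise", "loading"}
    for key, value in raw.items():
        if key == "stages":
            for stage_name, enabled in (value or {}).items():
                if stage_name == "curve_fit":
                    if not enabled:
                        raise ValueError("the curve_fit stage cannot be disabled")
                    continue
                if stage_name not in known_stage_flags:
                    raise ValueError(f"unknown stage key {stage_name!r}")
                setattr(cfg, f"{stage_name}_enabled", bool(enabled))
        elif key == "spatial":
            for opt, v in (value or {}).items():
                if opt == "enabled":
                    cfg.spatial_enabled = bool(v)
                elif opt == "span":
                    cfg.spatial_span = float(v)
                elif opt == "min_controls":
                    cfg.spatial_min_controls = int(v)
                elif opt == "clamp":
                    cfg.spatial_clamp = tuple(float(x) for x in v)
                else:
                    raise ValueError(f"unknown spatial option {opt!r}")
        elif key == "loading":
            for opt, v in (value or {}).items():
                if opt == "method":
                    cfg.loading_method = str(v)
                elif opt == "enabled":
                    cfg.loading_enabled = bool(v)
                else:
                    raise ValueError(f"unknown loading option {opt!r}")
        elif key == "fit":
            for opt, v in (value or {}).items():
                if opt in ("x_bounds",):
                    fit_kwargs[opt] = tuple(float(x) for x in v)
                elif opt == "fit_spot_types":
                    fit_kwargs[opt] = frozenset(v)
                else:
                    fit_kwargs[opt] = v
        elif key in ("input_dir", "output_dir", "loading_method"):
            setattr(cfg, key, str(value))
        elif key in ("workers", "seed"):
            setattr(cfg, key, int(value))
        elif key == "excluded_series":
            cfg.excluded_series = tuple(str(s) for s in (value or ()))
        elif key == "plots":
            cfg.plots = bool(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if fit_kwargs:
        cfg.fit = FitOptions(**fit_kwargs)
    if cfg.loading_method not in loading_norm.NORMALIZERS:
        raise ValueError(
            f"unknown loading method {cfg.loading_method!r}; "
            f"choose from {sorted(loading_norm.NORMALIZERS)}"
        )
    if cfg.workers < 1:
        raise ValueError("workers must be >= 1")
    return cfg


def plan_stages(config: RunConfig) -> list[Stage]:
    """Ordered stage plan derived from the config's enable flags."""
    enabled = {
        "spatial": config.spatial_enabled,
        "noise": config.noise_enabled,
        "loading": config.loading_enabled,
    }
    plan = []
    for name, optional, parallelizable in _STAGE_ORDER:
        if optional and not enabled.get(name, True):
            continue
        plan.append(Stage(name, optional, parallelizable))
    return plan


def _candidate_files(input_dir):
    paths = []
    for pattern in ("*.txt", "*.tsv"):
        paths.extend(glob.glob(os.path.join(input_dir, pattern)))
    # truth tables from the bundled simulator are not slide inputs
    paths = [p for p in paths if "_truth_" not in os.path.basename(p)
             and os.path.basename(p) != "loading_offsets.tsv"]
    return sorted(paths)


def _process_slide(path, design, config: RunConfig) -> SlideResult:
    """Per-slide stages: read, validate, optional spatial, fit, noise."""
    name = os.path.splitext(os.path.basename(path))[0]
    result = SlideResult(antibody_name=name, status="ok")
    t0 = time.perf_counter()
    stage = "read"
    try:
        slide = slide_io.read_slide_file(path)
        result.warnings.extend(("read", w) for w in slide.warnings)

        stage = "validate"
        discrepancies = slide_io.validate_against_design(slide, design)
        if discrepancies:
            shown = "; ".join(str(d) for d in discrepancies[:5])
            raise SlideError(
                f"{len(discrepancies)} design discrepancies: {shown}"
            )

        if config.spatial_enabled:
            stage = "spatial"
            surface = spatial.fit_spatial_surface(
                slide,
                design,
                span=config.spatial_span,
                min_controls=config.spatial_min_controls,
                clamp=config.spatial_clamp,
            )
            result.warnings.extend(("spatial", w) for w in surface.warnings)
            slide = spatial.apply_spatial_adjustment(slide, surface, design)
            result.surface = surface

        stage = "curve_fit"
        series = series_from_slide(
            slide,
            design,
            excluded_series=config.excluded_series,
            fit_spot_types=config.fit.fit_spot_types,
        )
        fit, estimates = fit_supercurve(series, config.fit)
        if not fit.converged:
            result.warnings.append(
                ("curve_fit", f"fit did not converge in {fit.n_iterations} iterations")
            )
        result.fit = fit
        result.estimates = estimates
        result.spot_type_of = {s.series_id: s.spot_type for s in series}

        if config.noise_enabled:
            stage = "noise"
            rep_estimates = [
                e for e in estimates
                if result.spot_type_of.get(e.series_id) == "NoiseRep"
            ]
            report, nwarnings = qc_noise.compute_noise(rep_estimates, name)
            result.noise_report = report
            result.warnings.extend(("noise", w) for w in nwarnings)
    except SlideError as exc:
        result.status = "error"
        result.error = (stage, str(exc))
    except Exception as exc:  # fault isolation: any failure stays on its slide
        result.status = "error"
        result.error = (stage, f"{type(exc).__name__}: {exc}")
    result.elapsed_s = time.perf_counter() - t0
    return result


def _assemble_matrix(results, design) -> loading_norm.ConcentrationMatrix | None:
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        return None
    sample_ids = [
        sid for sid, _ in design.series_roster
        if design_spot_type(design, sid) == "Sample"
    ]
    antibodies = [r.antibody_name for r in ok]
    values = np.full((len(sample_ids), len(antibodies)), np.nan)
    for j, r in enumerate(ok):
        x_of = {e.series_id: e.x for e in r.estimates}
        for i, sid in enumerate(sample_ids):
            if sid in x_of:
                values[i, j] = x_of[sid]
    return loading_norm.ConcentrationMatrix(
        values=values,
        sample_ids=tuple(sample_ids),
        antibody_names=tuple(antibodies),
    )


def design_spot_type(design, series_id):
    """Spot type of a series under a design.

    The roster carries series ids only; :func:`populate_series_types` caches
    the series -> spot-type map from the design's founding slide.  Unknown
    series default to Sample.
    """
    cache = getattr(design, "_series_spot_type", {})
    return cache.get(series_id, "Sample")


def populate_series_types(design, slide) -> None:
    """Cache series -> spot type on a design from its founding slide."""
    cache = {}
    for rec in slide.records:
        cache.setdefault(rec.series_id, rec.spot_type)
    object.__setattr__(design, "_series_spot_type", cache)


def run_batch(config: RunConfig) -> BatchResult:
    """Run the full batch; see the module docstring for the stage chain.

    The slide design is inferred from the first file (in lexicographic
    order) that parses and infers cleanly; every other slide is validated
    against it.  Raises :class:`SlideError` only when no file at all yields
    a valid design.
    """
    files = _candidate_files(config.input_dir)
    if not files:
        raise SlideError(f"no candidate input files in {config.input_dir}")

    result = BatchResult()
    design = None
    design_errors = []
    for path in files:
        try:
            first = slide_io.read_slide_file(path)
            design = slide_io.infer_design(first)
            populate_series_types(design, first)
            break
        except SlideError as exc:
            design_errors.append((os.path.basename(path), "read", str(exc)))
    if design is None:
        result.errors.extend(design_errors)
        raise SlideError("no valid input file to infer the slide design from")
    result.design = design

    runner = Parallel(n_jobs=config.workers, prefer="processes")
    slide_results = runner(
        delayed(_process_slide)(path, design, config) for path in files
    )
    result.slide_results = list(slide_results)

    for sr in result.slide_results:
        if sr.status == "error":
            result.errors.append((sr.antibody_name, sr.error[0], sr.error[1]))
        result.warnings.extend(
            (sr.antibody_name, stage, msg) for stage, msg in sr.warnings
        )

    matrix = _assemble_matrix(result.slide_results, design)
    result.matrix_raw = matrix
    if matrix is not None and config.loading_enabled:
        try:
            result.matrix_normalized = loading_norm.normalize(
                matrix, config.loading_method
            )
            result.warnings.extend(
                ("batch", "loading", w) for w in result.matrix_normalized.warnings
            )
        except ValueError as exc:
            # e.g. a single-antibody batch cannot be median-centered; pass
            # the matrix through rather than failing the whole run
            result.warnings.append(
                ("batch", "loading",
                 f"{config.loading_method} not applicable ({exc}); "
                 "matrix passed through unnormalized")
            )
            result.matrix_normalized = loading_norm.normalize_none(matrix)
    elif matrix is not None:
        result.matrix_normalized = loading_norm.normalize_none(matrix)

    result.manifest = slide_io.write_outputs(result, config.output_dir)
    report_errors(result, config.output_dir)

    if config.plots:
        from . import plots

        for sr in result.slide_results:
            if sr.status == "ok":
                plots.slide_figure(sr, config.output_dir)

    return result


def report_errors(result: BatchResult, out_dir) -> tuple[str, str]:
    """Write errors.txt / warnings.txt: timestamp, slide, stage, message.

    Both files are created even when empty.
    """
    os.makedirs(out_dir, exist_ok=True)
    now = datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    epath = os.path.join(out_dir, "errors.txt")
    wpath = os.path.join(out_dir, "warnings.txt")
    with open(epath, "w", encoding="utf-8") as fh:
        for slide_name, stage, message in result.errors:
            fh.write(f"{now}\t{slide_name}\t{stage}\t{message}\n")
    with open(wpath, "w", encoding="utf-8") as fh:
        for entry in result.warnings:
            if len(entry) == 3:
                slide_name, stage, message = entry
            else:  # pragma: no cover - defensive
                slide_name, stage, message = "batch", "unknown", str(entry)
            fh.write(f"{now}\t{slide_name}\t{stage}\t{message}\n")
    return epath, wpath
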