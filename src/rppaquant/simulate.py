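"""Ground-truthed synthetic RPPA slide generation.

Emulates a gridded slide on which every sample and control is printed as a
serial-dilution series.  Spot intensities follow the logistic response

    y = m(r, c) * [alpha + beta / (1 + exp(-gamma * (x_i + d_j)))] + eps,

with a per-series true log2 concentration ``x_i``, known dilution offsets
``d_j``, an optional smooth multiplicative spatial field ``m(r, c)``,
additive Gaussian measurement noise ``eps ~ N(0, sigma_y^2)`` and optional
per-series multiplicative outliers.  Technical-replicate series share one
true concentration (optionally jittered spot-batch to spot-batch to emulate
deposition variability); buffer series carry baseline-only signal.

Every generated slide comes with complete truth tables (per-series x, curve
parameters, spatial field, per-spot noiseless intensity), so each pipeline
stage can be tested by generate-and-recover.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .slide_io import REQUIRED_COLUMNS

__all__ = ["SimScenario", "SlideTruth", "simulate_slide", "generate_slide", "generate_batch"]

#: Constant scanner background added to net intensity to form raw intensity.
BACKGROUND = 50.0


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic slide.

    Defaults describe a realistic production-style slide: a 4x12 grid of 4x4
    sub-grids (768 spots), 96 sample series at dilution factor 2 over 4
    steps, 24 technical-replicate series, a baseline of 200 and dynamic
    range of 40000 scanner units with logistic slope 0.8 per log2 unit, and
    sample concentrations uniform on [-4, 4] log2 units.
    """

    seed: int  #: mandatory; all randomness flows from here
    n_main_rows: int = 4
    n_main_cols: int = 12
    n_sub_rows: int = 4
    n_sub_cols: int = 4
    n_dilution_steps: int = 4
    dilution_factor: float = 2.0
    alpha: float = 200.0
    beta: float = 40000.0
    gamma: float = 0.8
    n_samples: int = 96
    x_low: float = -4.0
    x_high: float = 4.0
    n_replicate_series: int = 24
    replicate_x: float = 0.0  #: common true position of the replicate sample
    replicate_x_sd: float = 0.0  #: per-series deposition jitter around replicate_x
    noise_sd: float = 0.0  #: additive Gaussian intensity noise sigma_y
    noise_proportional: bool = False  #: scale sigma_y by noiseless/(alpha+beta)
    spatial_field: str = "none"  #: none | linear | radial
    spatial_fold: float = 2.0  #: total fold range of the field across the slide
    outliers: tuple = ()  #: ((series_id, multiplicative factor), ...)
    loading_offset_by_sample: tuple = ()  #: ((sample index, log2 offset), ...)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.n_main_rows * self.n_sub_rows, self.n_main_cols * self.n_sub_cols)


@dataclass
class SlideTruth:
    """Ground truth accompanying one generated slide."""

    antibody_name: str
    scenario: SimScenario
    x_true: dict  #: series_id -> true log2 concentration (Sample + NoiseRep)
    spot_type: dict  #: series_id -> spot type
    spatial_true: np.ndarray  #: m(r, c) over the physical grid
    table: pd.DataFrame  #: the written slide table
    noiseless: np.ndarray  #: per-row noiseless intensity (before noise, after field)


def _spatial_field(scenario: SimScenario) -> np.ndarray:
    R, C = scenario.grid_shape
    if scenario.spatial_field == "none":
        return np.ones((R, C))
    fold = scenario.spatial_fold
    if scenario.spatial_field == "linear":
        frac = (np.arange(C) / max(C - 1, 1))[None, :] * np.ones((R, 1))
    elif scenario.spatial_field == "radial":
        rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        center = ((R - 1) / 2, (C - 1) / 2)
        dist = np.hypot(rr - center[0], cc - center[1])
        frac = 1.0 - dist / dist.max()
    else:
        raise ValueError(f"unknown spatial field {scenario.spatial_field!r}")
    # fold^(frac - 1/2): ratio across the field equals `fold`, median near 1.
    return np.power(fold, frac - 0.5)


def _layout(scenario: SimScenario):
    """Assign series to slots of D consecutive columns on the physical grid.

    Replicate series are spread on an even stride so they sample the whole
    surface; remaining slots carry the samples, then buffer series.
    """
    R, C = scenario.grid_shape
    D = scenario.n_dilution_steps
    slots_per_row = C // D
    n_slots = R * slots_per_row
    n_rep = scenario.n_replicate_series
    n_samp = scenario.n_samples
    if n_rep + n_samp > n_slots:
        raise ValueError(
            f"grid too small: {n_slots} series slots for "
            f"{n_samp} samples + {n_rep} replicates"
        )
    rep_slots = set()
    if n_rep:
        stride = n_slots / n_rep
        rep_slots = {int(round(k * stride)) % n_slots for k in range(n_rep)}
        # resolve rounding collisions deterministically
        k = 0
        while len(rep_slots) < n_rep:
            if k not in rep_slots:
                rep_slots.add(k)
            k += 1

    assignment = []  # (slot, series_id, spot_type)
    sample_i = rep_i = buf_i = 0
    for slot in range(n_slots):
        if slot in rep_slots and rep_i < n_rep:
            rep_i += 1
            assignment.append((slot, f"Rep{rep_i:02d}", "NoiseRep"))
        elif sample_i < n_samp:
            sample_i += 1
            assignment.append((slot, f"S{sample_i:03d}", "Sample"))
        else:
            buf_i += 1
            assignment.append((slot, f"Buf{buf_i:03d}", "Buffer"))
    return assignment, slots_per_row


def simulate_slide(scenario: SimScenario, antibody_name: str = "AB01") -> SlideTruth:
    """Generate one slide in memory; see the module docstring for the model."""
    rng = np.random.default_rng(scenario.seed)
    D = scenario.n_dilution_steps
    f = scenario.dilution_factor
    if D < 2:
        raise ValueError("at least 2 dilution steps are required")
    if f <= 1:
        raise ValueError("dilution factor must exceed 1")

    assignment, slots_per_row = _layout(scenario)
    m_true = _spatial_field(scenario)
    loading = dict(scenario.loading_offset_by_sample)
    outliers = dict(scenario.outliers)

    x_sample = rng.uniform(scenario.x_low, scenario.x_high, scenario.n_samples)
    x_rep = scenario.replicate_x + (
        rng.normal(0.0, scenario.replicate_x_sd, scenario.n_replicate_series)
        if scenario.replicate_x_sd > 0
        else np.zeros(scenario.n_replicate_series)
    )

    x_true: dict[str, float] = {}
    spot_type_of: dict[str, str] = {}
    rows = []
    noiseless_all = []
    order = 0
    d_steps = np.array([-(j) * math.log2(f) for j in range(D)])
    dil_values = np.array([f ** (-j) for j in range(D)])

    for slot, sid, stype in assignment:
        phys_row = slot // slots_per_row
        col0 = (slot % slots_per_row) * D
        if stype == "Sample":
            idx = int(sid[1:]) - 1
            x = float(x_sample[idx]) + float(loading.get(idx, 0.0))
        elif stype == "NoiseRep":
            x = float(x_rep[int(sid[3:]) - 1])
        else:
            x = None  # buffer: baseline only
        if x is not None:
            x_true[sid] = x
        spot_type_of[sid] = stype
        factor = outliers.get(sid, 1.0)

        for j in range(D):
            r = phys_row + 1
            c = col0 + j + 1
            if x is None:
                clean = scenario.alpha
            else:
                u = x + d_steps[j]
                clean = scenario.alpha + scenario.beta / (1.0 + math.exp(-scenario.gamma * u))
            clean = clean * m_true[r - 1, c - 1] * factor
            if scenario.noise_sd > 0:
                sd = scenario.noise_sd
                if scenario.noise_proportional:
                    sd = sd * clean / (scenario.alpha + scenario.beta)
                y = clean + rng.normal(0.0, sd)
            else:
                y = clean
            order += 1
            rows.append(
                {
                    "Order": order,
                    "Main.Row": (r - 1) // scenario.n_sub_rows + 1,
                    "Main.Col": (c - 1) // scenario.n_sub_cols + 1,
                    "Sub.Row": (r - 1) % scenario.n_sub_rows + 1,
                    "Sub.Col": (c - 1) % scenario.n_sub_cols + 1,
                    "Series.Id": sid,
                    "Spot.Type": stype,
                    "Dilution": dil_values[j],
                    "Net.Value": y,
                    "Raw.Value": y + BACKGROUND,
                    "Background.Value": BACKGROUND,
                }
            )
            noiseless_all.append(clean)

    table = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return SlideTruth(
        antibody_name=antibody_name,
        scenario=scenario,
        x_true=x_true,
        spot_type=spot_type_of,
        spatial_true=m_true,
        table=table,
        noiseless=np.asarray(noiseless_all),
    )


def _format_table(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in ("Dilution", "Net.Value", "Raw.Value", "Background.Value"):
        out[col] = out[col].map(lambda v: f"{v:.10g}")
    return out


def generate_slide(scenario: SimScenario, antibody_name: str, out_dir) -> tuple[str, SlideTruth]:
    """Generate one slide and write it plus its truth tables to ``out_dir``.

    Writes ``<antibody>.txt`` in the input dialect, ``<antibody>_truth_series.tsv``
    (series, spot type, true x), ``<antibody>_truth_curve.tsv`` (curve and
    noise parameters), ``<antibody>_truth_spatial.tsv`` (true field per grid
    node) and ``<antibody>_truth_spots.tsv`` (per-spot noiseless intensity).
    Same scenario and seed produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    truth = simulate_slide(scenario, antibody_name)
    path = Path(out_dir) / f"{antibody_name}.txt"
    _format_table(truth.table).to_csv(path, sep="\t", index=False, lineterminator="\n")

    series_rows = [
        {"Series.Id": sid, "Spot.Type": truth.spot_type[sid],
         "TrueX": f"{truth.x_true[sid]:.10g}" if sid in truth.x_true else "NA"}
        for sid in truth.spot_type
    ]
    pd.DataFrame(series_rows).to_csv(
        os.path.join(out_dir, f"{antibody_name}_truth_series.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    sc = scenario
    pd.DataFrame(
        [{"Alpha": sc.alpha, "Beta": sc.beta, "Gamma": sc.gamma,
          "DilutionFactor": sc.dilution_factor, "NSteps": sc.n_dilution_steps,
          "NoiseSD": sc.noise_sd, "Seed": sc.seed}]
    ).to_csv(
        os.path.join(out_dir, f"{antibody_name}_truth_curve.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    R, C = sc.grid_shape
    spatial_rows = [
        {"Row": r + 1, "Col": c + 1, "M": f"{truth.spatial_true[r, c]:.10g}"}
        for r in range(R) for c in range(C)
    ]
    pd.DataFrame(spatial_rows).to_csv(
        os.path.join(out_dir, f"{antibody_name}_truth_spatial.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    spots = truth.table[["Order", "Series.Id", "Spot.Type"]].copy()
    spots["Noiseless"] = [f"{v:.10g}" for v in truth.noiseless]
    spots.to_csv(
        os.path.join(out_dir, f"{antibody_name}_truth_spots.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    return path, truth


def generate_batch(
    base_scenario: SimScenario,
    n_antibodies: int,
    out_dir,
    loading_offset_sd: float = 0.0,
    antibody_prefix: str = "AB",
) -> dict:
    """Generate a batch of slides sharing one design.

    Each antibody gets fresh sample concentrations (independent seeds spawned
    from the base seed) on the shared layout.  With ``loading_offset_sd > 0``
    a per-sample loading offset drawn from N(0, sd^2) is added to every
    antibody's true concentrations — the planted signal for loading
    normalization tests; offsets are written to ``loading_offsets.tsv``.

    Returns a manifest dict: per-antibody file paths and truths, plus the
    offsets.
    """
    if n_antibodies < 1:
        raise ValueError("a batch needs at least 1 antibody")
    os.makedirs(out_dir, exist_ok=True)
    ss = np.random.SeedSequence(base_scenario.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_antibodies + 1)]

    offsets = ()
    offset_arr = np.zeros(base_scenario.n_samples)
    if loading_offset_sd > 0:
        rng = np.random.default_rng(child_seeds[-1])
        offset_arr = rng.normal(0.0, loading_offset_sd, base_scenario.n_samples)
        offsets = tuple((i, float(offset_arr[i])) for i in range(base_scenario.n_samples))

    manifest = {"slides": {}, "truths": {}, "loading_offsets": offset_arr}
    for k in range(n_antibodies):
        name = f"{antibody_prefix}{k + 1:03d}"
        scenario = replace(
            base_scenario, seed=child_seeds[k], loading_offset_by_sample=offsets
        )
        path, truth = generate_slide(scenario, name, out_dir)
        manifest["slides"][name] = path
        manifest["truths"][name] = truth

    pd.DataFrame(
        {
            "Series.Id": [f"S{i + 1:03d}" for i in range(base_scenario.n_samples)],
            "LoadingOffset": [f"{v:.10g}" for v in offset_arr],
        }
    ).to_csv(
        os.path.join(out_dir, "loading_offsets.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    return manifest
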