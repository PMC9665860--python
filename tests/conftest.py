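"""Shared fixtures: hand-built fixture files and fast synthetic scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from rppaquant import SimScenario, infer_design, read_slide_file
from rppaquant.simulate import generate_slide

#: Compact slide used throughout the unit tests: 8x24 physical grid,
#: 24 sample series + 8 replicate series at dilution factor 2 over 4 steps.
SMALL = dict(
    n_main_rows=2,
    n_main_cols=6,
    n_sub_rows=4,
    n_sub_cols=4,
    n_samples=24,
    n_replicate_series=8,
)


def small_scenario(seed: int, **overrides) -> SimScenario:
    return SimScenario(seed=seed, **{**SMALL, **overrides})


#: 8-row hand fixture: two Sample series of 4 steps on a 1x1 main grid with
#: 2x4 sub-grid.  Intensities lie exactly on the logistic curve
#: alpha=100, beta=1000, gamma=1 at x_A = 1, x_B = -1.
FIXTURE_HEADER = (
    "Order\tMain.Row\tMain.Col\tSub.Row\tSub.Col\tSeries.Id\tSpot.Type"
    "\tDilution\tNet.Value\tRaw.Value\tBackground.Value"
)


def fixture_rows():
    alpha, beta, gamma = 100.0, 1000.0, 1.0
    rows = []
    order = 0
    for sub_row, (sid, x) in enumerate([("A", 1.0), ("B", -1.0)], start=1):
        for j in range(4):
            order += 1
            dil = 0.5**j
            u = x + np.log2(dil)
            y = alpha + beta / (1 + np.exp(-gamma * u))
            rows.append(
                f"{order}\t1\t1\t{sub_row}\t{j + 1}\t{sid}\tSample\t{dil:g}"
                f"\t{y:.10g}\t{y + 50:.10g}\t50"
            )
    return rows


@pytest.fixture
def fixture_file(tmp_path):
    path = tmp_path / "AB_fixture.txt"
    path.write_text(FIXTURE_HEADER + "\n" + "\n".join(fixture_rows()) + "\n")
    return path


@pytest.fixture(scope="session")
def small_slide_noise_free(tmp_path_factory):
    """Noise-free small slide with its truth, parsed and design-inferred."""
    d = tmp_path_factory.mktemp("slide")
    path, truth = generate_slide(small_scenario(101), "AB001", d)
    slide = read_slide_file(path)
    design = infer_design(slide)
    return slide, design, truth
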