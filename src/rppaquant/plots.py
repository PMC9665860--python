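"""Optional per-slide diagnostic figures (off by default)."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .curve_model import response


def slide_figure(slide_result, out_dir) -> str:
    """Fitted curve with all spots, plus a per-series residual panel."""
    fit = slide_result.fit
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))

    xs, max_resid = [], []
    for est in slide_result.estimates:
        xs.append(est.x)
        max_resid.append(
            np.max(np.abs(est.residuals)) if est.residuals.size else np.nan
        )
    u = np.linspace(-8, 8, 200)
    ax1.plot(u, response(u, fit), "k-", lw=1.5, label="fitted curve")
    ax1.scatter(xs, response(np.asarray(xs), fit), s=8, alpha=0.6, label="series at x-hat")
    ax1.set_xlabel("relative log2 concentration")
    ax1.set_ylabel("intensity")
    ax1.set_title(f"{slide_result.antibody_name}: R2={fit.r2:.4f}")
    ax1.legend(fontsize=8)

    ax2.bar(range(len(max_resid)), max_resid, width=1.0)
    ax2.set_xlabel("series (input order)")
    ax2.set_ylabel("max |residual|")
    ax2.set_title("per-series residuals")

    fig.tight_layout()
    path = os.path.join(out_dir, f"{slide_result.antibody_name}_fit.png")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
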