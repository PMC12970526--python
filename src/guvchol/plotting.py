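"""Quick-look plots: GP maps, calibration lines, phasor plots."""

from __future__ import annotations

import numpy as np


def plot_gp_image(gp_image, ax=None, cmap="RdYlBu_r"):
    """Color-coded GP map of one vesicle (NaN outside the mask)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(gp_image.gp, cmap=cmap, vmin=-1, vmax=1)
    ax.figure.colorbar(im, ax=ax, label="GP")
    ax.set_title(f"mean GP = {np.nanmean(gp_image.gp):.3f}")
    return ax


def plot_calibration(result, points=None, ax=None):
    """Calibration line with its points and the fitted parameters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(0, 45, 50)
    ax.plot(x, result.intercept + result.slope * x, "--", color="0.3",
            label=f"y = {result.intercept:.3f} + {result.slope:.4f} x")
    if points is not None:
        ax.errorbar(
            [p.chol_molpct for p in points],
            [p.readout_mean for p in points],
            yerr=[p.readout_sd for p in points],
            fmt="o", capsize=3,
        )
    ax.set_xlabel("cholesterol (mol%)")
    ax.set_ylabel(result.modality or "readout")
    ax.legend()
    return ax


def plot_phasor(points, ax=None, **scatter_kwargs):
    """Phasor scatter with the universal semicircle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    phi = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(phi), 0.5 * np.sin(phi), color="0.6", lw=1)
    ax.scatter([p.g for p in points], [p.s for p in points],
               s=scatter_kwargs.pop("s", 4), **scatter_kwargs)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_aspect("equal")
    return ax
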