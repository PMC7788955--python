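"""Optional PNG rendering of group spectra and per-mouse field heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_band_summary", "plot_heatmap", "render_run"]


def plot_band_summary(bands: pd.DataFrame, path) -> Path:
    """Group mean spectra with shaded confidence bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, color in (("AD", "tab:red"), ("CO", "tab:blue")):
        ax.plot(bands["nm"], bands[f"mean_{cls}"], color=color, label=cls)
        ax.fill_between(bands["nm"], bands[f"ci_lo_{cls}"],
                        bands[f"ci_hi_{cls}"], color=color, alpha=0.25)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_heatmap(grid: pd.DataFrame, path) -> Path:
    """Mouse x field score grid; absent fields render blank."""
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(grid) + 1.5))
    data = np.ma.masked_invalid(grid.to_numpy(dtype=float))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(grid.shape[1]), [str(c) for c in grid.columns])
    ax.set_yticks(range(len(grid)), list(grid.index))
    ax.set_xlabel("field")
    fig.colorbar(im, ax=ax, label="HS score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def render_run(run_dir: Path) -> list:
    """Render figures from a finished pipeline run directory."""
    run_dir = Path(run_dir)
    written = []
    bands_csv = run_dir / "band_summary.csv"
    if bands_csv.exists():
        written.append(plot_band_summary(pd.read_csv(bands_csv),
                                         run_dir / "band_summary.png"))
    heat_csv = run_dir / "heatmap.csv"
    if heat_csv.exists():
        grid = pd.read_csv(heat_csv, index_col=0)
        written.append(plot_heatmap(grid, run_dir / "heatmap.png"))
    return written
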