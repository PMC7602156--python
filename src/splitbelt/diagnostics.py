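"""Residual diagnostics and the cosmetic moving-average smoother.

The exponential models assume zero-mean Gaussian residuals with constant
variance across strides.  Three views check that visually: residuals vs
stride (constant spread?), a histogram (read with care — it can mislead) and
a normal QQ plot, which deserves the most weight.  The bundle of plot data
is the tested surface; PNG rendering is optional convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .series_io import SymmetrySeries

__all__ = ["DiagnosticBundle", "residual_diagnostics", "moving_average"]


@dataclass(frozen=True)
class DiagnosticBundle:
    stride_index: np.ndarray
    residuals: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    qq_theoretical: np.ndarray  # standard-normal quantiles at (i - 0.5)/N
    qq_sample: np.ndarray  # sorted residual quantiles

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "residuals": pd.DataFrame(
                {"stride": self.stride_index, "residual": self.residuals}
            ),
            "histogram": pd.DataFrame(
                {
                    "bin_left": self.hist_edges[:-1],
                    "bin_right": self.hist_edges[1:],
                    "count": self.hist_counts,
                }
            ),
            "qq": pd.DataFrame(
                {
                    "theoretical": self.qq_theoretical,
                    "sample": self.qq_sample,
                }
            ),
        }

    def save_csv(self, directory, prefix: str = "diagnostics") -> dict[str, str]:
        import os

        paths = {}
        for name, frame in self.to_frames().items():
            path = os.path.join(directory, f"{prefix}_{name}.csv")
            frame.to_csv(path, index=False)
            paths[name] = path
        return paths

    def render(self, path) -> None:
        """Optional three-panel PNG (residuals vs stride, histogram, QQ)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        axes[0].plot(self.stride_index, self.residuals, ".", markersize=2)
        axes[0].axhline(0.0, color="k", linewidth=0.8)
        axes[0].set_xlabel("stride")
        axes[0].set_ylabel("residual")
        axes[1].stairs(self.hist_counts, self.hist_edges, fill=True)
        axes[1].set_xlabel("residual")
        axes[1].set_ylabel("count")
        axes[2].plot(self.qq_theoretical, self.qq_sample, ".", markersize=3)
        lim = [self.qq_theoretical.min(), self.qq_theoretical.max()]
        sd = self.residuals.std(ddof=1) if self.residuals.size > 1 else 1.0
        axes[2].plot(lim, [v * sd for v in lim], "k-", linewidth=0.8)
        axes[2].set_xlabel("normal quantile")
        axes[2].set_ylabel("residual quantile")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _hist_edges(residuals: np.ndarray) -> np.ndarray:
    # Freedman-Diaconis; degenerate IQR (e.g. near-identical residuals)
    # falls back to 10 equal bins
    try:
        edges = np.histogram_bin_edges(residuals, bins="fd")
    except Exception:
        edges = np.histogram_bin_edges(residuals, bins=10)
    if edges.size < 3 or not np.all(np.diff(edges) > 0):
        edges = np.histogram_bin_edges(residuals, bins=10)
    if edges.size < 2 or edges[0] == edges[-1]:
        center = float(residuals[0]) if residuals.size else 0.0
        edges = np.linspace(center - 0.5, center + 0.5, 11)
    return edges


def residual_diagnostics(fit: FitResult) -> DiagnosticBundle:
    """Assemble the residual diagnostic data for a fitted model."""
    resid = np.asarray(fit.residuals, dtype=float)
    n = resid.size
    edges = _hist_edges(resid)
    counts, edges = np.histogram(resid, bins=edges)
    positions = (np.arange(1, n + 1) - 0.5) / n
    return DiagnosticBundle(
        stride_index=np.arange(1, n + 1),
        residuals=resid,
        hist_edges=edges,
        hist_counts=counts,
        qq_theoretical=stats.norm.ppf(positions),
        qq_sample=np.sort(resid),
    )


def moving_average(series: SymmetrySeries, window: int = 3) -> SymmetrySeries:
    """Centered moving average for plotting only — never an input to fitting.

    The window must be odd and no longer than the series; it shrinks at the
    edges so the output keeps length N.
    """
    if window % 2 == 0:
        raise ValueError("moving-average window must be odd")
    if window > series.n_strides:
        raise ValueError("moving-average window longer than the series")
    smoothed = (
        pd.Series(series.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    label = f"{series.label} (smoothed)" if series.label else "smoothed"
    return SymmetrySeries(values=smoothed, label=label)
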