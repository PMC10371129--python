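"""Figure rendering: displacement heatmaps and coagulation spectrograms."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import PipelineResult

__all__ = ["render_figures"]


def _heatmap(ax, matrix):
    S_um = matrix.matrix.T * 1e6
    im = ax.pcolormesh(
        matrix.observation_times,
        matrix.tau * 1e3,
        S_um,
        shading="nearest",
        cmap="RdBu_r",
    )
    ax.set_xlabel("observation time T (s)")
    ax.set_ylabel("fast time τ (ms)")
    return im


def _spectrogram(ax, sg, ft, params):
    im = ax.pcolormesh(
        sg.observation_times, sg.frequency, sg.power.T, shading="nearest", cmap="magma"
    )
    ax.plot(ft.observation_times, ft.peak_frequency, "c.", ms=2, label="peak frequency")
    if params is not None and not params.no_clot and np.isfinite(params.T_int):
        ax.axvline(params.T_int, color="w", ls="--", lw=1, label="T_int")
        ax.axvline(params.T_end, color="w", ls=":", lw=1, label="T_end")
    ax.set_ylim(0, min(2.5 * np.nanmax(ft.peak_frequency) if np.isfinite(ft.peak_frequency).any() else sg.frequency[-1], sg.frequency[-1]))
    ax.set_xlabel("observation time T (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.legend(loc="upper left", fontsize=7)
    return im


def render_figures(result: PipelineResult, outdir: str | Path) -> list:
    """Write one displacement heatmap and one spectrogram PNG per channel.

    Channels without data get a placeholder figure carrying a flag note.
    Regeneration from identical inputs is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    channels = sorted(set(result.matrices) | set(result.spectrograms))
    for ch in channels:
        fig, axes = plt.subplots(1, 2, figsize=(10, 3.6), constrained_layout=True)
        matrix = result.matrices.get(ch)
        if matrix is None or matrix.matrix.size == 0:
            axes[0].text(0.5, 0.5, f"channel {ch}: no data (flagged)", ha="center")
        else:
            im = _heatmap(axes[0], matrix)
            fig.colorbar(im, ax=axes[0], label="displacement (µm)")
        sg = result.spectrograms.get(ch)
        if sg is None or sg.power.size == 0:
            axes[1].text(0.5, 0.5, f"channel {ch}: no spectra (flagged)", ha="center")
        else:
            im = _spectrogram(axes[1], sg, result.frequency_traces[ch], result.params.get(ch))
            fig.colorbar(im, ax=axes[1], label="normalized power")
        fig.suptitle(f"channel {ch}")
        path = outdir / f"channel_{ch:02d}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
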