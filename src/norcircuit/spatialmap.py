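"""Positional coherence mapping.

The session is cut into non-overlapping windows; each window is
assigned to the spatial bin of the animal's time-averaged body
position, and per bin the pooled Welch coherence of that bin's windows
(one segment per window) is band-averaged and color-codable as a map.
Maps are descriptive outputs: no statistics are computed from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Recording, TrackingTrace
from .connectivity import band_mean, msc


@dataclass
class SpatialCoherenceMap:
    """Grid of mean band coherence by animal position.

    ``values[iy, ix]`` is the mean band coherence of windows whose
    average position fell in that bin (NaN where occupancy < min_occ);
    ``occupancy`` counts assigned windows per bin.
    """

    pair: tuple
    band: tuple
    bin_size: float
    values: np.ndarray
    occupancy: np.ndarray
    n_windows: int

    @property
    def shape(self):
        return self.values.shape


def coherence_map(rec: Recording, trace: TrackingTrace, pair,
                  band, bin_size: float = 5.0, win_s: float = 1.0,
                  min_occ: int = 3, window: str = "hann") -> SpatialCoherenceMap:
    """Build a positional coherence map for one region pair and band.

    Windows overlapping the artifact mask are skipped; a bin's value is
    reported only when at least ``min_occ`` windows landed in it (a
    single window would make msc degenerately 1).
    """
    w, h = trace.arena
    if bin_size > max(w, h):
        raise ValueError("bin_size larger than the arena")
    nx = int(np.ceil(w / bin_size))
    ny = int(np.ceil(h / bin_size))
    nwin = int(round(win_s * rec.fs))
    n_windows_total = rec.n_samples // nwin

    x = rec.channel(pair[0])
    y = rec.channel(pair[1])
    assigned = {}
    n_assigned = 0
    for k in range(n_windows_total):
        i0, i1 = k * nwin, (k + 1) * nwin
        if rec.artifact_mask[i0:i1].any():
            continue
        t0, t1 = i0 / rec.fs, i1 / rec.fs
        sel = (trace.t >= t0) & (trace.t < t1)
        if not sel.any():
            continue
        px, py = trace.body_xy[sel].mean(axis=0)
        ix = min(int(px // bin_size), nx - 1)
        iy = min(int(py // bin_size), ny - 1)
        assigned.setdefault((iy, ix), []).append((x[i0:i1], y[i0:i1]))
        n_assigned += 1

    values = np.full((ny, nx), np.nan)
    occupancy = np.zeros((ny, nx), dtype=int)
    for (iy, ix), pairs_list in assigned.items():
        occupancy[iy, ix] = len(pairs_list)
        if len(pairs_list) < max(min_occ, 2):
            continue
        coh = msc(pairs_list, fs=rec.fs, seg_len_s=win_s, overlap=0.0,
                  window=window, pair=tuple(pair))
        values[iy, ix] = band_mean(coh, band)
    return SpatialCoherenceMap(tuple(pair), tuple(band), bin_size, values,
                               occupancy, n_assigned)


def write_map(smap: SpatialCoherenceMap, path_values, path_occupancy=None):
    """Write the map (and optionally occupancy) as delimited matrices;
    missing bins are written as NA."""
    np.savetxt(path_values, smap.values, delimiter="\t", fmt="%.6f")
    # rewrite NaN as NA for portability
    with open(path_values) as fh:
        text = fh.read().replace("nan", "NA")
    with open(path_values, "w") as fh:
        fh.write(text)
    if path_occupancy is not None:
        np.savetxt(path_occupancy, smap.occupancy, delimiter="\t", fmt="%d")


def render_map(smap: SpatialCoherenceMap, path):  # pragma: no cover - plotting
    """Save a color-coded image of the map (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(smap.values, origin="lower", cmap="viridis",
                   vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="band coherence")
    ax.set_title(f"{smap.pair[0]}-{smap.pair[1]} "
                 f"{smap.band[0]:g}-{smap.band[1]:g} Hz")
    ax.set_xlabel(f"x bin ({smap.bin_size:g} cm)")
    ax.set_ylabel(f"y bin ({smap.bin_size:g} cm)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
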