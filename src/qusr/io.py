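"""File formats: HDF5 RF scans and parametric maps, CSV tables, PNG export."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .qus_params import ParametricMap
from .rf_synth import RFScan
from .spectra import RFFrame

# Fixed colour-scale limits for PNG export, per parameter
MAP_COLOR_SCALES = {
    "MBF": (-10.0, 30.0),
    "SS": (-6.0, 2.0),
    "SI": (-20.0, 40.0),
    "SAS": (0.0, 2.0),
    "ASD": (0.0, 200.0),
    "AAC": (-20.0, 40.0),
}


def write_scan(
    path: str | Path,
    scan: RFScan,
    roi_masks: Sequence[np.ndarray] | None = None,
    dtype: str = "float32",
) -> None:
    """Write an RF scan (samples x lines x frames) with geometry attributes."""
    frames = scan.frames
    rf = np.stack([f.samples for f in frames], axis=2).astype(dtype)
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("rf", data=rf)
        ds.attrs["fs_mhz"] = frames[0].sampling_rate
        ds.attrs["c_mps"] = frames[0].sound_speed
        ds.attrs["line_pitch_mm"] = frames[0].line_pitch
        ds.attrs["plane_spacing_cm"] = scan.plane_spacing_cm
        if roi_masks is not None:
            h5.create_dataset("roi", data=np.stack(roi_masks, axis=2).astype(bool))


def read_scan(path: str | Path) -> tuple[RFScan, list[np.ndarray] | None]:
    with h5py.File(path, "r") as h5:
        ds = h5["rf"]
        rf = np.asarray(ds, dtype=np.float64)
        fs = float(ds.attrs["fs_mhz"])
        c = float(ds.attrs["c_mps"])
        pitch = float(ds.attrs["line_pitch_mm"])
        spacing = float(ds.attrs["plane_spacing_cm"])
        roi = None
        if "roi" in h5:
            roi_arr = np.asarray(h5["roi"], dtype=bool)
            roi = [roi_arr[:, :, k] for k in range(roi_arr.shape[2])]
    frames = [
        RFFrame(rf[:, :, k], fs, c, pitch) for k in range(rf.shape[2])
    ]
    return RFScan(frames, spacing), roi


def write_maps(path: str | Path, maps: Sequence[ParametricMap]) -> None:
    with h5py.File(path, "w") as h5:
        for m in maps:
            g = h5.create_dataset(f"{m.parameter_id}/frame{m.frame_index}", data=m.values)
            g.attrs["pixel_spacing_mm"] = m.pixel_spacing
            h5.create_dataset(
                f"{m.parameter_id}/frame{m.frame_index}_mask", data=m.roi_mask
            )


def export_map_png(path: str | Path, pmap: ParametricMap) -> None:
    """Render one parametric map with its fixed colour scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmin, vmax = MAP_COLOR_SCALES.get(pmap.parameter_id, (None, None))
    fig, ax = plt.subplots(figsize=(4, 4))
    shown = np.where(pmap.finite_mask(), pmap.values, np.nan)
    im = ax.imshow(shown, vmin=vmin, vmax=vmax, cmap="jet", aspect="auto")
    fig.colorbar(im, ax=ax, label=pmap.parameter_id)
    ax.set_xlabel("lateral window")
    ax.set_ylabel("axial window")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_manifest_csv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
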