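"""Readers and writers for multispectral images and result maps.

Supported inputs: a multi-page TIFF with pages ordered Blue, Green, Red, IR,
or four single-band PNG/TIFF files named by band.  Integer inputs are
rescaled to (0, 1] by the dtype maximum; the separation itself is invariant
to per-band gain, so the exact normalization is immaterial.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .optical_model import BAND_LABELS, MultispectralImage, SourceSet


def _rescale(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def read_multiband_tiff(path) -> MultispectralImage:
    """Read a 4-page TIFF (page order Blue, Green, Red, IR)."""
    pages = tifffile.imread(str(path))
    pages = np.asarray(pages)
    if pages.ndim != 3 or pages.shape[0] != 4:
        raise ValueError(f"{path}: expected 4 single-band pages, got shape "
                         f"{pages.shape}")
    return MultispectralImage(bands=_rescale(pages))


def read_band_files(paths: dict) -> MultispectralImage:
    """Read four single-band files keyed by band label (any order)."""
    missing = set(BAND_LABELS) - {k.lower() for k in paths}
    if missing:
        raise ValueError(f"missing band files: {sorted(missing)}")
    bands = []
    for label in BAND_LABELS:
        key = next(k for k in paths if k.lower() == label)
        arr = iio.imread(str(paths[key]))
        if arr.ndim != 2:
            raise ValueError(f"{paths[key]}: expected a single-band image")
        bands.append(_rescale(arr))
    return MultispectralImage(bands=np.stack(bands))


def write_multiband_tiff(path, image: MultispectralImage) -> None:
    """Write the four bands as float32 TIFF pages in canonical order."""
    tifffile.imwrite(str(path), image.bands.astype(np.float32),
                     photometric="minisblack")


def write_source_maps(out_dir, sources: SourceSet, prefix: str = "") -> None:
    """Export each present map as a 16-bit PNG normalized to [0, 1].

    Normalization is for image export only; numeric outputs keep their
    native (scale-indeterminate) values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in sources.labels:
        m = sources.map2d(name).astype(float)
        rng = np.ptp(m)
        norm = (m - m.min()) / rng if rng > 0 else np.zeros_like(m)
        iio.imwrite(out_dir / f"{prefix}{name}.png",
                    (norm * 65535).astype(np.uint16))


def write_ground_truth(out_dir, sources: SourceSet, mixing,
                       config=None, seed=None) -> None:
    """Sidecar for simulated images: source maps, mixing CSV, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "sources.npz", shape=np.array(sources.shape),
             **{k: sources[k] for k in sources.labels})
    pd.DataFrame(np.asarray(mixing), index=BAND_LABELS,
                 columns=["oxy", "deoxy", "melanin", "shading"]).to_csv(
        out_dir / "mixing_matrix.csv")
    manifest = {"seed": seed}
    if config is not None:
        manifest["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in vars(config).items()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
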