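"""Text-based trajectory and metrics output.

Frames are line-delimited records, one fiber per line:
``id lineage origin_tag x0 y0 x1 y1 ...`` (coordinates in µm), with
``# time <t>`` header lines separating frames.  A JSON run manifest records
the full configuration, seed and package version.
"""

from __future__ import annotations

import json
import os
from typing import List, Tuple

import numpy as np

from . import __version__
from .params import SimConfig


def write_frames(path, frames: List[Tuple[float, list]]) -> None:
    with open(path, "w") as fh:
        for t, frame in frames:
            fh.write(f"# time {t:.6g}\n")
            for rec in frame:
                coords = " ".join(f"{v:.6g}" for v in np.ravel(rec["vertices"]))
                fh.write(f"{rec['id']} {rec['lineage']} {rec['origin_tag']} {coords}\n")


def read_frames(path) -> List[Tuple[float, list]]:
    frames: List[Tuple[float, list]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# time"):
                frames.append((float(line.split()[2]), []))
                continue
            parts = line.split()
            fid, lineage, tag = int(parts[0]), parts[1], int(parts[2])
            xy = np.array(parts[3:], dtype=float).reshape(-1, 2)
            frames[-1][1].append({"id": fid, "lineage": lineage,
                                  "origin_tag": tag, "vertices": xy})
    return frames


def write_manifest(path, config: SimConfig, seed: int, extra: dict = None) -> None:
    manifest = {"config": config.to_dict(), "seed": int(seed),
                "filasim_version": __version__}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def write_image_png16(path, values: np.ndarray) -> None:
    """16-bit grayscale image (max intensity mapped to full scale)."""
    import imageio.v3 as iio

    v = np.asarray(values, dtype=float)
    peak = v.max()
    scaled = np.zeros_like(v, dtype=np.uint16) if peak <= 0 else \
        np.round(v / peak * 65535).astype(np.uint16)
    iio.imwrite(os.fspath(path), scaled[::-1])  # y up
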