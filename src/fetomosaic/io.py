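"""Format glue: frame sequences, transform JSON, mosaics, reports."""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .flow import Frame
from .geometry import AffineTransform
from .mosaic import MosaicCanvas, TrajectorySolution

__all__ = [
    "SequenceError",
    "read_sequence",
    "write_frames",
    "write_transforms",
    "read_transforms",
    "write_mosaic_png",
]

TRANSFORM_CONVENTION = "maps frame i+1 into frame i"
_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
_VIDEO_EXTENSIONS = (".mp4", ".avi", ".mov", ".mkv")


class SequenceError(IOError):
    """Unreadable, empty, or inconsistent frame sequence."""


def _numeric_key(path: Path):
    # zero-pad-insensitive ordering: frame_2 before frame_10
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def _to_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return img.astype(float)


def read_sequence(path) -> list[Frame]:
    """Read an ordered frame sequence from a directory of images or a video
    container.  Directory frames are sorted with numeric-aware ordering; a
    ``manifest.json`` with a ``"frames"`` list overrides the order.  All
    frames must share one size.
    """
    path = Path(path)
    if path.is_dir():
        manifest = path / "manifest.json"
        if manifest.exists():
            names = json.loads(manifest.read_text()).get("frames", [])
            files = [path / n for n in names]
            missing = [f.name for f in files if not f.exists()]
            if missing:
                raise SequenceError(f"manifest lists missing frames: {missing[:5]}")
        else:
            files = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
                key=_numeric_key,
            )
        if not files:
            raise SequenceError(f"no frames found in {path}")
        frames = [Frame(_to_float(iio.imread(f)), index=i) for i, f in enumerate(files)]
    elif path.suffix.lower() in _VIDEO_EXTENSIONS:
        try:
            stack = iio.imread(path)  # requires a video backend plugin
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise SequenceError(f"cannot decode video container {path}: {exc}") from exc
        frames = [Frame(_to_float(img), index=i) for i, img in enumerate(stack)]
    else:
        raise SequenceError(f"not a frame directory or video file: {path}")

    sizes = {f.shape for f in frames}
    if len(sizes) > 1:
        raise SequenceError(f"frames disagree in size: {sorted(sizes)}")
    return frames


def write_frames(frames, out_dir, prefix: str = "frame") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        arr = np.asarray(getattr(f, "pixels", f))
        img8 = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, img8)
        paths.append(p)
    return paths


def write_transforms(path, pairwise, traj: TrajectorySolution | None = None) -> None:
    """Serialize transforms to the JSON schema.  Each transform is the flat
    list [a11, a12, b1, a21, a22, b2]; the convention string is mandatory
    to prevent silent direction bugs."""
    payload = {
        "convention": TRANSFORM_CONVENTION,
        "reference_index": None if traj is None else traj.reference_index,
        "pairwise": [
            (p.transform if hasattr(p, "transform") else p).to_list() for p in pairwise
        ],
        "absolute": None if traj is None else [A.to_list() for A in traj.absolute],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transforms(path):
    """Read the transform JSON schema; returns (pairwise, trajectory | None)."""
    data = json.loads(Path(path).read_text())
    if data.get("convention") != TRANSFORM_CONVENTION:
        raise ValueError(
            f"transform file convention {data.get('convention')!r} != {TRANSFORM_CONVENTION!r}"
        )
    pairwise = [AffineTransform.from_list(v) for v in data["pairwise"]]
    traj = None
    if data.get("absolute"):
        traj = TrajectorySolution(
            reference_index=int(data["reference_index"]),
            absolute=[AffineTransform.from_list(v) for v in data["absolute"]],
        )
    return pairwise, traj


def write_mosaic_png(path, canvas: MosaicCanvas) -> None:
    img8 = np.clip(canvas.image * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), img8)
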