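"""Reading and writing echo loops, masks, flow frames and manifests.

Frames travel as grayscale float arrays in [0, 1].  On disk a loop is either
a single AVI (if an imageio video backend is available) or a directory of
zero-padded numbered PNG/TIFF frames; numbered sequences are the canonical
lossless interchange format.  Filename numbering must be unique and gap-free
— silent reordering or missing frames would corrupt optical flow, so both
are rejected loudly.  Non-square inputs are zero-padded to square before
resizing, which preserves wall geometry.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from .flow import FlowFrameEncoding
from .phantom import EchoSequence, Subject

__all__ = [
    "read_echo",
    "write_frames",
    "write_masks",
    "read_masks",
    "write_flow_frames",
    "write_cohort",
    "write_manifest",
    "save_yaml",
    "load_yaml",
]

_NUM = re.compile(r"(\d+)")


def _to_unit_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.dtype == np.uint8:
        img = img / 255.0
    elif img.dtype == np.uint16:
        img = img / 65535.0
    return np.clip(img.astype(np.float32), 0.0, 1.0)


def _pad_square_resize(img: np.ndarray, size: int | None) -> np.ndarray:
    h, w = img.shape
    if h != w:
        side = max(h, w)
        canvas = np.zeros((side, side), dtype=img.dtype)
        r0, c0 = (side - h) // 2, (side - w) // 2
        canvas[r0:r0 + h, c0:c0 + w] = img
        img = canvas
    if size is not None and img.shape[0] != size:
        img = resize(img, (size, size), anti_aliasing=True).astype(np.float32)
    return img


def _numbered_files(directory: Path) -> list[Path]:
    files = [p for p in sorted(directory.iterdir())
             if p.suffix.lower() in (".png", ".tif", ".tiff")]
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames in {directory}")
    nums = []
    for p in files:
        m = _NUM.findall(p.stem)
        if not m:
            raise ValueError(f"frame filename without a number: {p.name}")
        nums.append(int(m[-1]))
    order = np.argsort(nums)
    nums_sorted = [nums[i] for i in order]
    if len(set(nums_sorted)) != len(nums_sorted):
        raise ValueError(f"duplicate frame numbers in {directory}")
    if nums_sorted != list(range(nums_sorted[0], nums_sorted[0] + len(nums_sorted))):
        raise ValueError(f"frame numbering has gaps in {directory}")
    return [files[i] for i in order]


def read_echo(path: str | Path, view: str = "A4C", subject_id: str = "",
              label: str = "", input_size: int | None = None) -> EchoSequence:
    """Load a loop from an AVI file or a numbered image directory."""
    path = Path(path)
    if path.is_dir():
        frames = [_to_unit_gray(iio.imread(p)) for p in _numbered_files(path)]
    elif path.exists():
        try:
            raw = iio.imread(path)
        except Exception as e:
            raise RuntimeError(
                f"cannot read {path}: no video backend available for this format "
                f"({e}); use a numbered PNG/TIFF directory instead") from e
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        frames = [_to_unit_gray(f) for f in raw]
    else:
        raise FileNotFoundError(str(path))
    if not frames:
        raise ValueError(f"zero frames read from {path}")
    frames = [_pad_square_resize(f, input_size) for f in frames]
    return EchoSequence(frames=np.stack(frames), view=view,
                        subject_id=subject_id or path.stem, label=label)


def write_frames(seq: EchoSequence, directory: str | Path) -> list[Path]:
    """Write a loop as zero-padded numbered 8-bit PNGs (lossless round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        p = directory / f"frame_{i:04d}.png"
        iio.imwrite(p, np.round(frame * 255).astype(np.uint8))
        paths.append(p)
    return paths


def write_masks(masks: np.ndarray, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(np.asarray(masks)):
        p = directory / f"mask_{i:04d}.png"
        iio.imwrite(p, (m.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_masks(directory: str | Path) -> np.ndarray:
    files = _numbered_files(Path(directory))
    return np.stack([iio.imread(p) > 127 for p in files])


def write_flow_frames(encs: list[FlowFrameEncoding], directory: str | Path,
                      label: str = "", view: str = "") -> list[tuple[Path, Path]]:
    """Save 8-bit flow frames as paired ``*_x.png`` / ``*_y.png`` files,
    under per-label / per-view subdirectories when given."""
    directory = Path(directory)
    if label:
        directory = directory / label
    if view:
        directory = directory / view
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, e in enumerate(encs):
        px = directory / f"flow_{i:04d}_x.png"
        py = directory / f"flow_{i:04d}_y.png"
        iio.imwrite(px, e.x_frame)
        iio.imwrite(py, e.y_frame)
        out.append((px, py))
    return out


def write_cohort(subjects: list[Subject], directory: str | Path,
                 with_masks: bool = True) -> pd.DataFrame:
    """Write all loops (and masks) of a cohort plus a manifest CSV."""
    directory = Path(directory)
    rows = []
    for s in subjects:
        for view, (seq, gt) in s.views.items():
            d = directory / s.subject_id / view
            write_frames(seq, d / "frames")
            if with_masks:
                write_masks(gt.wall_masks, d / "masks")
            rows.append({"subject_id": s.subject_id, "view": view,
                         "label": s.label, "path": str(d / "frames")})
    manifest = pd.DataFrame(rows)
    directory.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
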