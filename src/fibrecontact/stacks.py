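"""Containers and file I/O for slice-ordered EM volumes and binary masks.

Coordinate convention, used everywhere in this package: indices are 0-based,
axis order is ``(z, y, x)`` with ``z`` the acquisition (slice) axis and ``y``
increasing downward in the raster.  Masks are stored on disk as 8-bit images
with background 0 and foreground 255; on read, any nonzero pixel counts as
foreground.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

MASK_FOREGROUND = 255

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclasses.dataclass
class VoxelStack:
    """An ordered stack of 2D integer-intensity slices.

    Parameters
    ----------
    slices
        Array of shape ``(n_slices, height, width)`` with non-negative
        integer grey values.
    voxel_size
        Physical voxel dimensions ``(z, y, x)`` in nanometres.  Metadata
        only; no operation in this package resamples by it.
    provenance
        Free-text label describing where the stack came from.
    """

    slices: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got shape {arr.shape}")
        if arr.shape[0] == 0:
            raise ValueError("stack contains zero slices")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"intensities must be integers, got dtype {arr.dtype}")
        if arr.size and int(arr.min()) < 0:
            raise ValueError("intensities must be non-negative")
        self.slices = arr

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.slices)


@dataclasses.dataclass
class MaskStack:
    """An ordered stack of 2D binary masks with the same shape contract as
    :class:`VoxelStack`.  Any nonzero input pixel is treated as foreground."""

    slices: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got shape {arr.shape}")
        if arr.shape[0] == 0:
            raise ValueError("mask stack contains zero slices")
        self.slices = arr != 0 if arr.dtype != bool else arr

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.slices)

    def foreground_count(self) -> int:
        return int(self.slices.sum())


def _read_frame(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        frame = tifffile.imread(path)
    else:
        frame = iio.imread(path)
    frame = np.asarray(frame)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        # colour image: collapse to luminance-free max so binary masks survive
        frame = frame.max(axis=-1)
    if frame.ndim != 2:
        raise ValueError(f"{path} is not a single 2D slice (shape {frame.shape})")
    return frame


def _frames_from_path(path: Path) -> list[np.ndarray]:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no slice images found in directory {path}")
        return [_read_frame(p) for p in files]
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = np.asarray(tifffile.imread(path))
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        return list(arr)
    raise ValueError(f"cannot interpret {path} (shape {arr.shape}) as a stack")


def read_stack(path, kind: str = "intensity") -> VoxelStack | MaskStack:
    """Read an intensity or mask stack from a multi-page TIFF or a directory
    of per-slice images.

    Directory entries are ordered by lexicographic filename sort, which is
    deterministic without sidecar metadata; TIFF pages keep file order.

    Parameters
    ----------
    path
        Multi-page TIFF file, single-slice image, or directory of slices.
    kind
        ``"intensity"`` returns a :class:`VoxelStack`; ``"mask"`` binarises
        each slice by a nonzero test and returns a :class:`MaskStack`.
    """
    if kind not in ("intensity", "mask"):
        raise ValueError(f"kind must be 'intensity' or 'mask', got {kind!r}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"stack path does not exist: {p}")
    frames = _frames_from_path(p)
    shape0 = frames[0].shape
    for i, frame in enumerate(frames):
        if frame.shape != shape0:
            raise ValueError(
                f"inconsistent slice shapes: slice 0 is {shape0} but "
                f"slice {i} is {frame.shape}"
            )
    stack = np.stack(frames)
    if kind == "mask":
        return MaskStack(stack)
    return VoxelStack(stack, provenance=str(p))


def write_mask_stack(masks: MaskStack, path) -> None:
    """Write a mask stack as lossless 8-bit binary images (0/255).

    A ``.tif``/``.tiff`` path becomes one multi-page TIFF; any other path is
    created as a directory holding one PNG per slice, with the zero-padded
    slice index in each filename.
    """
    data = (masks.slices.astype(np.uint8)) * MASK_FOREGROUND
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, data, photometric="minisblack")
        return
    p.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(data):
        iio.imwrite(p / f"mask_{i:04d}.png", frame)


def write_stack(stack: VoxelStack, path) -> None:
    """Write an intensity stack as a multi-page TIFF (``.tif`` path) or a
    directory of per-slice PNGs."""
    data = stack.slices
    if data.dtype not in (np.uint8, np.uint16):
        data = data.astype(np.uint16 if int(data.max(initial=0)) > 255 else np.uint8)
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, data, photometric="minisblack")
        return
    p.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(data):
        iio.imwrite(p / f"slice_{i:04d}.png", frame)


# Overlay colours (RGB): cell body in blue, collagen fibres in yellow.
CELL_COLOUR = (70, 130, 235)
FIBRE_COLOUR = (255, 215, 0)


def write_overlay(stack: VoxelStack, cell: MaskStack, fibres: MaskStack, path) -> None:
    """Write per-slice colour overlays: grey intensity base with the cell
    mask and the fibre mask painted in two distinct colours.

    The fibre colour is drawn last, so on (contractually impossible)
    cell/fibre overlap the fibre colour wins.
    """
    if not (stack.slices.shape == cell.slices.shape == fibres.slices.shape):
        raise ValueError(
            "shape mismatch between stack "
            f"{stack.slices.shape}, cell {cell.slices.shape} and "
            f"fibre {fibres.slices.shape} masks"
        )
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    peak = max(int(stack.slices.max()), 1)
    for i in range(stack.n_slices):
        grey = (stack.slices[i].astype(np.float64) * (255.0 / peak)).astype(np.uint8)
        rgb = np.repeat(grey[:, :, None], 3, axis=2)
        rgb[cell.slices[i]] = CELL_COLOUR
        rgb[fibres.slices[i]] = FIBRE_COLOUR
        iio.imwrite(p / f"overlay_{i:04d}.png", rgb)
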