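"""Local-mean adaptive thresholding of single EM slices.

The segmentation rule is the classic mean-of-block adaptive threshold: a
pixel is compared against ``T = local_mean - offset`` where ``local_mean``
is the arithmetic mean of the ``block_size x block_size`` window centred on
the pixel, with out-of-bounds samples supplied by edge replication.  With
``dark_foreground`` polarity (the default, appropriate for collagen fibres
that image darker than the resin background) a pixel is foreground iff its
intensity is at or below ``T``; ``bright_foreground`` selects the exact
complement.

For integer images the window mean is computed from exact integer window
sums (an integral image in int64), so the result is bit-identical to a
naive per-pixel window loop — including at ties, where intensity equals
``T`` exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

DARK_FOREGROUND = "dark_foreground"
BRIGHT_FOREGROUND = "bright_foreground"


@dataclasses.dataclass(frozen=True)
class ThresholdParams:
    """Parameters of the adaptive threshold.

    Attributes
    ----------
    block_size
        Odd window edge length in pixels (default 13).
    offset
        Signed value subtracted from the local mean to form the comparison
        bound ``T`` (default 6).
    polarity
        ``"dark_foreground"`` keeps pixels at least ``offset`` below the
        local mean; ``"bright_foreground"`` keeps the complement.
    """

    block_size: int = 13
    offset: float = 6.0
    polarity: str = DARK_FOREGROUND

    def __post_init__(self) -> None:
        _validate_block_size(self.block_size)
        if self.polarity not in (DARK_FOREGROUND, BRIGHT_FOREGROUND):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def _validate_block_size(block_size: int) -> None:
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")


def local_mean(image: np.ndarray, block_size: int) -> np.ndarray:
    """Mean of the ``block_size``-square window centred on each pixel.

    Out-of-bounds window samples are supplied by edge replication.  Window
    sums are accumulated exactly (int64 integral image for integer input),
    then divided once, so the output equals a naive windowed average to the
    last bit for integer images.
    """
    _validate_block_size(block_size)
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {img.shape}")
    r = block_size // 2
    padded = np.pad(img, r, mode="edge")
    acc_dtype = np.int64 if np.issubdtype(img.dtype, np.integer) else np.float64
    integral = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=acc_dtype)
    np.cumsum(padded, axis=0, dtype=acc_dtype, out=integral[1:, 1:])
    np.cumsum(integral[1:, 1:], axis=1, out=integral[1:, 1:])
    b = block_size
    window_sum = (
        integral[b:, b:] - integral[:-b, b:] - integral[b:, :-b] + integral[:-b, :-b]
    )
    return window_sum / (b * b)


def threshold_slice(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Binarise one slice against its local mean.

    Returns a boolean mask.  The two polarities are exact complements: ties
    (intensity exactly equal to ``local_mean - offset``) fall to foreground
    under ``dark_foreground``.
    """
    img = np.asarray(image)
    bound = local_mean(img, params.block_size) - params.offset
    if params.polarity == DARK_FOREGROUND:
        return img <= bound
    return img > bound
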