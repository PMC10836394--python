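"""MRC image reading and 8-bit PNG preview rendering.

Renders dashboard-sized previews of motion-corrected micrographs and
their calculated/experimental CTF images.  Intensities are normalized by
percentile (1–99 by default) rather than min–max so a handful of hot
pixels cannot wash out the preview.  The MRC reader/writer covers the
subset RELION emits for 2D images: MRC2014 headers, modes 0 (int8),
1 (int16) and 2 (float32), little-endian, with the pixel size taken
from the header cell dimensions.  Images are kept row-major with the
origin at top-left; no axis flips are applied.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "Image2D",
    "MrcFormatError",
    "read_mrc",
    "write_mrc",
    "normalize_to_8bit",
    "bin_image",
    "render_preview_pair",
]

_HEADER_SIZE = 1024
_MAP_MAGIC = b"MAP "
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}


class MrcFormatError(ValueError):
    pass


@dataclass
class Image2D:
    """A 2D image plus its physical sampling (Å per pixel), if known."""

    pixels: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise MrcFormatError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise MrcFormatError("image contains non-finite pixels")


def read_mrc(path) -> Image2D:
    """Read the first 2D section of an MRC file.

    Multi-section stacks are accepted; only the first section is
    returned (the count is logged).  Bad magic, truncated data or an
    unsupported mode raise :class:`MrcFormatError`.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MrcFormatError(f"{path}: truncated header ({len(header)} bytes)")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        magic = header[208:212]
        if magic != _MAP_MAGIC:
            raise MrcFormatError(f"{path}: bad MRC magic {magic!r}")
        if nx < 1 or ny < 1 or nz < 1:
            raise MrcFormatError(f"{path}: bad dimensions {(nx, ny, nz)}")
        if mode not in _MODE_DTYPES:
            raise MrcFormatError(
                f"{path}: unsupported MRC mode {mode} (supported: 0, 1, 2)"
            )
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        n_section = nx * ny * dtype.itemsize
        data = fh.read(n_section)
        if len(data) < n_section:
            raise MrcFormatError(
                f"{path}: truncated data ({len(data)} of {n_section} bytes)"
            )
    if nz > 1:
        logger.info("%s: stack of %d sections, returning the first", path, nz)
    pixels = np.frombuffer(data, dtype=dtype).reshape(ny, nx)
    pixel_size = cella[0] / mx if mx > 0 and cella[0] > 0 else None
    return Image2D(pixels=pixels.astype(pixels.dtype.newbyteorder("=")),
                   pixel_size=pixel_size)


def write_mrc(img: Image2D, path, mode: int = 2) -> None:
    """Write a 2D image as a single-section MRC2014 file."""
    if mode not in _MODE_DTYPES:
        raise MrcFormatError(f"unsupported MRC mode {mode}")
    pixels = np.ascontiguousarray(img.pixels, dtype=_MODE_DTYPES[mode])
    ny, nx = pixels.shape
    px = img.pixel_size if img.pixel_size else 1.0
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, mode)  # nx ny nz mode
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx my mz
    struct.pack_into("<3f", header, 40, nx * px, ny * px, px)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76,
                     float(pixels.min()), float(pixels.max()),
                     float(pixels.mean()))
    header[208:212] = _MAP_MAGIC
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(pixels.tobytes())


def normalize_to_8bit(img: Image2D, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Linear map of the [p_lo, p_hi] intensity percentiles onto [0, 255].

    Values outside the percentile window are clipped; a constant image
    maps to mid-gray 128.  The mapping is monotone in pixel intensity.
    """
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError(f"need 0 <= p_lo < p_hi <= 100, got ({p_lo}, {p_hi})")
    pixels = np.asarray(img.pixels, dtype=float)
    lo, hi = np.percentile(pixels, [p_lo, p_hi])
    if hi <= lo:
        return np.full(pixels.shape, 128, dtype=np.uint8)
    scaled = (pixels - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def bin_image(img: Image2D, factor: int) -> Image2D:
    """Mean-pool by an integer factor; output dims are ceil(input/factor).

    Trailing partial blocks average over the pixels they actually cover.
    """
    if factor < 1:
        raise ValueError(f"binning factor must be >= 1, got {factor}")
    if factor == 1:
        return Image2D(img.pixels.copy(), img.pixel_size)
    pixels = np.asarray(img.pixels, dtype=float)
    ny, nx = pixels.shape
    row_starts = np.arange(0, ny, factor)
    col_starts = np.arange(0, nx, factor)
    sums = np.add.reduceat(np.add.reduceat(pixels, row_starts, axis=0),
                           col_starts, axis=1)
    row_counts = np.minimum(row_starts + factor, ny) - row_starts
    col_counts = np.minimum(col_starts + factor, nx) - col_starts
    counts = np.outer(row_counts, col_counts)
    px = img.pixel_size * factor if img.pixel_size else None
    return Image2D(sums / counts, px)


def _write_png(array: np.ndarray, path: Path) -> None:
    Image.fromarray(array, mode="L").save(path, format="PNG")


def render_preview_pair(
    micrograph: Image2D,
    ctf_image: Image2D,
    out_dir,
    stem: str,
    binning: int = 4,
    p_lo: float = 1.0,
    p_hi: float = 99.0,
    composite: bool = False,
) -> Tuple[Path, ...]:
    """Write ``<stem>.png`` and ``<stem>_ctf.png`` previews.

    Output is deterministic: rendering the same inputs twice produces
    byte-identical files.  With ``composite=True`` an additional
    side-by-side ``<stem>_pair.png`` is written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mic8 = normalize_to_8bit(bin_image(micrograph, binning), p_lo, p_hi)
    ctf8 = normalize_to_8bit(bin_image(ctf_image, binning), p_lo, p_hi)
    mic_path = out_dir / f"{stem}.png"
    ctf_path = out_dir / f"{stem}_ctf.png"
    _write_png(mic8, mic_path)
    _write_png(ctf8, ctf_path)
    paths = [mic_path, ctf_path]
    if composite:
        h = max(mic8.shape[0], ctf8.shape[0])
        canvas = np.zeros((h, mic8.shape[1] + ctf8.shape[1]), dtype=np.uint8)
        canvas[: mic8.shape[0], : mic8.shape[1]] = mic8
        canvas[: ctf8.shape[0], mic8.shape[1] :] = ctf8
        pair_path = out_dir / f"{stem}_pair.png"
        _write_png(canvas, pair_path)
        paths.append(pair_path)
    return tuple(paths)
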