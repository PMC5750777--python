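"""Segmented single-cell images: container, validation and image I/O.

A cell is a pair of same-shape rasters: an 8-bit intensity image and an
integer label mask with the canonical encoding 0 = background,
1 = cytoplasm, 2 = nucleus.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND, CYTOPLASM, NUCLEUS = 0, 1, 2

#: ITU-R 601 luma weights used to collapse RGB input to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


class InvalidCellError(ValueError):
    """Raised when an intensity/mask pair violates the cell contract."""


@dataclasses.dataclass(frozen=True)
class SegmentedCell:
    """An intensity raster plus a 3-label segmentation mask.

    Parameters
    ----------
    intensity
        2-D uint8-range grayscale image.
    mask
        2-D integer raster, same shape, values in {0, 1, 2}
        (background / cytoplasm / nucleus).
    pixel_size
        Optional physical pixel pitch in micrometres per pixel. Metadata
        only; no feature uses it.
    """

    intensity: np.ndarray
    mask: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity)
        if intensity.ndim == 3:
            intensity = rgb_to_gray(intensity)
        intensity = intensity.astype(float)
        mask = np.asarray(self.mask).astype(np.int64)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "mask", mask)
        self._validate()

    def _validate(self) -> None:
        if self.intensity.ndim != 2 or self.mask.ndim != 2:
            raise InvalidCellError("intensity and mask must be 2-D rasters")
        if self.intensity.shape != self.mask.shape:
            raise InvalidCellError(
                f"shape mismatch: intensity {self.intensity.shape} "
                f"vs mask {self.mask.shape}"
            )
        labels = np.unique(self.mask)
        if not np.isin(labels, (BACKGROUND, CYTOPLASM, NUCLEUS)).all():
            raise InvalidCellError(f"mask labels {labels} outside {{0,1,2}}")
        if not (self.mask == NUCLEUS).any():
            raise InvalidCellError("empty nucleus region")
        if not (self.mask == CYTOPLASM).any():
            raise InvalidCellError("empty cytoplasm region")

    @property
    def nucleus(self) -> np.ndarray:
        return self.mask == NUCLEUS

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.mask == CYTOPLASM

    @property
    def cell_region(self) -> np.ndarray:
        """Nucleus plus cytoplasm."""
        return self.mask != BACKGROUND


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an RGB raster to grayscale with ITU-R 601 luma weights."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return rgb[..., :3] @ _LUMA


def load_cell(
    intensity_path: str | Path,
    mask_path: str | Path,
    color_table: dict[tuple[int, ...], int] | None = None,
    pixel_size: float | None = None,
) -> SegmentedCell:
    """Read an intensity/mask image pair (PNG or TIFF) into a SegmentedCell.

    ``color_table`` maps mask pixel values (RGB tuples, or 1-tuples for
    grayscale masks) onto the canonical 0/1/2 labels, for ground-truth
    masks that encode regions as colors. Without it the mask image is
    expected to already hold 0/1/2.
    """
    intensity = np.asarray(Image.open(intensity_path))
    mask_img = np.asarray(Image.open(mask_path))
    if color_table is not None:
        mask = _apply_color_table(mask_img, color_table)
    else:
        mask = mask_img
    return SegmentedCell(intensity=intensity, mask=mask, pixel_size=pixel_size)


def save_cell(cell: SegmentedCell, intensity_path: str | Path, mask_path: str | Path) -> None:
    """Write a cell as an 8-bit PNG/TIFF pair (mask stores raw 0/1/2)."""
    Image.fromarray(np.clip(cell.intensity, 0, 255).astype(np.uint8)).save(intensity_path)
    Image.fromarray(cell.mask.astype(np.uint8)).save(mask_path)


def _apply_color_table(mask_img: np.ndarray, table: dict[tuple[int, ...], int]) -> np.ndarray:
    if mask_img.ndim == 2:
        mask_img = mask_img[..., None]
    out = np.full(mask_img.shape[:2], -1, dtype=np.int64)
    for color, label in table.items():
        hit = (mask_img[..., : len(color)] == np.asarray(color)).all(axis=-1)
        out[hit] = label
    if (out < 0).any():
        raise InvalidCellError("mask contains colors missing from the color table")
    return out
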