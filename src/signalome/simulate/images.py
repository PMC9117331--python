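"""Synthetic multi-channel fluorescence images of visually barcoded cells.

Each image stack carries a nuclear-marker channel, a phase-contrast-like body
channel, and one channel per fluorophore in the panel.  Cells are rendered as
random ellipses with concentric elliptical nuclei; the clone's barcode decides
which fluorophore channel carries signal and with which subcellular pattern:

``whole_cell``
    uniform over the cell mask
``cytoplasmic``
    cell minus nucleus (nuclear-export-signal pattern)
``nuclear``
    nucleus only
``peroxisome``
    5-20 bright puncta scattered in the cytoplasm
``er``
    a perinuclear annulus a few pixels wide

Pixel convention is 0-based (row, col); stacks are 16-bit unsigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk, ellipse
from skimage.morphology import disk as disk_footprint

from signalome.panels import BarcodePanel

log = logging.getLogger(__name__)

#: Channel name of the nuclear marker (histone-fusion analogue).
NUCLEAR_CHANNEL = "nuclei"
#: Channel name of the body / phase-contrast-like channel used to segment cells.
BODY_CHANNEL = "dpc"


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition-noise model: offset + shot noise + Gaussian read noise.

    ``brightness_cv`` is the coefficient of variation of a per-cell lognormal
    expression factor (cells of one clone do not all express equally).
    """

    background: float = 100.0
    gaussian_sd: float = 60.0
    poisson: bool = True
    brightness_cv: float = 0.25

    @classmethod
    def none(cls) -> "NoiseParams":
        """Noise-free rendering (exact masks; used by oracle tests)."""
        return cls(background=0.0, gaussian_sd=0.0, poisson=False, brightness_cv=0.0)


@dataclass
class CloneImages:
    """All rendered fields of view for one clone."""

    clone: str
    stacks: list[np.ndarray]  # each (C, H, W) uint16
    label_maps: list[np.ndarray]  # each (H, W) uint16; 0 = background


@dataclass
class ImageSet:
    """A rendered image collection plus its ground truth.

    ``truth`` has one row per placed cell: clone, image index within the
    clone, cell label in the label map, and the true barcode.
    """

    channels: tuple[str, ...]
    clones: dict[str, CloneImages]
    truth: pd.DataFrame
    n_skipped: int = 0


# geometry defaults: cell area 300-1200 px, nucleus 30% of cell area,
# ER annulus width 3 px, puncta radius 1-2 px
_CELL_AREA = (300.0, 1200.0)
_NUCLEUS_FRACTION = 0.30
_ER_WIDTH = 3
_PUNCTA = (5, 20)
_PUNCTA_RADIUS = (1, 2)

_SIGNAL = 2500.0  # expected fluorophore counts over the pattern
_NUCLEAR_SIGNAL = 3000.0
_BODY_SIGNAL = 1200.0


def _ellipse_mask(shape, center, area, aspect, angle, rng=None):
    """Boolean mask of an ellipse of the given area/aspect/orientation."""
    # area = pi * a * b with b = aspect * a
    a = math.sqrt(area / (math.pi * aspect))
    b = aspect * a
    rr, cc = ellipse(center[0], center[1], a, b, shape=shape, rotation=angle)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _render_localization(loc, cell_mask, nucleus_mask, rng):
    """Binary pattern mask for one localization inside one cell."""
    if loc == "whole_cell":
        return cell_mask
    if loc == "cytoplasmic":
        return cell_mask & ~nucleus_mask
    if loc == "nuclear":
        return nucleus_mask
    if loc == "er":
        ring = ndi.binary_dilation(nucleus_mask, disk_footprint(_ER_WIDTH))
        return ring & cell_mask & ~nucleus_mask
    if loc == "peroxisome":
        cyto = cell_mask & ~nucleus_mask
        rows, cols = np.nonzero(cyto)
        pattern = np.zeros_like(cell_mask)
        if rows.size == 0:
            return pattern
        n_puncta = int(rng.integers(_PUNCTA[0], _PUNCTA[1] + 1))
        idx = rng.integers(0, rows.size, size=n_puncta)
        for r, c in zip(rows[idx], cols[idx]):
            radius = float(rng.uniform(*_PUNCTA_RADIUS))
            rr, cc = disk((r, c), radius + 0.5, shape=cell_mask.shape)
            pattern[rr, cc] = True
        return pattern & cyto
    raise ValueError(f"unknown localization {loc!r}")


def _place_cell(shape, occupied, rng, max_tries=40, center=None):
    """Sample a non-overlapping cell+nucleus geometry; None if placement fails."""
    h, w = shape
    for _ in range(max_tries):
        area = float(rng.uniform(*_CELL_AREA))
        aspect = float(rng.uniform(0.55, 1.0))
        angle = float(rng.uniform(0.0, math.pi))
        radius = math.sqrt(area / math.pi)
        margin = int(radius / math.sqrt(aspect)) + 2
        if 2 * margin >= min(h, w):
            continue
        if center is None:
            ctr = (
                float(rng.uniform(margin, h - margin)),
                float(rng.uniform(margin, w - margin)),
            )
        else:
            ctr = center
        cell = _ellipse_mask(shape, ctr, area, aspect, angle)
        if not cell.any() or (cell & occupied).any():
            if center is not None:
                return None
            continue
        nucleus = _ellipse_mask(shape, ctr, _NUCLEUS_FRACTION * area, aspect, angle)
        nucleus &= cell
        return cell, nucleus
    return None


def _apply_noise(expected, noise, rng):
    img = expected + noise.background
    if noise.poisson:
        img = rng.poisson(img).astype(np.float64)
    if noise.gaussian_sd > 0:
        img = img + rng.normal(0.0, noise.gaussian_sd, size=img.shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def generate_barcode_images(
    panel: BarcodePanel,
    n_cells_per_clone: int,
    image_shape: tuple[int, int] = (256, 256),
    noise: NoiseParams | None = None,
    seed: int = 0,
    cells_per_image: int | None = None,
) -> ImageSet:
    """Render per-clone image stacks with ground-truth label maps.

    Parameters
    ----------
    panel
        The barcode panel; one clone is rendered per barcode.
    n_cells_per_clone
        Cells to place for each clone (spread over as many fields of view as
        needed).  May be 0, yielding background-only images.
    image_shape
        (rows, cols), at least 64 x 64.
    noise
        Acquisition noise model; defaults to :class:`NoiseParams` defaults.
    seed
        Master seed; fans out to independent per-clone child streams.
    cells_per_image
        Target cells per field of view; defaults to a sparse density (one
        cell per ~8000 px).  Higher densities make overlapping placements
        fail after bounded retries; such cells are skipped and counted.
    """
    if n_cells_per_clone < 0:
        raise ValueError("n_cells_per_clone must be >= 0")
    if image_shape[0] < 64 or image_shape[1] < 64:
        raise ValueError("image_shape must be at least 64 x 64")
    noise = NoiseParams() if noise is None else noise

    channels = (NUCLEAR_CHANNEL, BODY_CHANNEL, *panel.fluorophores)
    if cells_per_image is None:
        cells_per_image = max(1, (image_shape[0] * image_shape[1]) // 8000)
    master = np.random.SeedSequence(seed)
    clone_seeds = master.spawn(len(panel.barcodes))

    clones: dict[str, CloneImages] = {}
    records = []
    n_skipped = 0
    for (fluor, loc), clone_name, child in zip(
        panel.barcodes, panel.clone_names, clone_seeds
    ):
        rng = np.random.default_rng(child)
        stacks, label_maps = [], []
        placed = 0
        n_images = max(1, math.ceil(n_cells_per_clone / cells_per_image))
        for image_index in range(n_images):
            expected = np.zeros((len(channels),) + tuple(image_shape))
            labels = np.zeros(image_shape, dtype=np.uint16)
            occupied = np.zeros(image_shape, dtype=bool)
            target = min(cells_per_image, n_cells_per_clone - placed)
            label = 0
            for _ in range(target):
                geom = _place_cell(image_shape, occupied, rng)
                if geom is None:
                    n_skipped += 1
                    continue
                cell, nucleus = geom
                occupied |= cell
                label += 1
                labels[cell] = label
                brightness = 1.0
                if noise.brightness_cv > 0:
                    sigma = math.sqrt(math.log1p(noise.brightness_cv**2))
                    brightness = float(rng.lognormal(-0.5 * sigma**2, sigma))
                expected[channels.index(NUCLEAR_CHANNEL)][nucleus] += (
                    _NUCLEAR_SIGNAL * brightness
                )
                expected[channels.index(BODY_CHANNEL)][cell] += _BODY_SIGNAL
                pattern = _render_localization(loc, cell, nucleus, rng)
                expected[channels.index(fluor)][pattern] += _SIGNAL * brightness
                placed += 1
                records.append(
                    {
                        "clone": clone_name,
                        "fluorophore": fluor,
                        "localization": loc,
                        "image_index": image_index,
                        "cell_label": label,
                    }
                )
            stack = np.stack([_apply_noise(ch, noise, rng) for ch in expected])
            stacks.append(stack)
            label_maps.append(labels)
        if placed < n_cells_per_clone:
            log.warning(
                "clone %s: placed %d of %d cells (%d placements failed)",
                clone_name,
                placed,
                n_cells_per_clone,
                n_cells_per_clone - placed,
            )
        clones[clone_name] = CloneImages(clone_name, stacks, label_maps)

    truth = pd.DataFrame(
        records,
        columns=["clone", "fluorophore", "localization", "image_index", "cell_label"],
    )
    if n_skipped:
        log.info("skipped %d overlapping-cell placements", n_skipped)
    return ImageSet(channels=channels, clones=clones, truth=truth, n_skipped=n_skipped)


def touching_nuclei_image(
    seed: int = 0, image_shape: tuple[int, int] = (128, 128)
) -> tuple[np.ndarray, np.ndarray, int]:
    """Render two cells whose nuclei touch (watershed-splitting fixture).

    Returns (nuclear channel, body channel, true cell count).  Deliberately
    noise-free so the only segmentation difficulty is the contact.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    area = 800.0
    nucleus_radius = math.sqrt(_NUCLEUS_FRACTION * area / math.pi)
    # centers separated by slightly less than two nucleus radii: nuclei fuse
    # into one blob by thresholding but remain two intensity/distance peaks
    gap = 1.8 * nucleus_radius
    c1 = (h / 2.0, w / 2.0 - gap / 2.0)
    c2 = (h / 2.0, w / 2.0 + gap / 2.0)
    nuclear = np.zeros(image_shape)
    body = np.zeros(image_shape)
    for ctr in (c1, c2):
        cell = _ellipse_mask(image_shape, ctr, area, 1.0, 0.0)
        nucleus = _ellipse_mask(image_shape, ctr, _NUCLEUS_FRACTION * area, 1.0, 0.0)
        body[cell] = _BODY_SIGNAL
        nuclear[nucleus] = _NUCLEAR_SIGNAL
    del rng  # geometry is deterministic; signature kept uniform
    return nuclear.astype(np.uint16), body.astype(np.uint16), 2
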