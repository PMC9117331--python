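"""Cytological profiles: per-cell intensity, texture, and shape features.

For each segmented cell the profile holds intensity statistics per
compartment per channel, texture summaries (local variance and gray-level
co-occurrence properties) per channel, shape descriptors, and a
similarity-to-nucleus feature per channel (the within-cell Pearson
correlation between a channel and the nuclear marker, the imaging-cytometry
"similarity" feature).  With a nuclear marker plus four fluorophore channels
the profile exceeds 200 features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops
from skimage.morphology import disk

from signalome.barcodes.segmentation import SegmentationResult

log = logging.getLogger(__name__)

MIN_CELL_PIXELS = 10
_STATS = ("mean", "median", "std", "q25", "q75", "q90", "integrated")
_GLCM_PROPS = ("contrast", "homogeneity", "energy", "correlation")
_GLCM_LEVELS = 32


def _intensity_stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {s: np.nan for s in _STATS}
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "std": float(values.std()),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
        "q90": float(np.percentile(values, 90)),
        "integrated": float(values.sum()),
    }


def _texture_features(crop: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Local-variance and co-occurrence summaries of one channel crop."""
    local_mean = ndi.uniform_filter(crop, size=3)
    local_var = ndi.uniform_filter(crop**2, size=3) - local_mean**2
    inside = local_var[mask]
    feats = {
        "localvar_mean": float(inside.mean()) if inside.size else np.nan,
        "localvar_std": float(inside.std()) if inside.size else np.nan,
    }
    lo, hi = float(crop.min()), float(crop.max())
    if hi > lo:
        quant = ((crop - lo) / (hi - lo) * (_GLCM_LEVELS - 1)).astype(np.uint8)
    else:
        quant = np.zeros_like(crop, dtype=np.uint8)
    glcm = graycomatrix(
        quant,
        distances=[1],
        angles=[0.0, np.pi / 2],
        levels=_GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )
    for prop in _GLCM_PROPS:
        feats[f"glcm_{prop}"] = float(graycoprops(glcm, prop).mean())
    return feats


def extract_features(
    seg: SegmentationResult,
    channels: dict[str, np.ndarray],
    nuclear_channel: str = "nuclei",
) -> pd.DataFrame:
    """One deterministic feature row per segmented cell.

    Parameters
    ----------
    seg
        Segmentation of the field of view.
    channels
        Channel name -> image; must include ``nuclear_channel`` (used for
        the similarity-to-nucleus correlations).
    """
    for name, img in channels.items():
        if img.shape != seg.cell_labels.shape:
            raise ValueError(f"channel {name!r} shape does not match segmentation")
    if nuclear_channel not in channels:
        raise ValueError(f"nuclear channel {nuclear_channel!r} missing")
    p = seg.params
    margin = p.background_outer + 1
    rows = []
    slices = ndi.find_objects(seg.cell_labels)
    n_dropped = 0
    for label, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        rs = slice(max(slc[0].start - margin, 0), min(slc[0].stop + margin, seg.cell_labels.shape[0]))
        cs = slice(max(slc[1].start - margin, 0), min(slc[1].stop + margin, seg.cell_labels.shape[1]))
        cell_crop = seg.cell_labels[rs, cs]
        nuc_crop = seg.nucleus_labels[rs, cs]
        cell = cell_crop == label
        if cell.sum() < MIN_CELL_PIXELS:
            n_dropped += 1
            continue
        nucleus = nuc_crop == label
        ring = ndi.binary_dilation(nucleus, disk(p.ring_width)) & cell & ~nucleus
        inner = ndi.binary_dilation(cell, disk(p.background_inner))
        outer = ndi.binary_dilation(cell, disk(p.background_outer))
        background = outer & ~inner & (cell_crop == 0)
        comps = {
            "cell": cell,
            "nucleus": nucleus,
            "cytoplasm": cell & ~nucleus,
            "perinuclear": ring,
            "background": background,
        }
        feats: dict[str, float] = {"cell_label": label}
        nuclear_crop = np.asarray(channels[nuclear_channel], dtype=float)[rs, cs]
        for name, img in channels.items():
            crop = np.asarray(img, dtype=float)[rs, cs]
            for comp_name, mask in comps.items():
                stats = _intensity_stats(crop[mask])
                for stat, value in stats.items():
                    feats[f"{name}__{comp_name}__{stat}"] = value
            for key, value in _texture_features(crop, cell).items():
                feats[f"{name}__{key}"] = value
            inside_ch = crop[cell]
            inside_nuc = nuclear_crop[cell]
            if inside_ch.std() > 0 and inside_nuc.std() > 0:
                sim = float(np.corrcoef(inside_ch, inside_nuc)[0, 1])
            else:
                sim = 0.0
            feats[f"{name}__similarity_to_nucleus"] = sim
        props = regionprops(cell.astype(np.uint8))[0]
        nuc_area = float(nucleus.sum())
        cell_area = float(cell.sum())
        nuc_props = regionprops(nucleus.astype(np.uint8))
        feats.update(
            {
                "shape__cell_area": cell_area,
                "shape__cell_eccentricity": float(props.eccentricity),
                "shape__cell_solidity": float(props.solidity),
                "shape__cell_perimeter": float(props.perimeter),
                "shape__cell_equivalent_diameter": float(props.equivalent_diameter_area),
                "shape__nucleus_area": nuc_area,
                "shape__nucleus_eccentricity": (
                    float(nuc_props[0].eccentricity) if nuc_props else 0.0
                ),
                "shape__nucleus_cell_area_ratio": nuc_area / cell_area,
            }
        )
        rows.append(feats)
    if n_dropped:
        log.info("dropped %d cells under %d px", n_dropped, MIN_CELL_PIXELS)
    if not rows:
        return pd.DataFrame()
    table = pd.DataFrame(rows).set_index("cell_label")
    # empty compartments (e.g. a clipped background annulus) become NaN;
    # impute to 0 so downstream classifiers see a complete matrix
    return table.fillna(0.0)
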