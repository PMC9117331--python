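"""End-to-end profiling of an image set: segment, featurize, label.

Convenience layer used by tests, the acceptance harness, and the CLI: runs
segmentation and feature extraction over every field of view of every clone
in a rendered :class:`~signalome.simulate.images.ImageSet` and returns one
feature table with true clone labels (images come from single-clone control
wells, so the clone of origin is the label).
"""

from __future__ import annotations

import pandas as pd

from signalome.barcodes.features import extract_features
from signalome.barcodes.segmentation import SegParams, segment
from signalome.simulate.images import BODY_CHANNEL, NUCLEAR_CHANNEL, ImageSet


def profile_image_set(
    image_set: ImageSet, params: SegParams | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table and clone labels for every cell in an image set."""
    frames = []
    labels = []
    for clone_name, clone in image_set.clones.items():
        for image_index, stack in enumerate(clone.stacks):
            channels = dict(zip(image_set.channels, stack))
            seg = segment(channels[NUCLEAR_CHANNEL], channels[BODY_CHANNEL], params)
            if seg.n_cells == 0:
                continue
            feats = extract_features(seg, channels, nuclear_channel=NUCLEAR_CHANNEL)
            if feats.empty:
                continue
            feats = feats.reset_index()
            feats.insert(0, "image_index", image_index)
            feats.insert(0, "clone", clone_name)
            frames.append(feats)
            labels.extend([clone_name] * len(feats))
    if not frames:
        return pd.DataFrame(), pd.Series(dtype=object)
    table = pd.concat(frames, ignore_index=True)
    truth = table["clone"].rename("true_clone")
    features = table.drop(columns=["clone"]).set_index(["image_index", "cell_label"])
    features.index = pd.RangeIndex(len(features))
    truth.index = features.index
    return features, truth
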