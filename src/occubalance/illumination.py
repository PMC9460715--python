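"""Binary illumination labeling and (region, illumination) partitioning.

Images are split into high and low illumination so that synthesis can
draw occlusion elements and base images whose lighting matches the
target sub-dataset.  The default labeler is a mean-luminance threshold
(Rec.601 luma); any callable mapping an RGB raster to a label can be
injected in its place, and records that already carry an illumination
tag (e.g. from a manifest) bypass classification entirely.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from occubalance.dataset_io import (
    Dataset,
    IlluminationLabel,
    ImageRecord,
    SubDatasetKey,
)
from occubalance.errors import ValidationError

#: Default mean-luma threshold separating low from high illumination, on
#: the 0..255 scale.  Dusk/backlit orchard frames fall well below it and
#: full daylight well above; the exact value is an injection point.
DEFAULT_LUMA_THRESHOLD = 90.0

_REC601 = np.array([0.299, 0.587, 0.114])


def mean_luma(image: np.ndarray) -> float:
    """Mean Rec.601 luma of an HxWx3 RGB array, in [0, 255]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 RGB array, got shape {image.shape}")
    return float(np.mean(image.astype(np.float64) @ _REC601))


def classify_illumination(
    image: np.ndarray,
    threshold: float = DEFAULT_LUMA_THRESHOLD,
    predictor: Callable[[np.ndarray], IlluminationLabel] | None = None,
) -> IlluminationLabel:
    """Label an RGB image high or low illumination.

    With no ``predictor``, the rule is: mean Rec.601 luma >= ``threshold``
    -> high, else low.  A supplied predictor's label is used verbatim,
    which is how a trained classifier plugs in.
    """
    if predictor is not None:
        return predictor(image)
    return (
        IlluminationLabel.HIGH
        if mean_luma(image) >= threshold
        else IlluminationLabel.LOW
    )


def partition_by_illumination(
    dataset: Dataset,
    labeler: Callable[[np.ndarray], IlluminationLabel] | None = None,
    threshold: float = DEFAULT_LUMA_THRESHOLD,
) -> dict[SubDatasetKey, Dataset]:
    """Split a dataset into (region, illumination) sub-datasets.

    Every record lands in exactly one sub-dataset.  Records with a
    pre-assigned illumination keep it; the rest are classified from
    their pixels.
    """
    buckets: dict[SubDatasetKey, list[ImageRecord]] = {}
    for record in dataset:
        if record.illumination is not None:
            label = record.illumination
        else:
            label = classify_illumination(
                record.load_raster(), threshold=threshold, predictor=labeler
            )
        key = SubDatasetKey(region=record.region, illumination=label)
        buckets.setdefault(key, []).append(record)
    return {
        key: Dataset(records=records, name=key.name)
        for key, records in sorted(buckets.items())
    }
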