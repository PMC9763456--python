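"""Training-corpus assembly bookkeeping.

Adjacent tomograms differ very little, so stacks are subsampled every
``stride`` layers before labelling; each kept slice is then expanded by a
4-way flip/rotation augmentation (the transverse section of a coconut is
approximately circular with no preferred direction), and the result is
split 9:1 into training and validation partitions.  At the scale of the
reference corpus this arithmetic is 217660 layers -> 10883 originals ->
54415 augmented pairs -> 48974 / 5441.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AUGMENT_TAGS",
    "DatasetIndex",
    "sample_layers",
    "augment",
    "split_dataset",
    "build_index",
]

AUGMENT_TAGS = ("orig", "hflip", "vflip", "rot90cw", "rot90ccw")


def sample_layers(n_layers_total: int, stride: int) -> np.ndarray:
    """Indices 0, stride, 2*stride, ... below ``n_layers_total``."""
    if n_layers_total < 1 or stride < 1:
        raise ValueError("n_layers_total and stride must be >= 1")
    return np.arange(0, n_layers_total, stride)


def _transform(arr: np.ndarray, tag: str) -> np.ndarray:
    if tag == "orig":
        return arr.copy()
    if tag == "hflip":
        return arr[:, ::-1].copy()
    if tag == "vflip":
        return arr[::-1, :].copy()
    if tag == "rot90cw":
        return np.rot90(arr, k=-1).copy()
    if tag == "rot90ccw":
        return np.rot90(arr, k=1).copy()
    raise ValueError(f"unknown augmentation tag {tag!r}")


def augment(image: np.ndarray, label: np.ndarray):
    """The 5 augmentation pairs [orig, hflip, vflip, rot90cw, rot90ccw].

    The label image is transformed identically; rotations of non-square
    slices emit the transposed shape.
    """
    image = np.asarray(image)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ValueError("image and label shapes differ")
    return [(_transform(image, t), _transform(label, t), t) for t in AUGMENT_TAGS]


def split_dataset(
    n_items: int, ratio_train: int = 9, ratio_val: int = 1
) -> tuple[int, int]:
    """Deterministic 9:1 item-level split: val = floor(n/(train+val)),
    train = n - val (54415 -> 48974/5441)."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    denom = ratio_train + ratio_val
    val = int(n_items * ratio_val // denom)
    return n_items - val, val


@dataclass
class DatasetIndex:
    """Record table of (sample, layer, augmentation tag, partition)."""

    records: pd.DataFrame  # columns: sample, layer, tag, partition

    def __post_init__(self) -> None:
        required = {"sample", "layer", "tag", "partition"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"index requires columns {sorted(required)}")
        if self.records.duplicated(["sample", "layer", "tag"]).any():
            raise ValueError("(sample, layer, tag) records must be unique")

    @property
    def counts(self) -> dict[str, int]:
        return self.records["partition"].value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetIndex":
        return cls(pd.read_csv(path))


def build_index(
    layers_per_sample: dict[str, int], stride: int = 20
) -> DatasetIndex:
    """Assemble the full deterministic index: subsample layers, expand the
    augmentation tags, order by (sample, layer, tag) and apply the 9:1
    split over that ordering."""
    rows = []
    for sample in sorted(layers_per_sample):
        for layer in sample_layers(layers_per_sample[sample], stride):
            for tag in AUGMENT_TAGS:
                rows.append((sample, int(layer), tag))
    df = pd.DataFrame(rows, columns=["sample", "layer", "tag"])
    df = df.sort_values(["sample", "layer", "tag"], kind="stable").reset_index(
        drop=True
    )
    n_train, n_val = split_dataset(len(df))
    df["partition"] = ["train"] * n_train + ["val"] * n_val
    return DatasetIndex(df)
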