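"""Labeled grayscale image sets: in-memory container and PNG/CSV round-trip.

Images live as a float array of shape (N, H, W) with intensities in [0, 1];
on disk they are 8-bit grayscale PNGs plus a ``manifest.csv`` mapping
``filename,label``.  The same layout serves synthetic and real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["ImageSet", "load_image_dir", "to_uint8", "from_uint8"]


def to_uint8(images: np.ndarray) -> np.ndarray:
    return np.clip(np.round(images * 255.0), 0, 255).astype(np.uint8)


def from_uint8(images: np.ndarray) -> np.ndarray:
    return images.astype(np.float64) / 255.0


@dataclass
class ImageSet:
    """A stack of same-size grayscale images with integer class labels."""

    images: np.ndarray  # (N, H, W) float in [0, 1]
    labels: np.ndarray  # (N,) int
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (N, H, W), got {self.images.shape}")
        if len(self.labels) != len(self.images):
            raise ValueError("labels length must match image count")
        if not self.names:
            self.names = [f"img_{i:06d}.png" for i in range(len(self.images))]

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def subset(self, idx) -> "ImageSet":
        idx = np.asarray(idx)
        return ImageSet(
            self.images[idx], self.labels[idx], [self.names[i] for i in idx]
        )

    def as_batch(self) -> np.ndarray:
        """(N, 1, H, W) float32 view for the model stack."""
        return self.images[:, None, :, :].astype(np.float32)

    def save(self, out_dir: str | Path) -> Path:
        """Write 8-bit grayscale PNGs plus manifest.csv; returns the dir."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        u8 = to_uint8(self.images)
        for name, img in zip(self.names, u8):
            iio.imwrite(out_dir / name, img)
        pd.DataFrame({"filename": self.names, "label": self.labels}).to_csv(
            out_dir / "manifest.csv", index=False
        )
        return out_dir


def load_image_dir(in_dir: str | Path) -> ImageSet:
    """Read a PNG directory written by :meth:`ImageSet.save`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    images = np.stack(
        [from_uint8(iio.imread(in_dir / fn)) for fn in manifest["filename"]]
    )
    return ImageSet(images, manifest["label"].to_numpy(), list(manifest["filename"]))
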