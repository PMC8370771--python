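"""Core containers shared across the pipeline.

An :class:`ImageEvent` is one cell's multi-channel image stack — the unit of
feature extraction and of CNN input.  Channels are named 2-D float arrays of
identical shape; the conventional names are ``"BF"`` (brightfield), ``"SSC"``
(darkfield / side scatter), ``"DNA"`` (nuclear dye) and ``"FL1"``, ``"FL2"``
for additional fluorescence channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channels treated as fluorescence: subject to spillover, compensation and
#: logicle transformation.  BF and SSC are scatter/transmission channels.
FLUORESCENCE_PREFIXES = ("DNA", "FL")


def is_fluorescence(channel: str) -> bool:
    return channel.startswith(FLUORESCENCE_PREFIXES)


@dataclass
class ImageEvent:
    """One event (cell) as a named stack of equally shaped 2-D channels.

    ``masks`` holds working segmentation masks (``"cell"``, ``"nucleus"``);
    ``truth_masks`` is filled by the synthetic generator with the ground-truth
    rasters so segmentation accuracy can be scored.
    """

    event_id: str
    sample_id: str
    channels: dict[str, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    truth_masks: dict[str, np.ndarray] | None = None
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def stack(self, order: list[str]) -> np.ndarray:
        """Return channels as an (H, W, C) array in the given order."""
        return np.stack([self.channels[c] for c in order], axis=-1)


class SpilloverMatrix:
    """Square spillover matrix: rows = true channels, cols = detected.

    ``detected = S.T @ true`` per pixel; the diagonal is 1 and off-diagonal
    entries are fractions in [0, 1).  Compensation applies the inverse.
    """

    def __init__(self, matrix: np.ndarray, channels: list[str]):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("spillover matrix must be square")
        if matrix.shape[0] != len(channels):
            raise ValueError("channel list does not match matrix size")
        if not np.allclose(np.diag(matrix), 1.0):
            raise ValueError("spillover diagonal must be 1")
        off = matrix[~np.eye(len(channels), dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("off-diagonal spillover must be in [0, 1)")
        if abs(np.linalg.det(matrix)) < 1e-9:
            raise ValueError("spillover matrix is singular")
        self.matrix = matrix
        self.channels = list(channels)

    @classmethod
    def identity(cls, channels: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), channels)

    @classmethod
    def read_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.channels, columns=self.channels).to_csv(path)

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.matrix, np.eye(len(self.channels)))
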