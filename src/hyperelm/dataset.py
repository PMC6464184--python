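"""Container for registered multichannel sample collections."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultichannelDataset:
    """N samples described by d+1 registered channels plus integer labels.

    Each channel is an ``N x n`` real matrix whose row i is the vectorized
    channel image of sample i (all channels share N and n).  ``labels`` are
    integer class ids in ``[0, n_classes)``.  Channel order is meaningful:
    channel 0 feeds the real slot of the hypercomplex representation,
    channel j+1 the imaginary unit ``e_j``.
    """

    channels: list[np.ndarray]
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = [np.asarray(c, dtype=float) for c in self.channels]
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.channels:
            raise ValueError("a dataset needs at least one channel")
        shape = self.channels[0].shape
        for c in self.channels:
            if c.ndim != 2 or c.shape != shape:
                raise ValueError("all channels must share one (N, n) shape")
        if self.labels.shape != (shape[0],):
            raise ValueError("labels must have one entry per sample")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.channel_names:
            self.channel_names = [f"channel{j}" for j in range(len(self.channels))]
        if len(self.channel_names) != len(self.channels):
            raise ValueError("one name per channel required")

    @property
    def n_samples(self) -> int:
        return self.channels[0].shape[0]

    @property
    def n_features(self) -> int:
        return self.channels[0].shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def d(self) -> int:
        """Number of imaginary units used when this dataset feeds a HELM."""
        return len(self.channels) - 1

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def subset(self, idx) -> "MultichannelDataset":
        idx = np.asarray(idx)
        return MultichannelDataset(
            [c[idx] for c in self.channels],
            self.labels[idx],
            list(self.channel_names),
        )

    def reorder_channels(self, order) -> "MultichannelDataset":
        order = list(order)
        return MultichannelDataset(
            [self.channels[j] for j in order],
            self.labels,
            [self.channel_names[j] for j in order],
        )
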