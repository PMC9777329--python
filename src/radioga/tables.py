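"""The samples-by-features container shared by extraction, selection and
model evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError


@dataclass
class FeatureTable:
    """A samples x features real matrix with per-sample class labels.

    ``labels`` are binary: 0 = benign, 1 = malignant (string labels are
    mapped on construction). Feature names must be unique.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.feature_names))
        self.feature_names = list(self.feature_names)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"{self.values.shape[1]} columns vs {len(self.feature_names)} names"
            )
        if self.labels is None:
            self.labels = np.zeros(self.values.shape[0], dtype=int)
        else:
            lab = np.asarray(self.labels)
            if lab.dtype.kind in "UOS":
                lab = (lab == "malignant").astype(int)
            self.labels = lab.astype(int)
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError("label count does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def subset(self, names_or_indices) -> "FeatureTable":
        """New table restricted to the given features (order preserved)."""
        idx = [
            self.feature_names.index(n) if isinstance(n, str) else int(n)
            for n in names_or_indices
        ]
        return FeatureTable(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=self.labels.copy(),
        )

    def rows(self, indices) -> "FeatureTable":
        """New table restricted to the given samples."""
        indices = np.asarray(indices)
        return FeatureTable(
            values=self.values[indices],
            feature_names=list(self.feature_names),
            labels=self.labels[indices],
        )
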