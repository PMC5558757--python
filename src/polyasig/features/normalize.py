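"""Min-max normalization to (-1, 1), fitted on training rows only."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class NormalizationParams:
    min_: np.ndarray
    max_: np.ndarray
    constant: np.ndarray  # bool mask of zero-range features

    def to_dict(self) -> dict:
        return {
            "min": self.min_.tolist(),
            "max": self.max_.tolist(),
            "constant": self.constant.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            min_=np.asarray(d["min"], dtype=float),
            max_=np.asarray(d["max"], dtype=float),
            constant=np.asarray(d["constant"], dtype=bool),
        )


def fit_normalization(train_features: np.ndarray) -> NormalizationParams:
    """Per-feature min/max from the training matrix (rows = sequences)."""
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("expected a non-empty 2-D feature matrix")
    mn, mx = X.min(axis=0), X.max(axis=0)
    constant = mx == mn
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) in training data; "
            "they will normalize to 0", stacklevel=2,
        )
    return NormalizationParams(min_=mn, max_=mx, constant=constant)


def apply_normalization(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """norm_i = (x_i - (max_i + min_i)/2) / ((max_i - min_i)/2).

    Training columns land in [-1, 1]; validation/test rows reuse training
    parameters and may exceed that range.  Constant features map to 0.
    """
    x = np.asarray(x, dtype=float)
    center = (params.max_ + params.min_) / 2.0
    half_range = np.where(params.constant, 1.0, (params.max_ - params.min_) / 2.0)
    out = (x - center) / half_range
    if x.ndim == 1:
        return np.where(params.constant, 0.0, out)
    return np.where(params.constant[None, :], 0.0, out)
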