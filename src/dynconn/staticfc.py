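"""Static functional connectivity: pairwise Pearson correlation, Fisher z."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FCMatrix", "static_fc", "fc_to_edge_table", "edge_vector", "edge_labels"]

_CLIP = 1.0 - 1e-12


@dataclass
class FCMatrix:
    """Symmetric matrix of Fisher-z-transformed correlations; diagonal is NaN (undefined)."""

    z_values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        off = ~np.eye(z.shape[0], dtype=bool)
        if not np.isfinite(z[off]).all():
            raise ValueError("non-finite off-diagonal z values")
        if not np.allclose(z[off], z.T[off]):
            raise ValueError("z_values must be symmetric")
        self.z_values = z

    @property
    def n(self) -> int:
        return self.z_values.shape[0]


def static_fc(timecourses: np.ndarray, labels: list[str] | None = None) -> FCMatrix:
    """Pairwise Pearson correlation of component time courses, Fisher z-transformed.

    ``timecourses`` is components x timepoints. Correlations are clipped to
    ±(1 − 1e−12) before atanh so degenerate (perfectly correlated) pairs yield
    large finite z rather than infinity; a constant row is an error naming the
    offending component.
    """
    x = np.asarray(timecourses, dtype=float)
    if x.ndim != 2:
        raise ValueError("timecourses must be components x timepoints")
    n, t = x.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    labels = labels or [f"IC{i + 1}" for i in range(n)]
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"component {labels[bad[0]]} has a constant time course")
    r = np.corrcoef(x)
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    np.fill_diagonal(z, np.nan)
    return FCMatrix(z_values=z, labels=list(labels))


def edge_labels(labels: list[str]) -> list[tuple[str, str]]:
    """Upper-triangle (i < j) component pairs, row-major."""
    n = len(labels)
    return [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]


def edge_vector(z: np.ndarray) -> np.ndarray:
    """Upper-triangle edge features of a square symmetric matrix, row-major."""
    z = np.asarray(z)
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu]


def fc_to_edge_table(fc: FCMatrix) -> pd.DataFrame:
    pairs = edge_labels(fc.labels)
    return pd.DataFrame(
        {
            "component_i": [p[0] for p in pairs],
            "component_j": [p[1] for p in pairs],
            "z": edge_vector(fc.z_values),
        }
    )


def write_fc(fc: FCMatrix, path: str | Path) -> None:
    pd.DataFrame(fc.z_values, index=fc.labels, columns=fc.labels).to_csv(path, sep="\t")
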