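"""Core domain containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MotionTrace",
    "CensorMask",
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "WeightedGraph",
    "SubjectRecord",
]


@dataclass
class MotionTrace:
    """Per-volume rigid-body realignment parameters.

    ``translations`` are in mm, ``rotations`` in radians (SPM column order).
    """

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3) rad

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValueError("translations must be (T, 3)")
        if self.rotations.shape != self.translations.shape:
            raise ValueError("rotations must match translations shape")
        if self.n_volumes < 2:
            raise ValueError("motion trace needs at least 2 volumes")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    @property
    def parameters(self) -> np.ndarray:
        """(T, 6) matrix: 3 translations then 3 rotations."""
        return np.hstack([self.translations, self.rotations])


# Censoring reason codes, in the order they are evaluated.
REASON_NONE = "none"
REASON_RUN_TRANSLATION = "run_translation"
REASON_RUN_ROTATION = "run_rotation"
REASON_FD = "fd"


@dataclass
class CensorMask:
    """Boolean censoring mask with one or more reason codes per volume."""

    censored: np.ndarray  # (T,) bool
    reasons: list[tuple[str, ...]]  # per volume, () or a tuple of reason codes

    def __post_init__(self) -> None:
        self.censored = np.asarray(self.censored, dtype=bool)
        if len(self.reasons) != self.censored.size:
            raise ValueError("reasons must have one entry per volume")

    @classmethod
    def clean(cls, n_volumes: int) -> "CensorMask":
        return cls(np.zeros(n_volumes, dtype=bool), [()] * n_volumes)

    @property
    def n_volumes(self) -> int:
        return self.censored.size

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def fraction_censored(self) -> float:
        return self.n_censored / self.n_volumes


@dataclass
class RoiTimeSeries:
    """T x N matrix of per-node averaged signals with acquisition metadata."""

    data: np.ndarray  # (T, N)
    tr: float  # seconds
    mask: Optional[CensorMask] = None
    node_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x nodes)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask is not None and self.mask.n_volumes != self.n_volumes:
            raise ValueError("censor mask length must equal number of volumes")
        if self.node_labels is not None and len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal number of nodes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def uncensored(self) -> np.ndarray:
        """Data restricted to uncensored volumes (all volumes if no mask)."""
        if self.mask is None:
            return self.data
        return self.data[~self.mask.censored]


@dataclass
class ConnectivityMatrix:
    """Full partial-correlation matrix with estimator provenance."""

    pcorr: np.ndarray  # (N, N), diag 1
    estimator: str  # "pseudo-inverse" | "shrinkage"
    condition_number: float
    node_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.pcorr = np.asarray(self.pcorr, dtype=float)
        n = self.pcorr.shape[0]
        if self.pcorr.shape != (n, n):
            raise ValueError("pcorr must be square")
        if not np.allclose(self.pcorr, self.pcorr.T, atol=1e-10):
            raise ValueError("pcorr must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.pcorr.shape[0]


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix in [0, 1] with zero diagonal."""

    weights: np.ndarray  # (N, N)
    node_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = w.shape[0]
        if w.shape != (n, n):
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w
        if self.node_labels is not None and len(self.node_labels) != n:
            raise ValueError("node_labels length must equal matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def labels(self) -> list[str]:
        if self.node_labels is not None:
            return list(self.node_labels)
        return [f"node{i:02d}" for i in range(self.n_nodes)]


@dataclass
class SubjectRecord:
    """Group membership and questionnaire scores for one subject."""

    subject_id: str
    group: str  # "HC" | "IBS"
    cohort: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("HC", "IBS"):
            raise ValueError("group must be 'HC' or 'IBS'")
        if not self.cohort:
            raise ValueError("cohort label must be non-empty")
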