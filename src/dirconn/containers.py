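"""Core data containers for the directed-connectivity pipeline.

The pipeline moves through three in-memory stages: per-subject region x time
activation matrices (:class:`RegionTimeSeries`), square weighted connectivity
matrices tagged with the method that produced them (:class:`ConnectivityMatrix`),
and directed adjacency matrices thresholded at a stated edge density
(:class:`ThresholdedNetwork`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Connectivity methods understood by the pipeline.
METHODS = ("lagged", "antisymmetric", "symmetric", "zerolag", "granger")


@dataclass
class RegionTimeSeries:
    """One subject's regional activation time series.

    Parameters
    ----------
    data : ndarray of shape (n_regions, n_timepoints)
        One row per region, one column per sampling time.
    region_labels : list of str, optional
        Unique region names; defaults to ``R000, R001, ...``.
    subject_id : str
        Identifier used to join with covariate tables.
    tr_seconds : float
        Sampling interval (repetition time); metadata only.
    """

    data: np.ndarray
    region_labels: list[str] | None = None
    subject_id: str = "subject"
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D region x time matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain missing or non-finite values")
        n = self.data.shape[0]
        if self.region_labels is None:
            self.region_labels = [f"R{i:03d}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ValueError("region_labels length must equal n_regions")
        if len(set(self.region_labels)) != n:
            raise ValueError("region_labels must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """A square weighted connectivity matrix with provenance.

    ``lag`` holds the temporal lag d for correlation-based methods and the
    autoregressive model order p for the Granger method.  ``clipped`` records
    whether negative entries and the diagonal have been zeroed (the network
    analyses exclude negative correlations and self-connections).
    """

    weights: np.ndarray
    method: str
    lag: int = 0
    clipped: bool = False
    region_labels: list[str] | None = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.lag < 0:
            raise ValueError("lag/order must be nonnegative")
        n = self.weights.shape[0]
        if self.region_labels is None:
            self.region_labels = [f"R{i:03d}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ValueError("region_labels length must equal matrix size")
        if self.clipped:
            if (self.weights < 0).any():
                raise ValueError("clipped matrix has negative entries")
            if np.diagonal(self.weights).any():
                raise ValueError("clipped matrix has nonzero diagonal")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedNetwork:
    """Directed adjacency at a stated density.

    In ``binary`` mode surviving edges are 1; in ``weighted`` mode they keep
    the source matrix's weights exactly.
    """

    adjacency: np.ndarray
    density: float
    mode: str = "binary"
    source_method: str = "lagged"
    lag: int = 0
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if self.mode not in ("binary", "weighted"):
            raise ValueError("mode must be 'binary' or 'weighted'")
        if not 0 < self.density <= 0.5:
            raise ValueError("density must lie in (0, 0.5]")
        if np.diagonal(a).any():
            raise ValueError("adjacency diagonal must be zero")
        n = a.shape[0]
        if self.region_labels is None:
            self.region_labels = [f"R{i:03d}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))
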