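"""Epoch-based functional connectivity and channel degree.

Recordings are cut into overlapping epochs (default 30 s, 5 s overlap);
epochs touching annotated artifact segments or containing saturated
HbO samples (|HbO| at or above 10 µM) are excluded.  The connectivity
matrix is the element-wise mean across retained epochs of the pairwise
absolute Pearson correlation of the HbO series; it is binarized at an
inclusive threshold (default 0.5) and the degree of a channel is its
number of supra-threshold connections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .recording import HemoRecording

logger = logging.getLogger(__name__)

SATURATION_LIMIT_UM = 10.0
DEGREE_THRESHOLD = 0.5


@dataclass
class EpochSet:
    """Fixed-length overlapping epochs of a multichannel HbO series."""

    starts: np.ndarray           # seconds
    data: list[np.ndarray]       # per epoch: (n_samples, n_channels)
    epoch_length: float
    hop: float
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    exclusion_log: list[str] = field(default_factory=list)  # kept|annotated|saturated

    def __post_init__(self) -> None:
        if not self.exclusion_log:
            self.exclusion_log = ["kept"] * len(self.data)

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    @property
    def kept(self) -> list[int]:
        return [i for i, r in enumerate(self.exclusion_log) if r == "kept"]

    @property
    def overlap(self) -> float:
        return self.epoch_length - self.hop


@dataclass
class ConnectivityResult:
    """Weighted |r| matrix, binarized matrix and per-channel degree."""

    weighted: np.ndarray
    binary: np.ndarray | None = None
    degree: np.ndarray | None = None
    threshold: float | None = None
    n_epochs_used: int = 0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.weighted, float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ParameterError("weighted matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ParameterError("weighted matrix must be symmetric")
        if np.any((W < -1e-12) | (W > 1 + 1e-12)):
            raise ParameterError("weighted entries must lie in [0, 1]")


def segment_epochs(
    hemo: HemoRecording,
    epoch_length: float = 30.0,
    overlap: float = 5.0,
) -> EpochSet:
    """Cut the HbO series into overlapping fixed-length epochs.

    Epochs start at 0, hop, 2*hop, ... with hop = epoch_length -
    overlap; the count is floor((T - epoch_length)/hop) + 1.  A
    recording shorter than one epoch yields an empty set with a warning.
    """
    if overlap >= epoch_length:
        raise ParameterError("overlap must be below epoch_length")
    hop = epoch_length - overlap
    T = hemo.duration
    if T < epoch_length:
        warnings.warn("recording shorter than one epoch; empty epoch set", stacklevel=2)
        return EpochSet(
            starts=np.array([]), data=[], epoch_length=epoch_length, hop=hop,
            sampling_rate=hemo.sampling_rate, channel_names=list(hemo.channel_names),
            exclusion_log=[],
        )
    n_epochs = int(np.floor((T - epoch_length) / hop + 1e-9)) + 1
    n_samp = int(round(epoch_length * hemo.sampling_rate))
    starts, data = [], []
    for k in range(n_epochs):
        s = k * hop
        i0 = int(round(s * hemo.sampling_rate))
        data.append(hemo.hbo[i0 : i0 + n_samp])
        starts.append(s)
    return EpochSet(
        starts=np.array(starts), data=data, epoch_length=epoch_length, hop=hop,
        sampling_rate=hemo.sampling_rate, channel_names=list(hemo.channel_names),
    )


def exclude_epochs(
    eps: EpochSet,
    annotations: list[tuple[float, float, str]] | None = None,
    saturation_limit: float = SATURATION_LIMIT_UM,
) -> EpochSet:
    """Flag epochs overlapping annotations or containing saturated HbO.

    An epoch is dropped when its interval intersects an annotation with
    positive measure, or when any sample in any channel satisfies
    |HbO| >= saturation_limit (inclusive threshold).
    """
    if saturation_limit <= 0:
        raise ParameterError("saturation_limit must be positive")
    annotations = annotations or []
    log = []
    for k in range(eps.n_epochs):
        a, b = eps.starts[k], eps.starts[k] + eps.epoch_length
        reason = "kept"
        for onset, duration, _ in annotations:
            if min(b, onset + duration) - max(a, onset) > 0:
                reason = "annotated"
                break
        if reason == "kept" and np.any(np.abs(eps.data[k]) >= saturation_limit):
            reason = "saturated"
        log.append(reason)
    n_drop = sum(r != "kept" for r in log)
    if n_drop:
        logger.info("excluded %d of %d epochs", n_drop, eps.n_epochs)
    if n_drop == eps.n_epochs and eps.n_epochs > 0:
        warnings.warn("all epochs excluded", stacklevel=2)
    return EpochSet(
        starts=eps.starts, data=eps.data, epoch_length=eps.epoch_length,
        hop=eps.hop, sampling_rate=eps.sampling_rate,
        channel_names=list(eps.channel_names), exclusion_log=log,
    )


def _abs_corr(segment: np.ndarray) -> np.ndarray:
    """|Pearson r| matrix of one epoch; zero-variance channels give 0."""
    sd = segment.std(axis=0)
    zero = sd <= 1e-12 * max(1.0, float(np.abs(segment).max(initial=0.0)))
    if np.any(zero):
        warnings.warn(
            f"zero-variance channel(s) {np.flatnonzero(zero).tolist()} in epoch; "
            "their correlations set to 0", stacklevel=3,
        )
        segment = segment.copy()
        segment[:, zero] = 0.0
        sd = sd.copy()
        sd[zero] = 1.0
    z = (segment - segment.mean(axis=0)) / sd
    r = np.abs(z.T @ z / segment.shape[0])
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def connectivity_matrix(eps: EpochSet, aggregate: str = "mean_abs_r") -> ConnectivityResult:
    """Aggregate per-epoch |Pearson r| into one weighted matrix.

    ``aggregate="mean_abs_r"`` (default) averages per-epoch |r|
    element-wise across retained epochs; ``"concatenate"`` computes one
    |r| over the retained epochs' concatenated samples.
    """
    kept = eps.kept
    if not kept:
        raise ParameterError("no retained epochs")
    if aggregate == "mean_abs_r":
        W = np.mean([_abs_corr(eps.data[k]) for k in kept], axis=0)
    elif aggregate == "concatenate":
        W = _abs_corr(np.concatenate([eps.data[k] for k in kept], axis=0))
    else:
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return ConnectivityResult(
        weighted=W, n_epochs_used=len(kept), channel_names=list(eps.channel_names)
    )


def binarize_and_degree(
    c: ConnectivityResult, threshold: float = DEGREE_THRESHOLD
) -> ConnectivityResult:
    """Inclusive thresholding (>=) and per-channel degree.

    The degree of channel i is the number of off-diagonal entries of
    row i at or above the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("threshold must lie in (0, 1]")
    B = (c.weighted >= threshold).astype(int)
    np.fill_diagonal(B, 0)
    degree = B.sum(axis=1)
    return ConnectivityResult(
        weighted=c.weighted, binary=B, degree=degree, threshold=threshold,
        n_epochs_used=c.n_epochs_used, channel_names=list(c.channel_names),
    )


def compute_connectivity(
    hemo: HemoRecording,
    epoch_length: float = 30.0,
    overlap: float = 5.0,
    saturation_limit: float = SATURATION_LIMIT_UM,
    threshold: float = DEGREE_THRESHOLD,
    aggregate: str = "mean_abs_r",
) -> ConnectivityResult:
    """Segment, exclude, correlate, binarize: one participant-session."""
    eps = segment_epochs(hemo, epoch_length, overlap)
    eps = exclude_epochs(eps, hemo.annotations, saturation_limit)
    return binarize_and_degree(connectivity_matrix(eps, aggregate), threshold)


def to_graph(result: ConnectivityResult):
    """Binarized connectivity as a networkx graph (nodes = channels)."""
    import networkx as nx

    if result.binary is None:
        raise ParameterError("binarize the result before exporting a graph")
    g = nx.Graph()
    g.add_nodes_from(result.channel_names)
    n = len(result.channel_names)
    for i in range(n):
        for j in range(i + 1, n):
            if result.binary[i, j]:
                g.add_edge(
                    result.channel_names[i],
                    result.channel_names[j],
                    weight=float(result.weighted[i, j]),
                )
    return g


def degree_rows(
    result: ConnectivityResult, participant: str, group: str, session: str
) -> pd.DataFrame:
    """Long-format degree rows for one participant-session result."""
    return pd.DataFrame(
        {
            "participant": participant,
            "group": group,
            "session": session,
            "channel": result.channel_names,
            "degree": result.degree,
        }
    )
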