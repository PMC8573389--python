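"""Correlation-based functional connectivity and significance thresholding.

The connectivity of a channel pair is the Pearson correlation R of their
band-filtered signals over one analysis segment.  An edge is retained when the
correlation-t statistic

    T = R * sqrt(K - 2) / sqrt(1 - R^2)

exceeds the two-sided critical t at significance ``alpha`` with K-2 degrees of
freedom, i.e. when |R| >= r* = t_crit / sqrt(K - 2 + t_crit^2).  Positive
correlations are labeled excitatory, negative ones inhibitory.

``K`` is nominally the number of samples.  For band-limited signals the samples
are autocorrelated and the nominal-K threshold is markedly permissive; the
``sample_mode="bandwidth"`` option substitutes the bandwidth-time product
K_eff = 2 * (f_hi - f_lo) * T, which restores the intended false-edge rate (see
docs/methods.md).  The default, ``"nominal"``, matches the stated procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import UndefinedCorrelationError
from .preprocess import AnalysisSegment, BandSpec

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass
class FCMatrix:
    """Symmetric matrix of pairwise Pearson correlations over one segment."""

    R: np.ndarray
    K: int
    band: BandSpec | None = None
    period: str | None = None
    fs: float | None = None
    channel_labels: list[str] = field(default_factory=list)
    region_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = self.R.shape[0]
        if self.R.shape != (n, n):
            raise ValueError("R must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if np.any(np.abs(self.R) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.K < 3:
            raise ValueError("K must be >= 3")

    @property
    def n_channels(self) -> int:
        return self.R.shape[0]


@dataclass
class ThresholdedNetwork:
    """Binary adjacency (with per-edge excitatory/inhibitory sign) surviving
    the correlation-t threshold."""

    adjacency: np.ndarray
    excitatory: np.ndarray
    r_threshold: float
    alpha: float
    K: int
    k_used: int
    band: BandSpec | None = None
    period: str | None = None
    channel_labels: list[str] = field(default_factory=list)
    region_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_list(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_channels, 1)
        mask = self.adjacency[iu]
        return list(zip(iu[0][mask], iu[1][mask]))

    def sign_label(self, i: int, j: int) -> str:
        return EXCITATORY if self.excitatory[i, j] else INHIBITORY


def pair_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation covariance(x, y) / (sd(x) * sd(y)) of two equal
    length signals.

    Raises
    ------
    UndefinedCorrelationError
        If either signal has zero variance (the correlation is undefined, not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need K >= 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero-variance signal has no defined correlation")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def fc_matrix(segment: AnalysisSegment) -> FCMatrix:
    """All-pairs correlation matrix of one band-filtered segment."""
    data = np.asarray(segment.data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if data.shape[1] < 3:
        raise ValueError("need K >= 3 samples")
    sd = data.std(axis=-1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = [segment.channel_labels[i] if segment.channel_labels else str(i) for i in flat]
        raise UndefinedCorrelationError(f"zero-variance channel(s): {names}")
    R = np.corrcoef(data)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return FCMatrix(
        R=R,
        K=data.shape[1],
        band=segment.band,
        period=segment.period,
        fs=segment.fs,
        channel_labels=list(segment.channel_labels),
        region_of=dict(segment.region_of),
    )


def correlation_t(R, K: int):
    """t statistic of a correlation: R * sqrt(K-2) / sqrt(1-R^2).

    Odd in R, increasing in |R| and in K.  Raises for |R| = 1 (divergent) and
    K < 3.
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    r = np.asarray(R, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|R| must be < 1 (t diverges at |R| = 1)")
    t = r * np.sqrt(K - 2) / np.sqrt(1.0 - r * r)
    return float(t) if np.isscalar(R) else t


def r_threshold(K: int, alpha: float = 0.05) -> float:
    """Minimum |R| whose correlation-t reaches the two-sided critical t at
    significance ``alpha`` with K-2 degrees of freedom:
    r* = t_crit / sqrt(K - 2 + t_crit^2)."""
    if K < 4:
        raise ValueError("K must be >= 4")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df=K - 2)
    return float(t_crit / np.sqrt(K - 2 + t_crit**2))


def effective_sample_count(K: int, fs: float, band: BandSpec) -> int:
    """Bandwidth-time effective sample count of a band-limited segment:
    K_eff = 2 * (f_hi - f_lo) * (K / fs), floored at 4 and capped at K."""
    T = K / fs
    k_eff = int(round(2.0 * band.bandwidth * T))
    return max(4, min(K, k_eff))


def threshold_network(
    fc: FCMatrix,
    alpha: float = 0.05,
    sample_mode: str = "nominal",
) -> ThresholdedNetwork:
    """Retain edges whose |R| passes the two-sided correlation-t criterion.

    ``sample_mode``: "nominal" uses K as-is; "bandwidth" uses the
    bandwidth-time effective sample count (requires ``fc.fs`` and ``fc.band``).
    """
    if sample_mode == "nominal":
        k_used = fc.K
    elif sample_mode == "bandwidth":
        if fc.fs is None or fc.band is None:
            raise ValueError('sample_mode="bandwidth" requires fs and band on the FCMatrix')
        k_used = effective_sample_count(fc.K, fc.fs, fc.band)
    else:
        raise ValueError(f"unknown sample_mode {sample_mode!r}")
    r_star = r_threshold(k_used, alpha)
    adjacency = np.abs(fc.R) >= r_star
    np.fill_diagonal(adjacency, False)
    return ThresholdedNetwork(
        adjacency=adjacency,
        excitatory=fc.R > 0,
        r_threshold=r_star,
        alpha=alpha,
        K=fc.K,
        k_used=k_used,
        band=fc.band,
        period=fc.period,
        channel_labels=list(fc.channel_labels),
        region_of=dict(fc.region_of),
    )
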