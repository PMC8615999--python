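"""Pairwise cross-sample entropy and the weighted connectivity matrix.

Cross-sample entropy follows the Richman-Moorman convention: count
cross-channel template pairs of length ``m`` and ``m + 1`` (same index
range for both lengths) whose Chebyshev distance is at most ``r`` and
return ``-ln(A / B)``.  Lower values mean stronger shared dynamics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CsEnParams",
    "ConnectivityMatrix",
    "UndefinedEntropyError",
    "cross_sample_entropy",
    "connectivity_matrix",
    "normalize_matrix",
    "mean_csen",
]

logger = logging.getLogger(__name__)


class UndefinedEntropyError(ValueError):
    """No template matches at tolerance r: -ln(A/B) is undefined."""


@dataclass(frozen=True)
class CsEnParams:
    """Cross-sample entropy parameters.

    ``r`` is the absolute matching tolerance; when ``None`` it is resolved
    as ``r_coeff`` times the pooled standard deviation of the data the
    entropy is computed over (field convention).  ``undefined`` selects the
    zero-match policy: ``"cap"`` replaces an undefined entry with the
    largest value observable at the given series length, ``-ln(1/(N-m)^2)``;
    ``"strict"`` raises :class:`UndefinedEntropyError`.
    """

    m: int = 2
    r: float | None = None
    r_coeff: float = 0.2
    undefined: str = "cap"

    def __post_init__(self) -> None:
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError("embedding dimension m must be an integer >= 1")
        if self.r is not None and self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.r_coeff <= 0:
            raise ValueError("r_coeff must be positive")
        if self.undefined not in ("cap", "strict"):
            raise ValueError("undefined policy must be 'cap' or 'strict'")


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise-entropy matrix; the diagonal is fixed at 0 and
    excluded from all statistics."""

    values: np.ndarray
    channel_labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("values must be a square matrix")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if self.channel_labels is not None and len(self.channel_labels) != n:
            raise ValueError("channel_labels length mismatch")
        if self.normalized:
            off = self.offdiag()
            if off.size and (off.min() < 0 or off.max() > 1):
                raise ValueError("normalized matrix must have off-diagonal in [0,1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Off-diagonal entries as a flat array (each unordered pair twice)."""
        n = self.n_channels
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]

    def to_tsv(self, path: str | Path) -> None:
        labels = self.channel_labels or [str(i) for i in range(self.n_channels)]
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(labels) + "\n")
            for lb, row in zip(labels, self.values):
                fh.write(lb + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConnectivityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                if line.strip():
                    rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
        return cls(np.array(rows), channel_labels=header)


# ---------------------------------------------------------------------------
# Cross-sample entropy
# ---------------------------------------------------------------------------

def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.concatenate([x, y]).std())


def _match_counts(wx: np.ndarray, wy: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts of cross template pairs within Chebyshev tolerance r.

    ``wx``/``wy`` are (N - m, m + 1) sliding windows; the length-m match
    uses the first m columns, the length-(m+1) match adds the last column.
    Returns (A, B) = (m+1-length matches, m-length matches).
    """
    diff = np.abs(wx[:, None, :] - wy[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    b = int(np.count_nonzero(d_m <= r))
    d_m1 = np.maximum(d_m, diff[:, :, m])
    a = int(np.count_nonzero(d_m1 <= r))
    return a, b


def _entropy_from_counts(a: int, b: int, n_templates: int, undefined: str) -> float:
    if a == 0 or b == 0:
        if undefined == "strict":
            raise UndefinedEntropyError(
                f"no template matches at tolerance (A={a}, B={b})"
            )
        cap = 2.0 * math.log(n_templates)
        logger.debug("undefined entropy capped at %.4f", cap)
        return cap
    return math.log(b / a)  # == -ln(A/B), written to avoid returning -0.0


def cross_sample_entropy(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    params: CsEnParams = CsEnParams(),
) -> float:
    """Cross-sample entropy between two equal-length series.

    Symmetric in (x, y) by construction and nonnegative wherever defined
    (every length-(m+1) match is also a length-m match, so A <= B).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if n <= params.m + 1:
        raise ValueError(f"series length {n} too short for m={params.m}")
    r = params.r
    if r is None:
        sd = _pooled_sd(x, y)
        if sd == 0:
            # both series constant: every template matches at any r > 0
            return 0.0
        r = params.r_coeff * sd
    wx = sliding_window_view(x, params.m + 1)
    wy = sliding_window_view(y, params.m + 1)
    a, b = _match_counts(wx, wy, params.m, r)
    return _entropy_from_counts(a, b, n - params.m, params.undefined)


def connectivity_matrix(
    epoch: np.ndarray,
    params: CsEnParams = CsEnParams(),
    channel_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pairwise cross-sample entropy over all channel pairs of one epoch.

    When ``params.r`` is None the tolerance is resolved once per epoch as
    ``r_coeff x`` the pooled standard deviation of the whole epoch, so all
    pairs are compared on the same scale.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("epoch must be (n_channels >= 2) x n_samples")
    n_ch, n_samp = epoch.shape
    if n_samp <= params.m + 1:
        raise ValueError("epoch too short for the embedding dimension")
    r = params.r
    if r is None:
        sd = float(epoch.std())
        if sd == 0:
            r = 1e-12  # degenerate all-constant epoch; every pair matches
        else:
            r = params.r_coeff * sd
    windows = [sliding_window_view(epoch[c], params.m + 1) for c in range(n_ch)]
    values = np.zeros((n_ch, n_ch))
    n_templates = n_samp - params.m
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            a, b = _match_counts(windows[i], windows[j], params.m, r)
            values[i, j] = values[j, i] = _entropy_from_counts(
                a, b, n_templates, params.undefined
            )
    return ConnectivityMatrix(values, channel_labels=channel_labels)


def normalize_matrix(A: ConnectivityMatrix) -> ConnectivityMatrix:
    """Min-max rescale the off-diagonal entries to [0, 1]; diagonal stays 0."""
    off = A.offdiag()
    lo, hi = float(off.min()), float(off.max())
    if hi == lo:
        raise ValueError("degenerate matrix: all off-diagonal values equal")
    scaled = (A.values - lo) / (hi - lo)
    np.fill_diagonal(scaled, 0.0)
    labels = list(A.channel_labels) if A.channel_labels else None
    return ConnectivityMatrix(scaled, channel_labels=labels, normalized=True)


def mean_csen(matrices: Sequence[ConnectivityMatrix]) -> float:
    """Arithmetic mean over all off-diagonal entries of all matrices."""
    if not matrices:
        raise ValueError("empty matrix list")
    shape = matrices[0].values.shape
    if any(m.values.shape != shape for m in matrices):
        raise ValueError("matrices must share a shape")
    return float(np.mean([m.offdiag() for m in matrices]))
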