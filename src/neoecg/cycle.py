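"""Period normalization and PCA extraction of a representative beat.

Each interior beat is cut on the window [R - 0.3 RRAvg, R + 0.7 RRAvg]
(the 30/70 split keeps the full T wave inside the cycle at neonatal rates)
and linearly resampled to a fixed phase length M.  The representative cycle
is the mean cycle plus the rank-1 principal-component reconstruction
averaged over cycles, with the eigenvector sign fixed by positive
correlation with the mean cycle; the retained component's variance fraction
is reported as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ECGSegment
from .qrs import QRSAnnotation

__all__ = [
    "CycleMatrix",
    "RepresentativeCycle",
    "InsufficientCyclesError",
    "build_cycle_matrix",
    "extract_representative",
    "R_PHASE",
]

#: phase position of the R apex inside the normalized cycle
R_PHASE = 0.3


class InsufficientCyclesError(ValueError):
    """Fewer than 3 usable cycles in the segment."""


@dataclass
class CycleMatrix:
    """M x N matrix of period-normalized cycles (columns are beats)."""

    data: np.ndarray  # shape (M, N)
    r_indices: np.ndarray
    rravg: float
    fs: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] < 3:
            raise InsufficientCyclesError("cycle matrix needs at least 3 columns")

    @property
    def m(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_cycles(self) -> int:
        return int(self.data.shape[1])


@dataclass
class RepresentativeCycle:
    """One synthesized beat in normalized phase, plus PCA provenance.

    The time axis is phase in [0, 1); multiply by ``rravg`` for seconds.
    ``offset``/``scale`` carry the segment's amplitude map back to mV.
    """

    waveform: np.ndarray
    variance_fraction: float
    n_cycles: int
    rravg: float
    offset: float = 0.0
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return int(self.waveform.size)

    @property
    def dt(self) -> float:
        """Seconds per phase sample."""
        return self.rravg / self.m

    def physical(self) -> np.ndarray:
        return self.waveform * self.scale + self.offset

    def time(self) -> np.ndarray:
        """Time axis in seconds, R apex at t = 0."""
        return (np.arange(self.m) / self.m - R_PHASE) * self.rravg


def build_cycle_matrix(
    segment: ECGSegment, ann: QRSAnnotation, m: int = 256
) -> CycleMatrix:
    """Resample each interior beat to ``m`` phase samples by linear interpolation.

    The first and last detected beats are dropped (their windows may exceed
    the segment); beats whose window still leaves the segment are skipped.
    """
    if ann.n_beats < 4:
        raise InsufficientCyclesError("need >= 4 beats (first/last are dropped)")
    x = np.asarray(segment.samples, dtype=float)
    rravg = ann.rravg
    half_pre = R_PHASE * rravg * segment.fs
    half_post = (1.0 - R_PHASE) * rravg * segment.fs
    cols, used_r = [], []
    for r in ann.r[1:-1]:
        grid = r - half_pre + np.arange(m) * (half_pre + half_post) / m
        if grid[0] < 0 or grid[-1] > x.size - 1:
            continue
        cols.append(np.interp(grid, np.arange(x.size), x))
        used_r.append(int(r))
    if len(cols) < 3:
        raise InsufficientCyclesError(f"only {len(cols)} usable cycles (need >= 3)")
    return CycleMatrix(
        data=np.column_stack(cols), r_indices=np.asarray(used_r),
        rravg=rravg, fs=segment.fs,
    )


def extract_representative(matrix: CycleMatrix) -> RepresentativeCycle:
    """Mean cycle + leading-component reconstruction, sign-aligned.

    The sample covariance across cycles (cycles as observations) is
    eigen-decomposed via SVD of the centered matrix; the representative is
    the mean cycle plus the first component scaled by the mean score (zero
    up to round-off for centered data, retained for contract fidelity).
    A degenerate matrix (all columns equal) returns that column with
    variance fraction 1.
    """
    x = matrix.data
    mu = x.mean(axis=1)
    xc = x - mu[:, None]
    total = float(np.sum(xc * xc))
    if total <= 1e-24 * max(float(np.sum(x * x)), 1.0):
        return RepresentativeCycle(
            waveform=x[:, 0].copy(), variance_fraction=1.0,
            n_cycles=matrix.n_cycles, rravg=matrix.rravg,
        )
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    eigvals = s * s / (matrix.n_cycles - 1)
    var_frac = float(eigvals[0] / eigvals.sum())
    v = u[:, 0]
    if np.dot(v, mu - mu.mean()) < 0:  # sign-ambiguous eigenvector
        v = -v
    scores = xc.T @ v
    rep = mu + float(scores.mean()) * v
    return RepresentativeCycle(
        waveform=rep, variance_fraction=var_frac,
        n_cycles=matrix.n_cycles, rravg=matrix.rravg,
        meta={"eigvals": eigvals},
    )
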