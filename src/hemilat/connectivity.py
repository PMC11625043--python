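"""Fisher-z functional connectivity, hemispheric strength sums and motion QC.

The connectivity matrix is the Pearson correlation of every vertex pair's
time series, Fisher r-to-z transformed (atanh) to improve normality. From it
each vertex gets two scalar strengths:

``intra``
    sum of z-connectivity to every other vertex in the *same* hemisphere,
``he``
    sum of z-connectivity to every vertex in the *opposite* hemisphere
    except the vertex's own homotopic partner (heterotopic connectivity).

Self-correlation is excluded from ``intra`` — atanh(1) is infinite and would
dominate the sum. Correlations are clipped to +/-(1 - 1e-7) before atanh so
degenerate inputs cannot produce infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas_io import HomotopicAtlas, TimeSeries
from .errors import DegenerateSignalError, ShapeError

#: correlations are clipped to +/-(1 - R_CLIP_EPS) before Fisher z
R_CLIP_EPS = 1e-7

FD_THRESHOLD_MM = 0.5
MAX_OUTLIER_FRACTION = 0.20


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix; the diagonal is undefined (NaN)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError("FC matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """A copy with the (undefined) diagonal replaced by 0, safe to sum over."""
        out = self.values.copy()
        np.fill_diagonal(out, 0.0)
        return out


@dataclass(frozen=True)
class StrengthSums:
    """Per-vertex heterotopic (he) and intrahemispheric (intra) z-strength sums."""

    he: np.ndarray
    intra: np.ndarray


@dataclass(frozen=True)
class QCReport:
    """Motion quality control for one subject."""

    subject_id: str
    n_frames: int
    n_outlier_frames: int
    outlier_fraction: float
    excluded: bool
    mfd: float


def censor_mask(fd: np.ndarray, fd_threshold: float = FD_THRESHOLD_MM) -> np.ndarray:
    """Boolean mask of frames to KEEP (FD strictly above threshold is censored)."""
    fd = np.asarray(fd, dtype=float)
    return ~(fd > fd_threshold)


def compute_fc(
    ts: TimeSeries,
    fd: np.ndarray | None = None,
    *,
    censor: bool = True,
    fd_threshold: float = FD_THRESHOLD_MM,
) -> FCMatrix:
    """Pearson-correlate vertex time series and Fisher z-transform.

    If an FD trace is supplied and ``censor`` is true, frames with
    FD > ``fd_threshold`` are dropped ("scrubbed") before correlation.

    Raises
    ------
    DegenerateSignalError
        if any vertex's (retained) time series has zero variance.
    ShapeError
        if the FD trace length disagrees with the number of timepoints.
    """
    values = ts.values
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.shape[0] != ts.n_timepoints:
            raise ShapeError(
                f"FD trace has {fd.shape[0]} frames, time series has {ts.n_timepoints}"
            )
        if censor:
            keep = censor_mask(fd, fd_threshold)
            if keep.sum() < 3:
                raise DegenerateSignalError(
                    f"subject {ts.subject_id!r}: fewer than 3 frames survive censoring"
                )
            values = values[:, keep]
    sd = values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateSignalError(
            f"subject {ts.subject_id!r}: zero-variance time series at vertex index {int(dead[0])}"
        )
    r = np.corrcoef(values)
    limit = 1.0 - R_CLIP_EPS
    z = np.arctanh(np.clip(r, -limit, limit))
    np.fill_diagonal(z, np.nan)
    # enforce exact symmetry against accumulated float asymmetry
    z = (z + z.T) / 2.0
    return FCMatrix(z)


def strength_sums(fc: FCMatrix, atlas: HomotopicAtlas) -> StrengthSums:
    """Per-vertex he/intra strength sums (see module docstring for definitions)."""
    if fc.n_vertices != atlas.n_vertices:
        raise ShapeError(
            f"FC matrix is {fc.n_vertices}x{fc.n_vertices}, atlas has {atlas.n_vertices} vertices"
        )
    z = fc.offdiag()
    left = atlas.left_mask
    same_hemi = left[:, None] == left[None, :]
    intra = np.where(same_hemi, z, 0.0).sum(axis=1)  # diagonal already zero
    hetero = np.where(~same_hemi, z, 0.0)
    n = atlas.n_vertices
    homotopic_z = z[np.arange(n), atlas.partner_index]
    he = hetero.sum(axis=1) - homotopic_z
    return StrengthSums(he=he, intra=intra)


def mean_global_fc(fc: FCMatrix) -> float:
    """Mean Fisher-z connectivity over the strict upper triangle (whole brain)."""
    n = fc.n_vertices
    if n < 2:
        raise ShapeError("mean global FC needs at least 2 vertices")
    iu = np.triu_indices(n, k=1)
    return float(fc.values[iu].mean())


def motion_qc(
    fd: np.ndarray,
    subject_id: str = "",
    fd_threshold: float = FD_THRESHOLD_MM,
    max_fraction: float = MAX_OUTLIER_FRACTION,
) -> QCReport:
    """Flag high-motion frames and apply the subject-exclusion rule.

    A frame is an outlier when FD strictly exceeds ``fd_threshold`` (0.5 mm);
    the subject is excluded when the outlier fraction strictly exceeds
    ``max_fraction`` (20%). mFD is the mean over *all* frames.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD trace")
    if (fd < 0).any():
        raise ValueError("FD values must be non-negative")
    n_out = int((fd > fd_threshold).sum())
    frac = n_out / fd.size
    return QCReport(
        subject_id=subject_id,
        n_frames=int(fd.size),
        n_outlier_frames=n_out,
        outlier_fraction=frac,
        excluded=frac > max_fraction,
        mfd=float(fd.mean()),
    )
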