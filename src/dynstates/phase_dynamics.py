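"""Band-limited phase dynamics of parcellated fMRI signals.

This module implements the front end of leading-eigenvector dynamics
analysis (LEiDA).  Component time courses are band-pass filtered to the
slow oscillatory band of interest, the instantaneous phase of each
component is estimated from the analytic signal, and every retained
timepoint is summarised by the unit leading eigenvector of its
phase-coherence matrix.  The sign pattern of that eigenvector splits the
components into two communities whose phases are locked with respect to
each other; the eigenvector series is the input to state clustering.

All operations accept either a plain ``(timepoints, components)`` array
or a :class:`pandas.DataFrame` with one column per component, and
preserve the container type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "AcquisitionSpec",
    "bandpass_filter",
    "instantaneous_phase",
    "edge_trim_count",
    "phase_coherence_matrix",
    "leading_eigenvector",
    "coherence_leading_eigenvectors",
    "align_eigenvector_sequence",
    "leida_transform",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition and filtering parameters for the phase pipeline.

    Parameters
    ----------
    tr_seconds
        Repetition time of the fMRI sequence in seconds.
    band_low_hz, band_high_hz
        Butterworth band-pass edges.  The defaults select the slow
        oscillations conventionally used for phase-coherence analysis
        of BOLD signals.
    filter_order
        Order of the Butterworth design (applied forward and backward,
        so the effective attenuation corresponds to twice this order).
    f_min_effective_hz
        Lowest frequency that meaningfully passes the filter skirt;
        one full cycle of this frequency determines how many volumes
        are trimmed from each end of the scan to remove filter and
        Hilbert transients.
    """

    tr_seconds: float = 1.6
    band_low_hz: float = 0.04
    band_high_hz: float = 0.07
    filter_order: int = 7
    f_min_effective_hz: float = 0.038

    def __post_init__(self) -> None:
        nyq = self.nyquist_hz
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ValueError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz must lie "
                f"inside (0, Nyquist = {nyq:.4g}) Hz and be increasing"
            )
        if self.f_min_effective_hz > self.band_low_hz:
            raise ValueError("f_min_effective_hz must not exceed band_low_hz")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    @property
    def trim_volumes(self) -> int:
        return edge_trim_count(self.f_min_effective_hz, self.tr_seconds)


def _as_array(tc) -> tuple[np.ndarray, object]:
    """Return (float array, template) where template rebuilds the container."""
    if isinstance(tc, pd.DataFrame):
        return tc.to_numpy(dtype=float), tc
    arr = np.asarray(tc, dtype=float)
    if arr.ndim != 2:
        raise ValueError("time courses must be 2-D (timepoints x components)")
    return arr, None


def _rewrap(values: np.ndarray, template) -> np.ndarray | pd.DataFrame:
    if template is None:
        return values
    index = template.index
    if len(index) != len(values):  # rows were trimmed
        index = index[: len(values)]
    return pd.DataFrame(values, columns=template.columns, index=index)


def bandpass_filter(tc, spec: AcquisitionSpec):
    """Zero-phase Butterworth band-pass filter, column-wise.

    The filter is designed in second-order sections and applied forward
    and backward (``sosfiltfilt``), which doubles the effective order
    and cancels the phase response, so no group delay is introduced.
    """
    x, template = _as_array(tc)
    if not np.all(np.isfinite(x)):
        raise ValueError("time courses contain non-finite values")
    fs = 1.0 / spec.tr_seconds
    sos = butter(
        spec.filter_order,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    n_sections = sos.shape[0]
    padlen = 3 * (2 * n_sections + 1)  # default sosfiltfilt edge padding
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series of length {x.shape[0]} is too short for a zero-phase "
            f"order-{spec.filter_order} band-pass filter; need more than "
            f"{padlen} timepoints"
        )
    y = sosfiltfilt(sos, x, axis=0)
    return _rewrap(y, template)


def instantaneous_phase(tc):
    """Phase of the analytic signal per component, wrapped to (-pi, pi].

    The input is expected to be band-limited and (near) zero-mean, as
    produced by :func:`bandpass_filter`; the analytic-signal phase of a
    broadband signal is not interpretable.
    """
    x, template = _as_array(tc)
    norms = np.max(np.abs(x), axis=0)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        raise ValueError(f"column {bad} is identically zero; phase undefined")
    phases = np.angle(hilbert(x, axis=0))
    return _rewrap(phases, template)


def edge_trim_count(f_min_hz: float, tr_seconds: float) -> int:
    """Number of volumes to drop at each end of a filtered series.

    One full cycle of the lowest effective frequency, expressed in
    volumes and rounded up: ``ceil((1 / f_min) / tr)``.
    """
    if f_min_hz <= 0 or tr_seconds <= 0:
        raise ValueError("f_min_hz and tr_seconds must be positive")
    return math.ceil((1.0 / f_min_hz) / tr_seconds)


def phase_coherence_matrix(phases: np.ndarray) -> np.ndarray:
    """Pairwise phase coherence cos(theta_i - theta_j) at one timepoint.

    The result is symmetric with unit diagonal and entries in [-1, 1].
    """
    theta = np.asarray(phases, dtype=float).ravel()
    m = np.cos(theta[:, None] - theta[None, :])
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return m


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    nz = np.nonzero(v)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def leading_eigenvector(matrix: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unit eigenvector of the algebraically largest eigenvalue.

    The sign of the returned vector is unconstrained (eigenvectors are
    defined up to sign); sequence-level sign consistency is handled by
    :func:`align_eigenvector_sequence`.  If the top two eigenvalues are
    numerically tied (within 1e-12), the lexicographically larger
    candidate (after sign canonicalisation) is returned so the choice
    is deterministic.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(m - m.T)) > tol:
        raise ValueError("matrix is not symmetric")
    n = m.shape[0]
    w, v = scipy.linalg.eigh(m, subset_by_index=[max(n - 2, 0), n - 1])
    if w.size > 1 and abs(w[-1] - w[-2]) < 1e-12:
        cands = sorted(
            (tuple(_canonical_sign(v[:, i])) for i in range(w.size)), reverse=True
        )
        vec = np.array(cands[0])
    else:
        vec = v[:, -1]
    return vec / np.linalg.norm(vec)


def coherence_leading_eigenvectors(phases) -> np.ndarray:
    """Leading eigenvector of the phase-coherence matrix at every timepoint.

    Exploits the identity ``cos(a - b) = cos a cos b + sin a sin b``:
    the coherence matrix equals ``c c' + s s'`` with ``c = cos(theta)``
    and ``s = sin(theta)``, so it has rank at most two and its leading
    eigenvector lies in span{c, s}.  Each timepoint therefore reduces to
    a 2 x 2 symmetric eigenproblem, which makes long scans cheap.

    Returns a ``(timepoints, components)`` array of unit row vectors
    with per-timepoint arbitrary sign.
    """
    theta, _ = _as_array(phases)
    c = np.cos(theta)  # (t, n)
    s = np.sin(theta)
    # Gram matrices of the 2-D basis [c, s] per timepoint.
    g11 = np.einsum("tn,tn->t", c, c)
    g22 = np.einsum("tn,tn->t", s, s)
    g12 = np.einsum("tn,tn->t", c, s)
    # Largest eigenvalue of [[g11, g12], [g12, g22]] and its eigenvector.
    half_tr = 0.5 * (g11 + g22)
    disc = np.sqrt(np.maximum(0.25 * (g11 - g22) ** 2 + g12**2, 0.0))
    lam = half_tr + disc
    # Eigenvector (w1, w2): rows of (G - lam I) are proportional; use the
    # numerically larger residual row for stability.
    w1 = np.where(np.abs(g12) > np.abs(lam - g11), lam - g22, g12)
    w2 = np.where(np.abs(g12) > np.abs(lam - g11), g12, lam - g11)
    degenerate = (np.abs(w1) + np.abs(w2)) < 1e-12 * np.maximum(lam, 1.0)
    w1 = np.where(degenerate, 1.0, w1)
    w2 = np.where(degenerate, 0.0, w2)
    vecs = c * w1[:, None] + s * w2[:, None]
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    return vecs / norms


def align_eigenvector_sequence(vectors):
    """Make eigenvector signs consistent over time.

    The first row is oriented so that the sum of its entries is <= 0
    (the convention that places the larger phase community on the
    negative side); every later row is flipped whenever its inner
    product with the previous aligned row is negative.  After alignment
    consecutive rows have non-negative inner products.
    """
    v, template = _as_array(vectors)
    out = v.copy()
    if out.shape[0] == 0:
        return _rewrap(out, template)
    if out[0].sum() > 0:
        out[0] = -out[0]
    for t in range(1, out.shape[0]):
        if np.dot(out[t], out[t - 1]) < 0:
            out[t] = -out[t]
    return _rewrap(out, template)


def leida_transform(
    tc,
    spec: AcquisitionSpec | None = None,
    retained_volumes: int | None = None,
):
    """Full front end: time courses -> aligned leading-eigenvector series.

    Pipeline: band-pass filter, analytic-signal phase, per-timepoint
    leading eigenvector of the phase-coherence matrix, edge trimming of
    ``spec.trim_volumes`` volumes at each end, and sign alignment.

    Parameters
    ----------
    tc
        ``(timepoints, components)`` array or DataFrame.
    spec
        Acquisition parameters; defaults to :class:`AcquisitionSpec`.
    retained_volumes
        Optional override of the number of rows kept after trimming.
        If smaller than the arithmetic count, the surplus is dropped
        from the end of the series.

    Returns
    -------
    Eigenvector series with ``timepoints - 2 * trim`` rows (or
    ``retained_volumes`` rows when overridden), unit-norm per row.
    """
    spec = spec or AcquisitionSpec()
    x, template = _as_array(tc)
    trim = spec.trim_volumes
    if x.shape[0] <= 2 * trim + 2:
        raise ValueError(
            f"need more than {2 * trim + 2} volumes to retain data after "
            f"trimming {trim} volumes at each end"
        )
    filtered = bandpass_filter(x, spec)
    phases = instantaneous_phase(filtered)
    vectors = coherence_leading_eigenvectors(phases)
    vectors = vectors[trim:-trim]
    if retained_volumes is not None:
        if retained_volumes < 1 or retained_volumes > vectors.shape[0]:
            raise ValueError(
                f"retained_volumes must be in [1, {vectors.shape[0]}]"
            )
        vectors = vectors[:retained_volumes]
    vectors = align_eigenvector_sequence(vectors)
    return _rewrap(vectors, template)
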