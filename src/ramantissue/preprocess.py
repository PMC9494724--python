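"""Spectral preprocessing for both classification routes.

Two chains are provided:

* the *quantitative* chain — iterative fourth-order polynomial baseline
  removal followed by max-normalisation — which feeds the threshold-table
  fingerprint classifier; and
* the *machine-learning* chain — baseline removal, max-normalisation,
  asymmetric-least-squares (Whittaker) smoothing, a 0.3 intensity threshold
  that removes valleys, peak extraction, and packing into fixed-length
  (default 650) feature vectors for the neural classifiers.

All heavy steps have ``*_batch`` variants operating on ``(n_spectra,
n_points)`` arrays so a full 51×51 raster map is processed in a handful of
vectorised linear-algebra calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import find_peaks

from .errors import DegenerateSpectrumError, GridMismatchError
from .spectra_io import Spectrum, _require_same_grid


class BaselineConvergenceWarning(UserWarning):
    """The iterative polynomial baseline fit stopped at max_iter without converging."""


@dataclass
class PreprocessConfig:
    """Tunable parameters of both preprocessing chains.

    baseline_order
        Degree of the iteratively refit polynomial baseline (4 by default).
    als_lambda, als_p, als_n_iter
        Whittaker second-difference smoothing penalty, asymmetry weight
        (``p = 0.5`` weights residuals symmetrically; smaller values bias the
        smooth curve below peaks) and number of reweighting rounds.
    threshold_tau
        Normalised-intensity cutoff below which the valley filter zeroes the
        signal (0.3 by default).
    peak_min_prominence
        Minimum prominence (normalised units) for a local maximum to count as
        a peak.
    feature_length
        Fixed slot count of the neural feature vectors (650 by default).
    """

    baseline_order: int = 4
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    als_lambda: float = 100.0
    als_p: float = 0.5
    als_n_iter: int = 10
    threshold_tau: float = 0.3
    peak_min_prominence: float = 0.05
    feature_length: int = 650

    def __post_init__(self) -> None:
        if self.baseline_order < 1 or self.baseline_max_iter < 1:
            raise ValueError("baseline_order and baseline_max_iter must be positive")
        if self.als_lambda <= 0 or not (0 < self.als_p < 1) or self.als_n_iter < 1:
            raise ValueError("als_lambda > 0, 0 < als_p < 1 and als_n_iter >= 1 required")
        if not (0 <= self.threshold_tau < 1):
            raise ValueError("threshold_tau must lie in [0, 1)")
        if self.feature_length < 1 or self.peak_min_prominence < 0:
            raise ValueError("feature_length must be positive, prominence non-negative")


@dataclass
class PeakFeatures:
    """Fixed-length peak representation fed to the neural classifiers.

    ``wavenumbers``/``intensities`` hold the first ``n_peaks`` slots in
    ascending wavenumber order; remaining slots are zero padding.  ``mode``
    is ``"1d"`` (intensities only, slot = peak rank) or ``"2d"``
    (wavenumber, intensity pairs).
    """

    mode: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    n_peaks: int

    def __post_init__(self) -> None:
        if self.mode not in ("1d", "2d"):
            raise ValueError("mode must be '1d' or '2d'")
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumber and intensity slots differ in shape")

    @property
    def length(self) -> int:
        return len(self.intensities)

    def as_array(self) -> np.ndarray:
        """1d → ``(length,)`` intensity vector; 2d → ``(length, 2)`` array."""
        if self.mode == "1d":
            return self.intensities.copy()
        return np.column_stack([self.wavenumbers, self.intensities])


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def modpoly_baseline_batch(
    grid: np.ndarray,
    intensities: np.ndarray,
    order: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative peak-suppressing polynomial baseline for many spectra at once.

    Modified-polyfit with noise-tolerant clipping: fit a degree-``order``
    polynomial, clip the working signal at ``fit + std(residual)`` so peaks are
    progressively suppressed while the fit stays at the *mean* of the noise
    (clipping at the bare point-wise minimum instead would chase the lower
    noise envelope and bias the baseline down by ~2 noise standard
    deviations), refit, and repeat until the fit changes by less than ``tol``
    (relative to each spectrum's intensity range) or ``max_iter`` is reached.
    Because the design matrix is shared, each iteration is one matrix product
    for the whole batch.

    Returns ``(baselines, converged)`` with shapes ``(n, p)`` and ``(n,)``.
    """
    Y = np.atleast_2d(np.asarray(intensities, float))
    n, p = Y.shape
    if p <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} points, got {p}")
    x = np.asarray(grid, float)
    # scale to [-1, 1] for conditioning
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(xs, order)  # (p, order+1)
    pinv = np.linalg.pinv(V)  # (order+1, p)
    # convergence scale: intensity range, floored by magnitude for flat inputs
    scale = np.maximum(np.maximum(Y.max(axis=1) - Y.min(axis=1),
                                  np.abs(Y).max(axis=1) * 1e-6),
                       np.finfo(float).tiny)

    Z = Y.copy()
    fit = (Z @ pinv.T) @ V.T
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter - 1):
        dev = (Z - fit).std(axis=1)
        Z = np.minimum(Z, fit + dev[:, None])
        new_fit = (Z @ pinv.T) @ V.T
        delta = np.abs(new_fit - fit).max(axis=1) / scale
        fit = new_fit
        converged = delta < tol
        if converged.all():
            break
    return fit, converged


def fit_polynomial_baseline(
    s: Spectrum,
    order: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Spectrum:
    """Baseline of one spectrum via :func:`modpoly_baseline_batch`.

    Emits :class:`BaselineConvergenceWarning` (not an exception) if the
    iteration hits ``max_iter`` without settling.
    """
    baseline, converged = modpoly_baseline_batch(
        s.wavenumbers, s.intensities, order=order, max_iter=max_iter, tol=tol)
    if not converged[0]:
        warnings.warn("baseline fit did not converge within max_iter",
                      BaselineConvergenceWarning, stacklevel=2)
    return s.with_intensities(baseline[0])


def subtract_baseline(s: Spectrum, baseline: Spectrum) -> Spectrum:
    """Point-wise signal minus baseline (grids must match)."""
    _require_same_grid(s.wavenumbers, baseline.wavenumbers)
    return s.with_intensities(s.intensities - baseline.intensities,
                              baseline_corrected=True)


def normalize_max(s: Spectrum, degenerate_tol: float = 0.0) -> Spectrum:
    """Scale intensities so the maximum is exactly 1.

    A maximum at or below ``degenerate_tol`` means there is no signal left
    (e.g. a pure-baseline input) and raises :class:`DegenerateSpectrumError`.
    """
    peak = float(s.intensities.max())
    if peak <= degenerate_tol:
        raise DegenerateSpectrumError(
            f"maximum intensity {peak:.3g} <= {degenerate_tol:.3g}; nothing to normalise")
    out = s.with_intensities(s.intensities / peak, normalized=True)
    out.intensities[np.argmax(out.intensities)] = 1.0  # exact despite rounding
    return out


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _whittaker_banded(lam: float, n: int) -> np.ndarray:
    """Upper banded form of lam * D2'D2 for the symmetric pentadiagonal system."""
    ab = np.zeros((3, n))
    ab[0, 2:] = lam                      # second super-diagonal
    ab[1, 1:] = -2.0 * lam
    ab[1, 1] = -2.0 * lam
    ab[2, :] = lam * 6.0
    ab[2, 0] = ab[2, -1] = lam * 1.0
    ab[2, 1] = ab[2, -2] = lam * 5.0
    ab[1, 1] = -2.0 * lam
    ab[1, -1] = -2.0 * lam
    # interior of first super-diagonal is -4*lam
    if n > 3:
        ab[1, 2:-1] = -4.0 * lam
    return ab


def als_smooth_batch(
    intensities: np.ndarray,
    lam: float = 100.0,
    p: float = 0.5,
    n_iter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares (Whittaker) smoothing of many spectra.

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum (Δ² z)^2`` with weights
    re-estimated each round: ``w_i = p`` where the signal sits above the
    current smooth curve and ``1 - p`` below it.  ``p = 0.5`` is the plain
    symmetric Whittaker smoother (one round suffices; extra rounds are no-ops).
    """
    Y = np.atleast_2d(np.asarray(intensities, float))
    n, m = Y.shape
    if m < 5:
        # too short for the banded pentadiagonal form; solve densely
        D = np.diff(np.eye(m), n=2, axis=0)
        A = lam * D.T @ D
        out = np.empty_like(Y)
        for i in range(n):
            y, w = Y[i], np.full(m, 0.5)
            for _ in range(n_iter):
                z = np.linalg.solve(A + np.diag(w), w * y)
                w_new = np.where(y > z, p, 1.0 - p)
                if np.array_equal(w_new, w):
                    break
                w = w_new
            out[i] = z
        return out
    penalty = _whittaker_banded(lam, m)
    out = np.empty_like(Y)
    for i in range(n):
        y = Y[i]
        w = np.full(m, 0.5)
        z = y
        for _ in range(n_iter):
            ab = penalty.copy()
            ab[2, :] += w
            z = solveh_banded(ab, w * y)
            w_new = np.where(y > z, p, 1.0 - p)
            if np.array_equal(w_new, w):
                break
            w = w_new
        out[i] = z
    return out


def als_smooth(s: Spectrum, lam: float = 100.0, p: float = 0.5, n_iter: int = 10) -> Spectrum:
    """Whittaker/ALS smoothing of one spectrum (see :func:`als_smooth_batch`)."""
    if lam <= 0 or not (0 < p < 1) or n_iter < 1:
        raise ValueError("require lam > 0, 0 < p < 1, n_iter >= 1")
    return s.with_intensities(als_smooth_batch(s.intensities, lam, p, n_iter)[0],
                              smoothed=True)


# ---------------------------------------------------------------------------
# thresholding and peaks
# ---------------------------------------------------------------------------

_NORMALIZED_ATOL = 1e-6


def threshold_filter(s: Spectrum, tau: float = 0.3) -> Spectrum:
    """Zero every intensity below ``tau``; the spectrum must be normalised.

    This removes the valleys between peaks so that only the chemically
    informative maxima survive.
    """
    if abs(float(s.intensities.max()) - 1.0) > _NORMALIZED_ATOL:
        raise ValueError("threshold_filter requires a max-normalised spectrum")
    out = np.where(s.intensities < tau, 0.0, s.intensities)
    return s.with_intensities(out, thresholded=True)


@dataclass
class PeakList:
    """Unpadded peak apices, ascending in wavenumber."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __len__(self) -> int:
        return len(self.wavenumbers)


def extract_peaks(s: Spectrum, min_prominence: float = 0.05) -> PeakList:
    """Strict local maxima of the (thresholded) signal with the given prominence.

    Each peak is recorded as the (wavenumber, intensity) of its apex, in
    ascending wavenumber order.  An empty peak list is valid.
    """
    idx, _ = find_peaks(s.intensities, prominence=min_prominence)
    idx = idx[s.intensities[idx] > 0]
    return PeakList(s.wavenumbers[idx].copy(), s.intensities[idx].copy())


def build_features(peaks: PeakList, mode: str, length: int = 650) -> PeakFeatures:
    """Pack a peak list into a fixed-length feature vector/array.

    Fewer peaks than ``length`` → zero-padded tail.  More → keep the
    ``length`` highest-intensity peaks (ties broken toward lower wavenumber),
    then restore wavenumber order.
    """
    wn, it = peaks.wavenumbers, peaks.intensities
    if len(wn) > length:
        order = np.lexsort((wn, -it))[:length]
        keep = np.sort(order)
        wn, it = wn[keep], it[keep]
    out_w = np.zeros(length)
    out_i = np.zeros(length)
    out_w[: len(wn)] = wn
    out_i[: len(it)] = it
    return PeakFeatures(mode=mode, wavenumbers=out_w, intensities=out_i, n_peaks=len(wn))


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def preprocess_qm_batch(
    grid: np.ndarray,
    intensities: np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Quantitative-method chain for a batch: baseline removal + max-normalisation.

    Returns ``(n, p)`` normalised intensities with each row's maximum exactly 1.
    """
    cfg = cfg or PreprocessConfig()
    Y = np.atleast_2d(np.asarray(intensities, float))
    baseline, _ = modpoly_baseline_batch(
        grid, Y, cfg.baseline_order, cfg.baseline_max_iter, cfg.baseline_tol)
    corrected = Y - baseline
    peak = corrected.max(axis=1)
    scale = np.maximum(np.abs(Y).max(axis=1), 1.0)
    bad = peak <= 1e-8 * scale
    if bad.any():
        raise DegenerateSpectrumError(
            f"{int(bad.sum())} spectra have no signal left after baseline removal")
    out = corrected / peak[:, None]
    out[np.arange(len(out)), corrected.argmax(axis=1)] = 1.0
    return out


def preprocess_qm(raw: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Baseline-correct and max-normalise one raw spectrum (quantitative chain)."""
    cfg = cfg or PreprocessConfig()
    out = preprocess_qm_batch(raw.wavenumbers, raw.intensities, cfg)[0]
    return raw.with_intensities(out, baseline_corrected=True, normalized=True)


def preprocess_ml(raw: Spectrum, cfg: PreprocessConfig | None = None,
                  mode: str = "2d") -> PeakFeatures:
    """Machine-learning chain: baseline → normalise → smooth → threshold → peaks.

    The smoothed trace is re-normalised before thresholding so that the 0.3
    cutoff always refers to a unit-maximum spectrum.
    """
    cfg = cfg or PreprocessConfig()
    s = preprocess_qm(raw, cfg)
    s = als_smooth(s, cfg.als_lambda, cfg.als_p, cfg.als_n_iter)
    s = normalize_max(s)
    s = threshold_filter(s, cfg.threshold_tau)
    peaks = extract_peaks(s, cfg.peak_min_prominence)
    return build_features(peaks, mode=mode, length=cfg.feature_length)


def preprocess_ml_batch(
    grid: np.ndarray,
    intensities: np.ndarray,
    cfg: PreprocessConfig | None = None,
    mode: str = "2d",
) -> list[PeakFeatures]:
    """Vectorised ML chain over ``(n, p)`` raw intensities on one grid."""
    cfg = cfg or PreprocessConfig()
    Y = preprocess_qm_batch(grid, intensities, cfg)
    Y = als_smooth_batch(Y, cfg.als_lambda, cfg.als_p, cfg.als_n_iter)
    peak = Y.max(axis=1)
    if np.any(peak <= 0):
        raise DegenerateSpectrumError("smoothed spectrum has non-positive maximum")
    Y = Y / peak[:, None]
    Y[Y < cfg.threshold_tau] = 0.0
    feats = []
    for row in Y:
        idx, _ = find_peaks(row, prominence=cfg.peak_min_prominence)
        idx = idx[row[idx] > 0]
        feats.append(build_features(
            PeakList(np.asarray(grid, float)[idx], row[idx]),
            mode=mode, length=cfg.feature_length))
    return feats
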