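"""Synthetic Raman tissue spectra and raster maps.

The generator stands in for patient measurements: each tissue class (tumor,
muscle, dermis, fat) gets a catalogue of Gaussian peaks over the fingerprint
region (400–1800 cm⁻¹, 1 cm⁻¹ steps) encoding the qualitative relationships
observed in real soft-tissue spectra:

* all four classes share peaks near 846–851, 935, 1002, 1313, 1438–1448,
  1657 and 1741 cm⁻¹, with class-specific amplitudes;
* tumor shows no peaks at 662, 744, 752, 1364 or 1396 cm⁻¹, whereas the
  benign tissues do; dermis and fat carry 1343/1364/1396 cm⁻¹ peaks of
  comparable size while muscle's 1343 cm⁻¹ peak dominates its 1364/1396 pair;
* the 1002 cm⁻¹ (phenylalanine) peak is weakest in fat, and tumor and muscle
  have only a small 1741 cm⁻¹ (ester carbonyl) peak;
* dermis has extra structure in the 1650–1700 cm⁻¹ band and fat in the
  1520–1640 cm⁻¹ band.

A smooth quartic additive baseline emulates the fluorescence background and
i.i.d. Gaussian noise the detector.  Per-spot amplitude/position jitter and a
per-patient wavenumber-grid offset emulate biological variation and the fact
that different acquisition sessions record different wavenumber ranges.

Exact amplitudes are a documented fixture of this package (real relative
intensities are only known qualitatively); all randomness flows through
explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra_io import (
    CLASS_ORDER,
    MapMeta,
    SpectralMap,
    Spectrum,
    SpectrumMeta,
    TissueClass,
)

#: fingerprint-region grid: 400–1800 cm⁻¹ in 1 cm⁻¹ steps (1401 points)
DEFAULT_GRID = np.arange(400.0, 1801.0, 1.0)

#: default quartic baseline coefficients, ascending powers of u=(w-400)/1400
DEFAULT_BASELINE = (0.5, 0.9, 0.4, -0.3, 0.2)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Per-class peak catalogue: wavenumber (cm⁻¹) → relative amplitude.
# Amplitudes at the shared peaks are deliberately class-specific (real common
# peaks differ in intensity across tissues) and sit mid-way inside 0.1-wide
# intensity bands so that the threshold-table fingerprints are robust to
# small amplitude jitter.
_PEAK_TABLE = {
    TissueClass.TUMOR: {
        848: 0.45, 935: 0.75, 1002: 0.85, 1313: 0.55,
        1443: 1.00, 1657: 0.95, 1741: 0.45,
    },
    TissueClass.MUSCLE: {
        662: 0.55, 744: 0.45, 752: 0.65,
        848: 0.65, 935: 0.55, 1002: 0.75, 1313: 0.65,
        1343: 0.85, 1364: 0.45, 1396: 0.45,
        1443: 1.00, 1657: 0.75, 1741: 0.45,
    },
    TissueClass.DERMIS: {
        662: 0.75, 744: 0.55, 752: 0.45,
        848: 0.85, 935: 0.45, 1002: 0.65, 1313: 0.45,
        1343: 0.45, 1364: 0.55, 1396: 0.65,
        1443: 1.00, 1657: 0.85, 1690: 0.55, 1741: 0.65,
    },
    TissueClass.FAT: {
        662: 0.45, 744: 0.65, 752: 0.55,
        848: 0.55, 935: 0.65, 1002: 0.45, 1313: 0.75,
        1343: 0.55, 1364: 0.65, 1396: 0.45,
        1443: 1.00, 1580: 0.55, 1657: 0.65, 1741: 0.75,
    },
}


@dataclass
class SyntheticTissueProfile:
    """Forward model for one tissue class: peaks + baseline + noise level."""

    tissue_class: TissueClass
    peaks: list[tuple[float, float, float]]  # (center cm⁻¹, FWHM cm⁻¹, amplitude)
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE
    noise_sigma: float = 0.05
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def amplitude(self, center: float) -> float:
        """Amplitude of the peak at ``center`` (0 if the class lacks it)."""
        for c, _, a in self.peaks:
            if abs(c - center) < 1e-9:
                return a
        return 0.0

    def baseline(self, wavenumbers: np.ndarray) -> np.ndarray:
        u = (np.asarray(wavenumbers, float) - 400.0) / 1400.0
        return np.polynomial.polynomial.polyval(u, self.baseline_coeffs)


@dataclass
class SimulationConfig:
    """Acquisition-level knobs: raster size, per-spot jitter, patient grid offset."""

    n_rows: int = 51
    n_cols: int = 51
    amplitude_jitter: float = 0.08   # fractional, per spot and peak
    shift_jitter: float = 1.0        # cm⁻¹ std of per-spot peak-centre wobble
    patient_grid_offset: float = 0.0  # cm⁻¹ shift of the recorded grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_jitter < 0 or self.shift_jitter < 0:
            raise ValueError("jitters must be non-negative")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster dimensions must be positive")


def default_profile(
    c: TissueClass,
    noise_sigma: float = 0.05,
    width: float = 8.0,
    grid: np.ndarray | None = None,
) -> SyntheticTissueProfile:
    """Default peak catalogue for one tissue class (``width`` = Gaussian FWHM)."""
    c = TissueClass(c)
    peaks = [(float(w), width, a) for w, a in sorted(_PEAK_TABLE[c].items())]
    return SyntheticTissueProfile(
        tissue_class=c, peaks=peaks, noise_sigma=noise_sigma,
        grid=DEFAULT_GRID.copy() if grid is None else np.asarray(grid, float))


def _peak_sum(
    grid: np.ndarray,
    centers: np.ndarray,
    sigmas: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Sum of Gaussians; ``centers``/``amplitudes`` may be (n_spots, n_peaks)."""
    centers = np.atleast_2d(centers)
    amplitudes = np.atleast_2d(amplitudes)
    out = np.zeros((centers.shape[0], len(grid)))
    for j in range(centers.shape[1]):
        z = (grid[None, :] - centers[:, j, None]) / sigmas[j]
        out += amplitudes[:, j, None] * np.exp(-0.5 * z * z)
    return out


def simulate_spectrum(
    p: SyntheticTissueProfile,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
) -> Spectrum:
    """One raw (un-normalised) spectrum: peaks + baseline + Gaussian noise."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    grid = p.grid + cfg.patient_grid_offset
    centers = np.array([c for c, _, _ in p.peaks])
    sigmas = np.array([w * _FWHM_TO_SIGMA for _, w, _ in p.peaks])
    amps = np.array([a for _, _, a in p.peaks])
    amp_eff = amps * np.clip(1.0 + cfg.amplitude_jitter * rng.standard_normal(len(amps)), 0, None)
    cent_eff = centers + cfg.shift_jitter * rng.standard_normal(len(centers))
    y = _peak_sum(grid, cent_eff, sigmas, amp_eff)[0]
    y += p.baseline(grid)
    if p.noise_sigma > 0:
        y += p.noise_sigma * rng.standard_normal(len(grid))
    return Spectrum(grid, y, SpectrumMeta(tissue_class=p.tissue_class))


def simulate_map(
    p: SyntheticTissueProfile,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
) -> SpectralMap:
    """A full raster map (default 51×51 = 2601 spectra) with per-spot jitter."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    grid = p.grid + cfg.patient_grid_offset
    n_spots = cfg.n_rows * cfg.n_cols
    centers = np.array([c for c, _, _ in p.peaks])
    sigmas = np.array([w * _FWHM_TO_SIGMA for _, w, _ in p.peaks])
    amps = np.array([a for _, _, a in p.peaks])
    amp_eff = amps[None, :] * np.clip(
        1.0 + cfg.amplitude_jitter * rng.standard_normal((n_spots, len(amps))), 0, None)
    cent_eff = centers[None, :] + cfg.shift_jitter * rng.standard_normal((n_spots, len(centers)))
    Y = _peak_sum(grid, cent_eff, sigmas, amp_eff)
    Y += p.baseline(grid)[None, :]
    if p.noise_sigma > 0:
        Y += p.noise_sigma * rng.standard_normal(Y.shape)
    return SpectralMap(
        grid, Y.reshape(cfg.n_rows, cfg.n_cols, len(grid)),
        MapMeta(tissue_class=p.tissue_class))


#: per-patient wavenumber grid offsets (cm⁻¹) emulating session-to-session range drift
DEFAULT_PATIENT_OFFSETS = (0.0, 3.0, -2.0)


def simulate_dataset(
    classes: Sequence[TissueClass] = CLASS_ORDER,
    n_maps_per_class: int = 1,
    cfg: SimulationConfig | None = None,
    noise_sigma: float = 0.05,
    patient_offsets: Sequence[float] = DEFAULT_PATIENT_OFFSETS,
) -> tuple[list[SpectralMap], pd.DataFrame]:
    """Labelled collection of maps across synthetic patients.

    Maps of each class are dealt round-robin to ``len(patient_offsets)``
    synthetic patients, each recording on its own offset wavenumber grid.
    Returns the maps (with metadata filled in) and a
    ``map_id,patient_id,tissue_class`` manifest.  Fully determined by
    ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(classes) * n_maps_per_class)
    maps: list[SpectralMap] = []
    rows = []
    k = 0
    for c in classes:
        c = TissueClass(c)
        profile = default_profile(c, noise_sigma=noise_sigma)
        for i in range(n_maps_per_class):
            patient = i % len(patient_offsets)
            patient_id = f"P{patient + 1}"
            map_id = f"{c.value}_{patient_id}_{i:02d}"
            map_cfg = replace(cfg, patient_grid_offset=patient_offsets[patient])
            seed = int(children[k].generate_state(1)[0] % (2**31))
            m = simulate_map(profile, map_cfg, seed=seed)
            m.meta = MapMeta(tissue_class=c, patient_id=patient_id, map_id=map_id)
            maps.append(m)
            rows.append({"map_id": map_id, "patient_id": patient_id, "tissue_class": c})
            k += 1
    manifest = pd.DataFrame(rows, columns=["map_id", "patient_id", "tissue_class"])
    return maps, manifest
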