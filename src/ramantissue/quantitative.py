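"""The quantitative threshold-table classification method.

A *reference spectrum* per tissue type (and per patient) is the average of
many baseline-corrected, max-normalised spectra of that tissue.  Its
fingerprint is a *reference table*: nine intensity levels 0.1, 0.2, …, 0.9,
each holding the set of grid wavenumbers whose normalised intensity falls in
``[level, level + 0.1)`` — an intensity on a boundary belongs to the lower
level, so the spectrum's maximum (1.0) always lands in the 0.9 set, and
intensities below 0.1 (noise floor) are excluded altogether.

An unknown spectrum is classified by building its own table the same way and
counting, level by level, how many wavenumbers coincide with each reference
table; the reference with the highest total match count wins.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GridMismatchError
from .evaluation import ConfusionMatrix
from .preprocess import PreprocessConfig, preprocess_qm_batch
from .spectra_io import (
    CLASS_ORDER,
    SpectralMap,
    Spectrum,
    SpectrumMeta,
    TissueClass,
    average_spectra,
    grids_equal,
)

_NORMALIZED_ATOL = 1e-6
#: slack added before flooring so that e.g. 0.3 (stored as 0.299999…) lands at level 0.3
_LEVEL_EPS = 1e-9


@dataclass
class ReferenceTable:
    """Threshold-level fingerprint of one normalised spectrum.

    ``level_tenths`` holds, per grid point, the level index 1–9 (level =
    index/10) or 0 for intensities below 0.1, which never match.
    """

    grid: np.ndarray
    level_tenths: np.ndarray
    tissue_class: TissueClass | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.level_tenths = np.asarray(self.level_tenths, dtype=int)
        if self.grid.shape != self.level_tenths.shape:
            raise ValueError("grid and level assignment differ in length")
        if self.level_tenths.min() < 0 or self.level_tenths.max() > 9:
            raise ValueError("levels must lie in 0..9 tenths")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, 10) / 10.0

    @property
    def assignment(self) -> dict[float, np.ndarray]:
        """Mapping level → array of wavenumbers assigned to that level."""
        return {k / 10.0: self.grid[self.level_tenths == k] for k in range(1, 10)
                if np.any(self.level_tenths == k)}

    @property
    def size(self) -> int:
        """Number of wavenumbers assigned to any level (intensity ≥ 0.1)."""
        return int(np.count_nonzero(self.level_tenths))

    def grid_hash(self) -> str:
        return hashlib.sha1(np.round(self.grid, 6).tobytes()).hexdigest()[:12]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# tissue_class: {self.tissue_class.value if self.tissue_class else ''}\n")
            fh.write(f"# patient_id: {self.patient_id or ''}\n")
            fh.write(f"# grid_hash: {self.grid_hash()}\n")
            fh.write("level,wavenumber_cm1\n")
            for k in range(1, 10):
                for w in self.grid[self.level_tenths == k]:
                    fh.write(f"{k / 10.0:.1f},{w:.9g}\n")

    @classmethod
    def read_csv(cls, path) -> "ReferenceTable":
        path = Path(path)
        tissue = patient = None
        pairs: list[tuple[float, float]] = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if line.startswith("# tissue_class:"):
                val = line.split(":", 1)[1].strip()
                tissue = TissueClass(val) if val else None
            elif line.startswith("# patient_id:"):
                val = line.split(":", 1)[1].strip()
                patient = val or None
            elif not line or line.startswith("#") or line.startswith("level,"):
                continue
            else:
                lvl, wn = line.split(",")
                pairs.append((float(lvl), float(wn)))
        pairs.sort(key=lambda t: t[1])
        grid = np.array([w for _, w in pairs])
        tenths = np.array([int(round(l * 10)) for l, _ in pairs])
        return cls(grid, tenths, tissue_class=tissue, patient_id=patient)


@dataclass
class MatchResult:
    """Outcome of matching an unknown table against a reference database."""

    counts: dict[int, int]            # reference index → match count
    reference_ids: list[tuple[TissueClass | None, str | None]]
    predicted_class: TissueClass
    tied: bool
    per_class_best: dict[TissueClass, int]


def build_reference_spectrum(spectra: Iterable[Spectrum]) -> Spectrum:
    """Average same-class preprocessed spectra and re-normalise to max 1."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    classes = {s.meta.tissue_class for s in spectra}
    if len(classes) != 1:
        raise ValueError(f"mixed tissue classes in reference input: {classes}")
    mean = average_spectra(spectra)
    out = mean.intensities / mean.intensities.max()
    out[np.argmax(out)] = 1.0
    return Spectrum(mean.wavenumbers, out,
                    SpectrumMeta(tissue_class=classes.pop(),
                                 patient_id=mean.meta.patient_id,
                                 baseline_corrected=True, normalized=True))


def extract_threshold_features(ref: Spectrum) -> ReferenceTable:
    """Assign each grid wavenumber to its intensity level (floor to tenths)."""
    if abs(float(ref.intensities.max()) - 1.0) > _NORMALIZED_ATOL:
        raise ValueError("threshold features require a max-normalised spectrum")
    tenths = np.floor(ref.intensities * 10.0 + _LEVEL_EPS).astype(int)
    tenths = np.clip(tenths, 0, 9)
    return ReferenceTable(ref.wavenumbers.copy(), tenths,
                          tissue_class=ref.meta.tissue_class,
                          patient_id=ref.meta.patient_id)


def count_matches(a: ReferenceTable, b: ReferenceTable) -> int:
    """Total, over all levels, of wavenumbers assigned to the same level in both."""
    if not grids_equal(a.grid, b.grid):
        raise GridMismatchError("reference tables are on different grids")
    same = (a.level_tenths == b.level_tenths) & (a.level_tenths >= 1)
    return int(np.count_nonzero(same))


def classify_qm(unknown: Spectrum, references: Sequence[ReferenceTable]) -> MatchResult:
    """Classify a preprocessed spectrum by maximum match count.

    Ties across classes are flagged and broken deterministically: larger
    per-class total count first, then the fixed class order
    (tumor, muscle, dermis, fat).
    """
    references = list(references)
    if not references:
        raise ValueError("empty reference set")
    table = extract_threshold_features(unknown)
    counts = {i: count_matches(table, r) for i, r in enumerate(references)}
    best = max(counts.values())
    per_class_best: dict[TissueClass, int] = {}
    per_class_total: dict[TissueClass, int] = {}
    for i, r in enumerate(references):
        c = r.tissue_class
        per_class_best[c] = max(per_class_best.get(c, 0), counts[i])
        per_class_total[c] = per_class_total.get(c, 0) + counts[i]
    winners = [c for c, v in per_class_best.items() if v == best]
    tied = len(winners) > 1
    winners.sort(key=lambda c: (-per_class_total[c], CLASS_ORDER.index(c)))
    return MatchResult(
        counts=counts,
        reference_ids=[(r.tissue_class, r.patient_id) for r in references],
        predicted_class=winners[0],
        tied=tied,
        per_class_best=per_class_best,
    )


def _resample_rows(grid: np.ndarray, flat: np.ndarray, target: np.ndarray) -> np.ndarray:
    if len(grid) == len(target) and np.max(np.abs(grid - target)) <= 1e-9:
        return flat
    return np.vstack([np.interp(target, grid, row) for row in flat])


def qm_blind_test(
    maps: Sequence[SpectralMap],
    train_fraction: float = 0.8,
    seed: int = 0,
    cfg: PreprocessConfig | None = None,
    unknown_per: str = "map",
) -> ConfusionMatrix:
    """80/20 blind test of the quantitative method on labelled raster maps.

    Per map, spot spectra are shuffled (seeded) and split; the training
    portions build one reference table per (patient, tissue) pair, and each
    map's held-out portion is averaged into a single unknown spectrum and
    classified against all references.  With ``unknown_per="patient_class"``
    the held-out portions are instead pooled per (patient, tissue) before
    averaging.  Returns the rows-as-actual confusion matrix.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if unknown_per not in ("map", "patient_class"):
        raise ValueError("unknown_per must be 'map' or 'patient_class'")
    maps = list(maps)
    if not maps:
        raise ValueError("no maps given")
    for m in maps:
        if m.meta.tissue_class is None:
            raise ValueError("all maps must carry a tissue_class label")
    present = {m.meta.tissue_class for m in maps}
    cfg = cfg or PreprocessConfig()
    rng = np.random.default_rng(seed)

    # common grid: intersection of all map ranges, on the first map's spacing
    lo = max(float(m.grid[0]) for m in maps)
    hi = min(float(m.grid[-1]) for m in maps)
    if hi <= lo:
        raise GridMismatchError("maps have no overlapping wavenumber range")
    step = float(np.median(np.diff(maps[0].grid)))
    grid = lo + step * np.arange(int(np.floor((hi - lo) / step)) + 1)

    train_pool: dict[tuple[str | None, TissueClass], list[np.ndarray]] = {}
    test_parts: list[tuple[str | None, TissueClass, np.ndarray]] = []
    for m in maps:
        flat = _resample_rows(m.grid, m.flat_intensities(), grid)
        prepped = preprocess_qm_batch(grid, flat, cfg)
        idx = rng.permutation(m.n_spectra)
        n_train = int(round(train_fraction * m.n_spectra))
        key = (m.meta.patient_id, m.meta.tissue_class)
        train_pool.setdefault(key, []).append(prepped[idx[:n_train]])
        test_parts.append((m.meta.patient_id, m.meta.tissue_class,
                           prepped[idx[n_train:]]))

    references = []
    for (patient, tissue), chunks in train_pool.items():
        mean = np.vstack(chunks).mean(axis=0)
        mean /= mean.max()
        ref = Spectrum(grid, mean, SpectrumMeta(tissue_class=tissue, patient_id=patient,
                                                normalized=True, baseline_corrected=True))
        references.append(extract_threshold_features(ref))

    if unknown_per == "patient_class":
        pooled: dict[tuple[str | None, TissueClass], list[np.ndarray]] = {}
        for patient, tissue, part in test_parts:
            pooled.setdefault((patient, tissue), []).append(part)
        test_parts = [(p, t, np.vstack(parts)) for (p, t), parts in pooled.items()]

    actual: list[TissueClass] = []
    predicted: list[TissueClass] = []
    for _, tissue, part in test_parts:
        if len(part) == 0:
            raise ValueError("a held-out partition is empty; map too small for the split")
        mean = part.mean(axis=0)
        mean /= mean.max()
        unknown = Spectrum(grid, mean, SpectrumMeta(normalized=True,
                                                    baseline_corrected=True))
        actual.append(tissue)
        predicted.append(classify_qm(unknown, references).predicted_class)
    return ConfusionMatrix.from_predictions(actual, predicted)


def build_reference_database(
    maps: Sequence[SpectralMap],
    cfg: PreprocessConfig | None = None,
    train_fraction: float = 1.0,
    seed: int = 0,
) -> list[ReferenceTable]:
    """One reference table per (patient, tissue) pair from labelled maps."""
    cfg = cfg or PreprocessConfig()
    rng = np.random.default_rng(seed)
    maps = list(maps)
    if not maps:
        raise ValueError("no maps given")
    grid = maps[0].grid
    pool: dict[tuple[str | None, TissueClass], list[np.ndarray]] = {}
    for m in maps:
        flat = _resample_rows(m.grid, m.flat_intensities(), grid)
        prepped = preprocess_qm_batch(grid, flat, cfg)
        if train_fraction < 1.0:
            idx = rng.permutation(m.n_spectra)[: int(round(train_fraction * m.n_spectra))]
            prepped = prepped[idx]
        pool.setdefault((m.meta.patient_id, m.meta.tissue_class), []).append(prepped)
    refs = []
    for (patient, tissue), chunks in pool.items():
        mean = np.vstack(chunks).mean(axis=0)
        mean /= mean.max()
        ref = Spectrum(grid, mean, SpectrumMeta(tissue_class=tissue, patient_id=patient,
                                                normalized=True, baseline_corrected=True))
        refs.append(extract_threshold_features(ref))
    return refs
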