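"""Spectrum and raster-map containers with file I/O, resampling, averaging and tiling.

A :class:`Spectrum` is one wavenumber-indexed intensity trace; a
:class:`SpectralMap` is a rectangular raster of spectra sharing one wavenumber
grid (the instrument scans a 100 µm × 100 µm area as 51 × 51 spots, i.e. 2601
spectra per map).  File formats are deliberately plain text: two-column ASCII
or CSV for single spectra, long-format CSV (``row,col,wavenumber_cm1,intensity``)
for maps, and a ``map_id,patient_id,tissue_class`` sidecar CSV for labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateWavenumberError,
    GridMismatchError,
    IncompleteMapError,
    OutOfRangeError,
    SpectrumParseError,
)

#: tolerance (cm⁻¹) within which two wavenumber grids count as identical
GRID_TOL = 1e-6

CSV_HEADER = "wavenumber_cm1,intensity"


class TissueClass(str, enum.Enum):
    """The four tissue types distinguished by the classifiers."""

    TUMOR = "tumor"
    MUSCLE = "muscle"
    DERMIS = "dermis"
    FAT = "fat"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical class ordering used for confusion matrices and tie-breaking
CLASS_ORDER = (TissueClass.TUMOR, TissueClass.MUSCLE, TissueClass.DERMIS, TissueClass.FAT)


@dataclass
class SpectrumMeta:
    """Provenance and preprocessing state attached to a spectrum."""

    tissue_class: TissueClass | None = None
    patient_id: str | None = None
    grid_pos: tuple[int, int] | None = None
    baseline_corrected: bool = False
    normalized: bool = False
    smoothed: bool = False
    thresholded: bool = False
    sorted_on_read: bool = False


@dataclass
class Spectrum:
    """One Raman spectrum: intensity (a.u.) versus wavenumber (cm⁻¹).

    Wavenumbers must be strictly increasing and intensities the same length.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError("wavenumbers and intensities differ in length")
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise DuplicateWavenumberError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with new intensities and updated meta flags."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        replace(self.meta, **meta_updates))


@dataclass
class MapMeta:
    tissue_class: TissueClass | None = None
    patient_id: str | None = None
    map_id: str | None = None
    extent_um: float | None = 100.0


@dataclass
class SpectralMap:
    """Raster of spectra on one shared wavenumber grid.

    Intensities are stored as one ``(n_rows, n_cols, n_points)`` array; use
    :meth:`spectrum` to materialise a single spot as a :class:`Spectrum`.
    """

    grid: np.ndarray
    intensities: np.ndarray  # (n_rows, n_cols, n_points)
    meta: MapMeta = field(default_factory=MapMeta)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (n_rows, n_cols, n_points)")
        if self.intensities.shape[2] != len(self.grid):
            raise GridMismatchError("map intensities do not match grid length")
        if not np.all(np.diff(self.grid) > 0):
            raise DuplicateWavenumberError("grid must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_spectra(self) -> int:
        return self.n_rows * self.n_cols

    def spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(
            self.grid,
            self.intensities[row, col],
            SpectrumMeta(tissue_class=self.meta.tissue_class,
                         patient_id=self.meta.patient_id, grid_pos=(row, col)),
        )

    def iter_spectra(self) -> Iterator[Spectrum]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield self.spectrum(r, c)

    def flat_intensities(self) -> np.ndarray:
        """All spectra as a ``(n_spectra, n_points)`` array (row-major spot order)."""
        return self.intensities.reshape(self.n_spectra, len(self.grid))


def grids_equal(a: np.ndarray, b: np.ndarray, tol: float = GRID_TOL) -> bool:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return a.shape == b.shape and bool(np.all(np.abs(a - b) <= tol))


def _require_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if not grids_equal(a, b):
        raise GridMismatchError("wavenumber grids differ")


# ---------------------------------------------------------------------------
# single-spectrum I/O
# ---------------------------------------------------------------------------

def read_spectrum(path, dialect: str = "auto") -> Spectrum:
    """Read a two-column spectrum file.

    ``dialect`` is ``"two_column_ascii"`` (whitespace separated), ``"csv"``
    (header ``wavenumber_cm1,intensity``) or ``"auto"`` (sniffed from content).
    Rows are sorted by wavenumber if needed (recorded in
    ``meta.sorted_on_read``); duplicated wavenumbers are an error.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    wn: list[float] = []
    it: list[float] = []
    sep = None
    if dialect == "csv" or (dialect == "auto" and text and "," in text[0]):
        sep = ","
    for line_no, line in enumerate(text, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(sep)
        if line_no == 1 and sep == "," and parts[0].lower().startswith("wavenumber"):
            continue
        if len(parts) < 2:
            raise SpectrumParseError(path, line_no, f"expected two columns, got {len(parts)}")
        try:
            wn.append(float(parts[0]))
            it.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(path, line_no, f"non-numeric value: {exc}") from None
    wn_arr = np.asarray(wn)
    it_arr = np.asarray(it)
    sorted_flag = False
    if not np.all(np.diff(wn_arr) > 0):
        order = np.argsort(wn_arr, kind="stable")
        wn_arr, it_arr = wn_arr[order], it_arr[order]
        sorted_flag = True
        if np.any(np.diff(wn_arr) <= 0):
            raise DuplicateWavenumberError(f"{path}: duplicate wavenumbers after sorting")
    return Spectrum(wn_arr, it_arr, SpectrumMeta(sorted_on_read=sorted_flag))


def write_spectrum(s: Spectrum, path, dialect: str = "csv") -> None:
    """Write a spectrum so that :func:`read_spectrum` round-trips to 9 significant digits."""
    path = Path(path)
    sep = "," if dialect == "csv" else " "
    lines = []
    if dialect == "csv":
        lines.append(CSV_HEADER)
    for w, i in zip(s.wavenumbers, s.intensities):
        lines.append(f"{w:.12g}{sep}{i:.12g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# map I/O  (long-format CSV: row,col,wavenumber_cm1,intensity; 0-based indices)
# ---------------------------------------------------------------------------

def read_map(path) -> SpectralMap:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    expected = ["row", "col", "wavenumber_cm1", "intensity"]
    if list(df.columns) != expected:
        raise SpectrumParseError(path, 1, f"expected header {expected}, got {list(df.columns)}")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    first = df[(df["row"] == 0) & (df["col"] == 0)]
    if first.empty:
        raise IncompleteMapError([(0, 0)])
    grid = np.sort(first["wavenumber_cm1"].to_numpy(float))
    n_pts = len(grid)

    counts = df.groupby(["row", "col"]).size()
    missing = [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if (r, c) not in counts.index
    ]
    if missing:
        raise IncompleteMapError(missing)

    intens = np.empty((n_rows, n_cols, n_pts))
    for (r, c), cell in df.groupby(["row", "col"]):
        order = np.argsort(cell["wavenumber_cm1"].to_numpy(float))
        cell_grid = cell["wavenumber_cm1"].to_numpy(float)[order]
        if len(cell_grid) != n_pts or not grids_equal(cell_grid, grid):
            raise GridMismatchError(f"cell ({r},{c}) grid differs from cell (0,0)")
        intens[r, c] = cell["intensity"].to_numpy(float)[order]
    return SpectralMap(grid, intens)


def write_map(m: SpectralMap, path) -> None:
    path = Path(path)
    n_pts = len(m.grid)
    rows = np.repeat(np.arange(m.n_rows), m.n_cols * n_pts)
    cols = np.tile(np.repeat(np.arange(m.n_cols), n_pts), m.n_rows)
    wns = np.tile(m.grid, m.n_spectra)
    with open(path, "w") as fh:
        fh.write("row,col,wavenumber_cm1,intensity\n")
        flat = m.intensities.reshape(-1)
        for r, c, w, i in zip(rows, cols, wns, flat):
            fh.write(f"{r},{c},{w:.12g},{i:.12g}\n")


def read_labels(path) -> pd.DataFrame:
    """Read the ``map_id,patient_id,tissue_class`` sidecar CSV."""
    df = pd.read_csv(path, dtype=str)
    df["tissue_class"] = df["tissue_class"].map(TissueClass)
    return df


def write_labels(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["tissue_class"] = out["tissue_class"].map(
        lambda c: c.value if isinstance(c, TissueClass) else str(c))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------

def resample_to_grid(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Extrapolation is refused: every requested wavenumber must lie inside the
    measured range.  Metadata is preserved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < s.wavenumbers[0] - GRID_TOL or grid.max() > s.wavenumbers[-1] + GRID_TOL:
        raise OutOfRangeError(
            f"requested grid [{grid.min():g}, {grid.max():g}] exceeds measured "
            f"range [{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}]")
    vals = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, vals, replace(s.meta))


def common_grid(spectra: Iterable[Spectrum], step: float | None = None) -> np.ndarray:
    """Largest regular grid contained in every spectrum's measured range.

    ``step`` defaults to the median spacing of the first spectrum.  Use with
    :func:`resample_to_grid` before operations that require identical grids.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if hi <= lo:
        raise OutOfRangeError("spectra have no overlapping wavenumber range")
    if step is None:
        step = float(np.median(np.diff(spectra[0].wavenumbers)))
    n = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def average_spectra(spectra: Iterable[Spectrum]) -> Spectrum:
    """Point-wise arithmetic mean of spectra on one shared grid.

    The tissue-class label is kept only when it is unanimous across inputs.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot average zero spectra")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        _require_same_grid(grid, s.wavenumbers)
    mean = np.mean([s.intensities for s in spectra], axis=0)
    classes = {s.meta.tissue_class for s in spectra}
    patients = {s.meta.patient_id for s in spectra}
    meta = SpectrumMeta(
        tissue_class=classes.pop() if len(classes) == 1 else None,
        patient_id=patients.pop() if len(patients) == 1 else None,
    )
    return Spectrum(grid.copy(), mean, meta)


#: division count → (row tiles, column tiles)
DIVISION_LAYOUT = {2: (2, 1), 4: (2, 2), 9: (3, 3), 16: (4, 4), 25: (5, 5)}


def _axis_splits(n: int, k: int) -> list[tuple[int, int]]:
    """Split ``n`` indices into ``k`` contiguous runs, larger runs first."""
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    bounds = np.cumsum([0] + sizes)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(k)]


def split_map_into_regions(m: SpectralMap, n_divisions: int) -> list[list[Spectrum]]:
    """Tile a raster map into ``n_divisions`` contiguous rectangular regions.

    Supported division counts are 2, 4, 9, 16 and 25 (2 splits along rows only;
    the perfect squares use a square tile layout).  When an axis does not divide
    evenly, tile extents differ by at most one row/column, larger tiles first.
    Returns, per tile, the list of member spectra.
    """
    if n_divisions not in DIVISION_LAYOUT:
        raise ValueError(f"n_divisions must be one of {sorted(DIVISION_LAYOUT)}")
    kr, kc = DIVISION_LAYOUT[n_divisions]
    tiles: list[list[Spectrum]] = []
    for r0, r1 in _axis_splits(m.n_rows, kr):
        for c0, c1 in _axis_splits(m.n_cols, kc):
            tiles.append([m.spectrum(r, c) for r in range(r0, r1) for c in range(c0, c1)])
    return tiles


def split_map_indices(m: SpectralMap, n_divisions: int) -> list[np.ndarray]:
    """Flat spot indices (row-major) for each tile of :func:`split_map_into_regions`."""
    if n_divisions not in DIVISION_LAYOUT:
        raise ValueError(f"n_divisions must be one of {sorted(DIVISION_LAYOUT)}")
    kr, kc = DIVISION_LAYOUT[n_divisions]
    out = []
    for r0, r1 in _axis_splits(m.n_rows, kr):
        for c0, c1 in _axis_splits(m.n_cols, kc):
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            out.append((rr * m.n_cols + cc).ravel())
    return out
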