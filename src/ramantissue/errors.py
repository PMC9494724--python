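"""Exception hierarchy shared across the package."""


class RamanTissueError(Exception):
    """Base class for all package-specific errors."""


class SpectrumParseError(RamanTissueError):
    """A spectrum or map file could not be parsed; carries the offending line."""

    def __init__(self, path, line_no, message):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class DuplicateWavenumberError(RamanTissueError):
    """Wavenumbers are not strictly increasing after sorting (duplicates present)."""


class GridMismatchError(RamanTissueError):
    """Two spectra/tables do not share an identical wavenumber grid."""


class IncompleteMapError(RamanTissueError):
    """A raster map file is missing one or more (row, col) cells."""

    def __init__(self, missing):
        self.missing = list(missing)
        shown = ", ".join(str(t) for t in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"map is missing cells: {shown}{more}")


class OutOfRangeError(RamanTissueError):
    """A requested wavenumber lies outside the measured range (no extrapolation)."""


class DegenerateSpectrumError(RamanTissueError):
    """A spectrum has no usable signal (e.g. non-positive maximum after baseline removal)."""


class UndefinedMetricError(RamanTissueError):
    """A confusion-matrix metric has a zero denominator for the requested class."""
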