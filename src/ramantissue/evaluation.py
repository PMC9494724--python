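"""Confusion-matrix metrics, classifier confidence fusion, and the
spectra-per-region feasibility study.

The canonical confusion-matrix orientation throughout the package is
**rows = actual class, columns = predicted class**.  Published count tables
with the opposite orientation are imported through
:meth:`ConfusionMatrix.from_printed` with an explicit flag.

Confidence fusion combines the accuracies of the two independent
classification routes (quantitative threshold-table matching, accuracy
``P_q``; machine-learning, accuracy ``P_m``) into one likelihood::

    P = 1 - (2 W_q / (W_q + W_m)) (1 - P_q) * (2 W_m / (W_q + W_m)) (1 - P_m)

with contribution weights constrained by ``W_q + W_m = 1``.  At equal weights
this reduces to ``1 - (1 - P_q)(1 - P_m)``.

The feasibility study asks how many neighbouring spot spectra must be
averaged for reliable classification — the question that decides whether a
wide-spot hand-held probe (which optically averages a large area in one
exposure) can replace a slow confocal raster scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .spectra_io import CLASS_ORDER, SpectralMap, Spectrum, TissueClass

# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Class-by-class count table; rows = actual, columns = predicted."""

    counts: np.ndarray
    classes: tuple[TissueClass, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls,
        actual: Sequence[TissueClass],
        predicted: Sequence[TissueClass],
        classes: tuple[TissueClass, ...] = CLASS_ORDER,
    ) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for a, p in zip(actual, predicted, strict=True):
            counts[index[TissueClass(a)], index[TissueClass(p)]] += 1
        return cls(counts, classes)

    @classmethod
    def from_printed(
        cls,
        counts: np.ndarray,
        class_order: Sequence[TissueClass],
        rows_are_actual: bool,
        canonical: tuple[TissueClass, ...] = CLASS_ORDER,
    ) -> "ConfusionMatrix":
        """Import a published count table into the canonical orientation.

        ``class_order`` gives the row/column class labels as printed (the same
        order on both axes); ``rows_are_actual`` states the printed
        orientation.  The result is reordered to ``canonical`` classes with
        rows as actual.
        """
        counts = np.asarray(counts)
        if not rows_are_actual:
            counts = counts.T
        perm = [list(class_order).index(c) for c in canonical]
        return cls(counts[np.ix_(perm, perm)], canonical)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _index(self, c: TissueClass) -> int:
        return self.classes.index(TissueClass(c))

    def accuracy(self, denominator: int | None = None) -> float:
        """Trace over total (or over an explicit ``denominator``).

        The override exists for published tables whose stated test-set size
        differs from the printed cell sum.
        """
        denom = self.total if denominator is None else int(denominator)
        if denom <= 0:
            raise UndefinedMetricError("empty confusion matrix")
        return float(np.trace(self.counts)) / denom

    def sensitivity(self, positive: TissueClass) -> float:
        """True positives over actual positives for the given class."""
        i = self._index(positive)
        actual_pos = self.counts[i, :].sum()
        if actual_pos == 0:
            raise UndefinedMetricError(f"no actual {positive} cases")
        return float(self.counts[i, i]) / float(actual_pos)

    def specificity(self, positive: TissueClass) -> float:
        """True negatives over actual negatives for the given class."""
        i = self._index(positive)
        actual_neg = self.total - self.counts[i, :].sum()
        if actual_neg == 0:
            raise UndefinedMetricError(f"no actual non-{positive} cases")
        false_pos = self.counts[:, i].sum() - self.counts[i, i]
        return float(actual_neg - false_pos) / float(actual_neg)

    def false_positive_rate(self, positive: TissueClass) -> float:
        return 1.0 - self.specificity(positive)

    def false_negative_rate(self, positive: TissueClass) -> float:
        return 1.0 - self.sensitivity(positive)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# orientation: rows=actual, columns=predicted\n")
            fh.write("actual," + ",".join(c.value for c in self.classes) + "\n")
            for c, row in zip(self.classes, self.counts):
                fh.write(c.value + "," + ",".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def read_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, comment="#", index_col=0)
        classes = tuple(TissueClass(c) for c in df.columns)
        return cls(df.to_numpy(dtype=int), classes)


def accuracy(cm: ConfusionMatrix, denominator: int | None = None) -> float:
    return cm.accuracy(denominator)


def sensitivity(cm: ConfusionMatrix, positive: TissueClass) -> float:
    return cm.sensitivity(positive)


def specificity(cm: ConfusionMatrix, positive: TissueClass) -> float:
    return cm.specificity(positive)


# ---------------------------------------------------------------------------
# confidence fusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionWeights:
    """Contribution weights of the two classification routes; must sum to 1."""

    w_q: float = 0.5
    w_m: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_q <= 1.0 and 0.0 <= self.w_m <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_q + self.w_m - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.w_q + self.w_m}")


@dataclass(frozen=True)
class FusionResult:
    p_q: float
    p_m: float
    weights: FusionWeights
    p: float


def fuse_confidence(p_q: float, p_m: float, w: FusionWeights | None = None) -> FusionResult:
    """Combined likelihood that a spectrum is correctly identified.

    Multiplies the weighted error rates of the two independent routes and
    subtracts from one; with equal weights this is ``1 - (1-P_q)(1-P_m)``,
    so redundancy always helps: the fused confidence is at least as large as
    either individual accuracy.
    """
    w = w or FusionWeights()
    if not (0.0 <= p_q <= 1.0 and 0.0 <= p_m <= 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    total = w.w_q + w.w_m
    p = 1.0 - (2.0 * w.w_q / total) * (1.0 - p_q) * (2.0 * w.w_m / total) * (1.0 - p_m)
    if not (0.0 <= p <= 1.0 + 1e-12):
        raise ValueError(f"fused confidence {p} outside [0, 1]")
    return FusionResult(p_q=p_q, p_m=p_m, weights=w, p=min(p, 1.0))


# ---------------------------------------------------------------------------
# feasibility of averaging fewer spectra (hand-held probe study)
# ---------------------------------------------------------------------------


@dataclass
class FeasibilityPoint:
    n_divisions: int
    n_spectra_per_region: int
    qm_accuracy: float
    ml_accuracy: float
    qm_false_positive_rate: float
    qm_false_negative_rate: float
    ml_false_positive_rate: float
    ml_false_negative_rate: float


@dataclass
class FeasibilityCurve:
    """Accuracy and tumor-detection error rates versus spectra averaged per region."""

    points: list[FeasibilityPoint] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def feasibility_curve(
    maps: Sequence[SpectralMap],
    references,
    ml_model,
    preprocess_cfg=None,
    divisions: Sequence[int] = (1, 2, 4, 9, 16, 25),
    positive: TissueClass = TissueClass.TUMOR,
) -> FeasibilityCurve:
    """Classify per-region average spectra for successively finer map tilings.

    For each division count, every labelled map is tiled into contiguous
    rectangles, each tile's preprocessed spectra are averaged into a single
    spectrum, and that average is classified by both the threshold-table
    method (against ``references``) and the neural model ``ml_model``.
    Division count 1 means the whole map.  Tumor-vs-rest false positive and
    false negative rates are recorded per method.
    """
    from .preprocess import (
        PreprocessConfig,
        build_features,
        preprocess_qm_batch,
        als_smooth_batch,
        PeakList,
    )
    from .quantitative import classify_qm, extract_threshold_features
    from .neural import predict
    from .spectra_io import SpectrumMeta, split_map_indices
    from scipy.signal import find_peaks

    cfg = preprocess_cfg or PreprocessConfig()
    if not references:
        raise ValueError("at least one reference table is required")
    ref_grid = references[0].grid

    curve = FeasibilityCurve()
    # preprocess each map once; reuse across division counts
    prepped: list[tuple[SpectralMap, np.ndarray]] = []
    for m in maps:
        if m.meta.tissue_class is None:
            raise ValueError("feasibility requires labelled maps")
        flat = m.flat_intensities()
        if len(m.grid) != len(ref_grid) or np.max(np.abs(m.grid - ref_grid)) > 1e-9:
            # resample onto the reference grid (no extrapolation beyond overlap)
            flat = np.vstack([np.interp(ref_grid, m.grid, row) for row in flat])
        prepped.append((m, preprocess_qm_batch(ref_grid, flat, cfg)))

    for d in divisions:
        actual: list[TissueClass] = []
        qm_pred: list[TissueClass] = []
        ml_pred: list[TissueClass] = []
        sizes: list[int] = []
        for m, P in prepped:
            if d == 1:
                tiles = [np.arange(m.n_spectra)]
            else:
                tiles = split_map_indices(m, d)
            for idx in tiles:
                sizes.append(len(idx))
                mean = P[idx].mean(axis=0)
                mean = mean / mean.max()
                spec = Spectrum(ref_grid, mean,
                                SpectrumMeta(normalized=True, baseline_corrected=True))
                qm_pred.append(classify_qm(spec, references).predicted_class)
                # finish the ML chain on the averaged spectrum
                sm = als_smooth_batch(mean, cfg.als_lambda, cfg.als_p, cfg.als_n_iter)[0]
                sm = sm / sm.max()
                sm[sm < cfg.threshold_tau] = 0.0
                pk, _ = find_peaks(sm, prominence=cfg.peak_min_prominence)
                pk = pk[sm[pk] > 0]
                feats = build_features(PeakList(ref_grid[pk], sm[pk]),
                                       mode=ml_model.spec.kind_mode(),
                                       length=cfg.feature_length)
                probs = predict(ml_model, feats)
                ml_pred.append(CLASS_ORDER[int(np.argmax(probs))])
                actual.append(m.meta.tissue_class)
        qm_cm = ConfusionMatrix.from_predictions(actual, qm_pred)
        ml_cm = ConfusionMatrix.from_predictions(actual, ml_pred)
        curve.points.append(FeasibilityPoint(
            n_divisions=d,
            n_spectra_per_region=int(round(float(np.mean(sizes)))),
            qm_accuracy=qm_cm.accuracy(),
            ml_accuracy=ml_cm.accuracy(),
            qm_false_positive_rate=qm_cm.false_positive_rate(positive),
            qm_false_negative_rate=qm_cm.false_negative_rate(positive),
            ml_false_positive_rate=ml_cm.false_positive_rate(positive),
            ml_false_negative_rate=ml_cm.false_negative_rate(positive),
        ))
    return curve


def format_percent(x: float) -> str:
    """Render a proportion as a percentage with one decimal (round-half-even)."""
    import decimal

    d = decimal.Decimal(x * 100).quantize(decimal.Decimal("0.1"),
                                          rounding=decimal.ROUND_HALF_EVEN)
    return f"{d}%"
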