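"""Published benchmark counts for soft-tissue-sarcoma Raman classification.

These are the printed results of the clinical study this methodology
reproduces: blind-test confusion counts for the quantitative threshold-table
method, for the 1D intensity-vector network (patient-1 test spectra) and for
the 2D wavenumber+intensity network (all patients), plus the study's
acquisition bookkeeping (scanned areas and spectrum counts per patient).
They serve as worked-example inputs for the metric and fusion functions —
no patient spectra are included or required.

Note on orientations: the quantitative-method table was printed with columns
as the actual (blind) class; the network tables are only numerically
consistent with their sensitivity/specificity figures when rows are read as
the actual class, so they are imported that way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix
from .spectra_io import TissueClass

#: quantitative-method blind test: rows = reference (predicted),
#: columns = blind spectra (actual); order tumor, muscle, dermis, fat
QM_BLIND_COUNTS = np.array([
    [14, 1, 2, 0],
    [0, 9, 0, 0],
    [0, 0, 7, 1],
    [1, 2, 1, 9],
])
QM_CLASS_ORDER = (TissueClass.TUMOR, TissueClass.MUSCLE, TissueClass.DERMIS, TissueClass.FAT)

#: 1D network on held-out patient-1 spectra; printed order fat, muscle, dermis, tumor.
#: The stated test-set size was 7000 although the printed cells sum to 6982,
#: so accuracy over this table takes an explicit denominator.
ANN1D_COUNTS = np.array([
    [1108, 98, 342, 4],
    [40, 1126, 209, 176],
    [177, 230, 1722, 195],
    [17, 68, 270, 1200],
])
ANN1D_STATED_TEST_SIZE = 7000

#: 2D network on held-out spectra from all patients; printed order
#: fat, muscle, dermis, tumor; rows read as actual (see module docstring).
CNN2D_COUNTS = np.array([
    [7011, 110, 250, 367],
    [291, 7735, 51, 562],
    [508, 52, 5395, 1898],
    [194, 133, 269, 11230],
])
ML_CLASS_ORDER = (TissueClass.FAT, TissueClass.MUSCLE, TissueClass.DERMIS, TissueClass.TUMOR)

#: reported accuracy of the 2D network on its test spectra (not derivable
#: from the printed counts, whose diagonal/total is ≈0.870)
CNN2D_REPORTED_ACCURACY = 0.858


def qm_blind_confusion() -> ConfusionMatrix:
    """Quantitative-method blind-test counts in canonical rows-as-actual form."""
    return ConfusionMatrix.from_printed(QM_BLIND_COUNTS, QM_CLASS_ORDER,
                                        rows_are_actual=False)


def ann1d_confusion() -> ConfusionMatrix:
    """1D-network test counts (patient 1) in canonical rows-as-actual form."""
    return ConfusionMatrix.from_printed(ANN1D_COUNTS, ML_CLASS_ORDER,
                                        rows_are_actual=True)


def cnn2d_confusion() -> ConfusionMatrix:
    """2D-network test counts (all patients) in canonical rows-as-actual form."""
    return ConfusionMatrix.from_printed(CNN2D_COUNTS, ML_CLASS_ORDER,
                                        rows_are_actual=True)


def scanned_area_summary() -> pd.DataFrame:
    """Scanned areas per patient and tissue plus per-patient spectrum totals."""
    return pd.DataFrame(
        {
            "tumor": [2, 4, 9],
            "muscle": [2, 4, 6],
            "dermis": [3, 0, 7],
            "fat": [2, 4, 4],
            "n_spectra": [23409, 30995, 65780],
        },
        index=["P1", "P2", "P3"],
    )
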