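"""Published reference values for the MPN study cohort.

These are inputs for worked examples and regression tests: the training
cohort class sizes, the reported per-class cross-validated one-vs-rest
AUCs, and the validation table of 13 MPN-NOS bone-marrow biopsies with
per-class classifier scores, the histological reading at the time of
biopsy, and the clinical follow-up outcome.
"""

from __future__ import annotations

import pandas as pd

from .profiles import CLASS_ORDER

__all__ = [
    "CLASS_SIZES",
    "REPORTED_CLASS_AUC",
    "nos_validation_table",
]

#: Training-cohort size per diagnostic class.
CLASS_SIZES: dict[str, int] = {"pre-PMF": 19, "PV": 30, "ET": 39}

#: Reported cross-validated one-vs-rest AUC per class.
REPORTED_CLASS_AUC: dict[str, float] = {"pre-PMF": 0.50, "PV": 0.80, "ET": 0.73}

_NOS_ROWS = [
    # id, reported prediction, score pre-PMF, score PV, score ET,
    # histology at biopsy, clinical follow-up
    ("BMB 103", "PV", 0.13, 0.76, 0.11, "pre-PMF-/PV-LIKE", "PV"),
    ("BMB 114", "ET", 0.30, 0.35, 0.35, "pre-PMF-/ET LIKE", "UNCHANGED (>LDH)"),
    ("BMB 15", "ET", 0.25, 0.29, 0.47, "ET-LIKE", "PV"),
    ("BMB 2", "PV", 0.18, 0.65, 0.16, "pre-PMF-/ET-LIKE", "ET"),
    ("BMB 24", "ET", 0.25, 0.03, 0.72, "pre-PMF-/ET-LIKE", "UNCHANGED (>LDH)"),
    ("BMB 36", "PV", 0.10, 0.82, 0.08, "pre-PMF-/PV-LIKE", "UNCHANGED"),
    ("BMB 40", "PV", 0.18, 0.62, 0.20, "PV-LIKE", "NA"),
    ("BMB 41", "PV", 0.18, 0.58, 0.24, "pre-PMF-/ET-LIKE", "NA"),
    ("BMB 63", "PV", 0.12, 0.76, 0.12, "PV-LIKE", "PV"),
    ("BMB 79", "ET", 0.27, 0.24, 0.49, "ET-LIKE", "ET"),
    ("BMB 93", "ET", 0.22, 0.15, 0.63, "ET-LIKE", "PV"),
    ("BMB 1643", "ET", 0.22, 0.04, 0.74, "ET-LIKE", "PMF"),
    ("BMB 1644", "ET", 0.22, 0.03, 0.75, "ET-LIKE", "ET"),
]


def nos_validation_table() -> pd.DataFrame:
    """The 13-case MPN-NOS validation table as a DataFrame.

    Columns: ``patient_id``, ``reported_prediction``, one score column
    per class in :data:`~mpnmorph.profiles.CLASS_ORDER`, ``histology``
    and ``followup``.
    """
    df = pd.DataFrame(
        _NOS_ROWS,
        columns=[
            "patient_id",
            "reported_prediction",
            *(f"score_{c}" for c in CLASS_ORDER),
            "histology",
            "followup",
        ],
    )
    return df
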