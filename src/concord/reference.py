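"""Published reference values used to validate the summary arithmetic.

These are the category counts, ANOVA-passing totals, and 12-split
classification metrics reported by a large multi-site neuroimaging
comparison of schizophrenia and autism against healthy controls.  They are
stored here as *inputs*: the percentages and cross-split aggregates are
always recomputed at run time through :func:`concord.contrast.summarize_table1`
and :func:`concord.classify.summarize_splits`, never read back from print.

Four printed percentage cells in the source table disagree with their own
printed counts by 0.1 at one-decimal rounding (noted inline); recomputation
from the counts is authoritative here.
"""

from __future__ import annotations

from .contrast import ChangeCategory

__all__ = [
    "REFERENCE_CATEGORY_TABLE",
    "REFERENCE_PRINTED_PERCENTAGES",
    "REFERENCE_SPLIT_METRICS",
]

_C = ChangeCategory

#: per measure family: ANOVA-passing total, category counts, ASD-weaker counts
REFERENCE_CATEGORY_TABLE: dict[str, dict] = {
    "functional_networks": {
        "total": 7293,
        "counts": {
            _C.COMMON_DECREASE: 2592,
            _C.COMMON_INCREASE: 2906,
            _C.SZ_UNIQUE_DECREASE: 1013,
            _C.ASD_UNIQUE_DECREASE: 782,
        },
        "weaker": {_C.COMMON_DECREASE: 2212, _C.COMMON_INCREASE: 2744},
    },
    "fnc": {
        "total": 449,
        "counts": {
            _C.COMMON_DECREASE: 191,
            _C.COMMON_INCREASE: 224,
            _C.SZ_UNIQUE_DECREASE: 17,
            _C.ASD_UNIQUE_DECREASE: 17,
        },
        "weaker": {_C.COMMON_DECREASE: 172, _C.COMMON_INCREASE: 204},
    },
    "fc_aal": {
        "total": 924,
        "counts": {
            _C.COMMON_DECREASE: 401,
            _C.COMMON_INCREASE: 391,
            _C.SZ_UNIQUE_DECREASE: 48,
            _C.ASD_UNIQUE_DECREASE: 84,
        },
        "weaker": {_C.COMMON_DECREASE: 361, _C.COMMON_INCREASE: 377},
    },
    "fc_brainnetome": {
        "total": 720,
        "counts": {
            _C.COMMON_DECREASE: 349,
            _C.COMMON_INCREASE: 215,
            _C.SZ_UNIQUE_DECREASE: 105,
            _C.ASD_UNIQUE_DECREASE: 51,
        },
        "weaker": {_C.COMMON_DECREASE: 321, _C.COMMON_INCREASE: 201},
    },
    "gm_volume": {
        "total": 114060,
        "counts": {
            _C.COMMON_DECREASE: 45898,
            _C.COMMON_INCREASE: 2205,
            _C.SZ_UNIQUE_DECREASE: 65957,
            _C.ASD_UNIQUE_DECREASE: 0,
        },
        "weaker": {_C.COMMON_DECREASE: 45891, _C.COMMON_INCREASE: 903},
    },
    "gm_density": {
        "total": 206738,
        "counts": {
            _C.COMMON_DECREASE: 185750,
            _C.COMMON_INCREASE: 155,
            _C.SZ_UNIQUE_DECREASE: 20833,
            _C.ASD_UNIQUE_DECREASE: 0,
        },
        "weaker": {_C.COMMON_DECREASE: 185724, _C.COMMON_INCREASE: 150},
    },
}

#: percentages as printed in the source table; entries tagged inconsistent=True
#: are off by 0.1 from their own printed counts (source rounding defect)
REFERENCE_PRINTED_PERCENTAGES: dict[str, dict] = {
    "functional_networks": {
        "common_decrease": 35.5,
        "common_increase": 39.9,  # inconsistent: 2906/7293 rounds to 39.8
        "sz_unique_decrease": 13.9,
        "asd_unique_decrease": 10.7,
        "weaker_decrease": 85.3,
        "weaker_increase": 94.4,
    },
    "fnc": {
        "common_decrease": 42.5,
        "common_increase": 49.9,
        "sz_unique_decrease": 3.8,
        "asd_unique_decrease": 3.8,
        "weaker_decrease": 90.1,
        "weaker_increase": 91.2,  # inconsistent: 204/224 rounds to 91.1
    },
    "fc_aal": {
        "common_decrease": 43.4,
        "common_increase": 42.3,
        "sz_unique_decrease": 5.2,
        "asd_unique_decrease": 9.1,
        "weaker_decrease": 90.0,
        "weaker_increase": 96.4,
    },
    "fc_brainnetome": {
        "common_decrease": 48.4,  # inconsistent: 349/720 rounds to 48.5
        "common_increase": 29.9,
        "sz_unique_decrease": 14.6,
        "asd_unique_decrease": 7.1,
        "weaker_decrease": 92.0,
        "weaker_increase": 93.5,
    },
    "gm_volume": {
        "common_decrease": 40.2,
        "common_increase": 2.0,  # inconsistent: 2205/114060 rounds to 1.9
        "sz_unique_decrease": 57.8,
        "asd_unique_decrease": 0.0,
        "weaker_decrease": 100.0,
        "weaker_increase": 41.0,
    },
    "gm_density": {
        "common_decrease": 89.8,
        "common_increase": 0.1,
        "sz_unique_decrease": 10.1,
        "asd_unique_decrease": 0.0,
        "weaker_decrease": 100.0,
        "weaker_increase": 96.8,
    },
}

#: which printed cells the source itself rounds inconsistently with its counts
INCONSISTENT_PRINTED_CELLS = {
    ("functional_networks", "common_increase"),
    ("fnc", "weaker_increase"),
    ("fc_brainnetome", "common_decrease"),
    ("gm_volume", "common_increase"),
}

#: (accuracy, sensitivity, specificity) percent per train/test assignment
REFERENCE_SPLIT_METRICS: list[tuple[float, float, float]] = [
    (75.8, 84.2, 61.0),
    (73.9, 85.3, 58.9),
    (78.1, 80.5, 73.7),
    (67.4, 88.7, 43.1),
    (78.9, 84.7, 70.0),
    (80.0, 90.0, 68.0),
    (77.9, 80.2, 73.9),
    (77.2, 85.4, 65.9),
    (73.1, 76.4, 66.8),
    (70.4, 88.2, 49.1),
    (73.8, 78.1, 66.8),
    (71.7, 77.9, 63.9),
]
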