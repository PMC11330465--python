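"""Published per-type summary statistics of the 17 breath-cycle parameters.

Means and SDs of the respiratory parameters observed in bedside recordings
of adult ICU patients ventilated in BiPAP mode through a single-limb leak
circuit, broken down by CO2-movement cycle type (I/II/III).  They are used
as inputs: to parameterize :func:`capnotype.simulate.sample_feature_table`
and as realistic class sizes for statistics/classifier evaluation.  They
are not reproduced by this package's own computations (that would require
the original per-cycle recordings).
"""

from __future__ import annotations

import numpy as np

from .simulate import ClassStats

#: the 16 numeric per-cycle parameters, in the feature-table column order
REFERENCE_FEATURES = [
    "insp_co2_volume",
    "insp_max_pressure_pat",
    "insp_time",
    "exp_time",
    "insp_pressure_integral_pat",
    "exp_pressure_integral_pat",
    "insp_vt_pat",
    "exp_vt_pat",
    "insp_vt_vent",
    "exp_vt_vent",
    "insp_max_flow_pat",
    "exp_max_flow_pat",
    "insp_max_flow_vent",
    "exp_max_flow_vent",
    "breath_frequency",
    "peep",
]

# mean, SD per type, rows aligned with REFERENCE_FEATURES
_TYPE_I = [
    (0.48, 0.25), (24, 5.4), (1.0, 0.8), (1.2, 0.5), (16.4, 7.9), (12, 5),
    (394, 238), (252, 87), (825, 472), (-69, 83.6), (683, 223), (385, 106),
    (1215, 296), (106, 76), (31, 8.2), (10.1, 1.4),
]
_TYPE_II = [
    (0.39, 0.31), (26.3, 4.6), (1.1, 0.4), (1.7, 0.7), (22.6, 6.5), (17.4, 7),
    (590, 200), (537, 165), (1141, 347), (81.5, 94.7), (799, 114), (617, 99),
    (1394, 171), (341, 91), (24, 8), (10.4, 1.3),
]
_TYPE_III = [
    (4.92, 4.88), (14.4, 3.5), (1.2, 0.5), (1.5, 0.6), (12.6, 5.3), (9.7, 3.9),
    (610, 283), (594, 270), (1027, 435), (307, 191), (703, 116), (575, 81),
    (1108, 137), (387, 84), (25, 6.1), (6.6, 0.3),
]

#: number of analyzed cycles per type in the reference data set
REFERENCE_CLASS_SIZES = {"I": 1849, "II": 1545, "III": 1353}

#: invasive / noninvasive split of cycles per type in the reference data set
REFERENCE_INTERFACE_COUNTS = {
    "I": (1196, 653),
    "II": (1026, 519),
    "III": (1002, 351),
}

#: number of patients contributing analyzed cycles
REFERENCE_N_PATIENTS = 16


def reference_class_stats() -> ClassStats:
    """The published per-type means/SDs packaged for the feature sampler."""
    table = {"I": _TYPE_I, "II": _TYPE_II, "III": _TYPE_III}
    means = {t: np.array([m for m, _ in rows]) for t, rows in table.items()}
    sds = {t: np.array([s for _, s in rows]) for t, rows in table.items()}
    invasive_p = {
        t: inv / (inv + noninv)
        for t, (inv, noninv) in REFERENCE_INTERFACE_COUNTS.items()
    }
    return ClassStats(features=list(REFERENCE_FEATURES), means=means,
                      sds=sds, invasive_p=invasive_p)
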