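"""Published summary tables of the reference clinical cohort (287 trotting horses).

The clinical recordings themselves are not publicly deposited; what is public
are the cohort's summary tables: the per-class sample sizes, the distribution
of visual lameness grades (11-point UK-style scale) among the lame horses, and
the five-class confusion matrix of the fitted support-vector classifier.
These constants make the derived statistics (per-class accuracies, overall
accuracy, mean grades) recomputable offline and serve as worked examples for
the reporting code.

Class order is fixed throughout the package: RF, LF, RH, LH, SOUND
(right fore, left fore, right hind, left hind, sound).
"""

from __future__ import annotations

CLASS_ORDER: tuple[str, ...] = ("RF", "LF", "RH", "LH", "SOUND")

#: number of horses per class in the reference cohort (total 287)
REFERENCE_CLASS_COUNTS: dict[str, int] = {
    "RF": 92,
    "LF": 89,
    "RH": 39,
    "LH": 36,
    "SOUND": 31,
}

#: grades covered by the lame-horse inclusion range (2/10 .. 7/10 inclusive)
GRADE_RANGE: tuple[int, ...] = (2, 3, 4, 5, 6, 7)

#: per-class counts of lameness grades 2..7 among the 256 lame horses
REFERENCE_GRADE_COUNTS: dict[str, tuple[int, ...]] = {
    "LF": (53, 13, 13, 5, 3, 2),
    "RF": (51, 12, 23, 4, 2, 0),
    "LH": (13, 8, 8, 1, 6, 0),
    "RH": (18, 4, 14, 1, 2, 0),
}

#: five-class confusion matrix of the reference classifier
#: rows = actual class, columns = predicted class, order = CLASS_ORDER
REFERENCE_CONFUSION_COUNTS: tuple[tuple[int, ...], ...] = (
    (86, 0, 0, 2, 4),    # RF lame
    (0, 81, 1, 1, 6),    # LF lame
    (5, 4, 30, 0, 0),    # RH lame
    (1, 2, 0, 33, 0),    # LH lame
    (6, 6, 1, 1, 17),    # sound
)

#: printed headline statistics of the reference cohort, used by the
#: ``reference-checks`` CLI command to verify the reporting code end to end
REFERENCE_PRINTED = {
    "overall_accuracy_pct": 86,          # rounded to integer percent
    "per_class_accuracy_pct": {          # one decimal
        "RF": 93.5,
        "LF": 91.0,
        "RH": 76.9,
        "LH": 91.7,
        "SOUND": 54.8,
    },
    "rh_predicted_rf_pct": 12.8,
    "mean_grade": {"LF": 2.9, "RF": 2.8, "LH": 3.4, "RH": 3.1},  # one decimal
    "sd_grade": {"LF": 1.3, "RF": 1.1, "LH": 1.4, "RH": 1.2},
}
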