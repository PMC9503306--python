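"""Published cohort summary statistics used as arithmetic anchors.

These are the reported per-arm means (± SD) of the four choriocapillaris
flow-deficit biomarkers on a 6 x 6 mm macular field, for the three study
arms of the hydroxychloroquine cohort this pipeline reproduces:

* ``1a`` — eyes under hydroxychloroquine without retinal toxicity,
* ``1b`` — eyes with hydroxychloroquine toxic retinopathy,
* ``2``  — healthy-control eyes.

FD% and total FD area are redundant on a fixed field (area = FD%/100 x
36 mm^2), which gives a self-consistency check on the published table.
The check holds to < 0.01 mm^2 for arms 1b and 2 at both radii; the arm
1a pairs are mutually inconsistent (a transcription artefact in the
source table), so only 1b and 2 serve as anchors.
"""

from __future__ import annotations

FIELD_AREA_MM2 = 36.0  # 6 x 6 mm macular field

#: (mean, sd) per radius -> arm -> metric.
REPORTED_SUMMARY: dict[int, dict[str, dict[str, tuple[float, float]]]] = {
    4: {
        "1a": {
            "fd_percent": (36.76, 1.42),
            "fd_mean_size_um2": (975.13, 117.83),
            "fd_total_area_mm2": (14.70, 1.29),
            "fd_count": (13639.5, 1120.76),
        },
        "1b": {
            "fd_percent": (48.96, 7.63),
            "fd_mean_size_um2": (9415.08, 14453.98),
            "fd_total_area_mm2": (17.62, 2.74),
            "fd_count": (5221.14, 4123.72),
        },
        "2": {
            "fd_percent": (45.61, 3.98),
            "fd_mean_size_um2": (3321.92, 1942.51),
            "fd_total_area_mm2": (16.42, 1.43),
            "fd_count": (7085.5, 2965.60),
        },
    },
    8: {
        "1a": {
            "fd_percent": (41.47, 1.40),
            "fd_mean_size_um2": (1157.83, 140.24),
            "fd_total_area_mm2": (13.50, 0.50),
            "fd_count": (11721.0, 982.87),
        },
        "1b": {
            "fd_percent": (49.41, 7.42),
            "fd_mean_size_um2": (8279.53, 10091.57),
            "fd_total_area_mm2": (17.78, 2.67),
            "fd_count": (4719.85, 3405.69),
        },
        "2": {
            "fd_percent": (46.07, 1.40),
            "fd_mean_size_um2": (3551.65, 1895.34),
            "fd_total_area_mm2": (16.58, 1.39),
            "fd_count": (5324.0, 2449.41),
        },
    },
}

#: (radius, arm) pairs whose FD% and total-area entries are mutually
#: consistent and therefore usable as arithmetic anchors.
CONSISTENCY_ANCHORS: tuple[tuple[int, str], ...] = (
    (4, "1b"), (4, "2"), (8, "1b"), (8, "2"),
)


def area_consistency_error_mm2(radius: int, arm: str) -> float:
    """|reported FD% x field area / 100 - reported total area| in mm^2."""
    entry = REPORTED_SUMMARY[radius][arm]
    implied = entry["fd_percent"][0] / 100.0 * FIELD_AREA_MM2
    return abs(implied - entry["fd_total_area_mm2"][0])
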