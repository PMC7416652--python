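"""Bundled example data: a boa strike-trial table and its capture log.

A high-speed capture study of amazon tree boa (*Corallus hortulanus*)
strikes — five 750 Hz cameras at 640×480 px — recorded 20 strike
captures, 15 of which could be fully processed into 3D tracking data.
The per-trial kinematics of those 15 strikes, and the quality log of all
20 captures, are bundled here as a worked example for the aggregation
utilities and as a regression reference.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["strike_trials", "capture_log", "select_processable"]

# trial, subject, duration (s), path distance (m), mean speed (m/s),
# max velocity (m/s) — strike window from initial forward movement until
# start of head retraction
_TRIALS = [
    (1, "Y4", 0.0866458717, 0.0958, 1.1055, 1.6393),
    (2, "Y4", 0.1359673678, 0.1731, 1.2732, 1.8036),
    (3, "Y4", 0.1506305153, 0.2136, 1.4182, 1.9968),
    (4, "Y4", 0.0786477912, 0.0829, 1.0542, 1.8137),
    (5, "Y2", 0.1146391533, 0.1461, 1.2743, 1.6408),
    (6, "Y2", 0.1066410728, 0.2192, 2.0556, 2.3136),
    (7, "Y2", 0.1306353142, 0.1472, 1.1270, 2.1715),
    (8, "Y2", 0.1426324349, 0.1567, 1.0984, 1.6513),
    (9, "Y2", 0.1652936629, 0.1419, 0.8583, 1.2661),
    (10, "Y2", 0.1986189981, 0.1573, 0.7920, 1.3873),
    (12, "B5", 0.1959529713, 0.1901, 0.9700, 1.4633),
    (13, "B5", 0.1746247567, 0.1695, 0.9705, 1.3763),
    (15, "B5", 0.1093070996, 0.0968, 0.8854, 1.4035),
    (17, "B5", 0.1479644885, 0.1462, 0.9878, 1.3030),
    (18, "B5", 0.155962569, 0.1468, 0.9411, 1.3333),
]

# capture quality flags for all 20 recorded strikes:
#   complete_images  — a consistent image set from all five cameras
#   standard_target  — strike elicited with the IR emitter (not the strong
#                      heat element whose visible light defeats thresholding)
#   standard_subject — one of the study-sized snakes (not the smaller one)
_CAPTURES = [
    # (trial, complete_images, standard_target, standard_subject)
    (1, True, True, True),
    (2, True, True, True),
    (3, True, True, True),
    (4, True, True, True),
    (5, True, True, True),
    (6, True, True, True),
    (7, True, True, True),
    (8, True, True, True),
    (9, True, True, True),
    (10, True, True, True),
    (11, False, True, True),   # partially missing data from one camera
    (12, True, True, True),
    (13, True, True, True),
    (14, True, False, True),   # heat-element target produced visible light
    (15, True, True, True),
    (16, True, False, True),   # heat-element target produced visible light
    (17, True, True, True),
    (18, True, True, True),
    (19, True, True, False),   # smaller snake
    (20, True, True, False),   # smaller snake
]


def strike_trials() -> pd.DataFrame:
    """The 15 fully processed strike trials with their kinematics."""
    return pd.DataFrame(
        _TRIALS,
        columns=["trial", "subject", "duration_s", "distance_m", "speed_ms",
                 "max_velocity_ms"],
    )


def capture_log() -> pd.DataFrame:
    """Quality log of all 20 recorded strike captures."""
    return pd.DataFrame(
        _CAPTURES,
        columns=["trial", "complete_images", "standard_target",
                 "standard_subject"],
    )


def select_processable(log: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply the capture exclusion rules; returns the usable captures.

    A capture is processable only if its image set is complete, the strike
    was elicited with the standard IR target, and the subject was one of
    the study-sized snakes.
    """
    if log is None:
        log = capture_log()
    ok = (log["complete_images"] & log["standard_target"]
          & log["standard_subject"])
    return log[ok].reset_index(drop=True)
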