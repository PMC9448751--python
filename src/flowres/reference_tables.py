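"""Published reference measurements used as worked-example inputs.

These are the value columns of a published four-resolution thoracic-aorta
comparison between 4D-flow MRI measurements and the CFD model driven by
them: inlet-plane equivalent diameters, phase-averaged maximum and mean
velocity magnitudes at the inlet and mid-ascending planes, and the derived
columns the source prints alongside them (symmetric percent differences and
mean +/- SD summaries).

Values are stored as the printed strings so that downstream checks can
propagate the precision actually printed (half a unit in the last decimal
place).  Use :func:`as_float` / :func:`half_ulp` to consume them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RESOLUTIONS_MM",
    "INLET_DIAMETER_CM",
    "VELOCITY_TABLES",
    "PRINTED_SUMMARIES",
    "as_float",
    "half_ulp",
]

#: Isotropic scan voxel sizes, coarse to fine.
RESOLUTIONS_MM = (4.0, 3.0, 2.0, 1.5)

#: Inlet-plane equivalent diameters (cm) per resolution, per method.
INLET_DIAMETER_CM = {
    "mri": ("2.659", "2.569", "2.499", "2.478"),
    "cfd": ("2.658", "2.555", "2.491", "2.474"),
}

#: Phase-averaged velocity magnitudes (m/s) per resolution: measured (mri)
#: and model (cfd) maxima and plane means, with the printed percent
#: differences between the two methods.
VELOCITY_TABLES = {
    ("inlet", "systole"): {
        "mri_umax": ("1.018", "0.8052", "0.7986", "0.7997"),
        "mri_umean": ("0.2838", "0.3745", "0.4683", "0.4835"),
        "cfd_umax": ("0.9988", "0.8209", "0.8010", "0.8089"),
        "cfd_umean": ("0.3589", "0.4511", "0.5333", "0.5248"),
        "printed_pct_diff_umax": ("1.904", "1.931", "0.3001", "1.144"),
        "printed_pct_diff_umean": ("23.37", "18.56", "12.98", "8.192"),
    },
    ("inlet", "diastole"): {
        "mri_umax": ("0.1038", "0.09520", "0.09600", "0.1087"),
        "mri_umean": ("0.03710", "0.04420", "0.05520", "0.06010"),
        "cfd_umax": ("0.08940", "0.09540", "0.1020", "0.1127"),
        "cfd_umean": ("0.04660", "0.05480", "0.06300", "0.06400"),
        "printed_pct_diff_umax": ("14.91", "0.2099", "6.061", "3.613"),
        "printed_pct_diff_umean": ("22.70", "21.41", "13.20", "6.285"),
    },
    ("mid_vessel", "systole"): {
        "mri_umax": ("0.6272", "0.6941", "0.7891", "0.7659"),
        "mri_umean": ("0.2646", "0.3958", "0.4707", "0.4910"),
        "cfd_umax": ("0.9358", "0.8436", "0.9096", "0.9019"),
        "cfd_umean": ("0.3396", "0.4016", "0.4777", "0.4289"),
        "printed_pct_diff_umax": ("39.49", "19.44", "14.19", "16.31"),
        "printed_pct_diff_umean": ("24.85", "1.476", "1.476", "13.49"),
    },
    ("mid_vessel", "diastole"): {
        "mri_umax": ("0.06131", "0.07451", "0.09052", "0.1177"),
        "mri_umean": ("0.02599", "0.02902", "0.03700", "0.04063"),
        "cfd_umax": ("0.1099", "0.09438", "0.09466", "0.1221"),
        "cfd_umean": ("0.04859", "0.05193", "0.05067", "0.06024"),
        "printed_pct_diff_umax": ("56.76", "23.53", "4.471", "3.670"),
        "printed_pct_diff_umean": ("60.59", "56.61", "31.18", "38.88"),
    },
}

#: Printed mean +/- sample-SD summaries over the four resolutions,
#: keyed by (table, phase or None, column).
PRINTED_SUMMARIES = {
    ("inlet_diameter", None, "mri"): ("2.551", "0.08186"),
    ("inlet_diameter", None, "cfd"): ("2.544", "0.08346"),
    ("inlet", "systole", "mri_umax"): ("0.8554", "0.1085"),
    ("inlet", "systole", "cfd_umax"): ("0.8574", "0.09462"),
    ("inlet", "diastole", "mri_umax"): ("0.1009", "0.006474"),
    ("inlet", "diastole", "cfd_umax"): ("0.09988", "0.009979"),
    ("mid_vessel", "systole", "mri_umean"): ("0.4055", "0.1025"),
    ("mid_vessel", "systole", "cfd_umean"): ("0.4120", "0.05758"),
    ("mid_vessel", "diastole", "mri_umean"): ("0.03316", "0.006809"),
    ("mid_vessel", "diastole", "cfd_umean"): ("0.05286", "0.005113"),
}


def as_float(values) -> np.ndarray:
    """Convert printed-string cells to a float array."""
    if isinstance(values, str):
        return np.array(float(values))
    return np.array([float(v) for v in values])


def half_ulp(printed: str) -> float:
    """Half a unit in the last printed decimal place of a table cell."""
    printed = printed.strip()
    if "." not in printed:
        return 0.5
    return 0.5 * 10.0 ** -(len(printed.split(".")[1]))
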