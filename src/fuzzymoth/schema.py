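"""Record-table schema and declared feature ranges.

One row of a record table is one 200 ms time step of one moth:

``id, t`` — moth identifier and time-step index;
``s01..s32`` — UV stimulus: for each of the four lamps (left UVA, left UVB,
right UVA, right UVB) the light intensity, exposure duration, pattern-moving
velocity (x, y, z) and pattern-moving distance (x, y, z);
``a01..a34`` — ambient conditions: temperature, humidity, atmospheric
pressure, O2, CO2, horizontal and vertical wind speed (m/s), then duration,
intensity and illuminance for nine wavelength bands (UVA, UVB, UVC, violet,
indigo, blue, yellow, green, orange);
``p1..p7`` — the seven flight parameters at the previous step;
``c1..c7`` — the seven parameters accumulated over the previous three steps;
``y1..y7`` — the target flight parameters at this step.

All features are stored normalised to [0, 1] except the two wind speeds,
stored in m/s with a hard cap of 1.5 m/s (stronger wind makes the flight
path uncontrollable and such records are rejected).
"""

from __future__ import annotations

import numpy as np

N_STIMULUS = 32
N_AMBIENT = 34
N_PREV = 7
N_ACCUM = 7
N_FLIGHT = 7
N_FEATURES = N_STIMULUS + N_AMBIENT + N_PREV + N_ACCUM   # 80

#: maximum controllable ambient wind speed, m/s
WIND_CAP = 1.5

#: indices of the horizontal/vertical wind speed inside the ambient block
WIND_IDX = (5, 6)

FLIGHT_PARAM_NAMES = ("theta_h", "omega_h", "theta_v", "omega_v",
                      "a_x", "a_y", "a_z")

#: per-lamp stimulus sub-block layout (8 variables per lamp, 4 lamps)
LAMP_NAMES = ("left_uva", "left_uvb", "right_uva", "right_uvb")
LAMP_BLOCK = ("intensity", "duration", "vx", "vy", "vz", "dx", "dy", "dz")

STIM_COLS = [f"s{i+1:02d}" for i in range(N_STIMULUS)]
AMB_COLS = [f"a{i+1:02d}" for i in range(N_AMBIENT)]
PREV_COLS = [f"p{i+1}" for i in range(N_PREV)]
ACCUM_COLS = [f"c{i+1}" for i in range(N_ACCUM)]
TARGET_COLS = [f"y{i+1}" for i in range(N_FLIGHT)]

RECORD_COLUMNS = ["id", "t"] + STIM_COLS + AMB_COLS + PREV_COLS \
    + ACCUM_COLS + TARGET_COLS

#: (low, high) raw range per ambient feature; winds are physical m/s
AMBIENT_RANGES = np.ones((N_AMBIENT, 2)) * np.array([0.0, 1.0])
AMBIENT_RANGES[WIND_IDX[0]] = (0.0, WIND_CAP)
AMBIENT_RANGES[WIND_IDX[1]] = (0.0, WIND_CAP)


def normalize_ambient(ambient: np.ndarray) -> np.ndarray:
    """Min-max normalise raw ambient features to [0, 1] by the declared
    ranges; raises if a wind speed exceeds the 1.5 m/s cap."""
    ambient = np.asarray(ambient, dtype=float)
    wind = ambient[..., list(WIND_IDX)]
    if np.any(wind > WIND_CAP + 1e-9):
        raise ValueError(
            f"ambient wind speed {float(wind.max()):.3g} m/s exceeds the "
            f"{WIND_CAP} m/s controllability cap")
    lo, hi = AMBIENT_RANGES[:, 0], AMBIENT_RANGES[:, 1]
    out = (ambient - lo) / (hi - lo)
    if np.any((out < -1e-9) | (out > 1 + 1e-9)):
        raise ValueError("ambient feature outside its declared range")
    return np.clip(out, 0.0, 1.0)


def denormalize_ambient(ambient01: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_ambient`."""
    lo, hi = AMBIENT_RANGES[:, 0], AMBIENT_RANGES[:, 1]
    return lo + np.asarray(ambient01, dtype=float) * (hi - lo)
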