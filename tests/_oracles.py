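"""Independent exhaustive-scan oracles for the kinematic features.

Deliberately written as plain Python loops from the feature definitions, with
no shared code with the package, so the vectorized implementations can be
checked against them.
"""

import math


def oracle_magnitude(positions):
    """Max Euclidean distance (mm) from the first frame."""
    x0, y0, z0 = positions[0]
    best = 0.0
    for x, y, z in positions:
        d = math.sqrt((x - x0) ** 2 + (y - y0) ** 2 + (z - z0) ** 2)
        if d > best:
            best = d
    return best * 1000.0


def oracle_lateral(positions, center_x):
    """Max |x - center| (mm)."""
    best = 0.0
    for x, _, _ in positions:
        d = abs(x - center_x)
        if d > best:
            best = d
    return best * 1000.0


def oracle_ap(positions, axis):
    """Max projection onto the interlocutor axis (meters)."""
    best = None
    for p in positions:
        d = p[0] * axis[0] + p[1] * axis[1] + p[2] * axis[2]
        if best is None or d > best:
            best = d
    return best


def oracle_peak_velocity(positions, rate_hz):
    """Max frame-to-frame speed (cm/s)."""
    best = 0.0
    for i in range(1, len(positions)):
        dx = positions[i][0] - positions[i - 1][0]
        dy = positions[i][1] - positions[i - 1][1]
        dz = positions[i][2] - positions[i - 1][2]
        v = math.sqrt(dx * dx + dy * dy + dz * dz) * rate_hz
        if v > best:
            best = v
    return best * 100.0
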