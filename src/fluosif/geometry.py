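"""Viewing geometry of the nadir bare fiber.

The radiance fiber looks straight down with a conical field of view; the
sampled target area on a horizontal surface is a circle whose diameter grows
linearly with the sensor-to-target distance.
"""

from __future__ import annotations

import math

__all__ = ["target_diameter"]


def target_diameter(distance_m: float, fov_deg: float = 25.0) -> float:
    """Diameter (m) of the circular nadir target area.

    d = 2 h tan(FOV/2) for a fiber at height ``distance_m`` above the target
    surface (the canopy top when the crop is grown, the ground when bare).
    """
    if distance_m < 0:
        raise ValueError("distance must be nonnegative")
    if not 0 < fov_deg < 180:
        raise ValueError("field of view must be in (0, 180) degrees")
    return 2.0 * distance_m * math.tan(math.radians(fov_deg / 2.0))
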