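"""Survey-planning arithmetic: altitude, swath, speed, pixels, data volume.

Deterministic relations for a push-broom transect: at 1 m altitude and
20 m/min a 1.28 m swath over 640 spatial pixels gives 0.2 cm lateral pixels,
and a 2 cm frame spacing gives 0.2 x 2 cm ground pixels; a 50 m transect at
2 cm spacing with 640 x 480 16-bit samples per frame is ~1.5 GB.
GB are reported as 10^9 bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SurveyPlan", "plan_summary"]


@dataclass
class SurveyPlan:
    """Transect survey parameterization (all quantities positive).

    altitude (m), swath (m), speed (m/min), frame_spacing (m, along-track
    distance between scan lines), transect_length (m); spatial_pixels and
    bands are the imager's fixed counts, bytes_per_sample the ADC sample size.
    """

    altitude: float = 1.0
    swath: float = 1.28
    speed: float = 20.0
    frame_spacing: float = 0.02
    transect_length: float = 50.0
    spatial_pixels: int = 640
    bands: int = 480
    bytes_per_sample: int = 2

    def __post_init__(self) -> None:
        for name in ("altitude", "swath", "speed", "frame_spacing", "transect_length",
                     "spatial_pixels", "bands", "bytes_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.spatial_pixels != int(self.spatial_pixels) or self.bands != int(self.bands):
            raise ValueError("spatial_pixels and bands must be integral")


def plan_summary(plan: SurveyPlan) -> dict:
    """Derived survey record; volume = data_rate x duration holds identically.

    Keys: lateral_pixel_cm, transverse_pixel_cm, coverage_m2_per_min,
    frame_rate_hz, data_rate_bytes_per_s, transect_volume_bytes,
    transect_volume_gb (10^9 bytes), duration_s.
    """
    speed_m_s = plan.speed / 60.0
    frame_rate = speed_m_s / plan.frame_spacing
    frame_bytes = plan.spatial_pixels * plan.bands * plan.bytes_per_sample
    data_rate = frame_rate * frame_bytes
    duration = plan.transect_length / speed_m_s
    volume = (plan.transect_length / plan.frame_spacing) * frame_bytes
    return {
        "lateral_pixel_cm": 100.0 * plan.swath / plan.spatial_pixels,
        "transverse_pixel_cm": 100.0 * plan.frame_spacing,
        "coverage_m2_per_min": plan.speed * plan.swath,
        "frame_rate_hz": frame_rate,
        "data_rate_bytes_per_s": data_rate,
        "transect_volume_bytes": volume,
        "transect_volume_gb": volume / 1e9,
        "duration_s": duration,
    }
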