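"""Scan-geometry description shared by the phantom generator and the pipeline.

Axis conventions used throughout the package:

* ``z`` — depth, increasing downward from the top of the frame (0-based).
* ``x`` — fast scan axis (A-lines within one B-scan).
* ``y`` — slow scan axis (B-scan positions).

Frame sequences are indexed ``(frame, x, z)``; volumes ``(x, y, z)``;
en-face maps ``(x, y)``.  Thickness is measured along ``z`` only.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel grid and physical pixel scales of one acquisition.

    Defaults emulate an endoscopic probe with a 9 x 9 mm field of view and
    14 um axial resolution in tissue: 256 depth pixels at 14 um, 256 A-lines
    across 9 mm (~35 um lateral), 64 slow-axis positions, and 4 repeated
    frames per position.

    Parameters
    ----------
    n_depth, n_fast, n_slow
        Pixel counts along z, x and y.  Each must be >= 8.
    axial_pixel_um, lateral_pixel_um
        Physical size of one pixel along z and x/y, in micrometres.
    n_repeats
        Repeated B-scans acquired at each slow-axis position (J + 1 frames
        entering the inter-frame variance).  Must be >= 2.
    """

    n_depth: int = 256
    n_fast: int = 256
    n_slow: int = 64
    axial_pixel_um: float = 14.0
    lateral_pixel_um: float = 35.0
    n_repeats: int = 4

    def __post_init__(self) -> None:
        for name in ("n_depth", "n_fast", "n_slow"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8, got {getattr(self, name)}")
        if self.axial_pixel_um <= 0 or self.lateral_pixel_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2 (inter-frame variance needs pairs)")

    @property
    def depth_um(self) -> float:
        """Total imaging depth in micrometres."""
        return self.n_depth * self.axial_pixel_um

    def to_dict(self) -> dict:
        return {
            "n_depth": self.n_depth,
            "n_fast": self.n_fast,
            "n_slow": self.n_slow,
            "axial_pixel_um": self.axial_pixel_um,
            "lateral_pixel_um": self.lateral_pixel_um,
            "n_repeats": self.n_repeats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomGeometry":
        return cls(**{k: d[k] for k in (
            "n_depth", "n_fast", "n_slow",
            "axial_pixel_um", "lateral_pixel_um", "n_repeats")})
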