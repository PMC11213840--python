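"""Acquisition geometry for a step-and-shoot parallel-hole SPECT camera.

The camera rotates around the z (scanner) axis; each projection is a 2-D
count image of size ``matrix = (n_u, n_v)`` where u lies in the transaxial
plane and v coincides with z.  Defaults follow a clinical ^177^Lu protocol:
120 views over 360 deg, 4.42 mm pixels, 30 s per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Parameters of one tomographic acquisition.

    ``psf_sigma0_mm`` and ``psf_slope`` describe the depth-dependent
    collimator-detector response: the Gaussian sigma of the blur applied to
    an emission plane at distance ``d`` from the detector is
    ``psf_sigma0_mm + psf_slope * d``.  The defaults are representative of a
    medium-energy general-purpose collimator at 208 keV, not a measured
    characterisation.
    """

    n_projections: int = 120
    angular_span_deg: float = 360.0
    start_angle_deg: float = 0.0
    matrix: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 4.42
    frame_duration_s: float = 30.0
    rotation_radius_mm: float = 250.0
    psf_sigma0_mm: float = 2.0
    psf_slope: float = 0.04
    sensitivity_cps_per_MBq: float = 10.0

    def __post_init__(self) -> None:
        if self.n_projections < 4 or self.n_projections % 4 != 0:
            raise ValueError(
                "n_projections must be a positive multiple of 4 "
                f"(got {self.n_projections})"
            )
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def angle_step_deg(self) -> float:
        return self.angular_span_deg / self.n_projections

    @property
    def angles_deg(self) -> np.ndarray:
        """Uniformly spaced view angles, strictly increasing."""
        return self.start_angle_deg + self.angle_step_deg * np.arange(
            self.n_projections, dtype=float
        )

    def with_projections(self, n_projections: int) -> "AcquisitionGeometry":
        return replace(self, n_projections=n_projections)
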