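"""Domain types for immunogold-EM localization of NPC components.

Coordinate conventions
----------------------
Every imaged nuclear pore complex (NPC) is mapped into a shared cylindrical
frame: ``x`` runs along the plane of the nuclear envelope (NE) through the
pore axis, ``z`` runs along the pore's cylindrical axis, with the NPC
midplane at ``z = 0`` and the nucleoplasm on the negative side.  The radial
coordinate ``R`` of the cylinder is observed only through its projection
onto ``x`` in thin sections, which is why radial estimation works on
folded ``|x|`` values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "NpcAnnotation",
    "GoldParticleRaw",
    "CommonFrameParticle",
    "SimTruth",
    "ParticleSet",
    "AnalysisConfig",
    "LocalizationEstimate",
    "SYMMETRIC",
    "NUCLEOPLASMIC",
    "CYTOPLASMIC",
    "InsufficientDataError",
    "SchemaError",
]

SYMMETRIC = "symmetric"
NUCLEOPLASMIC = "nucleoplasmic"
CYTOPLASMIC = "cytoplasmic"

#: allowed values for :attr:`NpcAnnotation.nucleoplasm_side`; "down" means the
#: half-plane at negative rotated-y is the nucleoplasm (no reflection needed).
NUCLEOPLASM_SIDES = ("down", "up")


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable cell."""


class InsufficientDataError(ValueError):
    """Too few particles for an estimate; carries the observed count."""

    def __init__(self, message: str, count: int):
        super().__init__(message)
        self.count = count


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class NpcAnnotation:
    """Geometric reference for one imaged pore.

    Encodes everything a montage builder needs from a micrograph in which
    the NPC was sectioned perpendicular to the NE plane: the pore center,
    the direction of the NE plane in image coordinates, which half-plane is
    nucleoplasm, and the pixel size.
    """

    npc_id: str
    micrograph_id: str
    center_px: tuple[float, float]
    ne_axis_angle: float  # radians, direction of the NE plane in the image
    nucleoplasm_side: str  # "down" | "up", relative to the rotated NE frame
    scale_nm_per_px: float
    nup_label: str = ""
    residual_angle: float = 0.0  # optional per-NPC fine-alignment, radians

    def __post_init__(self) -> None:
        _require_finite("center_px[0]", self.center_px[0])
        _require_finite("center_px[1]", self.center_px[1])
        _require_finite("ne_axis_angle", self.ne_axis_angle)
        _require_finite("residual_angle", self.residual_angle)
        if not (math.isfinite(self.scale_nm_per_px) and self.scale_nm_per_px > 0):
            raise ValueError(
                f"scale_nm_per_px must be positive and finite, got {self.scale_nm_per_px!r}"
            )
        if self.nucleoplasm_side not in NUCLEOPLASM_SIDES:
            raise ValueError(
                f"nucleoplasm_side must be one of {NUCLEOPLASM_SIDES}, "
                f"got {self.nucleoplasm_side!r}"
            )


@dataclass(frozen=True)
class GoldParticleRaw:
    """One gold particle in raw image coordinates (pixels)."""

    particle_id: str
    npc_id: str
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        _require_finite("x_px", self.x_px)
        _require_finite("y_px", self.y_px)


@dataclass(frozen=True)
class CommonFrameParticle:
    """One gold particle in the shared NPC frame (nm).

    ``x_nm`` is the signed distance along the NE plane from the pore axis;
    ``z_nm`` the signed distance along the pore axis from the midplane
    (negative = nucleoplasmic).
    """

    particle_id: str
    npc_id: str
    x_nm: float
    z_nm: float

    def __post_init__(self) -> None:
        _require_finite("x_nm", self.x_nm)
        _require_finite("z_nm", self.z_nm)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth attached to simulated datasets."""

    r0_nm: float
    z0_nm: float
    symmetric: bool


@dataclass
class ParticleSet:
    """All common-frame particles for one tagged protein.

    ``n_npcs`` is derived from the particles' provenance, so the invariant
    that it equals the number of distinct pore ids holds by construction.
    """

    nup_label: str
    particles: list[CommonFrameParticle] = field(default_factory=list)
    truth: Optional[SimTruth] = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_npcs(self) -> int:
        return len({p.npc_id for p in self.particles})

    def __len__(self) -> int:
        return len(self.particles)

    def x(self):
        import numpy as np

        return np.array([p.x_nm for p in self.particles], dtype=float)

    def z(self):
        import numpy as np

        return np.array([p.z_nm for p in self.particles], dtype=float)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the localization analysis.

    Lengths are nm.  ``kde_bandwidth`` of ``None`` selects the Silverman
    rule-of-thumb; a positive float fixes the bandwidth.  The axial and
    radial inclusion windows restrict which particles enter each axis'
    statistic (|x| <= axial_window_xmax_nm for Z, |z| <= radial_window_zmax_nm
    for R), mirroring the different particle counts the two axes report.
    """

    excision_radius_nm: float = 300.0
    bin_width_nm: float = 10.0
    ci_level: float = 0.95
    bootstrap_B: int = 2000
    axial_window_xmax_nm: float = 150.0
    radial_window_zmax_nm: float = 150.0
    kde_bandwidth: Optional[float] = None
    min_particles: int = 10
    symmetry_alpha: float = 0.05
    rng_seed: int = 0

    def violations(self) -> list[str]:
        """Return human-readable descriptions of every invalid field."""
        bad: list[str] = []
        for name in ("excision_radius_nm", "bin_width_nm",
                     "axial_window_xmax_nm", "radial_window_zmax_nm"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                bad.append(f"{name} must be a positive length, got {v!r}")
        if not (0.0 < self.ci_level < 1.0):
            bad.append(f"ci_level must lie in (0, 1), got {self.ci_level!r}")
        if not (0.0 < self.symmetry_alpha < 1.0):
            bad.append(f"symmetry_alpha must lie in (0, 1), got {self.symmetry_alpha!r}")
        if self.bootstrap_B < 100:
            bad.append(f"bootstrap_B must be >= 100, got {self.bootstrap_B!r}")
        if self.min_particles < 3:
            bad.append(f"min_particles must be >= 3, got {self.min_particles!r}")
        if self.kde_bandwidth is not None and not self.kde_bandwidth > 0:
            bad.append(f"kde_bandwidth must be positive or None, got {self.kde_bandwidth!r}")
        return bad

    def validate(self) -> "AnalysisConfig":
        bad = self.violations()
        if bad:
            raise ValueError("invalid analysis configuration:\n  " + "\n  ".join(bad))
        return self


@dataclass
class LocalizationEstimate:
    """One summary row for one tagged protein.

    ``z_ave_nm`` is signed when the protein is asymmetric (negative =
    nucleoplasmic) and the folded mean of ``|z|`` (reported as +/-) when
    symmetric.  Errors are half-widths of percentile bootstrap intervals at
    the configured confidence level.
    """

    nup_label: str
    z_ave_nm: float
    z_err_nm: float
    r_ave_nm: float
    r_err_nm: float
    n_r: int
    n_z: int
    n_npcs: int
    symmetry_class: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z_err_nm < 0 or self.r_err_nm < 0:
            raise ValueError("errors must be non-negative")
        if self.r_ave_nm < 0:
            raise ValueError("r_ave_nm must be non-negative")
        if self.symmetry_class not in (SYMMETRIC, NUCLEOPLASMIC, CYTOPLASMIC):
            raise ValueError(f"unknown symmetry class {self.symmetry_class!r}")
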