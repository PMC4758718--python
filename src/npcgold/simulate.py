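"""Synthetic immunogold labeling with known ground truth.

The generative model mirrors how gold particles arise in post-embedding
immuno-EM of the NPC: epitopes sit on a ring of radius R0 about the pore
axis at axial offset Z0 (both faces when the protein is symmetric), only
epitopes within the section slab are accessible, each detected epitope's
gold lies at the end of a primary+secondary antibody linkage, the section
projects away the depth coordinate, and montage alignment adds jitter.
Datasets produced here are written in the same table formats as real
annotation/particle tables, so the analysis cannot tell them apart.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .io import TableDialect, write_annotations, write_particle_table
from .model import (
    CommonFrameParticle,
    GoldParticleRaw,
    NpcAnnotation,
    ParticleSet,
    SimTruth,
)
from .montage import excise

__all__ = [
    "SimParams",
    "simulate_gold_particles",
    "simulate_study",
    "mean_abs_projection",
    "write_dataset",
]

UNIFORM_BALL = "uniform-ball"
ISOTROPIC_NORMAL = "isotropic-normal"


@dataclass(frozen=True)
class SimParams:
    """Ground-truth geometry and noise of one simulated labeling experiment.

    Lengths in nm.  ``linkage_max_nm`` bounds the antibody+gold displacement
    in the uniform-ball model: two IgG reaches of ~7 nm plus a 6 nm gold
    radius gives the 20 nm default; the 12 nm colloidal gold diameter is
    carried as metadata only.  ``section_thickness_nm`` is the slab within
    which epitopes are accessible (may be ``inf`` to disable truncation).
    """

    R0_nm: float = 40.0
    Z0_nm: float = 0.0
    symmetric: bool = True
    n_npcs: int = 25
    epitopes_per_npc: int = 20
    labeling_efficiency: float = 1.0
    linkage_max_nm: float = 20.0
    gold_diameter_nm: float = 12.0
    displacement_model: str = UNIFORM_BALL
    displacement_sd_nm: float = 7.0
    section_thickness_nm: float = 80.0
    alignment_jitter_sd_nm: float = 5.0
    excision_radius_nm: float = 300.0
    ring_spokes: int | None = None  # e.g. 8 for discrete octagonal spokes
    seed: int = 0

    def __post_init__(self):
        bad = []
        for name in ("R0_nm", "linkage_max_nm", "displacement_sd_nm",
                     "alignment_jitter_sd_nm", "gold_diameter_nm"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if not self.section_thickness_nm > 0:
            bad.append("section_thickness_nm must be > 0")
        if not (0.0 < self.labeling_efficiency <= 1.0):
            bad.append("labeling_efficiency must lie in (0, 1]")
        if self.n_npcs < 1 or self.epitopes_per_npc < 1:
            bad.append("n_npcs and epitopes_per_npc must be >= 1")
        if not self.excision_radius_nm > 0:
            bad.append("excision_radius_nm must be > 0")
        if self.displacement_model not in (UNIFORM_BALL, ISOTROPIC_NORMAL):
            bad.append(
                f"displacement_model must be '{UNIFORM_BALL}' or '{ISOTROPIC_NORMAL}'"
            )
        if self.ring_spokes is not None and self.ring_spokes < 1:
            bad.append("ring_spokes must be >= 1 or None")
        if bad:
            raise ValueError("invalid simulation parameters:\n  " + "\n  ".join(bad))


def mean_abs_projection(R_nm: float) -> float:
    """Expected |x| of a uniform ring of radius R projected on a diameter: 2R/pi."""
    if R_nm < 0:
        raise ValueError(f"R_nm must be >= 0, got {R_nm!r}")
    return 2.0 * R_nm / math.pi


def _displacements(rng: np.random.Generator, n: int, p: SimParams) -> np.ndarray:
    if p.displacement_model == UNIFORM_BALL:
        if p.linkage_max_nm == 0.0:
            return np.zeros((n, 3))
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = p.linkage_max_nm * rng.random(n) ** (1.0 / 3.0)
        return v * r[:, None]
    if p.displacement_sd_nm == 0.0:
        return np.zeros((n, 3))
    return rng.normal(scale=p.displacement_sd_nm, size=(n, 3))


def simulate_gold_particles(
    p: SimParams, label: str = "sim", rng: np.random.Generator | None = None
) -> ParticleSet:
    """Generate one protein's gold particles in the common frame, truth attached.

    Per pore and epitope copy: draw a ring angle (continuous by default, or
    one of ``ring_spokes`` discrete spokes with a random per-pore phase),
    place the epitope at (R0 cos, R0 sin [depth], +/-Z0), keep it if its
    depth lies within the section slab, thin by the labeling efficiency,
    displace by the antibody+gold linkage, project out the depth, jitter by
    alignment error, and excise at the montage radius.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    particles: list[CommonFrameParticle] = []
    half_t = p.section_thickness_nm / 2.0
    serial = 0
    for i in range(p.n_npcs):
        npc_id = f"{label}_npc{i:03d}"
        m = p.epitopes_per_npc
        if p.ring_spokes:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            spokes = phase + 2.0 * np.pi * rng.integers(0, p.ring_spokes, m) / p.ring_spokes
            phi = spokes
        else:
            phi = rng.uniform(0.0, 2.0 * np.pi, m)
        s = rng.choice([-1.0, 1.0], size=m) if p.symmetric else np.ones(m)
        pos = np.column_stack(
            [p.R0_nm * np.cos(phi), p.R0_nm * np.sin(phi), s * p.Z0_nm]
        )
        keep = np.abs(pos[:, 1]) <= half_t
        if p.labeling_efficiency < 1.0:
            keep &= rng.random(m) < p.labeling_efficiency
        pos = pos[keep]
        pos = pos + _displacements(rng, len(pos), p)
        xz = pos[:, [0, 2]]  # drop depth
        if p.alignment_jitter_sd_nm > 0:
            xz = xz + rng.normal(scale=p.alignment_jitter_sd_nm, size=xz.shape)
        for x, z in xz:
            particles.append(
                CommonFrameParticle(
                    particle_id=f"{label}_p{serial:05d}",
                    npc_id=npc_id,
                    x_nm=float(x),
                    z_nm=float(z),
                )
            )
            serial += 1
    particles = excise(particles, p.excision_radius_nm)
    return ParticleSet(
        nup_label=label,
        particles=particles,
        truth=SimTruth(r0_nm=p.R0_nm, z0_nm=p.Z0_nm, symmetric=p.symmetric),
        provenance={"simulated": True, "params": asdict(p), "n_npcs_simulated": p.n_npcs},
    )


def simulate_study(
    protein_specs: Sequence[tuple[str, SimParams]], seed: int = 0
) -> list[ParticleSet]:
    """Simulate several proteins with independent streams from one master seed."""
    labels = [label for label, _ in protein_specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate protein labels in study: {labels}")
    streams = np.random.SeedSequence(seed).spawn(len(protein_specs))
    return [
        simulate_gold_particles(params, label=label, rng=np.random.default_rng(ss))
        for (label, params), ss in zip(protein_specs, streams)
    ]


def write_dataset(
    datasets: Sequence[ParticleSet],
    out_dir: Union[str, Path],
    image_frame: bool = True,
    scale_nm_per_px: float = 2.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write simulated data as annotation + particle tables plus a truth file.

    With ``image_frame=True`` each pore is assigned a random micrograph
    placement (center, NE-axis angle, nucleoplasm side) and particle
    coordinates are written in pixels via the inverse of the common-frame
    map, so reading the dataset back exercises the full alignment path.
    With ``image_frame=False`` coordinates are written in nm as-is with
    identity annotations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    annotations: list[NpcAnnotation] = []
    raw_by_label: dict[str, list] = {}
    for ps in datasets:
        rows = []
        npc_ids = sorted({p.npc_id for p in ps.particles})
        anns: dict[str, NpcAnnotation] = {}
        for npc_id in npc_ids:
            if image_frame:
                ann = NpcAnnotation(
                    npc_id=npc_id,
                    micrograph_id=f"mg_{npc_id}",
                    center_px=(float(rng.uniform(200, 1800)), float(rng.uniform(200, 1800))),
                    ne_axis_angle=float(rng.uniform(-np.pi, np.pi)),
                    nucleoplasm_side=str(rng.choice(["down", "up"])),
                    scale_nm_per_px=scale_nm_per_px,
                    nup_label=ps.nup_label,
                )
            else:
                ann = NpcAnnotation(
                    npc_id=npc_id,
                    micrograph_id=f"mg_{npc_id}",
                    center_px=(0.0, 0.0),
                    ne_axis_angle=0.0,
                    nucleoplasm_side="down",
                    scale_nm_per_px=1.0,
                    nup_label=ps.nup_label,
                )
            anns[npc_id] = ann
            annotations.append(ann)
        for p in ps.particles:
            if not image_frame:
                rows.append(p)
                continue
            ann = anns[p.npc_id]
            # invert: unscale, undo reflection, rotate by +theta, untranslate
            u = p.x_nm / ann.scale_nm_per_px
            v = p.z_nm / ann.scale_nm_per_px
            if ann.nucleoplasm_side == "up":
                v = -v
            c, s = math.cos(ann.ne_axis_angle), math.sin(ann.ne_axis_angle)
            rows.append(
                GoldParticleRaw(
                    particle_id=p.particle_id,
                    npc_id=p.npc_id,
                    x_px=c * u - s * v + ann.center_px[0],
                    y_px=s * u + c * v + ann.center_px[1],
                )
            )
        raw_by_label[ps.nup_label] = rows
    units = "px" if image_frame else "nm"
    paths = {
        "annotations": write_annotations(annotations, out_dir / "annotations.csv"),
        "particles": write_particle_table(
            raw_by_label,
            out_dir / "particles.csv",
            dialect=TableDialect(nup_col="nup_label", units=units),
        ),
    }
    truth = {
        ps.nup_label: (
            None
            if ps.truth is None
            else {
                "R0_nm": ps.truth.r0_nm,
                "Z0_nm": ps.truth.z0_nm,
                "symmetric": ps.truth.symmetric,
            }
        )
        for ps in datasets
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths
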