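"""Montage geometry: common-frame transform, excision, binning, overlays.

"Superimposing" excised pore images is implemented as coordinate pooling:
every particle is mapped into one shared frame (nm, midplane at z = 0,
nucleoplasm at z < 0) and all downstream statistics work on the pooled
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .model import CommonFrameParticle, GoldParticleRaw, NpcAnnotation

__all__ = [
    "AxialHistogram",
    "transform_to_common_frame",
    "transform_all",
    "excise",
    "axial_histogram",
    "graduation_ticks",
    "render_montage",
]


@dataclass(frozen=True)
class AxialHistogram:
    """Histogram of axial (z) positions with half-open bins [k*w, (k+1)*w).

    Edges are anchored at integer multiples of the bin width so the NPC
    midplane is always a bin boundary.
    """

    bin_width_nm: float
    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # length n_bins, int

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts) + 1 entries")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        k = edges / self.bin_width_nm
        if not np.allclose(k, np.round(k)):
            raise ValueError("bin_edges must be integer multiples of bin_width_nm")


def transform_to_common_frame(
    raw: GoldParticleRaw, ann: NpcAnnotation
) -> CommonFrameParticle:
    """Map one raw particle into the common NPC frame.

    The map translates the pore center to the origin, rotates by minus the
    NE-axis angle (plus any per-NPC residual alignment angle) so the NE
    plane lies along x, reflects across the x-axis if the annotation places
    the nucleoplasm on the positive side, then scales pixels to nm.  Up to
    the uniform scale factor the map is an isometry.
    """
    if raw.npc_id != ann.npc_id:
        raise KeyError(
            f"particle {raw.particle_id!r} references NPC {raw.npc_id!r}, "
            f"annotation is for {ann.npc_id!r}"
        )
    theta = ann.ne_axis_angle + ann.residual_angle
    dx = raw.x_px - ann.center_px[0]
    dy = raw.y_px - ann.center_px[1]
    c, s = math.cos(-theta), math.sin(-theta)
    u = c * dx - s * dy
    v = s * dx + c * dy
    if ann.nucleoplasm_side == "up":
        v = -v
    return CommonFrameParticle(
        particle_id=raw.particle_id,
        npc_id=raw.npc_id,
        x_nm=u * ann.scale_nm_per_px,
        z_nm=v * ann.scale_nm_per_px,
    )


def transform_all(
    raws: Iterable[GoldParticleRaw], annotations: dict[str, NpcAnnotation]
) -> list[CommonFrameParticle]:
    """Transform a batch, resolving each particle's pore annotation by id."""
    out = []
    for raw in raws:
        ann = annotations.get(raw.npc_id)
        if ann is None:
            raise KeyError(
                f"particle {raw.particle_id!r} references unknown NPC {raw.npc_id!r}"
            )
        out.append(transform_to_common_frame(raw, ann))
    return out


def excise(
    particles: Sequence[CommonFrameParticle], radius_nm: float
) -> list[CommonFrameParticle]:
    """Keep particles within ``radius_nm`` of the pore center, order preserved."""
    if not radius_nm > 0:
        raise ValueError(f"radius_nm must be positive, got {radius_nm!r}")
    return [p for p in particles if math.hypot(p.x_nm, p.z_nm) <= radius_nm]


def axial_histogram(
    z_values, bin_width_nm: float = 10.0, range_nm: tuple[float, float] | None = None
) -> AxialHistogram:
    """Bin axial positions into half-open bins [k*w, (k+1)*w) anchored at 0.

    ``z_values`` may be an array of z coordinates or a sequence of
    common-frame particles.  When ``range_nm`` is given, only values inside
    it are counted and the edges cover exactly that range (rounded outward
    to bin boundaries).
    """
    if not bin_width_nm > 0:
        raise ValueError(f"bin_width_nm must be positive, got {bin_width_nm!r}")
    z = np.asarray(
        [p.z_nm for p in z_values]
        if len(z_values) and isinstance(z_values[0], CommonFrameParticle)
        else z_values,
        dtype=float,
    )
    w = float(bin_width_nm)
    if range_nm is not None:
        lo_k = math.floor(range_nm[0] / w)
        hi_k = math.ceil(range_nm[1] / w)
        z = z[(z >= range_nm[0]) & (z <= range_nm[1])]
    elif z.size:
        lo_k = math.floor(z.min() / w)
        hi_k = math.floor(z.max() / w) + 1
    else:
        lo_k, hi_k = 0, 1
    hi_k = max(hi_k, lo_k + 1)
    # integer bin index => exactly half-open bins, no edge ambiguity
    idx = np.floor(z / w).astype(int)
    idx = idx[(idx >= lo_k) & (idx < hi_k)]
    counts = np.bincount(idx - lo_k, minlength=hi_k - lo_k)
    edges = w * np.arange(lo_k, hi_k + 1)
    return AxialHistogram(bin_width_nm=w, bin_edges=edges, counts=counts)


def graduation_ticks(extent_nm: float, graduation_nm: float = 50.0) -> np.ndarray:
    """Symmetric tick positions every ``graduation_nm`` within +/- extent."""
    n = math.floor(extent_nm / graduation_nm)
    return graduation_nm * np.arange(-n, n + 1)


def render_montage(
    particles: Sequence[CommonFrameParticle],
    out_path: Union[str, Path],
    graduation_nm: float = 50.0,
    extent_nm: float = 300.0,
    title: str = "",
):
    """Render the pooled-coordinate montage overlay and save it.

    One marker per particle; graduation ticks every ``graduation_nm`` on
    both axes; the NE midplane drawn at z = 0 with the nucleoplasm labeled
    on the negative side.  Returns the matplotlib Figure.
    """
    if not particles:
        raise ValueError("render_montage requires a nonempty particle list")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.array([p.x_nm for p in particles])
    z = np.array([p.z_nm for p in particles])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, z, s=12, c="goldenrod", edgecolors="black", linewidths=0.3)
    ax.axhline(0.0, color="gray", lw=1.0)  # NE midplane
    ax.axvline(0.0, color="gray", lw=0.5, ls=":")  # pore axis
    ticks = graduation_ticks(extent_nm, graduation_nm)
    ax.set_xticks(ticks)
    ax.set_yticks(ticks)
    ax.set_xlim(-extent_nm, extent_nm)
    ax.set_ylim(-extent_nm, extent_nm)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm, along NE plane)")
    ax.set_ylabel("z (nm, pore axis)")
    ax.text(0.02, 0.02, "nucleoplasm", transform=ax.transAxes, fontsize=8)
    ax.text(0.02, 0.96, "cytoplasm", transform=ax.transAxes, fontsize=8)
    ax.set_title(title or f"montage overlay (n={len(particles)})", fontsize=10)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig
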