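"""Geometric parameters of the dendrite + spine + ER model and closed-form measures.

The morphology is a body of revolution per branch: a cylindrical dendrite
(axis z) carrying a concentric cylindrical ER tubule, and a spine (axis y,
attached at ``spine_position``) consisting of a cylindrical neck topped by a
spherical head. A thin spine-ER tubule may extend from the dendritic ER
surface along the spine axis, optionally terminating in a spherical bulb
("spine-within-spine" morphology).

Axial coordinate conventions
----------------------------
* Dendrite axis: z ∈ [0, dendrite_length]; the dendritic ER is centered.
* Spine axis: y, with y = 0 on the dendrite centerline. The neck spans
  y ∈ [r_dend, r_dend + neck_length]; the head sphere sits on the neck top.
* ``spine_er_length`` is the extent of the spine ER measured from the
  dendrite centerline (y = 0) to the ER tip, so a value below the dendrite
  radius describes a short stub that has not yet reached the neck entrance.
  With the default morphology the spine ER can reach at most
  r_dend + neck_length + head span ≈ 1.72 µm, which is why lengths up to
  1.7 µm are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


class InvalidSpineParams(ValueError):
    """Raised when a parameter set violates a geometric invariant.

    The message lists every violated invariant by name.
    """


@dataclass(frozen=True)
class SpineParams:
    """The characteristic geometric parameters of one spine configuration.

    All lengths in µm. Defaults are a reference morphology from super-resolution
    (STED) measurements of hippocampal spines.
    """

    dendrite_radius: float = 0.45
    dendrite_length: float = 10.0
    neck_radius: float = 0.08
    neck_length: float = 0.7
    head_radius: float = 0.29
    dendrite_er_radius: float = 0.11
    dendrite_er_length: float = 8.0
    spine_er_radius: float = 0.036
    spine_er_length: float = 1.5
    spine_er_head_radius: float = 0.0  # 0 = plain tubule, no terminal bulb
    head_volume_scale: float = 1.0
    spine_position: float | None = None  # default: dendrite mid-point
    # Measurement window on the dendrite, centered at the spine (µm).
    dendrite_roi_window: float = 1.0
    # Half-angle of the synaptic cap on the (unscaled) head, degrees.
    synapse_half_angle_deg: float = 30.0

    # ---- derived helpers -------------------------------------------------

    @property
    def z_spine(self) -> float:
        """Axial position of the spine on the dendrite."""
        if self.spine_position is None:
            return self.dendrite_length / 2.0
        return self.spine_position

    @property
    def head_radius_scaled(self) -> float:
        """Head radius after volume scaling (radius × scale^(1/3))."""
        return self.head_radius * self.head_volume_scale ** (1.0 / 3.0)

    @property
    def neck_base_y(self) -> float:
        return self.dendrite_radius

    @property
    def neck_top_y(self) -> float:
        return self.dendrite_radius + self.neck_length

    @property
    def head_center_y(self) -> float:
        """Center of the head sphere, placed so the sphere meets the neck rim."""
        rh = self.head_radius_scaled
        return self.neck_top_y + math.sqrt(max(rh * rh - self.neck_radius**2, 0.0))

    @property
    def spine_top_y(self) -> float:
        return self.head_center_y + self.head_radius_scaled

    @property
    def synapse_area(self) -> float:
        """Area of the synaptic release patch (µm²).

        Fixed at the spherical-cap area of the *unscaled* head so that head
        growth leaves the total synaptic Ca²⁺ entry unchanged.
        """
        theta = math.radians(self.synapse_half_angle_deg)
        return 2.0 * math.pi * self.head_radius**2 * (1.0 - math.cos(theta))

    @property
    def dendrite_er_z0(self) -> float:
        return (self.dendrite_length - self.dendrite_er_length) / 2.0

    @property
    def dendrite_er_z1(self) -> float:
        return (self.dendrite_length + self.dendrite_er_length) / 2.0

    def with_(self, **kwargs) -> "SpineParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def validate_params(p: SpineParams) -> SpineParams:
    """Check all geometric invariants; return ``p`` unchanged if valid.

    Raises
    ------
    InvalidSpineParams
        with a message naming every violated invariant.
    """
    errors: list[str] = []
    for f in fields(p):
        v = getattr(p, f.name)
        if f.name == "spine_position":
            continue
        if isinstance(v, (int, float)) and v < 0:
            errors.append(f"{f.name} must be >= 0 (got {v})")
    if p.dendrite_er_radius >= p.dendrite_radius:
        errors.append("dendritic ER wider than dendrite")
    if p.spine_er_length > 0 and p.spine_er_radius >= p.neck_radius:
        errors.append("ER wider than neck")
    rh = p.head_radius_scaled
    if p.neck_radius >= rh:
        errors.append("neck wider than head")
    if p.spine_er_head_radius >= rh:
        errors.append("ER head bulb wider than head")
    if p.spine_er_head_radius > 0 and p.spine_er_head_radius < p.spine_er_radius:
        errors.append("ER head bulb narrower than the ER tubule")
    max_extent = p.dendrite_radius + p.neck_length + 2.0 * rh
    if p.spine_er_length > max_extent:
        errors.append(
            f"spine ER must terminate inside the spine "
            f"(length {p.spine_er_length} > max extent {max_extent:.4g})"
        )
    if p.dendrite_er_length > p.dendrite_length:
        errors.append("dendritic ER longer than dendrite")
    if p.spine_er_length > 0 and p.spine_er_length <= p.dendrite_er_radius:
        errors.append(
            "spine ER does not reach beyond the dendritic ER surface "
            "(set spine_er_length = 0 for no spine ER)"
        )
    zs = p.z_spine
    if not (0.0 < zs < p.dendrite_length):
        errors.append("spine position outside the dendrite")
    if p.spine_er_head_radius > 0 and p.spine_er_length == 0:
        errors.append("ER head bulb requires spine_er_length > 0")
    if errors:
        raise InvalidSpineParams("; ".join(errors))
    return p


# ---------------------------------------------------------------------------
# Closed-form measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Measures:
    """Exact volumes (µm³) and areas (µm²) of one configuration."""

    cytosol_volume: float
    er_volume: float
    pm_area: float
    erm_area: float
    synapse_area: float
    roi_volumes: dict = field(default_factory=dict)  # head / neck / dendrite_roi


def _sphere_segment_volume(R: float, y0: float, y1: float, yc: float) -> float:
    """Volume of ∫ π(R² − (y−yc)²) dy over [y0, y1] (clipped to the sphere)."""
    a = max(y0, yc - R)
    b = min(y1, yc + R)
    if b <= a:
        return 0.0

    def F(y: float) -> float:
        return R * R * y - (y - yc) ** 3 / 3.0

    return math.pi * (F(b) - F(a))


def _spine_er_profile(p: SpineParams):
    """Return (tube_end_y, bulb) describing the spine-ER shape.

    ``bulb`` is None for a plain tubule, else (center_y, radius). The tubule
    spans y ∈ [dendrite_er_radius, tube_end_y]; the bulb (if any) continues
    to the ER tip at spine_er_length.
    """
    if p.spine_er_length <= 0:
        return None
    y0 = p.dendrite_er_radius
    tip = p.spine_er_length
    if p.spine_er_head_radius > 0:
        rb = p.spine_er_head_radius
        yb = tip - rb
        yj = yb - math.sqrt(max(rb * rb - p.spine_er_radius**2, 0.0))
        yj = max(yj, y0)
        return (y0, yj, (yb, rb))
    return (y0, tip, None)


def analytic_measures(p: SpineParams) -> Measures:
    """Exact cylinder/sphere mensuration of the configuration."""
    validate_params(p)
    rh = p.head_radius_scaled

    # --- ER volume ---------------------------------------------------------
    er_dend = math.pi * p.dendrite_er_radius**2 * p.dendrite_er_length
    er_spine = 0.0
    prof = _spine_er_profile(p)
    if prof is not None:
        y0, y1, bulb = prof
        er_spine = math.pi * p.spine_er_radius**2 * (y1 - y0)
        if bulb is not None:
            yb, rb = bulb
            er_spine += _sphere_segment_volume(rb, y1, p.spine_er_length, yb)
    er_volume = er_dend + er_spine

    # --- outer (membrane-bounded) volume ------------------------------------
    v_dend = math.pi * p.dendrite_radius**2 * p.dendrite_length
    v_neck = math.pi * p.neck_radius**2 * p.neck_length
    yc = p.head_center_y
    v_head = _sphere_segment_volume(rh, p.neck_top_y, p.spine_top_y, yc)
    outer = v_dend + v_neck + v_head
    cytosol = outer - er_volume

    # --- areas --------------------------------------------------------------
    pm = (
        2.0 * math.pi * p.dendrite_radius * p.dendrite_length
        - math.pi * p.neck_radius**2  # neck footprint removed from the shaft
        + 2.0 * math.pi * p.neck_radius * p.neck_length
        + 2.0 * math.pi * rh * (p.spine_top_y - p.neck_top_y)  # sphere zone
    )
    syn = min(p.synapse_area, 2.0 * math.pi * rh * (p.spine_top_y - p.neck_top_y))
    pm -= syn

    erm = (
        2.0 * math.pi * p.dendrite_er_radius * p.dendrite_er_length
        + 2.0 * math.pi * p.dendrite_er_radius**2  # the two end caps
    )
    if prof is not None:
        y0, y1, bulb = prof
        erm -= math.pi * p.spine_er_radius**2  # junction hole in the ER barrel
        erm += 2.0 * math.pi * p.spine_er_radius * (y1 - y0)
        if bulb is None:
            erm += math.pi * p.spine_er_radius**2  # flat tip cap
        else:
            yb, rb = bulb
            erm += 2.0 * math.pi * rb * (p.spine_er_length - y1)  # sphere zone

    # --- ROI volumes (cytosolic) --------------------------------------------
    # Spine-ER overlap with each axial range, for the cytosolic ROI volumes.
    def er_in_range(a: float, b: float) -> float:
        if prof is None:
            return 0.0
        y0, y1, bulb = prof
        v = math.pi * p.spine_er_radius**2 * max(0.0, min(b, y1) - max(a, y0))
        if bulb is not None:
            yb, rb = bulb
            v += _sphere_segment_volume(rb, max(a, y1), min(b, p.spine_er_length), yb)
        return v

    roi_neck = v_neck - er_in_range(p.neck_base_y, p.neck_top_y)
    roi_head = v_head - er_in_range(p.neck_top_y, p.spine_top_y)
    w = p.dendrite_roi_window
    zs = p.z_spine
    z0, z1 = max(0.0, zs - w / 2), min(p.dendrite_length, zs + w / 2)
    # Dendritic ER overlap with the window
    e0, e1 = p.dendrite_er_z0, p.dendrite_er_z1
    er_olap = max(0.0, min(z1, e1) - max(z0, e0))
    roi_dend = (
        math.pi * p.dendrite_radius**2 * (z1 - z0)
        - math.pi * p.dendrite_er_radius**2 * er_olap
        - er_in_range(0.0, p.dendrite_radius)
    )

    return Measures(
        cytosol_volume=cytosol,
        er_volume=er_volume,
        pm_area=pm,
        erm_area=erm,
        synapse_area=syn,
        roi_volumes={"head": roi_head, "neck": roi_neck, "dendrite_roi": roi_dend},
    )
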