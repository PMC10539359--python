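"""Pseudo-twofold (pseudo-dyad) axes and the Fab elbow angle.

A Fab's variable module (VH·VL) and constant module (CH1·CL) are each
related by an approximate twofold rotation between their heavy- and
light-chain domains.  The elbow angle is the angle between these two
pseudo-dyad axes and reports the bend at the switch region between the
variable and constant modules; crystallographic values for Fabs typically
fall between ~120° and ~195° (this implementation reports within (0°, 180°]).

The dyad of a region is obtained by superposing the heavy-chain domain Cα
trace onto the light-chain domain Cα trace (i-th onto i-th after trimming to
the shorter length — the two Ig domains share near-collinear numbering) and
taking the rotation axis of the fitted transform.  A good pseudo-twofold has
a rotation angle close to 180°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import FabStructure
from .superposition import kabsch_fit

__all__ = ["DyadAxis", "ElbowResult", "pseudo_dyad", "oriented_dyad_axes",
           "elbow_angle", "elbow_trajectory"]

MIN_DYAD_PAIRS = 20
#: below this pseudo-rotation angle the twofold is considered poor
DYAD_ANGLE_WARN = 150.0
#: axes closer than this (deg) to perpendicular to the module-orientation
#: vector make the sign convention ill-conditioned
PERP_WARN = 10.0

_REGION_DOMAINS = {"variable": ("VH", "VL"), "constant": ("CH1", "CL")}


@dataclass
class DyadAxis:
    axis: np.ndarray          # unit 3-vector
    rotation_angle: float     # degrees in [0, 180]
    fit_rmsd: float           # Å
    region: str               # "variable" | "constant"
    warnings: list = field(default_factory=list)


@dataclass
class ElbowResult:
    elbow_angle: float        # degrees in (0, 180]
    dyad_variable: DyadAxis
    dyad_constant: DyadAxis
    warnings: list = field(default_factory=list)


def pseudo_dyad(fab: FabStructure, region: str) -> DyadAxis:
    """Pseudo-twofold axis relating the heavy- and light-chain domains of a
    region ("variable": VH→VL, "constant": CH1→CL).

    The inter-domain correspondence pairs the i-th Cα of each domain after
    trimming both to the shorter length.  A warning is attached when the
    fitted rotation angle falls below 150° (weak pseudo-symmetry).
    """
    try:
        dom_h, dom_l = _REGION_DOMAINS[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}") from None
    ca_h = fab.domain_ca_coords(dom_h)
    ca_l = fab.domain_ca_coords(dom_l)
    n = min(len(ca_h), len(ca_l))
    if n < MIN_DYAD_PAIRS:
        raise ValueError(f"{region} correspondence yields {n} Cα pairs "
                         f"(need ≥ {MIN_DYAD_PAIRS})")
    fit = kabsch_fit(ca_h[:n], ca_l[:n])
    warns = []
    if fit.rotation_angle < DYAD_ANGLE_WARN:
        warns.append(f"{region} pseudo-dyad rotation angle "
                     f"{fit.rotation_angle:.1f}° < {DYAD_ANGLE_WARN:.0f}°: "
                     "poor pseudo-symmetry")
    return DyadAxis(axis=fit.rotation_axis, rotation_angle=fit.rotation_angle,
                    fit_rmsd=fit.rmsd, region=region, warnings=warns)


def _module_centroid(fab: FabStructure, region: str) -> np.ndarray:
    dom_h, dom_l = _REGION_DOMAINS[region]
    ca = np.vstack([fab.domain_ca_coords(dom_h), fab.domain_ca_coords(dom_l)])
    return ca.mean(axis=0)


def oriented_dyad_axes(fab: FabStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                                   DyadAxis, DyadAxis, list]:
    """Both pseudo-dyad axes, sign-oriented to a non-negative projection on
    the constant→variable centroid vector.

    Returns ``(axis_v, axis_c, orient_unit, dyad_v, dyad_c, warnings)``; the
    raw (pre-flip) projections are recorded in the warning logic of
    :func:`elbow_angle`.
    """
    dy_v = pseudo_dyad(fab, "variable")
    dy_c = pseudo_dyad(fab, "constant")
    orient = _module_centroid(fab, "variable") - _module_centroid(fab, "constant")
    norm = np.linalg.norm(orient)
    if norm < 1e-9:
        raise ValueError("variable and constant module centroids coincide")
    orient = orient / norm
    axis_v = dy_v.axis if float(dy_v.axis @ orient) >= 0 else -dy_v.axis
    axis_c = dy_c.axis if float(dy_c.axis @ orient) >= 0 else -dy_c.axis
    return axis_v, axis_c, orient, dy_v, dy_c, list(dy_v.warnings) + list(dy_c.warnings)


def elbow_angle(fab: FabStructure) -> ElbowResult:
    """Elbow angle: angle between the variable and constant pseudo-dyads.

    Each axis is sign-oriented to a non-negative projection onto the vector
    from the constant-module Cα centroid to the variable-module Cα centroid,
    then ``elbow = arccos(axis_V · axis_C)``.  When both axes are numerically
    perpendicular to the orientation vector the sign convention cannot pick a
    direction; the axes are then treated as undirected lines and the angle is
    folded to (90°, 180°] (``180° − arccos(|dot|)``), so a fully extended
    elbow reports 180°.  A warning is attached whenever either axis lies
    within 10° of perpendicular to the orientation vector.
    """
    axis_v, axis_c, orient, dy_v, dy_c, warns = oriented_dyad_axes(fab)
    proj_v = float(dy_v.axis @ orient)
    proj_c = float(dy_c.axis @ orient)

    for name, proj in (("variable", proj_v), ("constant", proj_c)):
        if abs(np.degrees(np.arcsin(np.clip(abs(proj), 0, 1)))) < PERP_WARN:
            warns.append(f"{name} dyad axis within {PERP_WARN:.0f}° of "
                         "perpendicular to the module-orientation vector; "
                         "sign convention ill-conditioned")

    dot = float(np.clip(axis_v @ axis_c, -1.0, 1.0))
    eps_perp = float(np.sin(np.radians(PERP_WARN)))
    if abs(proj_v) < eps_perp and abs(proj_c) < eps_perp:
        # both axes (numerically) perpendicular to the orientation vector:
        # the sign convention cannot orient them reliably, so compare the
        # axes as undirected lines, folded to (90°, 180°] — identical to the
        # signed formula for genuinely obtuse elbows and robust at 180°
        angle = 180.0 - float(np.degrees(np.arccos(abs(dot))))
        warns.append("orientation near-degenerate: axes compared as "
                     "undirected lines")
    else:
        angle = float(np.degrees(np.arccos(dot)))
        if angle == 0.0:
            angle = 180.0  # parallel oriented axes: extended-elbow convention
    return ElbowResult(elbow_angle=angle, dyad_variable=dy_v,
                       dyad_constant=dy_c, warnings=warns)


def elbow_trajectory(traj, fab: FabStructure) -> tuple[np.ndarray, np.ndarray, list]:
    """Elbow angle per frame of a trajectory.

    Returns ``(times_ns, angles_deg, per_frame_warnings)``; a frame whose
    dyad fit fails yields NaN and an entry in the warning list rather than
    being dropped.
    """
    times = traj.times()
    angles = np.full(len(traj.frames), np.nan)
    frame_warnings: list[tuple[int, str]] = []
    for t, frame in enumerate(traj.frames):
        moved = FabStructure(atoms=fab.atoms.with_coords(frame),
                             heavy_chain=fab.heavy_chain,
                             light_chain=fab.light_chain,
                             domain_ranges=fab.domain_ranges)
        try:
            res = elbow_angle(moved)
        except ValueError as exc:
            frame_warnings.append((t, str(exc)))
            continue
        angles[t] = res.elbow_angle
        for w in res.warnings:
            frame_warnings.append((t, w))
    return times, angles, frame_warnings
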