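"""Synthetic Fab-like structures, hinge trajectories and SAXS curves.

Every pipeline stage needs inputs with known ground truth: structures with
an exactly constructed elbow angle, trajectories following a prescribed
hinge schedule with Gaussian coordinate noise, and scattering curves with a
stated per-point noise model.  The generators here provide those.  They are
deliberately not physical models — domains are compact random clusters, not
Ig folds — but they carry elements, masses, residue names and chain
structure so that superposition, SASA, Rg, charge and SAXS all operate.

Geometry of :func:`build_toy_fab` (everything in the xy-plane, hinge at the
origin, designed elbow θ):

* constant module centroid at ``s·(−1, 0, 0)``, dyad axis ``(0, −1, 0)``;
* variable module centroid at ``s·(−cos θ, −sin θ, 0)``, dyad axis
  ``(sin θ, −cos θ, 0)``;

so the two axes subtend exactly θ after the sign-orientation convention,
and rotating the variable module about +z through the hinge by φ changes
both the elbow angle and the module separation (2·s·sin(θ/2)) consistently:
opening the hinge extends the molecule.

Each module's two domains are exact 180° copies of each other about the
module's dyad axis, displaced ±o along z, which makes the pseudo-twofold
fit exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import ATOMIC_MASSES, AtomSet, FabStructure, annotate_fab
from .fab_geometry import elbow_angle, oriented_dyad_axes, _module_centroid
from .scattering import ExpCurve, debye_profile
from .trajectory_metrics import Trajectory

__all__ = ["ToyFabSpec", "HingeSchedule", "build_toy_fab",
           "make_hinge_trajectory", "synth_saxs_curve", "plant_best_fit_frames"]

_RESIDUE_NAMES = np.array([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
], dtype=object)

_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
MIN_SPACING = 2.5  # Å, minimum inter-atom distance inside a domain cluster


@dataclass
class ToyFabSpec:
    atoms_per_domain: int = 120
    domain_radius: float = 9.0        # Å
    designed_elbow: float = 150.0     # degrees
    inter_domain_separation: float = 28.0  # Å, hinge→module-centroid
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.designed_elbow <= 180.0:
            raise ValueError("designed_elbow must lie in (0, 180] degrees")
        if self.atoms_per_domain < 20:
            raise ValueError("atoms_per_domain must be ≥ 20")
        if self.domain_radius <= 0 or self.inter_domain_separation <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class HingeSchedule:
    angles: np.ndarray                # per-frame target elbow, degrees
    noise_sigma: float = 0.0          # Å, per coordinate
    dt_ns: float = 0.1
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        if np.any((self.angles <= 0) | (self.angles > 180)):
            raise ValueError("scheduled angles must lie in (0, 180]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.dt_ns <= 0 or self.n_repeats < 1:
            raise ValueError("dt_ns > 0 and n_repeats ≥ 1 required")

    @property
    def n_frames(self) -> int:
        return len(self.angles)


def _compact_cluster(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Random points in a sphere with minimum pairwise spacing (rejection)."""
    pts: list[np.ndarray] = []
    tries = 0
    limit = 20000 * n
    while len(pts) < n:
        tries += 1
        if tries > limit:
            raise ValueError(
                f"cannot place {n} atoms at {MIN_SPACING} Å spacing inside "
                f"radius {radius} Å; increase domain_radius")
        p = rng.uniform(-radius, radius, 3)
        if p @ p > radius * radius:
            continue
        if pts and np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) < MIN_SPACING:
            continue
        pts.append(p)
    arr = np.asarray(pts)
    return arr - arr.mean(axis=0)


def _rotate_about(coords: np.ndarray, axis: np.ndarray, angle_deg: float,
                  center: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(np.asarray(axis, float) / np.linalg.norm(axis)
                               * np.radians(angle_deg))
    return (coords - center) @ rot.as_matrix().T + center


def build_toy_fab(spec: ToyFabSpec = ToyFabSpec()) -> FabStructure:
    """Four-domain Fab-like structure with an exactly designed elbow angle.

    Deterministic under ``spec.seed``; heavy chain "H" (VH then CH1), light
    chain "L" (VL then CL), residues of four backbone-named atoms each so
    every downstream analysis (Cα selection, SASA, Rg, charge, SAXS) has
    what it needs.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = spec.atoms_per_domain // 4
    theta = np.radians(spec.designed_elbow)
    s = spec.inter_domain_separation
    o = spec.domain_radius + 2.0

    c_var = s * np.array([-np.cos(theta), -np.sin(theta), 0.0])
    c_con = s * np.array([-1.0, 0.0, 0.0])
    axis_var = np.array([np.sin(theta), -np.cos(theta), 0.0])
    axis_con = np.array([0.0, -1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])

    # light-chain domains are fresh clusters; heavy-chain partners are their
    # exact 180° images about the module dyad axis → the pseudo-twofold fit
    # is exact by construction
    vl = _compact_cluster(rng, 4 * n_res, spec.domain_radius) + c_var + o * z
    vh = _rotate_about(vl, axis_var, 180.0, c_var)
    cl = _compact_cluster(rng, 4 * n_res, spec.domain_radius) + c_con + o * z
    ch1 = _rotate_about(cl, axis_con, 180.0, c_con)

    res_names_l = rng.choice(_RESIDUE_NAMES, size=2 * n_res)
    res_names_h = rng.choice(_RESIDUE_NAMES, size=2 * n_res)

    cols = {k: [] for k in ("atom_id", "element", "atom_name", "residue_name",
                            "residue_number", "insertion_code", "chain_id",
                            "occupancy", "b_factor", "mass")}
    coords: list[np.ndarray] = []
    serial = 0

    def add_domain(xyz: np.ndarray, chain: str, first_res: int,
                   names: np.ndarray, name_offset: int) -> None:
        nonlocal serial
        for r in range(len(xyz) // 4):
            res_name = names[name_offset + r]
            for k, (atom_name, element) in enumerate(_BACKBONE):
                serial += 1
                cols["atom_id"].append(serial)
                cols["element"].append(element)
                cols["atom_name"].append(atom_name)
                cols["residue_name"].append(res_name)
                cols["residue_number"].append(first_res + r)
                cols["insertion_code"].append("")
                cols["chain_id"].append(chain)
                cols["occupancy"].append(1.0)
                cols["b_factor"].append(0.0)
                cols["mass"].append(ATOMIC_MASSES[element])
                coords.append(xyz[4 * r + k])

    add_domain(vh, "H", 1, res_names_h, 0)
    add_domain(ch1, "H", n_res + 1, res_names_h, n_res)
    add_domain(vl, "L", 1, res_names_l, 0)
    add_domain(cl, "L", n_res + 1, res_names_l, n_res)

    atoms = AtomSet(
        atom_id=np.array(cols["atom_id"], int),
        element=np.array(cols["element"], object),
        atom_name=np.array(cols["atom_name"], object),
        residue_name=np.array(cols["residue_name"], object),
        residue_number=np.array(cols["residue_number"], int),
        insertion_code=np.array(cols["insertion_code"], object),
        chain_id=np.array(cols["chain_id"], object),
        coords=np.array(coords), occupancy=np.array(cols["occupancy"]),
        b_factor=np.array(cols["b_factor"]), mass=np.array(cols["mass"]),
    )
    boundaries = {"VH": (1, n_res), "VL": (1, n_res),
                  "CH1": (n_res + 1, 2 * n_res), "CL": (n_res + 1, 2 * n_res)}
    return annotate_fab(atoms, heavy="H", light="L", boundaries=boundaries)


def make_hinge_trajectory(fab: FabStructure,
                          schedule: HingeSchedule) -> list[Trajectory]:
    """Hinge-motion trajectories (one per repeat) following an elbow-angle
    schedule.

    Per frame the variable module (VH+VL) is rotated about the hinge normal
    (perpendicular to both dyad axes, through the midpoint of the module
    centroids) so the noise-free structure meets the scheduled elbow angle
    exactly; independent Gaussian noise of ``noise_sigma`` per coordinate is
    then added to every atom.  Repeats differ only by seed offset.
    """
    theta0 = elbow_angle(fab).elbow_angle
    axis_v, axis_c, _, _, _, _ = oriented_dyad_axes(fab)
    normal = np.cross(axis_c, axis_v)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise ValueError("dyad axes are parallel; hinge normal undefined "
                         "(elbow at 180°)")
    normal = normal / nn
    # hinge point: apex of the isoceles triangle over the module centroids
    # whose apex angle equals the elbow — rotating the variable module about
    # the normal through this point changes elbow angle and module
    # separation consistently (opening the hinge extends the molecule)
    c_v = _module_centroid(fab, "variable")
    c_c = _module_centroid(fab, "constant")
    sep = c_v - c_c
    w = np.cross(normal, sep)
    w = w / np.linalg.norm(w)
    half_d = 0.5 * np.linalg.norm(sep)
    hinge = 0.5 * (c_v + c_c) + w * half_d / np.tan(np.radians(theta0) / 2.0)
    var_mask = fab.domain_mask("VH") | fab.domain_mask("VL")

    out: list[Trajectory] = []
    for rep in range(schedule.n_repeats):
        rng = np.random.default_rng(schedule.seed + 7919 * rep)
        frames = []
        for target in schedule.angles:
            coords = fab.atoms.coords.copy()
            coords[var_mask] = _rotate_about(coords[var_mask], normal,
                                             float(target) - theta0, hinge)
            if schedule.noise_sigma > 0:
                coords = coords + rng.normal(0.0, schedule.noise_sigma,
                                             coords.shape)
            frames.append(coords)
        out.append(Trajectory(topology=fab.atoms, frames=frames,
                              dt_ns=schedule.dt_ns, repeat_id=f"r{rep + 1}"))
    return out


def synth_saxs_curve(atoms: AtomSet, q_grid: np.ndarray,
                     noise_fraction: float = 0.02, seed: int = 0,
                     coords: np.ndarray | None = None, mode: str = "atomic",
                     bin_width: float = 0.0,
                     sigma_floor_fraction: float = 1e-9) -> ExpCurve:
    """Noisy scattering curve from a known structure.

    ``I_obs = I_debye + N(0, σ(q))`` with ``σ(q) = noise_fraction·I_debye``
    floored at ``sigma_floor_fraction·I(0)``; the σ column records the true
    noise scale, so fitting the generating structure against its own curve
    yields reduced χ² ≈ 1.  Deterministic under ``seed``.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be ≥ 0")
    prof = debye_profile(atoms, q_grid, coords=coords, mode=mode,
                         bin_width=bin_width)
    floor = sigma_floor_fraction * float(prof.intensity.max())
    sigma = np.maximum(noise_fraction * prof.intensity, floor)
    intensity = prof.intensity.copy()
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, 1.0, len(sigma)) * sigma
    return ExpCurve(q=prof.q, intensity=intensity, sigma=sigma)


def plant_best_fit_frames(traj: Trajectory, target_coords: np.ndarray,
                          frame_ids: list[int], jitter_sigma: float = 0.01,
                          seed: int = 0) -> Trajectory:
    """Replace the listed frames with the target structure plus tiny jitter
    (≤ ~0.05 Å), creating a known best-fit set for recovery tests."""
    ids = list(frame_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate frame ids")
    if any(i < 0 or i >= len(traj.frames) for i in ids):
        raise ValueError("frame id out of range")
    target = np.asarray(target_coords, float).reshape(-1, 3)
    if len(target) != len(traj.topology):
        raise ValueError("target coordinate count mismatch")
    rng = np.random.default_rng(seed)
    frames = [f.copy() for f in traj.frames]
    for i in ids:
        frames[i] = target + rng.normal(0.0, jitter_sigma, target.shape)
    return Trajectory(topology=traj.topology, frames=frames, dt_ns=traj.dt_ns,
                      t0_ns=traj.t0_ns, repeat_id=traj.repeat_id)
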