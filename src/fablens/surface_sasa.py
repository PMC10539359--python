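"""Shrake–Rupley solvent-accessible surface area and APR aggregation.

Per-atom SASA is computed by the classic sphere-sampling construction: each
atom is expanded by the probe radius, covered with a deterministic
quasi-uniform (golden-spiral) point set, and the accessible fraction is the
share of test points not inside any neighbouring expanded sphere.

Aggregation-prone regions (APRs) are contiguous residue windows on one
chain; their SASA is the sum of per-atom areas of the window's residues
evaluated in the context of the whole structure.  The default APR table
holds the four windows reported for the A33 Fab: heavy V173–V188 (CH1),
light T129–F139 (CL), light L47–A51 (VL) and light T31–Y36 (VL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomSet, FabStructure

__all__ = ["RadiiSet", "AprWindow", "DEFAULT_RADII", "DEFAULT_APRS",
           "golden_spiral_points", "shrake_rupley", "apr_sasa",
           "apr_sasa_timeseries", "window_average"]


@dataclass
class RadiiSet:
    """Van der Waals radii (Å), probe radius, and quadrature density."""

    radii: dict[str, float] = field(default_factory=lambda: {
        "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "D": 1.20,
    })
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    fallback_radius: float | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be ≥ 60")

    def radius_of(self, elements: np.ndarray) -> np.ndarray:
        out = np.empty(len(elements))
        unknown = []
        for i, e in enumerate(elements):
            r = self.radii.get(str(e), self.fallback_radius)
            if r is None:
                unknown.append(str(e))
                r = np.nan
            out[i] = r
        if unknown:
            raise KeyError("no van der Waals radius for elements "
                           f"{sorted(set(unknown))} and no fallback configured")
        return out


@dataclass
class AprWindow:
    label: str
    chain_role: str            # "heavy" | "light"
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(f"APR {self.label}: first > last")
        if self.chain_role not in ("heavy", "light"):
            raise ValueError(f"APR {self.label}: chain_role must be heavy/light")


DEFAULT_RADII = RadiiSet()

DEFAULT_APRS: list[AprWindow] = [
    AprWindow("heavy_V173-V188", "heavy", 173, 188),
    AprWindow("light_T129-F139", "light", 129, 139),
    AprWindow("light_L47-A51", "light", 47, 51),
    AprWindow("light_T31-Y36", "light", 31, 36),
]


def _canonical_rotation(pos: np.ndarray) -> np.ndarray:
    """Structure-intrinsic rotation used to orient the quadrature sphere.

    Principal axes of the coordinates, each sign-fixed by the third moment
    (skewness) of the projections, made right-handed.  Because the frame
    co-rotates with the molecule, per-atom SASA is invariant under global
    rotations up to floating-point error rather than up to the quadrature
    resolution.
    """
    x = pos - pos.mean(axis=0)
    if len(x) < 2:
        return np.eye(3)
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    skew = np.einsum("ni,ni,ni->i", x @ vecs, x @ vecs, x @ vecs)
    for i in range(3):
        if skew[i] < 0:
            vecs[:, i] = -vecs[:, i]
    if np.linalg.det(vecs) < 0:
        j = int(np.argmin(np.abs(skew)))
        vecs[:, j] = -vecs[:, j]
    return vecs


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack((np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)))


def shrake_rupley(atoms: AtomSet, radii: RadiiSet = DEFAULT_RADII,
                  coords: np.ndarray | None = None,
                  include_hetero: bool = False) -> np.ndarray:
    """Per-atom SASA (Å²).

    ``SASA_i = 4π(r_i + r_p)² × (accessible points / total points)`` with the
    same fixed golden-spiral point set on every atom.  Neighbour search uses
    a k-d tree limited to pairs within ``r_i + r_j + 2 r_p``.  Waters and
    heteroatoms are excluded (SASA 0) unless ``include_hetero``; hydrogens
    participate only if present in the input.
    """
    xyz = atoms.coords if coords is None else np.asarray(coords, float).reshape(-1, 3)
    if len(xyz) != len(atoms):
        raise ValueError("coordinate count mismatch")
    active = np.ones(len(atoms), bool) if include_hetero else atoms.protein_mask()
    idx = np.flatnonzero(active)
    sasa = np.zeros(len(atoms))
    if idx.size == 0:
        return sasa
    r = radii.radius_of(atoms.element[idx]) + radii.probe_radius
    pos = xyz[idx]
    sphere = golden_spiral_points(radii.n_sphere_points) @ _canonical_rotation(pos).T
    tree = cKDTree(pos)
    rmax = r.max()
    for k in range(len(idx)):
        neigh = tree.query_ball_point(pos[k], r[k] + rmax)
        neigh = [j for j in neigh if j != k
                 and np.dot(pos[j] - pos[k], pos[j] - pos[k]) < (r[k] + r[j]) ** 2]
        pts = pos[k] + r[k] * sphere
        if neigh:
            buried = np.zeros(len(pts), bool)
            for j in neigh:
                d2 = np.sum((pts - pos[j]) ** 2, axis=1)
                buried |= d2 < r[j] ** 2
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[idx[k]] = 4.0 * np.pi * r[k] ** 2 * frac
    return sasa


# ---------------------------------------------------------------------------
# APR aggregation

@dataclass
class AprSasa:
    label: str
    sasa: float                 # Å²
    n_atoms: int
    missing_residues: list[int] = field(default_factory=list)

    @property
    def sasa_nm2(self) -> float:
        return self.sasa / 100.0


def _window_mask(fab: FabStructure, w: AprWindow) -> tuple[np.ndarray, list[int]]:
    chain = fab.heavy_chain if w.chain_role == "heavy" else fab.light_chain
    a = fab.atoms
    mask = (a.chain_id == chain) & (a.residue_number >= w.first_residue) \
        & (a.residue_number <= w.last_residue) & a.protein_mask()
    present = set(a.residue_number[mask].tolist())
    missing = [n for n in range(w.first_residue, w.last_residue + 1)
               if n not in present]
    return mask, missing


def apr_sasa(fab: FabStructure, windows: list[AprWindow] = DEFAULT_APRS,
             radii: RadiiSet = DEFAULT_RADII,
             per_atom: np.ndarray | None = None) -> list[AprSasa]:
    """Per-window SASA: sum of per-atom areas over the window's residues,
    computed in the context of the whole structure.  Residues referenced by a
    window but absent from the structure are reported, never silently
    ignored."""
    if per_atom is None:
        per_atom = shrake_rupley(fab.atoms, radii)
    out = []
    for w in windows:
        mask, missing = _window_mask(fab, w)
        out.append(AprSasa(label=w.label, sasa=float(per_atom[mask].sum()),
                           n_atoms=int(mask.sum()), missing_residues=missing))
    return out


def apr_sasa_timeseries(traj, fab: FabStructure,
                        windows: list[AprWindow] = DEFAULT_APRS,
                        radii: RadiiSet = DEFAULT_RADII,
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-window SASA per frame; returns ``(times_ns, {label: series})``."""
    times = traj.times()
    series = {w.label: np.empty(len(traj.frames)) for w in windows}
    for t, frame in enumerate(traj.frames):
        per_atom = shrake_rupley(fab.atoms, radii, coords=frame)
        moved = FabStructure(atoms=fab.atoms, heavy_chain=fab.heavy_chain,
                             light_chain=fab.light_chain,
                             domain_ranges=fab.domain_ranges)
        for res in apr_sasa(moved, windows, radii, per_atom=per_atom):
            series[res.label][t] = res.sasa
    return times, series


def window_average(series_per_repeat: list[tuple[np.ndarray, np.ndarray]],
                   window: tuple[float, float]) -> tuple[float, float]:
    """Final-window average across repeats.

    Each repeat is a ``(times_ns, values)`` pair; the per-repeat time-mean
    over ``window`` is taken first, then the mean and SEM (sample SD/√n)
    across repeats are returned.
    """
    if len(series_per_repeat) < 2:
        raise ValueError("need ≥ 2 repeats")
    lo, hi = window
    means = []
    for k, (times, values) in enumerate(series_per_repeat):
        sel = (np.asarray(times) >= lo) & (np.asarray(times) <= hi)
        if not sel.any():
            raise ValueError(f"window {window} empty in repeat {k}")
        means.append(float(np.mean(np.asarray(values)[sel])))
    means = np.array(means)
    n = len(means)
    sem = float(means.std(ddof=1) / np.sqrt(n))
    return float(means.mean()), sem
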