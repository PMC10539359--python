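"""Trajectory ingestion and per-frame summary metrics.

Trajectories are ordered coordinate frames over one topology with an
explicit frame→time mapping (``t = t0 + k·dt`` in ns; the saving interval is
never guessed from the file).  Metrics: mass-weighted radius of gyration,
Cα RMSD to the first frame (after superposition), repeat aggregation with
SEM, and a simple distance/angle hydrogen-bond detector for the heavy–light
chain interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AtomSet, FabStructure, read_structure
from .superposition import kabsch_fit

__all__ = ["Trajectory", "TimeSeriesStat", "read_trajectory",
           "radius_of_gyration", "rg_timeseries", "rmsd_to_start",
           "aggregate_repeats", "interchain_hbonds"]


@dataclass
class Trajectory:
    topology: AtomSet
    frames: list[np.ndarray]      # each (N, 3) Å
    dt_ns: float
    t0_ns: float = 0.0
    repeat_id: str = "r1"

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in self.frames]
        for k, f in enumerate(self.frames):
            if len(f) != n:
                raise ValueError(f"frame {k} has {len(f)} atoms, topology has {n}")

    def times(self) -> np.ndarray:
        return self.t0_ns + self.dt_ns * np.arange(len(self.frames))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TimeSeriesStat:
    """Mean ± SEM over repeats on a common time grid."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_repeats: int


def _read_multimodel_pdb_frames(path: Path, n_atoms: int) -> list[np.ndarray]:
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    seen_model = False
    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            seen_model = True
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                current = []
            current.append((float(line[30:38]), float(line[38:46]),
                            float(line[46:54])))
        elif rec == "ENDMDL" and current is not None:
            frames.append(current)
            current = None
    if current:
        frames.append(current)
    if not seen_model and len(frames) == 1 and len(frames[0]) % n_atoms == 0 \
            and len(frames[0]) != n_atoms:
        raise ValueError("multi-model PDB without MODEL records")
    return [np.asarray(f, dtype=float) for f in frames]


def read_trajectory(topology_path: str | Path,
                    trajectory_paths: "str | Path | list",
                    dt_ns: float, t0_ns: float = 0.0,
                    repeat_id: str = "r1") -> Trajectory:
    """Load a trajectory (multi-model PDB, DCD or XTC) over a PDB/mmCIF
    topology.  Multiple files are concatenated in argument order.  The frame
    interval ``dt_ns`` is a required input — trajectory files do not reliably
    carry it."""
    topology = read_structure(topology_path)
    if isinstance(trajectory_paths, (str, Path)):
        trajectory_paths = [trajectory_paths]
    frames: list[np.ndarray] = []
    for p in trajectory_paths:
        p = Path(p)
        if p.suffix.lower() == ".pdb":
            new = _read_multimodel_pdb_frames(p, len(topology))
        else:
            import MDAnalysis as mda
            u = mda.Universe(str(topology_path), str(p))
            new = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
        for k, f in enumerate(new):
            if len(f) != len(topology):
                raise ValueError(
                    f"{p}: frame {k} has {len(f)} atoms but topology has "
                    f"{len(topology)}")
        frames.extend(new)
    return Trajectory(topology=topology, frames=frames, dt_ns=dt_ns,
                      t0_ns=t0_ns, repeat_id=repeat_id)


# ---------------------------------------------------------------------------
# metrics

def radius_of_gyration(atoms: AtomSet, coords: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration in Å
    (``Rg² = Σ mᵢ|rᵢ − r_cm|² / Σ mᵢ``)."""
    xyz = atoms.coords if coords is None else np.asarray(coords, float).reshape(-1, 3)
    if len(xyz) == 0:
        raise ValueError("empty structure")
    m = atoms.mass
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    cm = (m[:, None] * xyz).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((xyz - cm) ** 2, axis=1)).sum() / total))


def rg_timeseries(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Rg (Å) with the frame→ns mapping."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    rg = np.array([radius_of_gyration(traj.topology, f) for f in traj.frames])
    return traj.times(), rg


def rmsd_to_start(traj: Trajectory,
                  selection: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Cα RMSD (Å) to frame 0, after superposition on the
    selection.  ``selection`` is a boolean mask or index array over topology
    atoms; default = all protein Cα."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    if selection is None:
        selection = top.ca_mask() & top.protein_mask()
    idx = np.flatnonzero(selection) if np.asarray(selection).dtype == bool \
        else np.asarray(selection, int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    ref = traj.frames[0][idx]
    out = np.empty(len(traj))
    for t, frame in enumerate(traj.frames):
        out[t] = kabsch_fit(frame[idx], ref).rmsd
    return traj.times(), out


def aggregate_repeats(series: list[tuple[np.ndarray, np.ndarray]]) -> TimeSeriesStat:
    """Pointwise mean and SEM (sample SD/√n) across ≥ 2 repeats sharing one
    time grid.  Grids must match exactly — no interpolation."""
    if len(series) < 2:
        raise ValueError("need ≥ 2 repeats")
    t0 = np.asarray(series[0][0], float)
    values = []
    for k, (t, v) in enumerate(series):
        t = np.asarray(t, float)
        if t.shape != t0.shape or not np.allclose(t, t0, atol=1e-9):
            raise ValueError(f"repeat {k} is on a different time grid")
        values.append(np.asarray(v, float))
    arr = np.vstack(values)
    n = arr.shape[0]
    return TimeSeriesStat(times=t0, mean=arr.mean(axis=0),
                          sem=arr.std(axis=0, ddof=1) / np.sqrt(n), n_repeats=n)


# ---------------------------------------------------------------------------
# hydrogen bonds across the heavy/light interface

_DONOR_ACCEPTOR_ELEMENTS = ("N", "O")


def interchain_hbonds(fab: FabStructure, d_max: float = 3.5,
                      angle_min: float = 120.0) -> list[tuple[tuple, tuple]]:
    """Donor–acceptor residue pairs hydrogen-bonded across the heavy/light
    interface.

    Criterion: donor-heavy-atom (N/O) to acceptor (N/O) distance ≤ ``d_max``
    Å; when the structure contains hydrogens, a D–H…A angle ≥ ``angle_min``
    degrees is additionally required (crystal structures without hydrogens
    use the distance criterion alone).  Pairs are deduplicated to
    ``((chain, resnum, resname), (chain, resnum, resname))``.
    """
    a = fab.atoms
    prot = a.protein_mask()
    polar = np.isin(a.element, _DONOR_ACCEPTOR_ELEMENTS) & prot
    heavy_m = polar & a.chain_mask(fab.heavy_chain)
    light_m = polar & a.chain_mask(fab.light_chain)
    h_mask = (a.element == "H") | (a.element == "D")
    has_h = bool(h_mask.any())
    h_pos = a.coords[h_mask]

    def bonded_hydrogens(i: int) -> np.ndarray:
        if not has_h:
            return np.empty((0, 3))
        d = np.linalg.norm(h_pos - a.coords[i], axis=1)
        return h_pos[d < 1.25]

    pairs: set[tuple[tuple, tuple]] = set()
    hi = np.flatnonzero(heavy_m)
    li = np.flatnonzero(light_m)
    if hi.size == 0 or li.size == 0:
        return []
    d = np.linalg.norm(a.coords[hi][:, None, :] - a.coords[li][None, :, :], axis=2)
    for p, q in zip(*np.nonzero(d <= d_max)):
        i, j = int(hi[p]), int(li[q])
        ok = True
        if has_h:
            ok = False
            for donor, acceptor in ((i, j), (j, i)):
                for h in bonded_hydrogens(donor):
                    v1 = a.coords[donor] - h
                    v2 = a.coords[acceptor] - h
                    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(c, -1, 1))) >= angle_min:
                        ok = True
                        break
                if ok:
                    break
        if ok:
            key_h = (str(a.chain_id[i]), int(a.residue_number[i]),
                     str(a.residue_name[i]))
            key_l = (str(a.chain_id[j]), int(a.residue_number[j]),
                     str(a.residue_name[j]))
            pairs.add((key_h, key_l))
    return sorted(pairs)
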