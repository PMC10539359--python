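"""Rigid-body superposition, matched-residue RMSD, windowed RMSF.

The workhorse is :func:`kabsch_fit`, a weighted least-squares proper-rotation
superposition (SVD with reflection correction).  Structure-to-structure RMSD
pairs Cα atoms by identical (chain role, residue number, insertion code) —
the two crystal forms analysed here share author numbering, so no sequence
alignment is needed or attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import FabStructure

__all__ = ["RigidTransform", "RmsfProfile", "kabsch_fit", "apply_transform",
           "rmsd_matched_ca", "rmsf_windowed"]

VARIABLE_DOMAINS = ("VH", "VL")
CONSTANT_DOMAINS = ("CH1", "CL")


@dataclass
class RigidTransform:
    """Proper rotation + translation minimising weighted RMSD."""

    rotation: np.ndarray       # (3,3), det = +1
    translation: np.ndarray    # (3,)
    rmsd: float                # Å, after superposition
    rotation_angle: float      # degrees, in [0, 180]
    rotation_axis: np.ndarray  # unit 3-vector

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rotation).T + translation


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Å) over a trajectory time window, one domain."""

    residues: list[tuple[int, str]]   # (residue_number, insertion_code)
    rmsf: np.ndarray                  # Å, aligned with residues
    window: tuple[float, float]       # ns
    domain: str


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> RigidTransform:
    """Optimal proper rotation + translation mapping ``mobile`` onto
    ``reference`` (point sets in correspondence).

    Uses the SVD of the weighted covariance; if the optimum would be a
    reflection the smallest singular direction is flipped so only proper
    rotations are returned.  The rotation angle and axis are extracted from
    the rotation matrix.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    n = len(mobile)
    if n != len(reference):
        raise ValueError("point sets differ in length")
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    translation = cr - rot @ cm
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - y) ** 2, axis=1))))
    r = Rotation.from_matrix(rot)
    rotvec = r.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle > 1e-12:
        axis = rotvec / np.linalg.norm(rotvec)
    else:
        axis = np.array([0.0, 0.0, 1.0])
    return RigidTransform(rotation=rot, translation=translation, rmsd=rmsd,
                          rotation_angle=angle, rotation_axis=axis)


# ---------------------------------------------------------------------------
# matched-residue RMSD between annotated structures

def _selection_domains(selection) -> tuple[str, ...]:
    if selection == "all":
        return VARIABLE_DOMAINS + CONSTANT_DOMAINS
    if selection == "variable":
        return VARIABLE_DOMAINS
    if selection == "constant":
        return CONSTANT_DOMAINS
    if isinstance(selection, (tuple, list)):
        return tuple(selection)
    raise ValueError(f"unknown selection {selection!r}")


def _matched_ca(a: FabStructure, b: FabStructure,
                domains: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, int]:
    xs, ys = [], []
    for dom in domains:
        keys_a = a.domain_ca_keys(dom)
        keys_b = set(b.domain_ca_keys(dom))
        common = [k for k in keys_a if k in keys_b]
        if not common:
            continue
        ca_a = dict(zip(keys_a, a.domain_ca_coords(dom)))
        ca_b = dict(zip(b.domain_ca_keys(dom), b.domain_ca_coords(dom)))
        xs.extend(ca_a[k] for k in common)
        ys.extend(ca_b[k] for k in common)
    return np.array(xs), np.array(ys), len(xs)


def rmsd_matched_ca(a: FabStructure, b: FabStructure,
                    selection="all") -> tuple[float, int]:
    """Post-superposition Cα RMSD over residues matched by identity.

    Correspondence is the intersection of (domain role, residue number,
    insertion code) observed in both structures; the superposition is
    restricted to the selected domains ("all", "variable", "constant" or an
    explicit domain tuple).  Returns ``(rmsd_Å, n_matched)``.
    """
    domains = _selection_domains(selection)
    x, y, n = _matched_ca(a, b, domains)
    if n < 3:
        raise ValueError(f"only {n} matched residues in selection {selection!r}")
    fit = kabsch_fit(x, y)
    return fit.rmsd, n


# ---------------------------------------------------------------------------
# windowed RMSF over a trajectory

def rmsf_windowed(traj, fab: FabStructure, domain: str,
                  window: tuple[float, float]) -> RmsfProfile:
    """Per-residue Cα RMSF of one domain over a time window.

    Frames in the window are superposed (domain Cα only) onto the window-mean
    structure with a single mean→fit→re-mean iteration, then
    ``RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²)``.
    """
    times = traj.times()
    lo, hi = window
    sel = np.flatnonzero((times >= lo) & (times <= hi))
    if sel.size == 0:
        raise ValueError(f"no frames in window {window} (span "
                         f"{times[0]:.3f}–{times[-1]:.3f} ns)")
    if sel.size < 2:
        raise ValueError("need at least 2 frames in the window")
    atoms = fab.atoms
    mask = fab.domain_mask(domain) & atoms.ca_mask() & atoms.protein_mask()
    idx = np.flatnonzero(mask)
    order = np.lexsort((atoms.insertion_code[idx], atoms.residue_number[idx]))
    idx = idx[order]
    residues = [(int(atoms.residue_number[i]), str(atoms.insertion_code[i]))
                for i in idx]

    stack = np.array([traj.frames[f][idx] for f in sel])  # (T, R, 3)
    mean = stack.mean(axis=0)
    fitted = np.empty_like(stack)
    for t in range(stack.shape[0]):
        fit = kabsch_fit(stack[t], mean)
        fitted[t] = fit.apply(stack[t])
    mean2 = fitted.mean(axis=0)
    for t in range(stack.shape[0]):
        fit = kabsch_fit(stack[t], mean2)
        fitted[t] = fit.apply(stack[t])
    mean_final = fitted.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((fitted - mean_final) ** 2, axis=2), axis=0))
    return RmsfProfile(residues=residues, rmsf=rmsf, window=(float(lo), float(hi)),
                       domain=domain)
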