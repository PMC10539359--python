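"""Trajectory I/O, Rg, RMSD-to-start, repeat aggregation, hydrogen bonds."""

import numpy as np
import pytest

from fablens import (HingeSchedule, ToyFabSpec, aggregate_repeats,
                     build_toy_fab, interchain_hbonds, make_hinge_trajectory,
                     radius_of_gyration, read_trajectory, rg_timeseries,
                     rmsd_to_start, write_multimodel_pdb, write_pdb)
from fablens.trajectory_metrics import Trajectory

from conftest import make_atoms, random_rotation


# ---------------------------------------------------------------------------
# ingestion

def test_multimodel_pdb_roundtrip(tmp_path, small_fab):
    frames = [small_fab.atoms.coords + k for k in range(3)]
    top = tmp_path / "top.pdb"
    trj = tmp_path / "traj.pdb"
    write_pdb(small_fab.atoms, top)
    write_multimodel_pdb(small_fab.atoms, frames, trj)
    traj = read_trajectory(top, trj, dt_ns=0.1)
    assert len(traj) == 3
    assert np.allclose(traj.frames[2], frames[2], atol=5e-4)
    assert np.allclose(traj.times(), [0.0, 0.1, 0.2])


def test_two_files_concatenate_in_order(tmp_path, small_fab):
    top = tmp_path / "top.pdb"
    write_pdb(small_fab.atoms, top)
    for k in (0, 1):
        write_multimodel_pdb(small_fab.atoms,
                             [small_fab.atoms.coords + 10 * k + i for i in range(5)],
                             tmp_path / f"part{k}.pdb")
    traj = read_trajectory(top, [tmp_path / "part0.pdb", tmp_path / "part1.pdb"],
                           dt_ns=0.1)
    assert len(traj) == 10
    assert traj.frames[7][0, 0] == pytest.approx(small_fab.atoms.coords[0, 0] + 12,
                                                 abs=5e-4)


def test_dcd_read_through_mdanalysis(tmp_path, small_fab):
    import MDAnalysis as mda
    top = tmp_path / "top.pdb"
    write_pdb(small_fab.atoms, top)
    frames = [small_fab.atoms.coords + k for k in range(4)]
    u = mda.Universe(str(top))
    dcd = tmp_path / "traj.dcd"
    with mda.Writer(str(dcd), n_atoms=len(small_fab.atoms)) as w:
        for f in frames:
            u.atoms.positions = f
            w.write(u.atoms)
    traj = read_trajectory(top, dcd, dt_ns=0.5)
    assert len(traj) == 4
    assert np.allclose(traj.frames[3], frames[3], atol=1e-3)


def test_atom_count_mismatch_raises(tmp_path, small_fab, toy_fab):
    top = tmp_path / "top.pdb"
    write_pdb(small_fab.atoms, top)
    trj = tmp_path / "traj.pdb"
    write_multimodel_pdb(toy_fab.atoms, [toy_fab.atoms.coords], trj)
    with pytest.raises(ValueError, match="atoms"):
        read_trajectory(top, trj, dt_ns=0.1)


def test_trajectory_validation():
    atoms = make_atoms(np.zeros((4, 3)))
    with pytest.raises(ValueError, match="dt_ns"):
        Trajectory(topology=atoms, frames=[np.zeros((4, 3))], dt_ns=0.0)
    with pytest.raises(ValueError, match="atoms"):
        Trajectory(topology=atoms, frames=[np.zeros((3, 3))], dt_ns=0.1)


# ---------------------------------------------------------------------------
# radius of gyration

def test_rg_point_mass_and_dumbbell():
    single = make_atoms([[1.0, 2.0, 3.0]])
    assert radius_of_gyration(single) == pytest.approx(0.0, abs=1e-12)
    pair = make_atoms([[0.0, 0, 0], [2.0, 0, 0]], elements=["H", "H"],
                      masses=[1.0, 1.0], residue_numbers=[1, 2])
    assert radius_of_gyration(pair) == pytest.approx(1.0)


def test_rg_uniform_sphere_closed_form():
    rng = np.random.default_rng(0)
    radius = 10.0
    pts = rng.normal(size=(100_000, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.uniform(0, 1, 100_000)[:, None] ** (1 / 3)
    atoms = make_atoms(pts, elements=["H"] * len(pts), masses=[1.0] * len(pts),
                       residue_numbers=[1] * len(pts),
                       atom_names=[f"H{i%9999}" for i in range(len(pts))])
    assert radius_of_gyration(atoms) == pytest.approx(np.sqrt(3 / 5) * radius,
                                                      rel=0.01)


def test_rg_series_static_dilation_and_hinge(toy_fab):
    coords = toy_fab.atoms.coords
    static = Trajectory(topology=toy_fab.atoms, frames=[coords] * 4, dt_ns=0.1)
    _, rg_static = rg_timeseries(static)
    assert np.allclose(rg_static, rg_static[0])
    center = coords.mean(axis=0)
    dilated = Trajectory(topology=toy_fab.atoms,
                         frames=[center + (coords - center) * s
                                 for s in (1.0, 1.5, 2.0)], dt_ns=0.1)
    _, rg_d = rg_timeseries(dilated)
    assert rg_d[1] == pytest.approx(1.5 * rg_d[0], rel=1e-12)
    opening = make_hinge_trajectory(
        toy_fab, HingeSchedule(angles=np.linspace(140, 175, 15)))[0]
    _, rg_open = rg_timeseries(opening)
    assert np.all(np.diff(rg_open) > 0)


def test_rg_invariant_to_rigid_motion_per_frame(toy_fab):
    coords = toy_fab.atoms.coords
    rot = random_rotation(4)
    moved = Trajectory(topology=toy_fab.atoms,
                       frames=[coords, coords @ rot.T + 20.0], dt_ns=0.1)
    _, rg = rg_timeseries(moved)
    assert rg[0] == pytest.approx(rg[1], abs=1e-9)


# ---------------------------------------------------------------------------
# RMSD to start

def test_rmsd_to_start_static_and_rigid(toy_fab):
    coords = toy_fab.atoms.coords
    rot = random_rotation(5)
    traj = Trajectory(topology=toy_fab.atoms,
                      frames=[coords, coords, coords @ rot.T + 3.0], dt_ns=0.1)
    _, rmsd = rmsd_to_start(traj)
    assert np.all(rmsd <= 1e-9)


def test_rmsd_to_start_matches_direct_oracle(toy_fab):
    """Noisy frames: values agree with an independent per-frame recomputation
    via scipy's align_vectors."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(6)
    coords = toy_fab.atoms.coords
    frames = [coords] + [coords + rng.normal(0, 0.4, coords.shape)
                         for _ in range(5)]
    traj = Trajectory(topology=toy_fab.atoms, frames=frames, dt_ns=0.1)
    sel = toy_fab.atoms.ca_mask()
    _, rmsd = rmsd_to_start(traj, sel)
    ref = frames[0][sel]
    for t, frame in enumerate(frames):
        x = frame[sel]
        _, rssd = Rotation.align_vectors(ref - ref.mean(0), x - x.mean(0))
        assert rmsd[t] == pytest.approx(rssd / np.sqrt(sel.sum()), abs=1e-5)


def test_rmsd_to_start_empty_selection_raises(toy_fab):
    traj = Trajectory(topology=toy_fab.atoms, frames=[toy_fab.atoms.coords],
                      dt_ns=0.1)
    with pytest.raises(ValueError):
        rmsd_to_start(traj, np.zeros(len(toy_fab.atoms), bool))


# ---------------------------------------------------------------------------
# aggregation

def test_aggregate_identical_and_two_repeat_formula():
    t = np.linspace(0, 5, 6)
    stat = aggregate_repeats([(t, t ** 2)] * 3)
    assert np.all(stat.sem == 0)
    stat2 = aggregate_repeats([(t, np.zeros(6)), (t, np.ones(6))])
    assert np.allclose(stat2.mean, 0.5)
    assert np.allclose(stat2.sem, 0.5)


def test_aggregate_mean_matches_independent_recompute():
    rng = np.random.default_rng(7)
    t = np.arange(20.0)
    reps = [(t, rng.normal(size=20)) for _ in range(6)]
    stat = aggregate_repeats(reps)
    assert np.allclose(stat.mean, np.mean([v for _, v in reps], axis=0))
    assert stat.n_repeats == 6


def test_aggregate_gaussian_sem_scaling():
    rng = np.random.default_rng(12)
    t = np.arange(5.0)
    sems = []
    for _ in range(500):
        reps = [(t, rng.normal(0, 2.0, 5)) for _ in range(6)]
        sems.append(aggregate_repeats(reps).sem)
    assert np.mean(sems) == pytest.approx(0.9515 * 2.0 / np.sqrt(6), rel=0.05)


def test_aggregate_rejects_mismatched_grids():
    t = np.arange(5.0)
    with pytest.raises(ValueError, match="time grid"):
        aggregate_repeats([(t, t), (t + 0.5, t)])


# ---------------------------------------------------------------------------
# hydrogen bonds

def _hbond_fixture(no_distance=2.9, angle_deg=165.0, with_h=True):
    """Heavy-chain amide N(-H) donating to a light-chain carbonyl O."""
    n_pos = np.array([0.0, 0, 0])
    h_dir = np.array([1.0, 0, 0])
    h_pos = n_pos + 1.0 * h_dir
    # place O so that the N-H...O angle at H equals angle_deg
    ang = np.radians(180.0 - angle_deg)
    o_dir = np.array([np.cos(ang), np.sin(ang), 0.0])
    # distance is measured N..O
    for d_ho in np.linspace(0.5, 6.0, 2000):
        o_pos = h_pos + d_ho * o_dir
        if abs(np.linalg.norm(o_pos - n_pos) - no_distance) < 2e-3:
            break
    coords = [n_pos, h_pos, o_pos] if with_h else [n_pos, o_pos]
    elements = ["N", "H", "O"] if with_h else ["N", "O"]
    names = ["N", "H", "O"] if with_h else ["N", "O"]
    chains = ["H", "H", "L"] if with_h else ["H", "L"]
    resnums = [1, 1, 1] if with_h else [1, 1]
    # pad each chain with a far-away second residue so annotation succeeds
    coords += [[80.0, 0, 0], [90.0, 0, 0]]
    elements += ["C", "C"]
    names += ["CA", "CA"]
    chains += ["H", "L"]
    resnums += [2, 2]
    atoms = make_atoms(coords, elements=elements, atom_names=names,
                       chain=chains, residue_numbers=resnums)
    from fablens import annotate_fab
    return annotate_fab(atoms, heavy="H", light="L",
                        boundaries={"VH": (1, 1), "CH1": (2, 2),
                                    "VL": (1, 1), "CL": (2, 2)})


def test_hbond_detected_at_good_geometry():
    fab = _hbond_fixture(2.9, 165.0)
    pairs = interchain_hbonds(fab)
    assert (("H", 1, "ALA"), ("L", 1, "ALA")) in pairs


def test_hbond_rejected_beyond_distance_cutoff():
    assert interchain_hbonds(_hbond_fixture(4.2, 165.0)) == []


def test_hbond_rejected_at_bad_angle():
    assert interchain_hbonds(_hbond_fixture(2.9, 95.0)) == []


def test_hbond_distance_only_without_hydrogens():
    fab = _hbond_fixture(2.9, 165.0, with_h=False)
    assert len(interchain_hbonds(fab)) == 1
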