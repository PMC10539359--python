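"""Debye SAXS profiles, Guinier Rg, χ² fitting and best-frame extraction."""

import numpy as np
import pytest

from fablens import (ExpCurve, FitResult, ToyFabSpec, build_toy_fab,
                     chi_square_fit, debye_profile, fit_trajectory,
                     guinier_rg, radius_of_gyration, read_exp_curve,
                     synth_saxs_curve, top_n_frames, write_exp_curve)
from fablens.trajectory_metrics import Trajectory

from conftest import make_atoms, random_rotation


def _two_points(d=5.0):
    return make_atoms([[0.0, 0, 0], [0, 0, d]], elements=["H", "H"],
                      masses=[1.0, 1.0], residue_numbers=[1, 2])


def test_debye_zero_angle_is_total_electrons_squared(small_fab):
    q = np.array([0.0, 0.05])
    prof = debye_profile(small_fab.atoms, q, bin_width=0.0)
    f_sum = small_fab.atoms.electron_counts().sum()
    assert prof.intensity[0] == pytest.approx(f_sum ** 2, rel=1e-12)
    assert np.all(prof.intensity <= prof.intensity[0] + 1e-9)


def test_debye_two_point_closed_form():
    d = 5.0
    q = np.linspace(0.0, 1.0, 40)
    prof = debye_profile(_two_points(d), q, bin_width=0.0)
    with np.errstate(invalid="ignore"):
        expected = 2.0 * (1.0 + np.sinc(q * d / np.pi))
    assert np.allclose(prof.intensity, expected, atol=1e-12)


def test_debye_binned_close_to_exact_sum(toy_fab):
    sub = toy_fab.atoms.subset(np.arange(min(480, len(toy_fab.atoms))))
    q = np.linspace(0.005, 0.3, 40)
    exact = debye_profile(sub, q, bin_width=0.0)
    binned = debye_profile(sub, q, bin_width=0.5)
    rel = np.abs(binned.intensity - exact.intensity) / exact.intensity
    assert rel.max() <= 0.005


def test_debye_rigid_invariance(small_fab):
    q = np.linspace(0.0, 0.3, 20)
    base = debye_profile(small_fab.atoms, q, bin_width=0.0)
    rot = random_rotation(9)
    moved = small_fab.atoms.with_coords(small_fab.atoms.coords @ rot.T + 12.0)
    other = debye_profile(moved, q, bin_width=0.0)
    assert np.allclose(base.intensity, other.intensity, rtol=1e-12)


def test_debye_residue_cg_reduces_centers(small_fab):
    q = np.linspace(0.0, 0.2, 10)
    cg = debye_profile(small_fab.atoms, q, mode="residue_cg", bin_width=0.0)
    # same total electron count → identical forward limit
    f_sum = small_fab.atoms.electron_counts().sum()
    assert cg.intensity[0] == pytest.approx(f_sum ** 2, rel=1e-12)


def test_debye_validation():
    with pytest.raises(ValueError, match="bin_width"):
        debye_profile(_two_points(), np.array([0.0, 0.1]), bin_width=-1.0)
    single = make_atoms([[0.0, 0, 0]])
    with pytest.raises(ValueError, match="scattering centers"):
        debye_profile(single, np.array([0.0, 0.1]))


# ---------------------------------------------------------------------------
# Guinier

def test_guinier_uniform_sphere():
    rng = np.random.default_rng(1)
    radius = 15.0
    pts = rng.normal(size=(3000, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.uniform(0, 1, 3000)[:, None] ** (1 / 3)
    atoms = make_atoms(pts, elements=["H"] * 3000, masses=[1.0] * 3000,
                       residue_numbers=list(range(1, 3001)))
    prof = debye_profile(atoms, np.linspace(0.002, 0.15, 150), bin_width=0.5)
    rg_true = radius_of_gyration(atoms)  # unit masses = electron weighting
    assert guinier_rg(prof) == pytest.approx(rg_true, rel=0.03)


def test_guinier_two_point_scatterers():
    d = 20.0
    prof = debye_profile(_two_points(d), np.linspace(0.002, 0.2, 300),
                         bin_width=0.0)
    # a dumbbell is strongly non-globular: the Guinier expansion needs a
    # conservative fit range to reach the d/2 closed form
    assert guinier_rg(prof, limit=0.8) == pytest.approx(d / 2, rel=0.03)


def test_guinier_needs_five_points():
    prof = debye_profile(_two_points(), np.linspace(0.01, 0.05, 4),
                         bin_width=0.0)
    with pytest.raises(ValueError):
        guinier_rg(prof)


# ---------------------------------------------------------------------------
# χ² fitting

def test_chi_square_self_fit_and_scale_recovery(small_fab):
    q = np.linspace(0.01, 0.3, 50)
    prof = debye_profile(small_fab.atoms, q, bin_width=0.0)
    exp = ExpCurve(q=q, intensity=prof.intensity.copy(), sigma=np.ones(50))
    fit = chi_square_fit(prof, exp)
    assert fit.chi_square == pytest.approx(0.0, abs=1e-18)
    assert fit.scale == pytest.approx(1.0)
    exp2 = ExpCurve(q=q, intensity=2 * prof.intensity, sigma=np.ones(50))
    fit2 = chi_square_fit(prof, exp2)
    assert fit2.chi_square == pytest.approx(0.0, abs=1e-15)
    assert fit2.scale == pytest.approx(2.0)


def test_chi_square_invariant_to_calc_rescaling(small_fab):
    q = np.linspace(0.01, 0.3, 50)
    prof = debye_profile(small_fab.atoms, q, bin_width=0.5)
    exp = synth_saxs_curve(small_fab.atoms, q, noise_fraction=0.05, seed=3,
                           bin_width=0.5)
    base = chi_square_fit(prof, exp)
    scaled = type(prof)(q=prof.q, intensity=prof.intensity * 37.5)
    other = chi_square_fit(scaled, exp)
    assert other.chi_square == pytest.approx(base.chi_square, abs=1e-9)
    assert other.scale == pytest.approx(base.scale / 37.5, rel=1e-9)


def test_chi_square_expectation_near_one(small_fab):
    """Fitting the truth against its own noise model gives reduced χ² ≈ 1."""
    q = np.linspace(0.01, 0.3, 60)
    prof = debye_profile(small_fab.atoms, q, bin_width=0.0)
    chis = [chi_square_fit(prof, synth_saxs_curve(small_fab.atoms, q,
                                                  noise_fraction=0.02, seed=s)
                           ).chi_square for s in range(50)]
    assert np.mean(chis) == pytest.approx(1.0, abs=0.1)


def test_chi_square_excludes_out_of_range_points(small_fab):
    q_calc = np.linspace(0.05, 0.2, 40)
    prof = debye_profile(small_fab.atoms, q_calc, bin_width=0.5)
    q_exp = np.linspace(0.01, 0.3, 50)
    exp = ExpCurve(q=q_exp, intensity=np.interp(q_exp, prof.q, prof.intensity),
                   sigma=np.ones(50))
    fit = chi_square_fit(prof, exp)
    assert fit.n_points + fit.n_excluded == 50
    assert fit.n_excluded > 0


def test_chi_square_insufficient_overlap_raises(small_fab):
    prof = debye_profile(small_fab.atoms, np.linspace(0.01, 0.02, 10),
                         bin_width=0.5)
    exp = ExpCurve(q=np.linspace(0.2, 0.3, 10), intensity=np.ones(10),
                   sigma=np.ones(10))
    with pytest.raises(ValueError, match="overlap"):
        chi_square_fit(prof, exp)


# ---------------------------------------------------------------------------
# trajectory fitting and top-N

def _planted_setup(seed=0, n_frames=30, noise=0.0):
    from fablens import HingeSchedule, make_hinge_trajectory
    fab = build_toy_fab(ToyFabSpec(atoms_per_domain=80, seed=4))
    sched = HingeSchedule(angles=np.linspace(150, 135, n_frames),
                          noise_sigma=noise, seed=seed)
    traj = make_hinge_trajectory(fab, sched)[0]
    k = 12
    target = traj.frames[k]
    q = np.linspace(0.01, 0.25, 50)
    curve = synth_saxs_curve(fab.atoms, q, noise_fraction=0.0, seed=0,
                             coords=target, mode="residue_cg", bin_width=0.5)
    return fab, traj, curve, k


def test_fit_trajectory_planted_optimum_noise_free():
    _, traj, curve, k = _planted_setup()
    fits = fit_trajectory(traj, curve)
    chis = np.array([f.chi_square for f in fits])
    assert int(np.argmin(chis)) == k
    assert chis[k] == pytest.approx(0.0, abs=1e-12)


def test_fit_trajectory_constant_frames_constant_series(small_fab):
    q = np.linspace(0.01, 0.25, 40)
    curve = synth_saxs_curve(small_fab.atoms, q, noise_fraction=0.02, seed=1,
                             mode="residue_cg", bin_width=0.5)
    traj = Trajectory(topology=small_fab.atoms,
                      frames=[small_fab.atoms.coords.copy()] * 4, dt_ns=0.1)
    fits = fit_trajectory(traj, curve)
    chis = [f.chi_square for f in fits]
    assert np.allclose(chis, chis[0], rtol=1e-12)


def test_fit_trajectory_noisy_recovery_rate():
    """With σ = 0.1 Å structural noise the planted frame stays the arg-min in
    at least 90% of seeds."""
    hits = 0
    for seed in range(20):
        _, traj, curve, k = _planted_setup(seed=seed, noise=0.1)
        chis = np.array([f.chi_square for f in fit_trajectory(traj, curve)])
        hits += int(np.argmin(chis) == k)
    assert hits >= 18


def test_top_n_selection_and_tie_rule(small_fab):
    frames = [small_fab.atoms.coords.copy() for _ in range(6)]
    traj_a = Trajectory(topology=small_fab.atoms, frames=frames, dt_ns=0.1,
                        repeat_id="r1")
    traj_b = Trajectory(topology=small_fab.atoms, frames=frames, dt_ns=0.1,
                        repeat_id="r2")
    def fr(chi, frame, rep, t):
        return FitResult(chi_square=chi, scale=1.0, n_points=10,
                         frame=frame, repeat_id=rep, time_ns=t)
    fits_a = [fr(c, i, "r1", 0.1 * i) for i, c in enumerate([5, 1, 3, 2, 2, 9])]
    fits_b = [fr(c, i, "r2", 0.1 * i) for i, c in enumerate([4, 1, 8, 8, 8, 8])]
    best, m = top_n_frames([fits_a, fits_b], [traj_a, traj_b], 4)
    assert [(f.repeat_id, f.frame) for f in best] == [
        ("r1", 1), ("r2", 1), ("r1", 3), ("r1", 4)]
    assert m.shape == (4, 4)
    assert np.allclose(m, 0.0, atol=1e-9)  # identical frames


def test_top_n_requires_enough_frames(small_fab):
    traj = Trajectory(topology=small_fab.atoms,
                      frames=[small_fab.atoms.coords], dt_ns=0.1)
    fits = [FitResult(chi_square=1.0, scale=1.0, n_points=10, frame=0,
                      repeat_id="r1", time_ns=0.0)]
    with pytest.raises(ValueError):
        top_n_frames([fits], [traj], 2)


# ---------------------------------------------------------------------------
# curve I/O

def test_exp_curve_roundtrip_and_units(tmp_path):
    q = np.linspace(0.01, 0.3, 20)
    curve = ExpCurve(q=q, intensity=np.exp(-q * 10), sigma=0.01 * np.ones(20))
    p = tmp_path / "curve.dat"
    write_exp_curve(curve, p)
    back = read_exp_curve(p)
    assert np.allclose(back.q, curve.q, rtol=1e-5)
    assert np.allclose(back.intensity, curve.intensity, rtol=1e-6)
    # nm⁻¹ input converts to Å⁻¹
    nm = tmp_path / "nm.dat"
    nm.write_text("# q I s\n" + "\n".join(
        f"{10 * qq:.6f} {ii:.6f} 0.01" for qq, ii in zip(q, curve.intensity)))
    back_nm = read_exp_curve(nm, q_units="1/nm")
    assert np.allclose(back_nm.q, curve.q, rtol=1e-4)


def test_exp_curve_validation(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("0.1 1.0\n")
    with pytest.raises(ValueError, match="3 columns"):
        read_exp_curve(p)
    with pytest.raises(ValueError, match="sigma"):
        ExpCurve(q=np.array([0.1]), intensity=np.array([1.0]),
                 sigma=np.array([0.0]))
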