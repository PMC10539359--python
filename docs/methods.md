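# Methods

`fablens` analyses antibody Fab fragments — four-domain molecules with a
heavy chain (VH + CH1) and a light chain (VL + CL) — both as static crystal
structures and as conformational ensembles from molecular-dynamics
trajectories, and relates ensembles to solution small-angle X-ray
scattering (SAXS) data. This note records the models, conventions and
numerical choices; it is the authoritative description of what each number
the package reports means.

## Structures and domain annotation

Structures are read from PDB or mmCIF via gemmi into a column-oriented
`AtomSet` (coordinates in Å, author residue numbering, occupancy, B-factor,
mass). Alternate locations are resolved to the highest-occupancy copy, ties
broken by file order; zero-occupancy atoms are dropped. Waters and
heteroatoms are excluded from all analyses unless explicitly included.

A Fab is annotated by chain roles and the four inclusive residue ranges.
The default variable-domain boundaries are **VL 1–109** and **VH 1–117**
(the usual convention for κ light / γ heavy Fabs); the constant domains
take the remainder of each chain. Residue identity is always
(chain, author residue number, insertion code); concatenated numbering
schemes that run the light chain after the heavy chain are supported only
as a derived report index, never internally.

Unresolved loops are reported per chain as one gap record per jump > 1 in
consecutive observed residue numbers, with `n_missing = first_after −
last_before − 1`; when the entry carries a full-sequence record the missing
one-letter stretch is filled in and a C-terminal truncation is reported
separately. Insertion codes adjacent to a putative gap mark it
numbering-ambiguous instead of silently counting it.

### Formal charge (model-pKa null)

`total_formal_charge` assigns each ionisable group its majority protonation
state by comparing pH with a model pKa (protonated iff pH < pKa): Asp 3.8,
Glu 4.2, His 6.0, Cys 8.3, Tyr 10.1, Lys 10.5, Arg 12.5, N-terminus 8.0,
C-terminus 3.1. Protonated bases count +1, deprotonated acids −1. This is a
deliberate sequence-only null model: it ignores the structural environment,
so it cannot reproduce structure-based pKa-shifted charges (tools like
PDB2PQR/PROPKA can assign the same sequence materially different total
charges at low pH). It is monotonically non-increasing in pH by
construction — a property the tests assert.

## Superposition, RMSD, RMSF

Rigid superposition is the weighted Kabsch solution: SVD of the weighted
covariance with the determinant-correction that forbids reflections.
Weights default to uniform for Cα fits (the common convention for Cα RMSD;
mass weighting is available but not default). The rotation angle/axis are
extracted from the rotation matrix.

Structure-to-structure RMSD pairs Cα atoms by identical (domain role,
residue number, insertion code) in both structures — the two crystal forms
this package was built around share author numbering, so sequence alignment
is out of scope by design. The superposition and the reported RMSD are
restricted to a selection: all four domains, the variable module, the
constant module, or an explicit domain set. When an asymmetric unit holds
two copies, the copy with the lowest chain-ID pair is the default
representative.

Per-residue RMSF over a trajectory window superposes each in-window frame's
domain Cα set onto the window-mean structure with one mean → fit → re-mean
iteration (less biased than using frame 1 as the reference), then
`RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²)`. For isotropic Gaussian
coordinate noise of width σ this converges to σ√3, which is the closed form
the tests check.

## Pseudo-dyad axes and the elbow angle

Each Ig module of a Fab is related by an approximate twofold: VH ↔ VL and
CH1 ↔ CL. The pseudo-dyad of a module is the rotation axis of the Kabsch
transform superposing the heavy-chain domain Cα trace onto the light-chain
domain Cα trace. The inter-domain correspondence pairs the i-th Cα of each
domain after trimming both to the shorter length (VH 1–117 vs VL 1–109
gives 109 pairs); the Ig fold's near-collinear numbering makes this
adequate, and a structure-based pairing is deliberately out of scope. A
rotation angle below 150° attaches a poor-pseudo-symmetry warning.

The **elbow angle** is the angle between the two pseudo-dyad axes. Axis
sign is fixed by requiring a non-negative projection onto the vector from
the constant-module Cα centroid to the variable-module Cα centroid; then
`elbow = arccos(axis_V · axis_C)`, reported in (0°, 180°]. When both axes
fall within 10° of perpendicular to that orientation vector the sign
convention is ill-conditioned; the axes are then compared as undirected
lines, folded to (90°, 180°] via `180° − arccos(|dot|)` with a warning.
This is identical to the signed formula for any genuinely obtuse elbow and
keeps a fully extended (180°) Fab at 180° instead of collapsing it to 0°.
The extended crystallographic convention that distinguishes elbow angles
beyond 180° is not implemented; Fab elbows in the 120°–180° range are
unaffected, and this is a known limitation for strongly over-extended
molecules.

Per-frame elbow angles over a trajectory flag failing frames as missing
(NaN plus a warning record) rather than dropping them.

## Solvent-accessible surface area

Per-atom SASA uses the Shrake–Rupley construction: each atom expanded by
the probe radius is covered with a deterministic golden-spiral point set
and `SASA = 4π(r+rp)² × (accessible points / total points)`. Defaults:
radii C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å; probe 1.4 Å; 960 points.
Neighbour search uses a k-d tree restricted to pairs within
`r_i + r_j + 2rp`. The quadrature sphere is oriented in a
structure-intrinsic frame (principal axes of the coordinates, sign-fixed by
the skewness of the projections), so per-atom SASA is invariant under
global rotations to floating-point precision rather than to the quadrature
resolution. Hydrogens participate only when present in the input; crystal
structures (no H) and simulation frames (with H) therefore differ
systematically, and atom counts are carried in the results so the
discrepancy is visible.

Aggregation-prone regions (APRs) are contiguous residue windows on one
chain; the default table holds the four windows reported for the A33 Fab
(heavy V173–V188 in CH1, light T129–F139 in CL, light L47–A51 and T31–Y36
in VL — three further predicted APRs are not named in print and are left
user-configurable). A window's SASA is the sum of per-atom areas of its
residues computed in the context of the whole structure; residues a window
references but the structure lacks are reported, never silently ignored.
Values are reported in Å² with an nm² convenience accessor, since figure
axes in the literature are not always unit-labelled.

Final-window averages take the per-repeat time-mean over the window first,
then the mean and SEM (sample SD/√n) across repeats — SEM over repeats,
never over correlated frames.

## Trajectory metrics

Trajectories are ordered frames over one topology with an explicit
`t = t0 + k·dt` (ns) mapping; the saving interval is a required input
because trajectory files do not reliably carry it. Multi-model PDB, DCD and
XTC are supported (the latter two via MDAnalysis); multiple files
concatenate in argument order and atom-count mismatches are errors.

Radius of gyration is mass-weighted,
`Rg = sqrt(Σ mᵢ|rᵢ−r_cm|²/Σ mᵢ)`, reported in Å (÷10 for nm). RMSD-to-start
is the per-frame Cα RMSD to frame 0 after superposition on the selection.
Repeat aggregation computes the pointwise mean and SEM across repeats and
refuses mismatched time grids — no silent interpolation. Equilibration
handling is an explicit `discard_ns` parameter on the window selectors
rather than a hard-coded burn-in.

Inter-chain hydrogen bonds use conventional geometric defaults — donor
heavy-atom to acceptor distance ≤ 3.5 Å and, when hydrogens are present,
D–H…A angle ≥ 120° — restricted to pairs crossing the heavy/light
interface and deduplicated to residue pairs. These criteria are a
diagnostic convention, not a fitted quantity.

## SAXS forward model and ensemble fitting

The forward model is the vacuum Debye equation

    I(q) = Σᵢ Σⱼ fᵢ fⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ)

with constant form factors equal to atomic electron counts (atomic mode) or
per-residue electron sums placed at the Cα (residue coarse-grain mode, the
default for trajectories where the O(N²) atomic sum is too costly). Pair
distances can be histogram-binned (default 0.5 Å) before the sinc sum; a
bin width of 0 evaluates the exact double sum. `I(0) = (Σf)²` exactly, and
binning deviates from the exact sum by ≤ 0.5% for q ≤ 0.3 Å⁻¹ on test
structures. **No excluded-volume or hydration-shell terms are included**:
absolute χ² values against real solution data are therefore not comparable
with solvent-aware predictors (CRYSOL, FoXS, SasCalc), and published
absolute χ² magnitudes for such tools are not reproduced here. All χ²-based
conclusions in this package are about fits that are self-consistent with
its own forward model.

Guinier analysis fits ln I vs q² iteratively until `q_max·Rg ≤ limit`
(default 1.3), `Rg = sqrt(−3·slope)`. The default limit assumes a roughly
globular scatterer; strongly anisometric toys (a two-point dumbbell) need a
more conservative limit to reach their closed-form Rg.

χ² fitting uses the reduced convention with a free multiplicative scale
only: `c = Σ(I_c I_e/σ²)/Σ(I_c²/σ²)` in closed form and
`χ² = (1/(N−1)) Σ[(c·I_c − I_e)/σ]²`. The calculated profile is linearly
interpolated onto the experimental grid; experimental σ is never
interpolated; points outside the calculated range are excluded and counted.
An additive-background variant of the scale fit exists but is off by
default. Fitting a profile against a curve generated from it with the
stated noise model gives reduced χ² ≈ 1, which the tests verify over 50
noise realisations.

Best-fit extraction ranks all frames across repeats by ascending χ², ties
broken by (repeat label, earlier time), writes the top N as a multi-model
PDB and reports their pairwise matched-Cα RMSD matrix.

## Synthetic ground truth

The generators exist so every stage is testable without downloads, with
known answers:

* **Toy Fab** — four compact random clusters (uniform-in-sphere points with
  a 2.5 Å minimum spacing, 4-atom backbone-named residues carrying
  elements/masses) arranged so each module's heavy-chain domain is the
  exact 180° image of its light-chain domain about the module's dyad axis,
  and the two axes subtend exactly the designed elbow under the package's
  orientation convention. Defaults: 120 atoms (30 residues) per domain,
  9 Å domain radius, 28 Å hinge-to-module-centroid separation — sized so
  the molecule is Fab-like in proportion while keeping per-frame analyses
  fast. Deterministic under its seed; no global random state anywhere.
* **Hinge trajectories** — per frame the variable module is rotated about
  the normal to both dyad axes through the hinge apex (reconstructed as the
  apex of the isoceles triangle over the module centroids whose apex angle
  is the elbow) so the noise-free structure meets the scheduled elbow
  exactly, then independent Gaussian noise of width σ is added to every
  coordinate. Opening the hinge extends the molecule, so scheduled opening
  and closing reproduce the qualitative Rg/elbow patterns of real
  pH-dependent simulations (the tests assert monotonicity, never any
  published numeric endpoint). Repeats differ only by a seed offset.
* **SAXS curves** — Debye profile of a known structure plus Gaussian noise
  with σ(q) = noise_fraction·I(q), floored at a tiny positive value; the σ
  column records the true noise scale, making the reduced-χ² ≈ 1
  calibration exact in expectation. Default noise fraction 0.02,
  representative of well-measured protein SAXS in the Guinier-to-mid-q
  range.
* **Planted best-fit frames** — selected frames replaced by a target
  conformation plus ≤ 0.05 Å jitter, giving an exactly known top-N set.

What the toys do **not** emulate: real Ig β-sandwich topology, side chains,
sequence-structure consistency, solvent, or physically correlated motion.
Passing tests therefore demonstrate the correctness of the geometry,
surface, scattering and statistics machinery — not force-field realism.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately modest sizes
chosen as sufficient for their tolerances: 10-point clouds against a 4°
rotation-grid oracle, 10⁵-point uniform balls for Rg, 20-atom peptides for
SASA oracles at up to 10⁴ sphere points, 50 noise realisations for χ²
calibration, and a 600-frame six-repeat ensemble for planted-frame
recovery. Every stochastic quantity is a pure function of an explicit seed.

## Known limitations

* The model-pKa charge is a null model; do not expect agreement with
  structure-based protonation assignment beyond ~neutral pH.
* The dyad correspondence is index-based after trimming; Fabs with strongly
  non-collinear VH/VL numbering would need a structure-based pairing.
* Vacuum Debye only — no hydration layer, no absolute intensity scale, no
  P(r) inversion.
* Elbow angles are folded into (0°, 180°]; over-extended (> 180°)
  conventions are not distinguished.
* Crystal-form checks against deposited coordinates require the user to
  download the entries; the repository ships no coordinate data.
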