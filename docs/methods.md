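# Methods

## Scope and data model

The package analyses trajectories of a two-chain complex (a "ligand" chain
and a "receptor" chain) plus pulling-force traces. A `Trajectory` is an
ordered list of frames sharing one atom ordering; coordinates are in Å,
frame spacing in ns. Trajectories are read and written as multi-model PDB
(wwPDB v3.3 fixed columns, coordinates at 3-decimal precision, so a
write/read round trip is exact at that precision). Missing element columns
are inferred from atom names, the common case for MD-written PDBs. Running
the MD itself, topology/parameter parsing, solvent handling and force-field
energies are out of scope; an interaction-energy series can be supplied as
a precomputed column and is only aggregated/correlated.

## Hydrogen-bond detection and occupancy

A donor–acceptor pair forms a bond in a frame when d(D, A) ≤ 3.5 Å and the
angular criterion ≤ 30° holds. Two angle conventions exist in the
literature and differ materially; both are implemented:

* **donor-vertex** (default): angle between the D→H and D→A vectors —
  the convention of the common visualization tools;
* **hydrogen-vertex**: 180° − ∠D–H–A.

Donor/acceptor heavy atoms come from a standard per-residue chemistry
table (backbone N donor / O acceptor; Ser/Thr/Tyr hydroxyls, Asn/Gln
amide N/O, Lys NZ, Arg NE/NH1/NH2, Trp NE1, His ND1/NE2 both ways,
Asp/Glu carboxylate O). Hydrogens are attached to their donor
*geometrically* (same residue, < 1.25 Å) rather than by name tables, which
makes detection robust to H-naming conventions (H/HN/HT1…). A structure
without hydrogens either raises (when `require_hydrogens`) or falls back to
the distance criterion alone with an explicit flag — never silently.

Bond identity across frames is keyed by the heavy atoms only, so hydrogen
relabelling cannot split a bond's raster row, and a bond that breaks and
re-forms keeps one identity. The survival raster (bond × frame booleans)
yields the per-frame interface bond count N_HB (column sums) and per-bond
occupancies ω (row means). Salt bridges use the 4 Å acidic-O/basic-N
criterion, collapsed to one bridge per residue pair per frame.

## Connectivity model

With bonds treated as independent Bernoulli events at probability ω, the
pair, residue and complex quantities are complement products (see README
for the formulas). Two numerical points matter:

* P_D is evaluated as a product of complements directly
  (Π rows Π cols (1 − p)); computing 1 − P_j after rounding P_j ≈ 1 would
  lose up to the full magnitude of a small P_D. The ligand-side and
  receptor-side groupings are both computed and must agree to 1e-12
  relative — an internal consistency check of the algebraic identity.
* Occupancies enter per bond instance, not per residue pair: a pair with
  two distinct bonds contributes two ω factors. Transient bonds keep their
  small ω; no occupancy floor is applied.

f_D across a replica sweep is the mean of per-replica ratios
P_D(f, r)/P_D(0, r) by default; a `ratio-of-means` switch uses
mean P_D(f)/mean P_D(0) instead. Per-replica pairing was chosen because it
cancels replica-level offsets in overall bond strength. The independence
assumption itself is a modelling choice, not something the package can
validate from a trajectory: the exhaustive-enumeration tests verify the
arithmetic, not the biology.

## Geometry descriptors

Kabsch superposition (rotation solve via `scipy`'s `align_vectors`,
reflections corrected, degenerate fit sets rejected) underlies the Cα-RMSD
series and RMSF. RMSF uses a two-pass iteratively refined mean structure
as reference (switchable to first-frame); for isotropic per-atom jitter σ
it converges to σ√3. Segment axes are the leading principal component of
the Cα run, sign-fixed toward increasing residue number and rejected as
ill-conditioned when the leading singular value does not dominate the
second by at least 5 % — directions of near-isotropic point sets are
meaningless. All angles (inter-axis θ, turn angle γ between two Cα–Cα
lines) are cross angles of undirected lines, reported on [0°, 90°]; the
segment residue windows and the four γ anchor atoms are configuration, not
constants, since strand/helix boundaries are system-specific.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points) on each solvent-expanded sphere (vdW + 1.4 Å probe); a point is
accessible when outside every neighbour's expanded sphere. Deterministic
points make results bit-reproducible and testable against analytic values:
an isolated sphere is exact by construction, and the two-sphere case
matches the spherical-cap closed form to well under 1 %. Radii default to
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å (overridable). Buried
interface area is (S_A + S_B − S_AB)/2 with each group's "alone" SASA
computed with the other group's atoms removed entirely.

## Force traces

Rupture force is the global maximum of the (by default unsmoothed) force
spectrum, earliest sample on ties; the time of that maximum is the rupture
time. Traces are classified into the high-strength pathway (type 1) when
the rupture force strictly exceeds 200 pN, else type 2 — the threshold is
a config value. An optional centred moving average (shrunken windows at
the ends) is available but off by default, since smoothing can only lower
the read maximum. Clamp-window segmentation reports, per target force, the
longest contiguous stretch with |F − target| ≤ tolerance, flagging targets
the trace never holds. The virtual-spring model F(t) = k·(v·t − x(t)) with
k = 13.9 pN/Å and v = 3 Å/ns serves both unit sanity checks and the
generator.

## Run statistics

Replica aggregation is mean ± *sample* (n−1) SD. Gaussian histogram fits
use nonlinear least squares with deterministic moment initialisation and
σ > 0 bounds; R² = 1 − SS_res/SS_tot. Pearson r carries the exact
two-tailed t-based p-value; group comparison is the pooled-variance
two-sample t test (df = n_a + n_b − 2). Significance stars
(0.05/0.01/0.005) live in the report layer only. No multiple-testing
correction is applied.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions, not physics:

* **Scheduled bond trajectories.** Two toy chains of glycine-like 5-atom
  residues (explicit N–H donors, so detection runs in full geometric mode).
  Each scheduled bond is collinear at d = 2.9 Å in "on" frames and
  displaced to 5.0 Å in "off" frames; residue pairs sit 20 Å apart so no
  accidental bonds arise. Patterns: `block` (deterministic; realised
  occupancy within 1/n_frames of target — the default), `periodic`, and
  `bernoulli` (i.i.d. frames, for statistical tests). Defaults: 1000
  frames per replica, three replicas, and base occupancies
  (0.971, 0.719, 0.722, 0.539, 0.131, 0.179) — the equilibrium values of
  the most stable replica of the system this toolkit was built around.
* **Force sweep.** Clamp forces (0, 20, 40, 60, 80) pN. The default
  profile scales each bond's breakage probability by
  s(f) = (1.0, 0.8, 0.6, 0.4, 0.7), so the closed-form
  f_D(f) = s(f)^n_bonds dips to a minimum at 60 pN — the catch–slip turn
  point the sweep pipeline must recover. These factors are the designed
  study condition, fixed in the generator defaults.
* **Rupture traces.** Linear rise to a designed (peak, time) — e.g.
  (240 pN, 13 ns) and (170 pN, 10 ns), the two pathway exemplars — then
  exponential decay; a peak above the stiff-spring bound k·v·t is rejected
  as inconsistent. At zero noise the maximum is exact by construction.
* **Rigid + jitter trajectories** with closed-form RMSD/RMSF expectations,
  and **sphere clusters** with analytic SASA.

What passing these tests shows: the detection, statistics and model
arithmetic are correct and the pipeline recovers designed parameters
through its full path. What it does not show: anything about real
conformational dynamics — the toy geometry has no dihedral structure, no
correlated bond breaking, no solvent, and bond events are independent by
construction (the very assumption of the connectivity model). MD-derived
observables of the original system (actual rupture forces, θ rising
22°→30°, L_F 14→17 Å, per-force correlation coefficients) are not
desk-reproducible and are covered only by round-trip and property tests.

## Numerical and design choices

* Gaussian-fit acceptance uses a 9-bond Bernoulli schedule with mean
  N_HB ≈ 4.3 over 50,000 frames, emulating the equilibrium bond-count
  statistics; its histogram fits with R² ≫ 0.98.
* Problem sizes in tests and the acceptance script (1000-frame replicas,
  2000-frame jitter runs, 960 sphere points) are chosen so every
  quantisation/convergence bound in the contracts is met with margin while
  a full run stays in the tens of seconds.
* Tie-breaks: earliest time at equal force maxima; mergesort (stable) when
  ranking occupancy tables.
* Degenerate inputs fail loudly: empty trajectories, single-frame RMSF,
  zero-variance histograms, P_D(0) = 0 in f_D, collinear fit sets.
* The equilibrium report treats a pair absent from one replica as 0 %
  occupancy in that replica (the bond was never observed there), which is
  how per-run occupancy tables are conventionally averaged.

## Known limitations

* Hydrogen-bond chemistry covers the 20 standard amino acids only; no
  π-stacking, cation–π or water-mediated bridges.
* The SASA implementation is O(n²) in selected atoms per frame — fine for
  interface-sized selections, slow for full solvated systems.
* `segment_axis` assumes the segment is elongated; very short or bent
  segments are rejected rather than guessed.
* The connectivity model has no kinetics: it ranks states by occupancy
  products and says nothing about lifetimes or loading-rate dependence.
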