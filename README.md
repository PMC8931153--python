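# mechbond

Post-processing toolkit for steered-molecular-dynamics (SMD) studies of a
two-chain protein complex under mechanical load — written for the
Talin-F3 / β3-integrin-tail class of problem, where the question is whether
pulling force weakens or *strengthens* the interface (a slip vs catch
bond), and the evidence is carried by interface hydrogen-bond statistics
rather than by a single trajectory snapshot.

It is aimed at people who already have trajectories (multi-model PDB) and
pulling-force traces and want the downstream numbers: bond occupancies,
dissociation probabilities, rupture forces, interface areas and the
structural descriptors that explain them.

## The model

For every interface hydrogen bond (detected geometrically: donor–acceptor
distance ≤ 3.5 Å and a 30° angular cutoff), the **occupancy** ω is the
fraction of frames in which the bond is present. Treating each bond as an
independent Bernoulli event, the probability that ligand residue *i* is
bound to receptor residue *j* through any of its M<sub>ij</sub> bonds is

    p_ij = 1 − Π_l (1 − ω_ij,l)

the per-residue binding probabilities are the row/column marginals

    P_{j,L} = 1 − Π_i (1 − p_ji),   P_{j,R} = 1 − Π_i (1 − p_ij)

and the **complex dissociation probability** is

    P_D = Π_j (1 − P_{j,L}) = Π_j (1 − P_{j,R}) = Π_bonds (1 − ω)

Comparing clamp forces through the **mechano-regulation factor**

    f_D = P_D|_{f=f0} / P_D|_{f=0}

gives a force-normalised dissociation: f<sub>D</sub> < 1 means the load
*enhances* the linkage (catch regime); a biphasic f<sub>D</sub>(f) with a
minimum marks the catch-to-slip transition. Around this core the package
provides Shrake–Rupley SASA and the buried interface area
(S<sub>A</sub> + S<sub>B</sub> − S<sub>AB</sub>)/2, Kabsch-superposition
Cα-RMSD/RMSF, inter-segment and turn angles, rupture-force extraction from
force spectra (global maximum; pathway split at 200 pN), and the run-level
statistics (Gaussian N<sub>HB</sub> fits, mean ± SD aggregation, Pearson,
pooled t test).

Because real SMD runs are expensive, the `synthgen` module generates every
input with known ground truth — scheduled hydrogen-bond trajectories,
rigid-motion/jitter trajectories, spring-ramp force traces (k = 13.9 pN/Å,
v = 3 Å/ns), sphere clusters with analytic SASA — so the entire pipeline is
testable end to end by parameter recovery.

## Worked example

```python
import numpy as np
from mechbond import interactions, connectivity
from mechbond.structio import select
from mechbond.synthgen import BondSchedule, make_hbond_trajectory, RUN2_OCCUPANCIES

# a 1000-frame two-chain toy trajectory whose six interface bonds are
# present in 97.1 %, 71.9 %, 72.2 %, 53.9 %, 13.1 % and 17.9 % of frames
traj = make_hbond_trajectory(
    [BondSchedule(target_occupancy=w) for w in RUN2_OCCUPANCIES], 1000
)
raster = interactions.build_raster(
    traj, select(traj, "chain L"), select(traj, "chain R")
)
occ = interactions.occupancy(raster)
print(np.sort(occ["occupancy"].to_numpy()))
# [0.131 0.179 0.539 0.719 0.722 0.971]

cpm = connectivity.ContactProbabilityMatrix.from_occupancies(occ)
print(connectivity.dissociation_probability(cpm).P_D)
# 0.0007450972708803587
```

The six occupancies are recovered exactly (they are multiples of the
1/1000-frame quantum), and the dissociation probability is their
complement product, P_D = Π(1 − ω) ≈ 7.45 × 10⁻⁴ — the number a fully
wired detection → occupancy → connectivity chain must reproduce.

The same stages are exposed as a CLI (`mechbond equilibrium|sweep|rupture|
sasa|geometry|simulate|table1`); `mechbond simulate` writes inspectable
multi-model PDB fixtures and plain-text force traces.

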