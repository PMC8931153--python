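"""End-to-end analysis orchestration.

Three entry points mirror the three stages of a ramp-clamp pulling study:

* :func:`run_equilibrium_analysis` — replica equilibrium trajectories →
  ranked interface-bond occupancy table (per-run and mean ± SD columns),
  N_HB time series with Gaussian fits, per-residue RMSF;
* :func:`run_force_sweep_analysis` — per-clamp-force replica sets →
  occupancies, P_D and the mechano-regulation factor f_D per force, with
  segmented Pearson correlations around the catch–slip turn point;
* :func:`run_rupture_analysis` — force-ramp traces → rupture force/time
  and pathway classification with per-type aggregates.

All reports are plain DataFrames/dataclasses with ``write`` methods that
emit CSV/JSON, so identical inputs and configuration produce byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import connectivity, forcecurve, geomdesc, interactions, runstats, sasa
from .structio import ForceTrace, Trajectory, select

__all__ = [
    "AnalysisConfig",
    "EquilibriumReport",
    "SweepReport",
    "RuptureReport",
    "run_equilibrium_analysis",
    "run_force_sweep_analysis",
    "run_rupture_analysis",
]


@dataclass
class AnalysisConfig:
    """Analysis parameters; every default mirrors the standard protocol."""

    ligand_selection: str = "chain L"
    receptor_selection: str = "chain R"
    hbond_distance_cutoff_A: float = 3.5
    hbond_angle_cutoff_deg: float = 30.0
    hbond_angle_convention: str = "donor-vertex"
    salt_bridge_cutoff_A: float = 4.0
    sasa_probe_radius_A: float = 1.4
    sasa_n_sphere_points: int = 960
    pathway_threshold_pN: float = 200.0
    clamp_forces_pN: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0)
    clamp_tolerance_pN: float = 10.0
    turn_point_pN: float = 60.0
    top_k: int = 6
    fd_aggregation: str = "mean-of-ratios"  # or 'ratio-of-means'
    gamma_anchors: list[str] | None = None  # four 'chain:resid:name' atoms
    theta_segment_a: str | None = None
    theta_segment_b: str | None = None
    lf_atoms: list[str] | None = None  # two 'chain:resid:name' atoms
    seed: int = 0

    @property
    def hbond_criteria(self) -> interactions.HBondCriteria:
        return interactions.HBondCriteria(
            d_cut_A=self.hbond_distance_cutoff_A,
            angle_cut_deg=self.hbond_angle_cutoff_deg,
            angle_convention=self.hbond_angle_convention,
        )

    @property
    def sasa_params(self) -> sasa.SasaParams:
        return sasa.SasaParams(
            probe_radius_A=self.sasa_probe_radius_A,
            n_sphere_points=self.sasa_n_sphere_points,
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "clamp_forces_pN" in data:
            data["clamp_forces_pN"] = tuple(float(x) for x in data["clamp_forces_pN"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["clamp_forces_pN"] = list(self.clamp_forces_pN)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _raster_for(traj: Trajectory, config: AnalysisConfig) -> interactions.BondRaster:
    ga = select(traj, config.ligand_selection)
    gb = select(traj, config.receptor_selection)
    return interactions.build_raster(traj, ga, gb, config.hbond_criteria)


# --------------------------------------------------------------------------
# Equilibrium analysis


@dataclass
class EquilibriumReport:
    occupancy_table: pd.DataFrame
    nhb: list[np.ndarray]
    gaussian_fits: list[runstats.GaussianFitResult | None]
    rmsf: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_runs: int = 0

    @property
    def empty(self) -> bool:
        return self.occupancy_table.empty

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.occupancy_table.to_csv(out / "occupancy_table.csv", index=False)
        for k, series in enumerate(self.nhb, start=1):
            pd.DataFrame({"frame": np.arange(len(series)), "N_HB": series}).to_csv(
                out / f"nhb_run{k}.csv", index=False
            )
        fits = [
            None if g is None else asdict(g) for g in self.gaussian_fits
        ]
        (out / "gaussian_fits.json").write_text(json.dumps(fits, indent=2))
        for name, df in self.rmsf.items():
            df.to_csv(out / f"rmsf_{name}.csv", index=False)


def run_equilibrium_analysis(
    trajs: Sequence[Trajectory],
    config: AnalysisConfig = AnalysisConfig(),
) -> EquilibriumReport:
    """Replica equilibrium analysis: ranked occupancy table, N_HB, RMSF.

    The table has one row per interface residue pair with per-run occupancy
    percentages and mean ± sample-SD columns, ranked by mean occupancy and
    truncated to the ``top_k`` pairs.  Pairs absent from a run contribute
    0 % for that run.
    """
    if not trajs:
        raise ValueError("need at least one replica trajectory")
    n_runs = len(trajs)
    pair_occ: dict[tuple[str, str], dict[int, float]] = {}
    nhb_list: list[np.ndarray] = []
    fits: list[runstats.GaussianFitResult | None] = []
    for r, traj in enumerate(trajs):
        raster = _raster_for(traj, config)
        occ = interactions.occupancy(raster)
        for (lig, rec), grp in occ.groupby(["ligand_residue", "receptor_residue"]):
            pair_occ.setdefault((lig, rec), {})[r] = float(
                grp["pair_occupancy"].iloc[0]
            )
        series = interactions.nhb_series(raster)
        nhb_list.append(series)
        values, counts = np.unique(series, return_counts=True)
        try:
            fits.append(runstats.gaussian_fit(values, counts))
        except ValueError:
            fits.append(None)

    rows = []
    for (lig, rec), per_run in pair_occ.items():
        occs = [100.0 * per_run.get(r, 0.0) for r in range(n_runs)]
        agg = runstats.aggregate_runs(occs)
        row = {"ligand_residue": lig, "receptor_residue": rec}
        row.update({f"run{r + 1}_pct": occs[r] for r in range(n_runs)})
        row["mean_pct"] = agg.mean
        row["sd_pct"] = agg.sd
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = (
            table.sort_values("mean_pct", ascending=False, kind="mergesort")
            .head(config.top_k)
            .reset_index(drop=True)
        )

    rmsf_tables: dict[str, pd.DataFrame] = {}
    for name, expr in (
        ("ligand", f"({config.ligand_selection}) and name CA"),
        ("receptor", f"({config.receptor_selection}) and name CA"),
    ):
        try:
            sel = select(trajs[0], expr)
            if sel.size >= 3 and trajs[0].n_frames >= 2:
                per_run_rmsf = np.column_stack(
                    [geomdesc.rmsf(t, sel) for t in trajs]
                )
                rmsf_tables[name] = pd.DataFrame(
                    {
                        "resid": [trajs[0].atoms[int(k)].resid for k in sel],
                        **{
                            f"run{r + 1}_A": per_run_rmsf[:, r]
                            for r in range(n_runs)
                        },
                    }
                )
        except geomdesc.DegenerateGeometryError:
            pass
    return EquilibriumReport(
        occupancy_table=table,
        nhb=nhb_list,
        gaussian_fits=fits,
        rmsf=rmsf_tables,
        n_runs=n_runs,
    )


# --------------------------------------------------------------------------
# Force sweep


@dataclass
class SweepReport:
    per_force: pd.DataFrame
    per_replica: pd.DataFrame
    correlations: dict[str, dict[str, float]]
    turn_point_pN: float

    @property
    def fd_minimum_force_pN(self) -> float:
        k = self.per_force["f_D"].idxmin()
        return float(self.per_force.loc[k, "force_pN"])

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_force.to_csv(out / "sweep_per_force.csv", index=False)
        self.per_replica.to_csv(out / "sweep_per_replica.csv", index=False)
        payload = {
            "turn_point_pN": self.turn_point_pN,
            "fd_minimum_force_pN": self.fd_minimum_force_pN,
            "correlations": self.correlations,
        }
        (out / "sweep_summary.json").write_text(json.dumps(payload, indent=2))


def run_force_sweep_analysis(
    trajectories_by_force: Mapping[float, Sequence[Trajectory]],
    config: AnalysisConfig = AnalysisConfig(),
) -> SweepReport:
    """Clamp-force sweep: occupancies → P_D → f_D per force.

    ``trajectories_by_force`` maps each clamp force (pN) to its replica
    trajectories; the zero-force set is required since f_D normalises by it.
    f_D is aggregated as the mean of per-replica ratios by default
    (``config.fd_aggregation='ratio-of-means'`` switches to the ratio of
    mean P_D values).  Pearson correlations of f_D and N_HB against force
    are reported separately for the segments at-or-below and at-or-above
    the configured turn point.
    """
    forces = sorted(trajectories_by_force)
    if 0.0 not in [float(f) for f in forces]:
        raise ValueError("the zero-force replica set is required to compute f_D")

    rep_rows = []
    for f in forces:
        for r, traj in enumerate(trajectories_by_force[f]):
            raster = _raster_for(traj, config)
            occ = interactions.occupancy(raster)
            if occ.empty:
                p_d = 1.0
            else:
                cpm = connectivity.ContactProbabilityMatrix.from_occupancies(occ)
                p_d = connectivity.dissociation_probability(cpm, force_pN=f).P_D
            rep_rows.append(
                {
                    "force_pN": float(f),
                    "replica": r,
                    "P_D": p_d,
                    "mean_N_HB": float(interactions.nhb_series(raster).mean()),
                    "n_bonds": len(raster.bonds),
                }
            )
    per_replica = pd.DataFrame(rep_rows)

    zero = per_replica[per_replica["force_pN"] == 0.0].set_index("replica")["P_D"]
    if (zero == 0).any():
        raise ZeroDivisionError("a zero-force replica has P_D = 0; f_D undefined")
    per_replica["f_D"] = [
        row.P_D / zero[row.replica] if row.replica in zero.index else np.nan
        for row in per_replica.itertuples()
    ]

    force_rows = []
    for f in forces:
        sub = per_replica[per_replica["force_pN"] == float(f)]
        if config.fd_aggregation == "ratio-of-means":
            fd = float(sub["P_D"].mean() / zero.mean())
        else:
            fd = float(sub["f_D"].mean())
        force_rows.append(
            {
                "force_pN": float(f),
                "mean_P_D": float(sub["P_D"].mean()),
                "f_D": fd,
                "f_D_sd": float(sub["f_D"].std(ddof=1)) if len(sub) > 1 else np.nan,
                "mean_N_HB": float(sub["mean_N_HB"].mean()),
            }
        )
    per_force = pd.DataFrame(force_rows)

    correlations: dict[str, dict[str, float]] = {}
    for var in ("f_D", "mean_N_HB"):
        correlations[var] = {}
        for seg, mask in (
            ("below", per_replica["force_pN"] <= config.turn_point_pN),
            ("above", per_replica["force_pN"] >= config.turn_point_pN),
        ):
            sub = per_replica[mask]
            try:
                r, p = runstats.pearson(sub["force_pN"], sub[var])
                correlations[var][f"{seg}_r"] = r
                correlations[var][f"{seg}_p"] = p
            except ValueError:
                correlations[var][f"{seg}_r"] = float("nan")
                correlations[var][f"{seg}_p"] = float("nan")

    return SweepReport(
        per_force=per_force,
        per_replica=per_replica,
        correlations=correlations,
        turn_point_pN=config.turn_point_pN,
    )


# --------------------------------------------------------------------------
# Rupture analysis


@dataclass
class RuptureReport:
    table: pd.DataFrame
    per_type: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "rupture_table.csv", index=False)
        self.per_type.to_csv(out / "rupture_per_type.csv", index=False)
        (out / "rupture_report.json").write_text(
            json.dumps(
                {
                    "traces": self.table.to_dict(orient="records"),
                    "per_type": self.per_type.to_dict(orient="records"),
                },
                indent=2,
            )
        )


def run_rupture_analysis(
    traces: Sequence[ForceTrace],
    config: AnalysisConfig = AnalysisConfig(),
    labels: Sequence[str] | None = None,
) -> RuptureReport:
    """Per-trace rupture force/time and pathway type, with per-type means."""
    if not traces:
        raise ValueError("need at least one force trace")
    labels = list(labels) if labels is not None else [
        f"trace{k + 1}" for k in range(len(traces))
    ]
    rows = []
    for lab, tr in zip(labels, traces):
        res = forcecurve.rupture(tr, pathway_threshold_pN=config.pathway_threshold_pN)
        rows.append(
            {
                "label": lab,
                "rupture_force_pN": res.rupture_force_pN,
                "rupture_time_ns": res.rupture_time_ns,
                "pathway_type": res.pathway_type,
            }
        )
    table = pd.DataFrame(rows)
    per_type_rows = []
    for ptype, grp in table.groupby("pathway_type"):
        fa = runstats.aggregate_runs(grp["rupture_force_pN"])
        ta = runstats.aggregate_runs(grp["rupture_time_ns"])
        per_type_rows.append(
            {
                "pathway_type": ptype,
                "n": fa.n,
                "mean_force_pN": fa.mean,
                "sd_force_pN": fa.sd,
                "mean_time_ns": ta.mean,
                "sd_time_ns": ta.sd,
            }
        )
    return RuptureReport(table=table, per_type=pd.DataFrame(per_type_rows))
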