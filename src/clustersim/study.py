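"""Factorial study orchestration: scenario grid x shift draws x replicates.

The full-scale study runs 1,000 shift-SD values x 100 replicates per ICC
level for continuous x (100,000 samples per level) and 500 x 100 per
(ICC level, target prevalence) cell for binary x.  ``scale_factor``
shrinks both factors proportionally for desk-scale runs; everything else
— the grid, the generative model, the acceptance ranges — is unchanged.

Seeding: every random draw descends from a numpy SeedSequence keyed by
(master_seed, stream_tag, scenario_index, shift_index[, replicate_index]),
so reruns are bit-identical and results do not depend on execution order
or worker count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import grids
from .estimators import FitResult, fit_both
from .evaluation import ReplicateRecord, SummaryTable, summarize
from .simulate import SimulationSpec, draw_sd_shift, generate_accepted_sample

__all__ = [
    "StudyPlan",
    "Scenario",
    "run_study",
    "run_scenario",
    "reproduce_table1",
    "records_to_frame",
    "frame_to_records",
]

log = logging.getLogger("clustersim")

_SHIFT_STREAM = 101  # stream tags keep sd_shift draws and replicate
_REP_STREAM = 202  # streams from colliding


class InfeasibleScenarioError(ValueError):
    """A scenario whose expected ICC lies outside its acceptance range."""


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial grid."""

    index: int
    x_type: str
    sd_u: float
    icc_range: tuple[float, float]
    icc_label: float
    target_prevalence: float | None = None

    @property
    def scenario_id(self) -> str:
        if self.target_prevalence is None:
            return f"cont_icc{self.icc_label:g}"
        return f"bin_p{self.target_prevalence:g}_icc{self.icc_label:g}"


@dataclass(frozen=True)
class StudyPlan:
    """Parameterization of one full (or scaled) study arm.

    Defaults reproduce the study conditions; ``scale_factor`` in (0, 1]
    multiplies both the number of shift values and the replicates per
    shift (each rounded, floored at 1).
    """

    x_type: Literal["continuous", "binary"] = "continuous"
    icc_levels: tuple[grids.IccLevel, ...] = grids.ICC_LEVELS
    target_prevalences: tuple[float, ...] = grids.TARGET_PREVALENCES
    n_shift_values: int | None = None  # default: 1000 continuous / 500 binary
    replicates_per_shift: int = 100
    beta1_true: float = 1.0
    master_seed: int = 0
    scale_factor: float = 1.0
    n_clusters: int = 100
    cluster_size: int = 100
    max_attempts: int = 10_000
    icc_estimator: Literal["realized", "fitted"] = "fitted"
    ri_method: Literal["ml", "reml"] = "ml"
    alpha: float = 0.05
    n_bins: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale_factor must lie in (0, 1]")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")
        if self.n_shift_values is None:
            default = 1000 if self.x_type == "continuous" else 500
            object.__setattr__(self, "n_shift_values", default)
        levels = tuple(
            lev if isinstance(lev, grids.IccLevel) else grids.IccLevel(
                lev[0], tuple(lev[1]), lev[2])
            for lev in self.icc_levels
        )
        object.__setattr__(self, "icc_levels", levels)
        object.__setattr__(
            self, "target_prevalences", tuple(self.target_prevalences)
        )

    @property
    def n_shift_eff(self) -> int:
        return max(1, round(self.n_shift_values * self.scale_factor))

    @property
    def replicates_eff(self) -> int:
        return max(1, round(self.replicates_per_shift * self.scale_factor))

    def scenarios(self) -> list[Scenario]:
        out: list[Scenario] = []
        if self.x_type == "continuous":
            for lev in self.icc_levels:
                out.append(Scenario(len(out), "continuous", lev.sd_u,
                                    lev.icc_range, lev.label))
        else:
            for prev in self.target_prevalences:
                for lev in self.icc_levels:
                    out.append(Scenario(len(out), "binary", lev.sd_u,
                                        lev.icc_range, lev.label, prev))
        return out

    def validate_feasible(self) -> None:
        """Fail before simulating if any scenario cannot reach its range."""
        for scen in self.scenarios():
            lo, hi = scen.icc_range
            expected = grids.icc_from_components(scen.sd_u)
            if not lo <= expected <= hi:
                raise InfeasibleScenarioError(
                    f"{scen.scenario_id}: expected ICC {expected:.5g} outside "
                    f"target range [{lo}, {hi}]"
                )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["icc_levels"] = [
            {"sd_u": lev.sd_u, "icc_range": list(lev.icc_range), "label": lev.label}
            for lev in self.icc_levels
        ]
        d["target_prevalences"] = list(self.target_prevalences)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyPlan":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: plan config must be a mapping")
        if "icc_levels" in d:
            d["icc_levels"] = tuple(
                grids.IccLevel(v["sd_u"], tuple(v["icc_range"]), v["label"])
                for v in d["icc_levels"]
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown plan keys: {sorted(unknown)}")
        return cls(**d)


def _replicate(
    plan: StudyPlan, scen: Scenario, shift_idx: int, rep_idx: int, sd_shift: float
) -> ReplicateRecord:
    rng = np.random.default_rng(
        np.random.SeedSequence(
            (plan.master_seed, _REP_STREAM, scen.index, shift_idx, rep_idx)
        )
    )
    spec = SimulationSpec(
        sd_u=scen.sd_u,
        n_clusters=plan.n_clusters,
        cluster_size=plan.cluster_size,
        beta1=plan.beta1_true,
        icc_target_range=scen.icc_range,
        x_type=scen.x_type,  # type: ignore[arg-type]
        sd_shift=sd_shift,
        target_prevalence=scen.target_prevalence,
        max_attempts=plan.max_attempts,
        icc_estimator=plan.icc_estimator,
    )
    sample = generate_accepted_sample(spec, rng)
    ols, ri = fit_both(sample, method=plan.ri_method)
    return ReplicateRecord(
        scenario_id=scen.scenario_id,
        sd_shift=sd_shift,
        sample_icc=sample.sample_icc,
        x_dispersion=sample.x_dispersion,
        ols=ols,
        ri=ri,
        icc_level=scen.icc_label,
        target_prevalence=scen.target_prevalence,
    )


def run_scenario(plan: StudyPlan, scen: Scenario) -> list[ReplicateRecord]:
    """All replicates of one scenario (n_shift_eff x replicates_eff)."""
    records: list[ReplicateRecord] = []
    for shift_idx in range(plan.n_shift_eff):
        shift_rng = np.random.default_rng(
            np.random.SeedSequence(
                (plan.master_seed, _SHIFT_STREAM, scen.index, shift_idx)
            )
        )
        sd_shift = draw_sd_shift(scen.x_type, shift_rng)  # type: ignore[arg-type]
        for rep_idx in range(plan.replicates_eff):
            records.append(_replicate(plan, scen, shift_idx, rep_idx, sd_shift))
    return records


def run_study(
    plan: StudyPlan,
    out_dir: str | Path | None = None,
    n_jobs: int = 1,
) -> tuple[list[ReplicateRecord], SummaryTable]:
    """Run every scenario of the plan; return (records, summary).

    With ``out_dir`` set, per-scenario record CSVs act as checkpoints: a
    scenario whose file already exists is loaded instead of re-simulated,
    and the summary CSV is written alongside.
    """
    plan.validate_feasible()
    scenarios = plan.scenarios()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def _one(scen: Scenario) -> list[ReplicateRecord]:
        if out_path is not None:
            ckpt = out_path / f"records_{scen.scenario_id}.csv"
            if ckpt.exists():
                log.info("%s: loading checkpoint", scen.scenario_id)
                return frame_to_records(pd.read_csv(ckpt))
        log.info(
            "%s: %d shift values x %d replicates",
            scen.scenario_id, plan.n_shift_eff, plan.replicates_eff,
        )
        recs = run_scenario(plan, scen)
        if out_path is not None:
            records_to_frame(recs).to_csv(
                out_path / f"records_{scen.scenario_id}.csv", index=False
            )
        return recs

    if n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_jobs)(delayed(_one)(s) for s in scenarios)
    else:
        chunks = [_one(s) for s in scenarios]
    records = [r for chunk in chunks for r in chunk]
    summary = summarize(records, plan.beta1_true, alpha=plan.alpha,
                        n_bins=plan.n_bins)
    if out_path is not None:
        summary.to_csv(out_path / "summary.csv")
    return records, summary


_FIT_COLS = ["beta1_hat", "se_beta1", "ci_low", "ci_high", "p_value",
             "sd_u_hat", "sd_e_hat", "converged"]


def records_to_frame(records: Sequence[ReplicateRecord]) -> pd.DataFrame:
    """Long (two rows per replicate, one per model) tidy frame."""
    rows = []
    for i, rec in enumerate(records):
        for model in ("OLS", "RI"):
            f = rec.fit(model)  # type: ignore[arg-type]
            rows.append(
                {
                    "replicate": i,
                    "scenario_id": rec.scenario_id,
                    "icc_level": rec.icc_level,
                    "target_prevalence": rec.target_prevalence,
                    "sd_shift": rec.sd_shift,
                    "sample_icc": rec.sample_icc,
                    "x_dispersion": rec.x_dispersion,
                    "model": model,
                    "beta0_hat": f.beta0_hat,
                    "beta1_hat": f.beta1_hat,
                    "se_beta1": f.se_beta1,
                    "ci_low": f.ci_low,
                    "ci_high": f.ci_high,
                    "p_value": f.p_value,
                    "sd_u_hat": f.sd_u_hat,
                    "sd_e_hat": f.sd_e_hat,
                    "icc_hat": f.icc_hat,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[ReplicateRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for _, grp in frame.groupby("replicate", sort=True):
        fits: dict[str, FitResult] = {}
        for _, row in grp.iterrows():
            fits[row["model"]] = FitResult(
                model=row["model"],
                beta0_hat=row["beta0_hat"],
                beta1_hat=row["beta1_hat"],
                se_beta1=row["se_beta1"],
                ci_low=row["ci_low"],
                ci_high=row["ci_high"],
                p_value=row["p_value"],
                sd_u_hat=row["sd_u_hat"],
                sd_e_hat=row["sd_e_hat"],
                icc_hat=row["icc_hat"],
                converged=bool(row["converged"]),
            )
        first = grp.iloc[0]
        prev = first["target_prevalence"]
        records.append(
            ReplicateRecord(
                scenario_id=first["scenario_id"],
                sd_shift=first["sd_shift"],
                sample_icc=first["sample_icc"],
                x_dispersion=first["x_dispersion"],
                ols=fits["OLS"],
                ri=fits["RI"],
                icc_level=first["icc_level"],
                target_prevalence=None if pd.isna(prev) else float(prev),
            )
        )
    return records


def reproduce_table1(
    scale_factor: float,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    n_jobs: int = 1,
    min_cell_n: int = 20,
) -> pd.DataFrame:
    """Coverage (%) of the true slope beta1 = 1 by 95% CIs, continuous x:
    6 ICC levels x dispersion fifths x {RI, OLS}, plus pooled totals and
    the published Total-column reference values for comparison.

    Cells with fewer than ``min_cell_n`` replicates are flagged in a
    ``warnings`` column.
    """
    plan = StudyPlan(
        x_type="continuous",
        beta1_true=1.0,
        master_seed=master_seed,
        scale_factor=scale_factor,
        n_bins=5,
    )
    _, summary = run_study(plan, out_dir=out_dir, n_jobs=n_jobs)
    rows = []
    for lev in plan.icc_levels:
        row: dict = {"icc_level": lev.label}
        flags = []
        sel = summary.rows[
            (summary.rows["icc_level"] == lev.label)
            & (summary.rows["metric"] == "coverage")
        ]
        for model in ("RI", "OLS"):
            for bin_label in list(range(1, 6)) + ["all"]:
                cell = sel[(sel["model"] == model)
                           & (sel["dispersion_bin"].astype(str) == str(bin_label))]
                name = f"{model}_fifth{bin_label}" if bin_label != "all" else f"{model}_total"
                if len(cell) == 1:
                    row[name] = float(cell["value"].iloc[0])
                    if int(cell["n_replicates"].iloc[0]) < min_cell_n:
                        flags.append(name)
                else:
                    row[name] = float("nan")
                    flags.append(name)
        row["RI_total_reference"] = grids.REFERENCE_COVERAGE_TOTAL_RI[lev.label]
        row["OLS_total_reference"] = grids.REFERENCE_COVERAGE_TOTAL_OLS[lev.label]
        row["warnings"] = ";".join(flags) if flags else ""
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "table1.csv", index=False)
    return table
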