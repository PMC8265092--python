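"""Metrics over Monte-Carlo replicates: deviation from the true slope,
SE ratio, 95% CI coverage, and null-rejection (Type I) rates, stratified
by ICC level, dispersion bins of the explanatory variable, and (binary x)
target prevalence.

Rates are reported in percent with a binomial Monte-Carlo SE; means carry
SD/sqrt(n).  Replicates whose RI fit did not converge are excluded from
every metric and counted per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .estimators import FitResult

__all__ = [
    "ReplicateRecord",
    "MetricValue",
    "SummaryTable",
    "EmptyStratumError",
    "deviation_from_truth",
    "se_ratio",
    "coverage_rate",
    "type1_rate",
    "assign_dispersion_bins",
    "summarize",
]

Model = Literal["OLS", "RI"]


class EmptyStratumError(ValueError):
    """A stratum contains no (converged) replicates; flagged, never 0."""


@dataclass
class ReplicateRecord:
    """Paired OLS/RI fits of one accepted sample — the atomic study row."""

    scenario_id: str
    sd_shift: float
    sample_icc: float
    x_dispersion: float
    ols: FitResult
    ri: FitResult
    icc_level: float | None = None
    target_prevalence: float | None = None

    @property
    def converged(self) -> bool:
        return self.ols.converged and self.ri.converged

    def fit(self, model: Model) -> FitResult:
        return self.ols if model == "OLS" else self.ri


@dataclass
class MetricValue:
    """A point estimate with its Monte-Carlo SE and replicate count."""

    value: float
    mc_se: float
    n: int


def deviation_from_truth(fit: FitResult, beta1_true: float) -> float:
    """Signed error of the slope estimate."""
    return fit.beta1_hat - beta1_true


def se_ratio(record: ReplicateRecord) -> float:
    """SE_RI / SE_OLS for one replicate (> 1: RI less precise)."""
    if record.ols.se_beta1 <= 0:
        raise ZeroDivisionError("OLS SE is zero; ratio undefined")
    return record.ri.se_beta1 / record.ols.se_beta1


def _converged(records: Iterable[ReplicateRecord]) -> list[ReplicateRecord]:
    return [r for r in records if r.converged]


def _rate(hits: int, n: int) -> MetricValue:
    p = hits / n
    return MetricValue(100.0 * p, 100.0 * np.sqrt(p * (1.0 - p) / n), n)


def coverage_rate(
    records: Sequence[ReplicateRecord], model: Model, beta1_true: float
) -> MetricValue:
    """Percent of 95% CIs containing the true slope."""
    recs = _converged(records)
    if not recs:
        raise EmptyStratumError("no converged replicates in stratum")
    hits = sum(
        1 for r in recs if r.fit(model).ci_low <= beta1_true <= r.fit(model).ci_high
    )
    return _rate(hits, len(recs))


def type1_rate(
    records: Sequence[ReplicateRecord], model: Model, alpha: float = 0.05
) -> MetricValue:
    """Percent of replicates rejecting slope = 0 at level alpha.

    Under a null-generated study (true slope 0) this is the Type I error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    recs = _converged(records)
    if not recs:
        raise EmptyStratumError("no converged replicates in stratum")
    hits = sum(1 for r in recs if r.fit(model).p_value < alpha)
    return _rate(hits, len(recs))


def assign_dispersion_bins(
    records: Sequence[ReplicateRecord],
    n_bins: int,
    stratify: bool = True,
) -> np.ndarray:
    """Label every record with an empirical-quantile bin (1..n_bins) of
    x_dispersion, computed within each (icc_level, target_prevalence)
    stratum (``stratify=False`` pools everything).

    Bins are equal-count up to rounding (e.g. 100 records into thirds ->
    34/33/33).  Ties at a boundary are resolved by stable sort order on
    (dispersion, record index), so the labelling is deterministic.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(records) < n_bins:
        raise ValueError("fewer records than bins")
    labels = np.zeros(len(records), dtype=np.int64)
    if stratify:
        keys = [(r.icc_level, r.target_prevalence) for r in records]
    else:
        keys = [(None, None)] * len(records)
    for key in sorted(set(keys), key=lambda k: (str(k[0]), str(k[1]))):
        idx = np.array([i for i, k in enumerate(keys) if k == key])
        disp = np.array([records[i].x_dispersion for i in idx])
        if len(idx) < n_bins:
            raise ValueError(
                f"stratum {key} has {len(idx)} records, fewer than {n_bins} bins"
            )
        if np.ptp(disp) == 0.0:
            warnings.warn(
                f"all dispersions identical in stratum {key}; "
                "every record assigned to bin 1",
                stacklevel=2,
            )
            labels[idx] = 1
            continue
        order = np.argsort(disp, kind="stable")
        sizes = [len(chunk) for chunk in np.array_split(np.arange(len(idx)), n_bins)]
        bin_of_rank = np.repeat(np.arange(1, n_bins + 1), sizes)
        labels[idx[order]] = bin_of_rank
    return labels


def _group_sizes(records: Sequence[ReplicateRecord]) -> list[int]:
    """Record counts of each (icc_level, target_prevalence) stratum."""
    counts: dict[tuple, int] = {}
    for r in records:
        key = (r.icc_level, r.target_prevalence)
        counts[key] = counts.get(key, 0) + 1
    return list(counts.values())


@dataclass
class SummaryTable:
    """Tidy aggregation of the four metric families.

    ``rows`` has one row per (icc_level, target_prevalence,
    dispersion_bin, model, metric); dispersion_bin "all" pools the
    stratum.  ``excluded`` counts non-converged replicates per stratum.
    """

    rows: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def value(
        self,
        metric: str,
        model: str,
        icc_level: float | None = None,
        dispersion_bin: str | int = "all",
        target_prevalence: float | None = None,
    ) -> float:
        """Pull one cell; raises if the selection is not unique."""
        sel = self.rows[
            (self.rows["metric"] == metric)
            & (self.rows["model"] == model)
            & (self.rows["dispersion_bin"].astype(str) == str(dispersion_bin))
        ]
        if icc_level is not None:
            sel = sel[sel["icc_level"] == icc_level]
        if target_prevalence is not None:
            sel = sel[sel["target_prevalence"] == target_prevalence]
        if len(sel) != 1:
            raise KeyError(
                f"selection ({metric}, {model}, icc={icc_level}, "
                f"bin={dispersion_bin}, prev={target_prevalence}) matched "
                f"{len(sel)} rows"
            )
        return float(sel["value"].iloc[0])

    def wide(self, metric: str, model: str) -> pd.DataFrame:
        """Pivot one metric/model to ICC-level rows x dispersion-bin columns."""
        sel = self.rows[
            (self.rows["metric"] == metric) & (self.rows["model"] == model)
        ]
        return sel.pivot_table(
            index=["icc_level", "target_prevalence"],
            columns="dispersion_bin",
            values="value",
            dropna=False,
        )


def _metric_rows(
    recs: list[ReplicateRecord], beta1_true: float, alpha: float
) -> list[tuple[str, str, MetricValue]]:
    """(model, metric, value) triples for one stratum of converged records."""
    out: list[tuple[str, str, MetricValue]] = []
    n = len(recs)
    for model in ("OLS", "RI"):
        devs = np.array([deviation_from_truth(r.fit(model), beta1_true) for r in recs])
        sd = float(np.std(devs, ddof=1)) if n > 1 else float("nan")
        out.append((model, "mean_deviation",
                    MetricValue(float(devs.mean()), sd / np.sqrt(n), n)))
        out.append((model, "sd_beta1", MetricValue(sd, float("nan"), n)))
        out.append((model, "coverage", coverage_rate(recs, model, beta1_true)))
        out.append((model, "rejection_rate", type1_rate(recs, model, alpha)))
    ratios = np.array([se_ratio(r) for r in recs])
    rsd = float(np.std(ratios, ddof=1)) if n > 1 else float("nan")
    out.append(("RI/OLS", "mean_se_ratio",
                MetricValue(float(ratios.mean()), rsd / np.sqrt(n), n)))
    return out


def summarize(
    records: Sequence[ReplicateRecord],
    beta1_true: float,
    alpha: float = 0.05,
    n_bins: int = 5,
) -> SummaryTable:
    """Aggregate replicate records into a tidy SummaryTable.

    Within every (icc_level, target_prevalence) stratum, metrics are
    reported pooled ("all") and by empirical-quantile dispersion bins
    (1..n_bins).  Under a null study (beta1_true = 0) ``rejection_rate``
    is the Type I error and equals 100 - coverage exactly.
    """
    if not records:
        raise ValueError("no records to summarize")
    records = list(records)
    conv_mask = np.array([r.converged for r in records])
    bins = np.zeros(len(records), dtype=np.int64)
    conv_idx = np.flatnonzero(conv_mask)
    conv_records = [records[i] for i in conv_idx]
    if conv_records:
        # clamp so a stratum smaller than n_bins degrades to fewer bins
        # instead of failing a whole study summary
        smallest = min(_group_sizes(conv_records))
        n_bins_eff = min(n_bins, smallest)
        if n_bins_eff < n_bins:
            warnings.warn(
                f"smallest stratum has {smallest} converged replicates; "
                f"using {n_bins_eff} dispersion bins instead of {n_bins}",
                stacklevel=2,
            )
        bins[conv_idx] = assign_dispersion_bins(conv_records, n_bins_eff)

    keys = [(r.icc_level, r.target_prevalence) for r in records]
    rows = []
    excluded = []
    for key in sorted(set(keys), key=lambda k: (str(k[0]), str(k[1]))):
        idx = [i for i, k in enumerate(keys) if k == key]
        stratum = [records[i] for i in idx]
        n_excl = sum(1 for r in stratum if not r.converged)
        excluded.append(
            {"icc_level": key[0], "target_prevalence": key[1], "excluded": n_excl}
        )
        groups: dict[str | int, list[ReplicateRecord]] = {
            "all": [r for r in stratum if r.converged]
        }
        for i in idx:
            if conv_mask[i]:
                groups.setdefault(int(bins[i]), []).append(records[i])
        for bin_label, recs in groups.items():
            if not recs:
                continue
            for model, metric, mv in _metric_rows(recs, beta1_true, alpha):
                rows.append(
                    {
                        "icc_level": key[0],
                        "target_prevalence": key[1],
                        "dispersion_bin": bin_label,
                        "model": model,
                        "metric": metric,
                        "value": mv.value,
                        "mc_se": mv.mc_se,
                        "n_replicates": mv.n,
                    }
                )
    return SummaryTable(rows=pd.DataFrame(rows), excluded=pd.DataFrame(excluded))
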