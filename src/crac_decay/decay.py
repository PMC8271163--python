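"""First-order mRNA decay fitting from SLAM-seq conversion time courses.

T->C conversion rates are computed after technical replicates are pooled
(sum of counts, not mean of rates), normalized to the t = 0 rate per gene,
and fitted with nonlinear least squares to y(t) = exp(-lambda t) with
lambda >= 0. The half-life is ln2 / lambda. A log-linear regression of
ln y on t provides the initial value (and serves as an independent check
of the fit in the test-suite).
"""

from __future__ import annotations

import enum
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LN2 = float(np.log(2.0))


class FitStatus(str, enum.Enum):
    ok = "ok"
    no_converge = "no_converge"
    insufficient = "insufficient"
    degenerate = "degenerate"


@dataclass
class ConversionSeries:
    gene_id: str
    timepoints: np.ndarray  # minutes, strictly increasing, includes 0
    rates: np.ndarray  # tc_count / t_coverage
    normalized: np.ndarray  # rates / rate(t=0)
    coverage: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError(f"{self.gene_id}: timepoints not strictly increasing")


@dataclass
class DecayFit:
    gene_id: str
    status: FitStatus
    decay_rate: float = float("nan")  # lambda, per minute
    t_half: float = float("nan")  # minutes
    rss: float = float("nan")
    n_points: int = 0


def collapse_technical(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool technical replicates by summing counts per (gene, timepoint).

    Summing counts before forming rates weights replicates by their
    coverage, unlike a mean of per-replicate rates. Timepoints with zero
    pooled coverage are flagged in the ``missing`` column.
    """
    required = {"gene_id", "timepoint", "tech_rep", "t_coverage", "tc_count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    pooled = (
        counts.groupby(["gene_id", "timepoint"], as_index=False)[
            ["t_coverage", "tc_count"]
        ].sum()
    )
    pooled["missing"] = pooled["t_coverage"] == 0
    return pooled


def series_from_counts(
    pooled: pd.DataFrame, min_coverage: int = 1
) -> tuple[list[ConversionSeries], list[str]]:
    """Build normalized per-gene series; genes unusable at t=0 are excluded.

    A gene is excluded (and reported) when t = 0 is missing, has coverage
    below ``min_coverage``, or has a zero conversion rate — normalization
    to t0 is then undefined.
    """
    out: list[ConversionSeries] = []
    excluded: list[str] = []
    for gene, grp in pooled.groupby("gene_id", sort=True):
        grp = grp.sort_values("timepoint")
        t = grp["timepoint"].to_numpy(dtype=float)
        cov = grp["t_coverage"].to_numpy(dtype=float)
        tc = grp["tc_count"].to_numpy(dtype=float)
        usable = cov >= max(min_coverage, 1)
        if 0.0 not in t[usable]:
            excluded.append(str(gene))
            continue
        t, cov, tc = t[usable], cov[usable], tc[usable]
        rates = tc / cov
        r0 = rates[t == 0.0][0]
        if r0 <= 0:
            excluded.append(str(gene))
            continue
        out.append(
            ConversionSeries(
                gene_id=str(gene),
                timepoints=t,
                rates=rates,
                normalized=rates / r0,
                coverage=cov,
            )
        )
    return out, excluded


def normalize_series(series: ConversionSeries) -> ConversionSeries:
    """Re-normalize a series to its t = 0 rate (idempotent on built series)."""
    r0 = series.rates[series.timepoints == 0.0]
    if r0.size == 0 or r0[0] <= 0:
        raise ValueError(f"{series.gene_id}: rate at t=0 missing or zero")
    return ConversionSeries(
        gene_id=series.gene_id,
        timepoints=series.timepoints,
        rates=series.rates,
        normalized=series.rates / r0[0],
        coverage=series.coverage,
    )


def loglinear_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Decay-rate estimate from a regression of ln y on t (y > 0 points)."""
    mask = y > 0
    if mask.sum() < 2:
        return 0.0
    slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
    return float(max(-slope, 0.0))


def fit_decay(
    series: ConversionSeries,
    min_points: int = 4,
    tol: float = 1e-10,
    degenerate_rate: float = 1e-7,
) -> DecayFit:
    """Nonlinear least-squares fit of y(t) = exp(-lambda t), lambda >= 0.

    Initialized from the log-linear estimate. A fitted rate at or below
    ``degenerate_rate`` per minute (less than ~0.02% decay over a 24 h
    chase, i.e. no measurable decay) is reported as status ``degenerate``
    with no numeric half-life.
    """
    t = np.asarray(series.timepoints, dtype=float)
    y = np.asarray(series.normalized, dtype=float)
    finite = np.isfinite(y)
    t, y = t[finite], y[finite]
    if t.size < min_points or 0.0 not in t:
        return DecayFit(series.gene_id, FitStatus.insufficient, n_points=int(t.size))
    lam0 = max(loglinear_rate(t, y), 1e-6)
    try:
        res = least_squares(
            lambda lam: np.exp(-lam[0] * t) - y,
            x0=[lam0],
            bounds=([0.0], [np.inf]),
            xtol=tol,
            ftol=tol,
            gtol=tol,
        )
    except Exception:
        return DecayFit(series.gene_id, FitStatus.no_converge, n_points=int(t.size))
    if not res.success:
        return DecayFit(series.gene_id, FitStatus.no_converge, n_points=int(t.size))
    lam = float(res.x[0])
    rss = float(np.sum(res.fun**2))
    if lam <= degenerate_rate:
        return DecayFit(
            series.gene_id, FitStatus.degenerate, decay_rate=lam, rss=rss,
            n_points=int(t.size),
        )
    return DecayFit(
        series.gene_id,
        FitStatus.ok,
        decay_rate=lam,
        t_half=LN2 / lam,
        rss=rss,
        n_points=int(t.size),
    )


@dataclass
class DecayCurveSummary:
    group: str
    timepoints: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    median_t_half: float
    n_series: int
    n_ok_fits: int


def median_decay_curve(
    series_by_group: Mapping[str, Sequence[ConversionSeries]],
    fits_by_group: Mapping[str, Sequence[DecayFit]],
) -> dict[str, DecayCurveSummary]:
    """Per-timepoint median and quartile decay curves, plus median half-life.

    Requires >= 3 series per group; the group half-life is the median over
    status-ok fits only.
    """
    out: dict[str, DecayCurveSummary] = {}
    for group, series_list in series_by_group.items():
        if len(series_list) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 series")
        timepoints = np.asarray(series_list[0].timepoints, dtype=float)
        stack = []
        for s in series_list:
            if not np.array_equal(np.asarray(s.timepoints, dtype=float), timepoints):
                raise ValueError("series in a group must share timepoints")
            stack.append(s.normalized)
        arr = np.vstack(stack)
        ok = [f.t_half for f in fits_by_group.get(group, []) if f.status is FitStatus.ok]
        out[group] = DecayCurveSummary(
            group=group,
            timepoints=timepoints,
            median=np.median(arr, axis=0),
            q1=np.quantile(arr, 0.25, axis=0),
            q3=np.quantile(arr, 0.75, axis=0),
            median_t_half=float(np.median(ok)) if ok else float("nan"),
            n_series=len(series_list),
            n_ok_fits=len(ok),
        )
    return out


def fits_table(fits: Sequence[DecayFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (f.gene_id, f.status.value, f.decay_rate, f.t_half, f.rss, f.n_points)
            for f in fits
        ],
        columns=["gene_id", "status", "decay_rate", "t_half", "rss", "n_points"],
    )
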