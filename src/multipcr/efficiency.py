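"""Per-sequence amplification-efficiency estimation from serial coverage.

Relative coverage of template ``i`` after ``c`` cumulative PCR cycles follows
the two-parameter exponential model

    x_i(c) = x_i(0) * eps_i**c,

where ``x_i(0)`` is the synthesis bias (relative initial abundance) and
``eps_i`` the relative per-cycle amplification efficiency.  Taking logs gives
a linear system ``log x_i(c_j) = log x_i(0) + c_j * log eps_i`` which is
solved by least squares; because no parameters are shared across sequences the
sparse global system decouples into independent per-sequence two-parameter
regressions.  Estimates are finally normalised to their mean over retained
sequences.

Sequences observed in fewer than two sequencing runs are excluded from
estimation; the bottom 2% of retained sequences by estimated efficiency are
labelled "low efficiency" for classifier training.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg

from .twin import normalize_columns


@dataclasses.dataclass
class CoverageSeries:
    """Mean-normalised coverage of N sequences across M serial experiments."""

    ids: list[str]
    cycles: np.ndarray  # cumulative cycle numbers, strictly increasing, (M,)
    coverage: np.ndarray  # normalised coverage, (N, M)

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.shape != (len(self.ids), self.cycles.size):
            raise ValueError("coverage shape does not match ids x cycles")
        if (np.diff(self.cycles) <= 0).any():
            raise ValueError("cycles must be strictly increasing")
        if (self.coverage < 0).any():
            raise ValueError("coverage must be non-negative")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def runs_observed(self) -> np.ndarray:
        """Number of experiments in which each sequence has nonzero coverage."""
        return (self.coverage > 0).sum(axis=1)


def normalize_coverage(
    raw_counts: np.ndarray, cycles: Sequence[float], ids: Sequence[str]
) -> CoverageSeries:
    """Divide each experiment's counts by its mean over reference sequences."""
    return CoverageSeries(
        ids=list(ids), cycles=np.asarray(cycles), coverage=normalize_columns(raw_counts)
    )


def filter_low_occurrence(series: CoverageSeries, min_runs: int = 2) -> np.ndarray:
    """Boolean mask of sequences observed in at least ``min_runs`` runs."""
    retained = series.runs_observed >= min_runs
    if not retained.any():
        raise ValueError("no sequence passes the occurrence filter")
    return retained


def subset_series(series: CoverageSeries, mask: np.ndarray, renormalize: bool = True) -> CoverageSeries:
    """Restrict a series to masked sequences, recomputing per-run means."""
    cov = series.coverage[mask]
    if renormalize:
        cov = normalize_columns(cov)
    return CoverageSeries(
        ids=[i for i, m in zip(series.ids, mask) if m],
        cycles=series.cycles,
        coverage=cov,
    )


def _per_sequence_ols(cycles: np.ndarray, cov_row: np.ndarray) -> tuple[float, float, int]:
    """Closed-form OLS of log coverage on cycles for one sequence.

    Returns (x0, eps, n_positive).  Zero-coverage points are dropped (their
    log is undefined); sequences with fewer than two positive observations are
    unestimable and return NaNs.
    """
    pos = cov_row > 0
    n_pos = int(pos.sum())
    if n_pos < 2:
        return np.nan, np.nan, n_pos
    c = cycles[pos]
    y = np.log(cov_row[pos])
    c_mean = c.mean()
    y_mean = y.mean()
    denom = ((c - c_mean) ** 2).sum()
    slope = ((c - c_mean) * (y - y_mean)).sum() / denom
    intercept = y_mean - slope * c_mean
    return float(np.exp(intercept)), float(np.exp(slope)), n_pos


def fit_two_parameter_model(
    series: CoverageSeries, min_runs: int = 2, normalize: bool = True
) -> pd.DataFrame:
    """Estimate x0 and eps for every sequence by per-sequence log-linear OLS.

    Returns a DataFrame indexed by sequence id with columns ``x0``, ``eps``,
    ``runs_observed``, ``retained`` (passed the occurrence filter) and
    ``estimable`` (had >= 2 positive observations).  With ``normalize`` both
    parameter vectors are divided by their mean over estimable retained
    sequences.
    """
    retained = series.runs_observed >= min_runs
    x0 = np.full(series.n_sequences, np.nan)
    eps = np.full(series.n_sequences, np.nan)
    n_pos = np.zeros(series.n_sequences, dtype=int)
    for i in range(series.n_sequences):
        if not retained[i]:
            n_pos[i] = int((series.coverage[i] > 0).sum())
            continue
        x0[i], eps[i], n_pos[i] = _per_sequence_ols(series.cycles, series.coverage[i])
    estimable = retained & np.isfinite(eps)
    if not estimable.any():
        raise ValueError("no sequence is estimable")
    if normalize:
        x0 = x0 / np.nanmean(x0[estimable])
        eps = eps / np.nanmean(eps[estimable])
    return pd.DataFrame(
        {
            "x0": x0,
            "eps": eps,
            "runs_observed": series.runs_observed,
            "retained": retained,
            "estimable": estimable,
        },
        index=pd.Index(series.ids, name="id"),
    )


def fit_global_sparse(series: CoverageSeries, min_runs: int = 2, normalize: bool = True) -> pd.DataFrame:
    """Solve the full sparse log-linear system in one least-squares problem.

    Mathematically equivalent to :func:`fit_two_parameter_model` (the system is
    block-diagonal per sequence); kept as an independent route for testing.
    """
    retained = series.runs_observed >= min_runs
    rows, cols, vals, rhs = [], [], [], []
    seq_idx = np.flatnonzero(retained)
    pos_counts = {}
    r = 0
    for k, i in enumerate(seq_idx):
        pos = series.coverage[i] > 0
        pos_counts[i] = int(pos.sum())
        if pos_counts[i] < 2:
            continue
        for j in np.flatnonzero(pos):
            rows += [r, r]
            cols += [2 * k, 2 * k + 1]
            vals += [1.0, float(series.cycles[j])]
            rhs.append(np.log(series.coverage[i, j]))
            r += 1
    A = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(r, 2 * len(seq_idx)))
    sol = scipy.sparse.linalg.lsqr(A, np.asarray(rhs), atol=1e-14, btol=1e-14)[0]
    x0 = np.full(series.n_sequences, np.nan)
    eps = np.full(series.n_sequences, np.nan)
    for k, i in enumerate(seq_idx):
        if pos_counts[i] >= 2:
            x0[i] = np.exp(sol[2 * k])
            eps[i] = np.exp(sol[2 * k + 1])
    estimable = retained & np.isfinite(eps)
    if normalize:
        x0 = x0 / np.nanmean(x0[estimable])
        eps = eps / np.nanmean(eps[estimable])
    return pd.DataFrame(
        {
            "x0": x0,
            "eps": eps,
            "runs_observed": series.runs_observed,
            "retained": retained,
            "estimable": estimable,
        },
        index=pd.Index(series.ids, name="id"),
    )


def label_low_efficiency(
    estimates: pd.DataFrame,
    fraction: float = 0.02,
    include_dropouts: bool = False,
) -> pd.Series:
    """Binary labels: 1 for the bottom ``fraction`` of estimable sequences by
    eps (ties broken by (eps, id) for determinism).

    ``include_dropouts`` optionally force-labels sequences that were dropped
    for single-run occurrence as positives (they are plausible very poor
    amplifiers, but are excluded by default as unestimable).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    est = estimates[estimates["estimable"]]
    n_pos = int(np.floor(fraction * len(est)))
    order = est.reset_index().sort_values(["eps", "id"], kind="mergesort")
    positives = set(order["id"].iloc[:n_pos])
    labels = pd.Series(0, index=estimates.index, dtype=int, name="label")
    labels[labels.index.isin(positives)] = 1
    if include_dropouts:
        labels[~estimates["retained"]] = 1
    return labels


def underrepresentation_stats(
    series: CoverageSeries, thresholds: Sequence[float] = (0.30, 0.10, 0.05)
) -> pd.DataFrame:
    """Fraction of sequences below each relative-coverage threshold, per cycle
    point (the progressive-skew summary)."""
    out = {}
    for t in thresholds:
        out[t] = (series.coverage < t).mean(axis=0)
    return pd.DataFrame(out, index=pd.Index(series.cycles, name="cycles"))


def summarize_estimates(
    estimates: pd.DataFrame,
    series: CoverageSeries | None = None,
    thresholds: Sequence[float] = (0.30, 0.10, 0.05),
) -> dict:
    """JSON-ready summary: parameter quantiles and coverage-skew fractions."""
    est = estimates[estimates["estimable"]]
    qs = [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99]
    out = {
        "n_total": int(len(estimates)),
        "n_estimable": int(len(est)),
        "eps_quantiles": {str(q): float(est["eps"].quantile(q)) for q in qs},
        "x0_quantiles": {str(q): float(est["x0"].quantile(q)) for q in qs},
    }
    if series is not None:
        under = underrepresentation_stats(series, thresholds)
        out["fraction_below"] = {
            str(t): {str(int(c)): float(v) for c, v in under[t].items()}
            for t in thresholds
        }
    return out


def cycles_to_halve(relative_eff: float) -> float:
    """Number of cycles over which a relative efficiency deficit halves a
    sequence's relative abundance: ln(1/2) / ln(eps)."""
    if not (0.0 < relative_eff < 1.0):
        raise ValueError("relative efficiency must be in (0, 1) for halving")
    return float(np.log(0.5) / np.log(relative_eff))


def cycles_to_halve_rounded(relative_eff: float) -> int:
    """Integer convenience form of :func:`cycles_to_halve` (round-half-even)."""
    return round(cycles_to_halve(relative_eff))


def fold_change(relative_eff: float, cycles: float) -> float:
    """Relative-abundance factor after ``cycles`` cycles: eps**cycles.

    The underrepresentation factor is its reciprocal (e.g. eps=0.95 over 12
    cycles gives 0.54, i.e. ~2-fold underrepresentation).
    """
    if relative_eff <= 0:
        raise ValueError("relative efficiency must be positive")
    return float(relative_eff**cycles)
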