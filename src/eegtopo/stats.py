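"""Normalized pre/post change and paired active-vs-sham comparison.

Every global metric M is normalized within subject and arm to its own
pre-stimulation value,

    M_nor = (M_post - M_pre) / M_pre,

separately for the active and sham arms. The two arms are then compared
with dependent-samples (paired) t-tests across subjects, one test per
(metric, band, sparsity) cell, flagging cells with p below the
significance criterion (default 0.05, two-sided). No multiple-comparison
correction is applied across cells; the map reports raw p values so any
correction can be applied downstream.

Missing values (metric undefined at a sparsity level, or a zero
pre-value) propagate as NaN and are handled by pairwise deletion; cells
with fewer than three complete pairs, or with zero variance of the
within-subject differences, yield a missing result rather than a
fabricated statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graphmetrics import MetricCurves

MIN_PAIRS = 3


@dataclass
class NormalizedChange:
    """(post - pre)/pre per metric x band x sparsity; NaN marks missing."""

    values: np.ndarray
    metrics: tuple[str, ...]
    bands: tuple[str, ...]
    sparsity_grid: tuple[float, ...]

    def get(self, metric: str, band: str) -> np.ndarray:
        return self.values[self.metrics.index(metric), self.bands.index(band)]


def normalized_change(pre: MetricCurves, post: MetricCurves) -> NormalizedChange:
    """Elementwise (post - pre)/pre; zero or missing pre-values yield NaN."""
    if pre.sparsity_grid != post.sparsity_grid:
        raise ValueError("pre and post sparsity grids differ")
    if pre.bands != post.bands or pre.metrics != post.metrics:
        raise ValueError("pre and post metric/band axes differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (post.values - pre.values) / pre.values
    values = np.where(pre.values == 0, np.nan, values)
    return NormalizedChange(
        values=values, metrics=pre.metrics, bands=pre.bands,
        sparsity_grid=pre.sparsity_grid,
    )


@dataclass
class PairedTestResult:
    t: float
    p: float
    n_pairs: int
    reason: str = ""  # non-empty when the result is missing


def paired_test(active: np.ndarray, sham: np.ndarray) -> PairedTestResult:
    """Dependent-samples t-test on within-subject differences, two-sided.

    Subjects with a missing value in either arm are excluded pairwise.
    """
    active = np.asarray(active, float)
    sham = np.asarray(sham, float)
    if active.shape != sham.shape:
        raise ValueError("active and sham must have the same subjects")
    ok = np.isfinite(active) & np.isfinite(sham)
    n = int(ok.sum())
    if n < MIN_PAIRS:
        return PairedTestResult(np.nan, np.nan, n, reason="fewer than 3 complete pairs")
    d = active[ok] - sham[ok]
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return PairedTestResult(0.0, 1.0, n)
        return PairedTestResult(np.nan, np.nan, n, reason="degenerate variance")
    t, p = sps.ttest_rel(active[ok], sham[ok])
    return PairedTestResult(float(t), float(p), n)


@dataclass
class SignificanceMap:
    """Per-cell paired-test results for one side (left or right).

    Arrays are metric x band x sparsity; ``significant`` is exactly
    ``p < alpha``.
    """

    t: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    alpha: float
    metrics: tuple[str, ...]
    bands: tuple[str, ...]
    sparsity_grid: tuple[float, ...]
    mean_diff: np.ndarray | None = None  # mean(active - sham) normalized change
    side: str = ""

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(self.p), self.p < self.alpha, False)

    def cell(self, metric: str, band: str) -> tuple[np.ndarray, np.ndarray]:
        m, b = self.metrics.index(metric), self.bands.index(band)
        return self.t[m, b], self.p[m, b]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        sig = self.significant
        for m, metric in enumerate(self.metrics):
            for b, band in enumerate(self.bands):
                for s, sp in enumerate(self.sparsity_grid):
                    rows.append({
                        "side": self.side, "metric": metric, "band": band,
                        "sparsity": sp, "t": self.t[m, b, s], "p": self.p[m, b, s],
                        "n_pairs": int(self.n_pairs[m, b, s]),
                        "significant": bool(sig[m, b, s]),
                    })
        return pd.DataFrame(rows)


def _paired_test_cells(active: np.ndarray, sham: np.ndarray):
    """Vectorized paired t over the subject axis (axis 0) with NaN handling."""
    ok = np.isfinite(active) & np.isfinite(sham)
    d = np.where(ok, active - sham, np.nan)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(d, axis=0) / np.maximum(n, 1)
        resid = np.where(ok, d - mean, 0.0)
        var = (resid**2).sum(axis=0) / np.maximum(n - 1, 1)
        se = np.sqrt(var / np.maximum(n, 1))
        t = mean / se
    p = 2.0 * sps.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
    bad = (n < MIN_PAIRS) | ~np.isfinite(t)
    # zero differences across all subjects: t = 0/0; define as no effect
    all_zero = (var == 0) & (mean == 0) & (n >= MIN_PAIRS)
    t = np.where(all_zero, 0.0, t)
    p = np.where(all_zero, 1.0, p)
    bad = bad & ~all_zero
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return t, p, n, mean


def compare_conditions(
    active: dict[str, NormalizedChange] | list[NormalizedChange],
    sham: dict[str, NormalizedChange] | list[NormalizedChange],
    alpha: float = 0.05,
    side: str = "",
) -> SignificanceMap:
    """Paired active-vs-sham comparison per (metric, band, sparsity) cell.

    ``active`` and ``sham`` hold one :class:`NormalizedChange` per
    subject for the same side; dict inputs are matched by subject key,
    list inputs by position.
    """
    if isinstance(active, dict) != isinstance(sham, dict):
        raise ValueError("active and sham must both be dicts or both be sequences")
    if isinstance(active, dict):
        common = sorted(set(active) & set(sham))
        if set(active) != set(sham):
            raise ValueError(
                "unmatched arms: subjects differ between active and sham "
                f"({sorted(set(active) ^ set(sham))})"
            )
        act_list = [active[k] for k in common]
        sham_list = [sham[k] for k in common]
    else:
        act_list, sham_list = list(active), list(sham)
        if len(act_list) != len(sham_list):
            raise ValueError("unmatched arms: different numbers of subjects")
    if not act_list:
        raise ValueError("no subjects to compare")
    ref = act_list[0]
    for nc in act_list + sham_list:
        if (nc.metrics, nc.bands, nc.sparsity_grid) != (
            ref.metrics, ref.bands, ref.sparsity_grid
        ):
            raise ValueError("all NormalizedChange inputs must share axes")
    a = np.stack([nc.values for nc in act_list])
    s = np.stack([nc.values for nc in sham_list])
    t, p, n, mean_diff = _paired_test_cells(a, s)
    return SignificanceMap(
        t=t, p=p, n_pairs=n, alpha=alpha,
        metrics=ref.metrics, bands=ref.bands, sparsity_grid=ref.sparsity_grid,
        mean_diff=mean_diff, side=side,
    )


@dataclass
class SummaryRow:
    side: str
    band: str
    metric: str
    direction: str  # "up" | "down"
    sparsity_ranges: list[tuple[float, float]]
    n_significant: int


def summarize_significance(sig: SignificanceMap) -> list[SummaryRow]:
    """Table-style summary: per band/metric, direction and contiguous
    significant sparsity ranges."""
    rows: list[SummaryRow] = []
    flags = sig.significant
    grid = np.asarray(sig.sparsity_grid)
    for b, band in enumerate(sig.bands):
        for m, metric in enumerate(sig.metrics):
            cells = flags[m, b]
            if not cells.any():
                continue
            idx = np.nonzero(cells)[0]
            ranges: list[tuple[float, float]] = []
            start = prev = idx[0]
            for i in idx[1:]:
                if i == prev + 1:
                    prev = i
                    continue
                ranges.append((float(grid[start]), float(grid[prev])))
                start = prev = i
            ranges.append((float(grid[start]), float(grid[prev])))
            md = sig.mean_diff[m, b, cells] if sig.mean_diff is not None else np.array([0.0])
            direction = "up" if np.nanmean(md) >= 0 else "down"
            rows.append(SummaryRow(
                side=sig.side, band=band, metric=metric, direction=direction,
                sparsity_ranges=ranges, n_significant=int(cells.sum()),
            ))
    return rows


def summary_to_markdown(rows: list[SummaryRow]) -> str:
    lines = ["| Side | Band | Metric | Direction | Significant sparsity |",
             "|------|------|--------|-----------|----------------------|"]
    for r in rows:
        spans = ", ".join(
            f"{a:.2f}" if a == b else f"{a:.2f}-{b:.2f}" for a, b in r.sparsity_ranges
        )
        arrow = "↑" if r.direction == "up" else "↓"
        lines.append(f"| {r.side} | {r.band} | {r.metric} | {arrow} | {spans} |")
    return "\n".join(lines)
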