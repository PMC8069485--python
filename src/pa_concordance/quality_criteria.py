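"""Stability, reliability and validity of physical-activity measurements.

The analysis framework compares weekly minute estimates from several tools
(accelerometry at 10-s and 60-s epochs, diary, IPAQ) over two measurement
weeks T0 and T1:

* **difference parameters** — per-participant paired differences
  ``tool_a - tool_b`` within one week; missing propagates (if either source
  is missing the difference is missing for that participant);
* **stability of differences** (main statistic) — Spearman correlation of a
  difference parameter at T0 against the same parameter at T1: are the
  disagreements between two tools systematic across weeks?
* **test-retest reliability** — each tool correlated T0 vs T1;
* **concurrent validity** — all unordered tool pairs correlated within one
  week.

All correlations are Spearman's r_s with average ranks for ties, two-sided
p from the t approximation (an exact permutation option exists for n <= 10),
and percentile bootstrap confidence intervals (n = 1000 resamples of
participant pairs). Pairwise deletion throughout: each statistic uses every
participant complete for exactly the variables it involves. Significance is
judged at alpha = 0.05 on the p-value, not the CI.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateBootstrapError, UndefinedCorrelationError, ValidationError

ALPHA = 0.05
DEFAULT_N_BOOT = 1000

#: display order of tools, matching the published table layout
TOOL_ORDER = ["acc10", "acc60", "diary", "ipaq"]
TOOL_LABELS = {"acc10": "Acc 10", "acc60": "Acc 60", "diary": "Diary", "ipaq": "IPAQ"}

ADULT_TOOLS = ["acc10", "acc60", "diary", "ipaq"]
CHILD_TOOLS = ["acc10", "acc60", "diary"]  # children have no minutes questionnaire


def tool_pairs(tools: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered tool pairs in display order (6 for adults, 3 for children)."""
    ordered = [t for t in TOOL_ORDER if t in tools]
    return list(itertools.combinations(ordered, 2))


def pair_label(tool_a: str, tool_b: str) -> str:
    return f"{TOOL_LABELS.get(tool_a, tool_a)}–{TOOL_LABELS.get(tool_b, tool_b)}"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """Two aligned value vectors with NaN as missing; pairwise deletion built in."""

    x: np.ndarray
    y: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("paired sample requires equal-length 1-D vectors")
        if self.ids is not None and len(self.ids) != self.x.size:
            raise ValidationError("ids length mismatch")

    def complete(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~(np.isnan(self.x) | np.isnan(self.y))
        return self.x[keep], self.y[keep]

    @property
    def n_complete(self) -> int:
        return int((~(np.isnan(self.x) | np.isnan(self.y))).sum())


@dataclass
class DifferenceParameter:
    """Per-participant ``tool_a - tool_b`` minutes at one week (NaN = missing)."""

    tool_a: str
    tool_b: str
    intensity: str
    week: str
    values: pd.Series  # index: participant_id

    @property
    def label(self) -> str:
        return pair_label(self.tool_a, self.tool_b)


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    p_value: float
    n: int
    ci_lo: float = math.nan
    ci_hi: float = math.nan
    n_boot_used: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class SummaryRow:
    """One row of the stability summary table (numeric; rounding at render)."""

    label: str
    intensity: str
    n: int
    t0_mean: float = math.nan
    t0_sd: float = math.nan
    t0_min: float = math.nan
    t0_max: float = math.nan
    t1_mean: float = math.nan
    t1_sd: float = math.nan
    t1_min: float = math.nan
    t1_max: float = math.nan
    diff_mean: float = math.nan
    diff_sd: float = math.nan
    r_s: float = math.nan
    p: float = math.nan
    ci_lo: float = math.nan
    ci_hi: float = math.nan
    error: str = ""


# ---------------------------------------------------------------------------
# difference parameters
# ---------------------------------------------------------------------------

def _pivot(estimates: pd.DataFrame, intensity: str) -> pd.DataFrame:
    """participant x (tool, week) minutes matrix for one intensity."""
    sub = estimates[estimates["intensity"] == intensity]
    if sub.empty:
        raise ValidationError(f"no estimates for intensity {intensity!r}")
    wide = sub.pivot_table(
        index="participant_id",
        columns=["tool", "week"],
        values="minutes_per_week",
        aggfunc="first",
        dropna=False,
    )
    return wide


def _tool_week(wide: pd.DataFrame, tool: str, week: str) -> pd.Series:
    if (tool, week) not in wide.columns:
        raise ValidationError(f"tool {tool!r} at week {week!r} absent from estimates")
    return wide[(tool, week)]


def difference_parameter(
    estimates: pd.DataFrame, tool_a: str, tool_b: str, intensity: str, week: str
) -> DifferenceParameter:
    """Per-participant ``tool_a - tool_b``; missing in either source propagates."""
    wide = _pivot(estimates, intensity)
    values = _tool_week(wide, tool_a, week) - _tool_week(wide, tool_b, week)
    return DifferenceParameter(tool_a, tool_b, intensity, week, values)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _check_margins(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 complete pairs for a correlation, got {x.size}"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant margin: correlation undefined")


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    r = np.corrcoef(rx, ry)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def spearman(sample: PairedSample, method: str = "t") -> CorrelationResult:
    """Spearman's r_s with a two-sided p-value.

    ``method="t"`` uses the t approximation
    ``t = r_s * sqrt((n-2)/(1-r_s^2))`` on n-2 degrees of freedom; for
    ``|r_s| = 1`` the p-value is reported as the permutation bound ``2/n!``
    for n <= 10 and 0 beyond. ``method="exact"`` (n <= 10) enumerates all rank
    permutations and reports the two-sided tail proportion
    ``P(|r_perm| >= |r_obs|)``.
    """
    x, y = sample.complete()
    _check_margins(x, y)
    n = x.size
    r = _spearman_r(x, y)

    if method == "exact":
        if n > 10:
            raise ValidationError("exact permutation p-value limited to n <= 10")
        p = _exact_permutation_p(x, y, r)
    elif method == "t":
        if abs(r) >= 1.0 - 1e-15:
            p = 2.0 / math.factorial(n) if n <= 10 else 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        raise ValidationError(f"unknown p-value method {method!r}")
    return CorrelationResult(r_s=r, p_value=float(min(p, 1.0)), n=n)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    ry = stats.rankdata(y)
    n = x.size
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _spearman_r(x, ry[list(perm)])
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    sample: PairedSample,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for Spearman's r_s.

    Complete pairs are resampled with replacement as units; replicates with a
    constant margin (where r_s is undefined) are discarded and the usable
    count returned. More than 50% degenerate replicates raise an error.
    """
    x, y = sample.complete()
    _check_margins(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size
    reps = np.empty(n_boot)
    used = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bx, by = x[idx], y[idx]
        if np.all(bx == bx[0]) or np.all(by == by[0]):
            continue
        reps[used] = _spearman_r(bx, by)
        used += 1
    if n_boot > 0 and used < n_boot / 2:
        raise DegenerateBootstrapError(
            f"{n_boot - used}/{n_boot} bootstrap replicates had a constant margin"
        )
    if used == 0:
        return math.nan, math.nan, 0
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps[:used], [tail, 1.0 - tail])
    return float(lo), float(hi), used


def _correlate(
    x: pd.Series,
    y: pd.Series,
    n_boot: int,
    seed,
    method: str = "t",
) -> CorrelationResult:
    sample = PairedSample(x.to_numpy(float), y.to_numpy(float), ids=list(x.index))
    res = spearman(sample, method=method)
    if n_boot > 0:
        lo, hi, used = bootstrap_ci(sample, n_boot=n_boot, seed=seed)
        res = CorrelationResult(res.r_s, res.p_value, res.n, lo, hi, used)
    return res


# ---------------------------------------------------------------------------
# the three analyses
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "intensity",
    "label",
    "tool_a",
    "tool_b",
    "week",
    "n",
    "r_s",
    "p_value",
    "ci_lo",
    "ci_hi",
    "n_boot_used",
    "error",
]


def _result_row(intensity, label, tool_a, tool_b, week, res: CorrelationResult | None, err=""):
    return {
        "intensity": intensity,
        "label": label,
        "tool_a": tool_a,
        "tool_b": tool_b,
        "week": week,
        "n": res.n if res else 0,
        "r_s": res.r_s if res else math.nan,
        "p_value": res.p_value if res else math.nan,
        "ci_lo": res.ci_lo if res else math.nan,
        "ci_hi": res.ci_hi if res else math.nan,
        "n_boot_used": res.n_boot_used if res else 0,
        "error": err,
    }


def stability_analysis(
    estimates: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    intensity: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stability of differences: corr(diff at T0, diff at T1) per tool pair.

    Pairwise deletion across weeks: a participant enters a pair's correlation
    only with all four underlying values present. Rows with undefined
    correlations carry NaN statistics and an error note; the run continues.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tool_a, tool_b in pairs:
        d0 = difference_parameter(estimates, tool_a, tool_b, intensity, "T0").values
        d1 = difference_parameter(estimates, tool_a, tool_b, intensity, "T1").values
        label = pair_label(tool_a, tool_b)
        try:
            res = _correlate(d0, d1, n_boot, rng)
            rows.append(_result_row(intensity, label, tool_a, tool_b, "T0T1", res))
        except (UndefinedCorrelationError, DegenerateBootstrapError) as e:
            rows.append(_result_row(intensity, label, tool_a, tool_b, "T0T1", None, str(e)))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def reliability_analysis(
    estimates: pd.DataFrame,
    tools: Sequence[str],
    intensity: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test-retest reliability: each tool correlated T0 vs T1."""
    rng = np.random.default_rng(seed)
    rows = []
    for tool in tools:
        wide = _pivot(estimates, intensity)
        x = _tool_week(wide, tool, "T0")
        y = _tool_week(wide, tool, "T1")
        label = TOOL_LABELS.get(tool, tool)
        try:
            res = _correlate(x, y, n_boot, rng)
            rows.append(_result_row(intensity, label, tool, tool, "T0T1", res))
        except (UndefinedCorrelationError, DegenerateBootstrapError) as e:
            rows.append(_result_row(intensity, label, tool, tool, "T0T1", None, str(e)))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def validity_analysis(
    estimates: pd.DataFrame,
    tools: Sequence[str],
    intensity: str,
    week: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Concurrent validity: all unordered tool pairs within one week."""
    rng = np.random.default_rng(seed)
    rows = []
    for tool_a, tool_b in tool_pairs(tools):
        wide = _pivot(estimates, intensity)
        x = _tool_week(wide, tool_a, week)
        y = _tool_week(wide, tool_b, week)
        label = pair_label(tool_a, tool_b)
        try:
            res = _correlate(x, y, n_boot, rng)
            rows.append(_result_row(intensity, label, tool_a, tool_b, week, res))
        except (UndefinedCorrelationError, DegenerateBootstrapError) as e:
            rows.append(_result_row(intensity, label, tool_a, tool_b, week, None, str(e)))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# normality check (advisory)
# ---------------------------------------------------------------------------

def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    Advisory only: the analysis always proceeds with Spearman regardless of
    the outcome — the rank correlation needs no normality.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValidationError("normality check needs >= 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant vector: normality check undefined")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def build_summary_table(
    estimates: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    intensity: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> list[SummaryRow]:
    """Stability summary rows: per-week difference descriptives + stability r_s.

    All statistics are computed on the across-week complete subset (the
    participants entering the stability correlation), so ``diff_mean`` equals
    both ``t1_mean - t0_mean`` and the mean of per-participant T1-T0 changes.
    An empty complete subset yields an n=0 row with NaN statistics.
    """
    rng = np.random.default_rng(seed)
    rows: list[SummaryRow] = []
    for tool_a, tool_b in pairs:
        d0 = difference_parameter(estimates, tool_a, tool_b, intensity, "T0").values
        d1 = difference_parameter(estimates, tool_a, tool_b, intensity, "T1").values
        keep = d0.notna() & d1.notna()
        v0, v1 = d0[keep].to_numpy(float), d1[keep].to_numpy(float)
        row = SummaryRow(label=pair_label(tool_a, tool_b), intensity=intensity, n=int(keep.sum()))
        if row.n > 0:
            change = v1 - v0
            row.t0_mean, row.t0_sd = float(v0.mean()), float(v0.std(ddof=1)) if row.n > 1 else math.nan
            row.t0_min, row.t0_max = float(v0.min()), float(v0.max())
            row.t1_mean, row.t1_sd = float(v1.mean()), float(v1.std(ddof=1)) if row.n > 1 else math.nan
            row.t1_min, row.t1_max = float(v1.min()), float(v1.max())
            row.diff_mean = float(change.mean())
            row.diff_sd = float(change.std(ddof=1)) if row.n > 1 else math.nan
            try:
                res = _correlate(d0[keep], d1[keep], n_boot, rng)
                row.r_s, row.p = res.r_s, res.p_value
                row.ci_lo, row.ci_hi = res.ci_lo, res.ci_hi
            except (UndefinedCorrelationError, DegenerateBootstrapError) as e:
                row.error = str(e)
        rows.append(row)
    return rows


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    if isinstance(value, float) and math.isnan(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def render_summary_table(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    """Numeric summary table rounded to 2 decimals, half away from zero."""
    stat_cols = [
        "t0_mean", "t0_sd", "t0_min", "t0_max",
        "t1_mean", "t1_sd", "t1_min", "t1_max",
        "diff_mean", "diff_sd", "r_s", "ci_lo", "ci_hi",
    ]
    recs = []
    for r in rows:
        rec = {"label": r.label, "intensity": r.intensity, "n": r.n}
        for c in stat_cols:
            rec[c] = round_half_away(getattr(r, c), 2)
        rec["p"] = round_half_away(r.p, 3) if not math.isnan(r.p) else r.p
        rec["error"] = r.error
        recs.append(rec)
    return pd.DataFrame(
        recs, columns=["label", "intensity", "n", *stat_cols, "p", "error"]
    )
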