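"""Group statistics for morphometry and electrophysiology tables.

Covers the downstream comparisons between control (CTR) and conditional
knockout (cKO) groups: two-tailed Mann-Whitney tests (exact for small
tie-free samples), iterated two-sided Grubbs outlier exclusion, per-animal
aggregation, percent-change-of-means reporting, the 3-parameter Hill fit of
spike-count versus injected-current curves, and the combined "swelling
report" that contrasts per-cell volumes with per-radius Sholl profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AstromorphError, ConfigurationError

__all__ = [
    "mann_whitney_u",
    "grubbs_exclude",
    "percent_change",
    "aggregate_per_animal",
    "hill",
    "hill_fit",
    "HillFitParams",
    "holm_adjust",
    "swelling_report",
    "type_one_error_rate",
]


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney test; returns (U for the first sample, p).

    The p-value is exact (doubled one-sided tail, capped at 1) when the pooled
    sample is tie-free with n_x + n_y <= 20, and a tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_exclude(x, alpha: float = 0.05) -> tuple[np.ndarray, list[float]]:
    """Iterated two-sided Grubbs outlier exclusion at level ``alpha``.

    Repeatedly removes the most extreme value while G = max|x - mean| / sd
    exceeds the critical value; returns (retained, excluded-in-order). Samples
    with n < 3 or zero spread are returned unchanged with a warning.
    """
    vals = np.asarray(x, dtype=float)
    excluded: list[float] = []
    while True:
        n = vals.size
        if n < 3:
            if not excluded:
                warnings.warn("Grubbs test needs n >= 3; no exclusion performed")
            break
        sd = vals.std(ddof=1)
        if sd == 0:
            warnings.warn("zero standard deviation; Grubbs test skipped")
            break
        dev = np.abs(vals - vals.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > _grubbs_critical(n, alpha):
            excluded.append(float(vals[i]))
            vals = np.delete(vals, i)
        else:
            break
    return vals, excluded


def percent_change(mean_ctr: float, mean_cko: float) -> float:
    """Percent change of the cKO mean relative to the CTR mean."""
    if mean_ctr <= 0:
        raise ConfigurationError("control mean must be positive")
    return 100.0 * (mean_cko - mean_ctr) / mean_ctr


def aggregate_per_animal(table: pd.DataFrame, value_col: str = "volume_um3") -> pd.DataFrame:
    """One mean per (group, animal): the per-animal dots of the figures."""
    required = {"group", "animal_id", value_col}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"table must have columns {sorted(required)}")
    out = (
        table.groupby(["group", "animal_id"], as_index=False)[value_col]
        .mean()
        .sort_values(["group", "animal_id"])
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# Hill fit of I-V (spike count vs injected current) curves
# ---------------------------------------------------------------------------


def hill(x, a, b, c):
    """3-parameter Hill sigmoid f(x) = a*x^b / (c^b + x^b); f(c) = a/2."""
    x = np.asarray(x, dtype=float)
    xb = np.power(x, b)
    return a * xb / (np.power(c, b) + xb)


@dataclass
class HillFitParams:
    a: float  # plateau (response units)
    b: float  # steepness exponent, dimensionless
    c: float  # half-maximal current (pA)
    rss: float
    steepness: float  # = b, reported explicitly
    current_at_max_pa: float  # smallest step attaining the max observed response


def hill_fit(steps_pa, responses) -> HillFitParams:
    """Least-squares Hill fit over the positive-current steps.

    Non-positive steps are excluded (x^b is ill-defined for x <= 0 with real
    b). Initialization is a deterministic multistart: a0 = max response, c0 =
    the step whose response is nearest a0/2, b0 in {1, 2, 4}; the best
    residual sum of squares wins. The "current at maximum frequency" is the
    first observed step attaining the maximal observed response (the fitted
    plateau is only reached asymptotically).
    """
    steps = np.asarray(steps_pa, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if steps.shape != resp.shape:
        raise ConfigurationError("steps and responses must have equal length")
    if np.any(resp < 0):
        raise ConfigurationError("responses must be non-negative")
    if not np.any(resp > 0):
        raise AstromorphError("no spiking: all responses are zero")
    pos = steps > 0
    x, y = steps[pos], resp[pos]
    if x.size < 4:
        raise ConfigurationError("need at least 4 positive-current steps")

    a0 = float(y.max())
    c0 = float(x[np.argmin(np.abs(y - a0 / 2))])
    c0 = max(c0, float(x.min()))
    best = None
    for b0 in (1.0, 2.0, 4.0):
        try:
            popt, _ = optimize.curve_fit(
                hill, x, y, p0=[a0, b0, c0],
                bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((hill(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise AstromorphError("Hill fit failed to converge from all starts")
    (a, b, c), rss = best
    i_max = float(steps[resp == resp.max()].min())
    return HillFitParams(a=float(a), b=float(b), c=float(c), rss=rss,
                         steepness=float(b), current_at_max_pa=i_max)


# ---------------------------------------------------------------------------
# Swelling report
# ---------------------------------------------------------------------------


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


_METRICS = ("volume_um3", "area_um2", "soma_um3")


def swelling_report(
    ctr: pd.DataFrame,
    cko: pd.DataFrame,
    ctr_sholl: pd.DataFrame | None = None,
    cko_sholl: pd.DataFrame | None = None,
    alpha: float = 0.05,
    use_grubbs: bool = False,
) -> dict:
    """Compare CTR and cKO morphometry tables metric by metric.

    For each of volume, surface area and soma volume: group means, percent
    change, a cell-level Mann-Whitney p (optionally after Grubbs filtering)
    and, when ``animal_id`` is present, an animal-level p on per-animal means.
    Significance flags use Holm adjustment within the three-metric family.
    Sholl tables (long format: cell_id, radius_um, intersections) are compared
    separately at each radius, Holm-adjusted within the radius family.
    """
    for name, df in (("ctr", ctr), ("cko", cko)):
        if df is None or len(df) == 0:
            raise ConfigurationError(f"group {name!r} is missing or empty")

    report: dict = {"alpha": alpha, "metrics": {}, "sholl": None}
    raw_ps = []
    for metric in _METRICS:
        if metric not in ctr.columns or metric not in cko.columns:
            continue
        x = ctr[metric].dropna().to_numpy()
        y = cko[metric].dropna().to_numpy()
        if use_grubbs:
            x, _ = grubbs_exclude(x, alpha)
            y, _ = grubbs_exclude(y, alpha)
        u, p = mann_whitney_u(x, y)
        entry = {
            "mean_ctr": float(np.mean(x)),
            "mean_cko": float(np.mean(y)),
            "percent_change": percent_change(float(np.mean(x)), float(np.mean(y))),
            "percent_change_rounded": int(round(
                percent_change(float(np.mean(x)), float(np.mean(y))))),
            "U": u,
            "p_cell": p,
            "n_ctr": int(x.size),
            "n_cko": int(y.size),
        }
        if "animal_id" in ctr.columns and "animal_id" in cko.columns:
            ax = aggregate_per_animal(ctr.assign(group="CTR"), metric)[metric].to_numpy()
            ay = aggregate_per_animal(cko.assign(group="cKO"), metric)[metric].to_numpy()
            if ax.size and ay.size:
                _, entry["p_animal"] = mann_whitney_u(ax, ay)
        report["metrics"][metric] = entry
        raw_ps.append(p)

    if raw_ps:
        adj = holm_adjust(raw_ps)
        for metric, a_p in zip(report["metrics"], adj):
            report["metrics"][metric]["p_adjusted"] = float(a_p)
            report["metrics"][metric]["significant"] = bool(a_p < alpha)

    if ctr_sholl is not None and cko_sholl is not None and len(ctr_sholl) and len(cko_sholl):
        radii = sorted(set(ctr_sholl.radius_um) & set(cko_sholl.radius_um))
        rows = []
        for r in radii:
            x = ctr_sholl.loc[ctr_sholl.radius_um == r, "intersections"].to_numpy(float)
            y = cko_sholl.loc[cko_sholl.radius_um == r, "intersections"].to_numpy(float)
            if x.size == 0 or y.size == 0:
                continue
            _, p = mann_whitney_u(x, y)
            rows.append({"radius_um": float(r), "mean_ctr": float(x.mean()),
                         "mean_cko": float(y.mean()), "p": p})
        if rows:
            adj = holm_adjust([r["p"] for r in rows])
            for row, a_p in zip(rows, adj):
                row["p_adjusted"] = float(a_p)
                row["significant"] = bool(a_p < alpha)
        report["sholl"] = rows
        report["n_significant_sholl_radii"] = int(sum(r["significant"] for r in rows))
    return report


def type_one_error_rate(
    n_replicates: int = 200,
    n_cells: int = 15,
    n_animals: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    config=None,
) -> float:
    """Empirical type-I error of the swelling report's primary volume test.

    Each replicate draws two groups of ``n_cells`` cells from the same
    morphology distribution (the generator's analytic measurement tables) and
    tests cell-level volume; returns the rejection fraction at ``alpha``.
    """
    from .synthgen import SimulationConfig, sample_morphometry_table

    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = sample_morphometry_table(cfg, n_cells, n_animals, "CTR", rng)
        b = sample_morphometry_table(cfg, n_cells, n_animals, "cKO", rng)
        _, p = mann_whitney_u(a.volume_um3.to_numpy(), b.volume_um3.to_numpy())
        if p < alpha:
            rejections += 1
    return rejections / n_replicates
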