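"""Evaluation suite: prediction accuracy and foraging path statistics.

The statistics are the field's standard descriptors of a selection path:

* number of runs and maximum run length (maximal blocks of one target class);
* PAO, the percentage by which the travelled path exceeds the shortest
  Hamiltonian path through the same points (free endpoints);
* best-r, the larger absolute Pearson correlation of selection order with
  the x or y coordinate (high for systematic sweeps);
* intersection rate, the number of crossings between non-consecutive path
  segments;
* the Levy exponent mu, the maximum-likelihood power-law tail index of the
  inter-selection distances (continuous variant, x_min chosen by
  Kolmogorov-Smirnov minimisation).

Prediction accuracy scores item-wise model predictions against observed
selections, with an analytic chance baseline: predicting uniformly among
the items remaining at each of the N selection steps succeeds with average
probability H(N)/N (H the harmonic number).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .model import DataValidationError, InvalidParameterError

__all__ = [
    "PathStatistics",
    "AccuracyReport",
    "LevyFit",
    "chance_baseline",
    "count_runs",
    "max_run_length",
    "shortest_hamiltonian_path",
    "pao",
    "best_r",
    "intersection_rate",
    "levy_exponent",
    "path_statistics",
    "path_statistics_table",
    "prediction_accuracy",
    "switch_confusion",
    "statistic_error_summary",
]

STATISTIC_NAMES = (
    "n_runs",
    "max_run_length",
    "pao",
    "best_r",
    "intersection_rate",
    "levy_mu",
)


# ---------------------------------------------------------------------------
# Chance baseline
# ---------------------------------------------------------------------------

def chance_baseline(n_items: int) -> float:
    """Expected accuracy of guessing uniformly among remaining items.

    Averaged over all N selection steps of an exhaustive trial this is
    mean_i 1/(N - i + 1) = H(N)/N.
    """
    if n_items < 1:
        raise InvalidParameterError("n_items must be >= 1")
    return float(np.mean(1.0 / np.arange(1, n_items + 1)))


# ---------------------------------------------------------------------------
# Run statistics
# ---------------------------------------------------------------------------

def _run_lengths(class_sequence) -> list[int]:
    seq = list(class_sequence)
    if not seq:
        raise DataValidationError("class sequence must be nonempty")
    return [len(list(g)) for _, g in groupby(seq)]


def count_runs(class_sequence) -> int:
    """Number of maximal same-class blocks in the selection sequence."""
    return len(_run_lengths(class_sequence))


def max_run_length(class_sequence) -> int:
    """Length of the longest same-class block."""
    return max(_run_lengths(class_sequence))


# ---------------------------------------------------------------------------
# PAO: percentage above the optimal (shortest Hamiltonian) path
# ---------------------------------------------------------------------------

def _path_length(points: np.ndarray, order=None) -> float:
    pts = points if order is None else points[np.asarray(order)]
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def _held_karp_path(dist: np.ndarray) -> float:
    """Exact shortest open Hamiltonian path by subset dynamic programming."""
    n = dist.shape[0]
    full = (1 << n) - 1
    dp = np.full((1 << n, n), np.inf)
    for i in range(n):
        dp[1 << i, i] = 0.0
    for mask in range(1, full + 1):
        row = dp[mask]
        if not np.any(np.isfinite(row)):
            continue
        best_to = np.min(row[:, None] + dist, axis=0)
        for j in range(n):
            if mask & (1 << j):
                continue
            new_mask = mask | (1 << j)
            if best_to[j] < dp[new_mask, j]:
                dp[new_mask, j] = best_to[j]
    return float(dp[full].min())


def _two_opt_path(points: np.ndarray, max_rounds: int = 50) -> float:
    """Nearest-neighbour construction + 2-opt refinement (open path)."""
    n = len(points)
    dist = np.hypot(
        points[:, None, 0] - points[None, :, 0],
        points[:, None, 1] - points[None, :, 1],
    )
    # nearest-neighbour tours from a few starts, keep the best
    best_order, best_len = None, np.inf
    for start in range(min(n, 8)):
        order = [start]
        left = set(range(n)) - {start}
        while left:
            last = order[-1]
            nxt = min(left, key=lambda j: dist[last, j])
            order.append(nxt)
            left.discard(nxt)
        length = _path_length(points, order)
        if length < best_len:
            best_order, best_len = order, length
    order = np.array(best_order)
    for _ in range(max_rounds):
        improved = False
        for i in range(n - 2):
            for j in range(i + 2, n):
                # reverse order[i+1 .. j]; endpoints are free
                a = dist[order[i], order[i + 1]]
                b = dist[order[j - 1], order[j]] if j < n - 1 else 0.0
                c = dist[order[i], order[j - 1]]
                d = dist[order[i + 1], order[j]] if j < n - 1 else 0.0
                if c + d < a + b - 1e-12:
                    order[i + 1 : j] = order[i + 1 : j][::-1]
                    improved = True
        if not improved:
            break
    return _path_length(points, order)


def shortest_hamiltonian_path(points, exact_threshold: int = 15) -> float:
    """Length of the shortest open path through all points.

    Exact subset-DP for up to ``exact_threshold`` points, a
    nearest-neighbour + 2-opt heuristic above (an upper bound on the true
    optimum; see docs for the consequences).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise DataValidationError("need at least two points")
    if n <= exact_threshold:
        dist = np.hypot(
            points[:, None, 0] - points[None, :, 0],
            points[:, None, 1] - points[None, :, 1],
        )
        return _held_karp_path(dist)
    return _two_opt_path(points)


def pao(points_in_selection_order) -> float:
    """Percentage of the travelled path length above the optimal path.

    0 means the observed order attains the shortest Hamiltonian path; 100
    means the path was twice as long as optimal.  The observed path itself
    is admitted as a candidate optimum, so the result is never negative
    even in the heuristic regime.
    """
    pts = np.asarray(points_in_selection_order, dtype=float)
    if len(pts) < 2:
        raise DataValidationError("PAO needs at least two points")
    actual = _path_length(pts)
    optimal = min(shortest_hamiltonian_path(pts), actual)
    if optimal == 0.0:
        return 0.0
    return float(100.0 * (actual - optimal) / optimal)


# ---------------------------------------------------------------------------
# best-r
# ---------------------------------------------------------------------------

def best_r(points_in_selection_order) -> float:
    """Best absolute Pearson correlation of selection order with x or y.

    NaN if both coordinates are constant (undefined).
    """
    pts = np.asarray(points_in_selection_order, dtype=float)
    if len(pts) < 3:
        raise DataValidationError("best_r needs at least three points")
    order = np.arange(1, len(pts) + 1, dtype=float)
    rs = []
    for axis in range(2):
        coord = pts[:, axis]
        if np.std(coord) > 0:
            rs.append(abs(np.corrcoef(order, coord)[0, 1]))
    if not rs:
        return float("nan")
    return float(max(rs))


# ---------------------------------------------------------------------------
# Intersection rate
# ---------------------------------------------------------------------------

def intersection_rate(points_in_selection_order) -> int:
    """Number of crossings between non-consecutive path segments.

    Proper crossings count once; touching at an endpoint does not count;
    collinear overlap counts as one intersection.  Paths with fewer than
    four points cannot self-intersect and return 0.
    """
    pts = np.asarray(points_in_selection_order, dtype=float)
    n = len(pts)
    if n < 4:
        return 0
    segments = [LineString([pts[i], pts[i + 1]]) for i in range(n - 1)]
    count = 0
    for i in range(len(segments)):
        for j in range(i + 2, len(segments)):
            a, b = segments[i], segments[j]
            if a.crosses(b):
                count += 1
            elif a.intersects(b):
                inter = a.intersection(b)
                if inter.geom_type in ("LineString", "MultiLineString") and (
                    inter.length > 0
                ):
                    count += 1
    return count


# ---------------------------------------------------------------------------
# Levy exponent
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevyFit:
    """Continuous power-law tail fit of inter-selection distances."""

    mu: float
    xmin: float
    n_tail: int
    degenerate: bool = False
    low_n: bool = False
    ks_distance: float = float("nan")


def levy_exponent(
    inter_item_distances,
    xmin_candidates: int = 100,
    min_tail: int = 10,
    low_n_threshold: int = 50,
) -> LevyFit:
    """Fit p(x) ~ x^-mu to the distance tail by maximum likelihood.

    x_min is chosen to minimise the Kolmogorov-Smirnov distance between the
    tail sample and the fitted power law; mu is the continuous MLE
    1 + n / sum(log(x / x_min)) above it.
    """
    x = np.asarray(inter_item_distances, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise DataValidationError("no positive distances supplied")
    if np.ptp(x) == 0.0:
        return LevyFit(
            mu=float("nan"), xmin=float(x[0]), n_tail=len(x), degenerate=True
        )
    x = np.sort(x)
    uniq = np.unique(x)
    # keep the tail identifiable: x_min candidates leaving >= min_tail points
    cutoff = x[-min_tail] if len(x) >= min_tail else x[0]
    uniq = uniq[uniq <= cutoff]
    if len(uniq) > xmin_candidates:
        idx = np.unique(
            np.linspace(0, len(uniq) - 1, xmin_candidates).astype(int)
        )
        uniq = uniq[idx]
    best = None
    for xmin in uniq:
        tail = x[x >= xmin]
        n = len(tail)
        logsum = np.sum(np.log(tail / xmin))
        if logsum <= 0:
            continue
        mu = 1.0 + n / logsum
        cdf_fit = 1.0 - (tail / xmin) ** (1.0 - mu)
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        ks = max(np.max(np.abs(ecdf_hi - cdf_fit)), np.max(np.abs(ecdf_lo - cdf_fit)))
        if best is None or ks < best[0]:
            best = (ks, mu, xmin, n)
    if best is None:
        return LevyFit(
            mu=float("nan"), xmin=float(x[0]), n_tail=len(x), degenerate=True
        )
    ks, mu, xmin, n = best
    return LevyFit(
        mu=float(mu),
        xmin=float(xmin),
        n_tail=int(n),
        low_n=len(x) < low_n_threshold,
        ks_distance=float(ks),
    )


# ---------------------------------------------------------------------------
# Per-trial bundle and tidy tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStatistics:
    """The descriptive statistics of one selection path.

    ``levy_mu`` is NaN when the trial has too few distances for a stable
    tail fit (it is usually computed on distances pooled across trials).
    """

    n_runs: int
    max_run_length: int
    pao: float
    best_r: float
    intersection_rate: int
    levy_mu: float = float("nan")


def path_statistics(
    points_in_selection_order, classes, fit_levy: bool = False
) -> PathStatistics:
    """Compute the full bundle for one trial path."""
    pts = np.asarray(points_in_selection_order, dtype=float)
    levy_mu = float("nan")
    if fit_levy and len(pts) >= 2:
        dists = np.hypot(*np.diff(pts, axis=0).T)
        fit = levy_exponent(dists)
        levy_mu = fit.mu
    return PathStatistics(
        n_runs=count_runs(classes),
        max_run_length=max_run_length(classes),
        pao=pao(pts),
        best_r=best_r(pts),
        intersection_rate=intersection_rate(pts),
        levy_mu=levy_mu,
    )


def _selected_sorted(trial_df: pd.DataFrame) -> pd.DataFrame:
    sel = trial_df[trial_df["order"] > 0]
    return sel.sort_values("order")


def path_statistics_table(
    trials: pd.DataFrame, source: str = "observed"
) -> pd.DataFrame:
    """Tidy per-participant-per-condition statistics table.

    Run/path statistics are averaged over trials; the Levy exponent is
    fitted once per participant x condition on the pooled inter-selection
    distances (single trials rarely have enough distances for a tail fit).

    Output: one row per observer x condition x statistic, with columns
    ``value`` and ``source``.
    """
    rows = []
    for (observer, condition), group in trials.groupby(
        ["observer", "condition"], sort=True
    ):
        per_trial = []
        pooled = []
        for _, tdf in group.groupby("trial"):
            sel = _selected_sorted(tdf)
            pts = sel[["x", "y"]].to_numpy()
            if len(pts) < 4:
                continue
            stats = path_statistics(pts, sel["item_class"].tolist())
            per_trial.append(stats)
            pooled.append(np.hypot(*np.diff(pts, axis=0).T))
        if not per_trial:
            continue
        values = {
            "n_runs": np.mean([s.n_runs for s in per_trial]),
            "max_run_length": np.mean([s.max_run_length for s in per_trial]),
            "pao": np.mean([s.pao for s in per_trial]),
            "best_r": np.nanmean([s.best_r for s in per_trial]),
            "intersection_rate": np.mean(
                [s.intersection_rate for s in per_trial]
            ),
            "levy_mu": levy_exponent(np.concatenate(pooled)).mu,
        }
        for stat, value in values.items():
            rows.append(
                {
                    "observer": observer,
                    "condition": condition,
                    "statistic": stat,
                    "value": value,
                    "source": source,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Item-wise prediction accuracy against observed selections."""

    overall: float
    per_participant: pd.DataFrame  # observer, accuracy, hpdi_lo, hpdi_hi
    per_position: pd.DataFrame  # order, accuracy
    chance: float
    n_selections: int


def _merge_predictions(
    predictions: pd.DataFrame, observed: pd.DataFrame
) -> pd.DataFrame:
    required = {"observer", "condition", "trial", "order", "predicted_id"}
    missing = required - set(predictions.columns)
    if missing:
        raise DataValidationError(f"predictions table missing columns {missing}")
    obs_sel = observed[observed["order"] > 0][
        ["observer", "condition", "trial", "order", "item_id"]
    ]
    keys = ["observer", "condition", "trial", "order"]
    merged = predictions.merge(obs_sel, on=keys, how="left", validate="m:1")
    if merged["item_id"].isna().any():
        raise DataValidationError(
            "predictions refer to selections absent from the observed data"
        )
    return merged


def prediction_accuracy(
    predictions: pd.DataFrame, observed: pd.DataFrame
) -> AccuracyReport:
    """Score item-wise predictions (selections after the first).

    ``predictions`` has one row per (draw, observer, condition, trial,
    order) with the predicted item id; accuracy per participant is
    summarised over draws with a 95% highest-density interval.
    """
    from .inference import hpdi

    merged = _merge_predictions(predictions, observed)
    merged = merged[merged["order"] >= 2].copy()
    if merged.empty:
        raise DataValidationError("no predictions at selection positions >= 2")
    merged["correct"] = merged["predicted_id"] == merged["item_id"]

    overall = float(merged["correct"].mean())
    per_position = (
        merged.groupby("order")["correct"].mean().rename("accuracy").reset_index()
    )
    if "draw" not in merged.columns:
        merged["draw"] = 0
    rows = []
    for observer, g in merged.groupby("observer"):
        by_draw = g.groupby("draw")["correct"].mean().to_numpy()
        if len(by_draw) >= 2:
            lo, hi = hpdi(by_draw, 0.95)
        else:
            lo = hi = float(by_draw.mean())
        rows.append(
            {
                "observer": observer,
                "accuracy": float(g["correct"].mean()),
                "hpdi_lo": lo,
                "hpdi_hi": hi,
            }
        )
    # chance: average the analytic baseline over trials (item counts differ)
    n_by_trial = (
        observed[observed["order"] > 0]
        .groupby(["observer", "condition", "trial"])["order"]
        .max()
    )
    chance = float(np.mean([chance_baseline(int(n)) for n in n_by_trial]))
    return AccuracyReport(
        overall=overall,
        per_participant=pd.DataFrame(rows),
        per_position=per_position,
        chance=chance,
        n_selections=int(len(merged)),
    )


def switch_confusion(
    predictions: pd.DataFrame, observed: pd.DataFrame
) -> pd.DataFrame:
    """Stick/switch confusion: does the model predict class repetitions?

    Each prediction at position >= 2 is labelled stick or switch by
    comparing the predicted item's class with the class of the previously
    *observed* selection, and likewise for the observed selection.  Reports
    P(predicted stick | observed stick) and P(predicted switch | observed
    switch) per condition.
    """
    item_classes = observed[["observer", "condition", "trial", "item_id", "item_class"]]
    merged = _merge_predictions(predictions, observed)
    obs_sel = observed[observed["order"] > 0].copy()
    obs_sel["prev_order"] = obs_sel["order"] + 1
    prev = obs_sel[
        ["observer", "condition", "trial", "prev_order", "item_class"]
    ].rename(columns={"prev_order": "order", "item_class": "prev_class"})
    keys = ["observer", "condition", "trial", "order"]
    merged = merged.merge(prev, on=keys, how="left")
    merged = merged.merge(
        item_classes.rename(
            columns={"item_id": "predicted_id", "item_class": "pred_class"}
        ),
        on=["observer", "condition", "trial", "predicted_id"],
        how="left",
    )
    merged = merged.merge(
        item_classes.rename(columns={"item_class": "obs_class"}),
        on=["observer", "condition", "trial", "item_id"],
        how="left",
    )
    merged = merged[merged["order"] >= 2].dropna(subset=["prev_class"])
    merged["observed_stick"] = merged["obs_class"] == merged["prev_class"]
    merged["predicted_stick"] = merged["pred_class"] == merged["prev_class"]
    rows = []
    for condition, g in merged.groupby("condition"):
        for label, mask in (
            ("stick", g["observed_stick"]),
            ("switch", ~g["observed_stick"]),
        ):
            sub = g[mask]
            agree = (sub["predicted_stick"] == sub["observed_stick"]).mean()
            rows.append(
                {
                    "condition": condition,
                    "transition": label,
                    "accuracy": float(agree) if len(sub) else float("nan"),
                    "n": int(len(sub)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Observed-vs-predicted error summary
# ---------------------------------------------------------------------------

def statistic_error_summary(
    observed_stats: pd.DataFrame, predicted_stats: pd.DataFrame
) -> pd.DataFrame:
    """Scaled absolute error per statistic.

    Inputs are tidy tables from :func:`path_statistics_table` (matched
    observer x condition rows).  For each statistic the mean absolute
    observed-predicted difference is divided by the between-participant SD
    of the observed statistic, making errors comparable across statistics;
    a statistic whose observed values have zero spread gets NaN.
    """
    keys = ["observer", "condition", "statistic"]
    merged = observed_stats.merge(
        predicted_stats, on=keys, suffixes=("_obs", "_pred"), validate="1:1"
    )
    rows = []
    for stat, g in merged.groupby("statistic"):
        sd = float(g["value_obs"].std(ddof=1))
        err = float((g["value_obs"] - g["value_pred"]).abs().mean())
        rows.append(
            {
                "statistic": stat,
                "scaled_error": err / sd if sd > 0 else float("nan"),
                "n": int(len(g)),
            }
        )
    return pd.DataFrame(rows)
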