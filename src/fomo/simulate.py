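"""Generative machinery: populations, stimuli, and simulated foraging trials.

Three simulation modes mirror the model's generated quantities:

* ``predict_next`` — draw the next selection given a partial trial (P);
* ``simulate_trial`` — simulate a whole trial from scratch (Q);
* ``simulate_trial(..., fix_first=...)`` — same, but with the first
  selection pinned to an observed item (F).

``simulate_dataset`` ties these together into a synthetic multilevel study:
a population of observers drawn from group-level parameters, two
experimental conditions, and a fresh, slightly jittered cardinal grid of
two-class targets for every trial — the structure of typical screen-based
foraging experiments (16-58 observers, 10-20 trials per condition, 20-40
targets on a grid).

A single seeded generator drives each top-level call; nested draws consume
from it, so one seed reproduces an entire dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    CoreParams,
    DirectionParams,
    InvalidParameterError,
    InvalidStateError,
    ModelConfig,
    SelectionState,
    Stimulus,
    _von_mises_basis,
    selection_probabilities,
)

__all__ = [
    "GroupParams",
    "SimulatedDataset",
    "as_rng",
    "sample_population",
    "generate_stimulus",
    "predict_next",
    "simulate_trial",
    "simulate_dataset",
]

CORE_PARAM_NAMES = ("b_a", "b_s", "rho_delta", "rho_psi")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed (or an existing Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Group-level parameters
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Group-level (fixed-effect) parameters of a two-condition population.

    Core parameters (b_a, b_s, rho_delta, rho_psi) vary by condition and by
    observer; their per-observer deviations share a full 8x8 covariance
    (2 conditions x 4 parameters).  Direction weights theta also vary by
    condition and observer but their deviations are independent — modelling
    a full 16x16 covariance is not attempted.

    Arrays are indexed [condition, parameter].
    """

    conditions: tuple = ("feature", "conjunction")
    core_mean: np.ndarray = None  # (2, 4)
    core_sd: np.ndarray = None  # (2, 4), >= 0
    core_corr: np.ndarray = None  # (8, 8) correlation matrix
    n_directions: int = 4
    theta_mean: np.ndarray = None  # (2, K)
    theta_sd: np.ndarray = None  # (2, K), >= 0
    kappa: float = 20.0
    delta0: float = 20.0

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise InvalidParameterError("exactly two conditions are supported")
        k = self.n_directions
        self.core_mean = self._shape(self.core_mean, (2, 4), 0.0)
        self.core_sd = self._shape(self.core_sd, (2, 4), 0.0)
        self.theta_mean = self._shape(self.theta_mean, (2, k), 0.0)
        self.theta_sd = self._shape(self.theta_sd, (2, k), 0.0)
        if self.core_corr is None:
            self.core_corr = np.eye(8)
        self.core_corr = np.asarray(self.core_corr, dtype=float)
        if self.core_corr.shape != (8, 8):
            raise InvalidParameterError("core_corr must be 8x8")
        if not np.allclose(self.core_corr, self.core_corr.T):
            raise InvalidParameterError("core_corr must be symmetric")
        if not np.allclose(np.diag(self.core_corr), 1.0):
            raise InvalidParameterError("core_corr must have unit diagonal")
        if np.any(self.core_sd < 0) or np.any(self.theta_sd < 0):
            raise InvalidParameterError("random-effect SDs must be nonnegative")
        try:
            np.linalg.cholesky(self.core_corr + 1e-12 * np.eye(8))
        except np.linalg.LinAlgError:
            raise InvalidParameterError(
                "core_corr must be positive definite"
            ) from None

    @staticmethod
    def _shape(value, shape, fill):
        if value is None:
            return np.full(shape, fill, dtype=float)
        arr = np.asarray(value, dtype=float)
        if arr.shape != shape:
            arr = np.broadcast_to(arr, shape).copy()
        return arr.copy()

    def core_cov(self) -> np.ndarray:
        """Full 8x8 covariance of the stacked (condition x parameter) core
        random effects."""
        d = np.diag(self.core_sd.ravel())
        return d @ self.core_corr @ d

    def model_config(self, version: str = "v1.3") -> ModelConfig:
        return ModelConfig(version=version, delta0=self.delta0, kappa=self.kappa)


@dataclass
class ObserverParams:
    """True parameters of one simulated observer: per-condition core and
    direction parameters."""

    observer: int
    core: Mapping[str, CoreParams]
    direction: Mapping[str, DirectionParams]


def sample_population(
    gp: GroupParams, n_participants: int, seed
) -> list[ObserverParams]:
    """Draw a population of observers from the group-level distribution.

    Core deviations come from the full-covariance multivariate normal;
    theta deviations are independent normals.  With all SDs at zero every
    observer equals the group means.
    """
    rng = as_rng(seed)
    cov = gp.core_cov()
    try:
        chol = np.linalg.cholesky(cov + 1e-18 * np.eye(8))
    except np.linalg.LinAlgError:
        raise InvalidParameterError("core covariance is not positive definite")
    mean = gp.core_mean.ravel()
    core_draws = mean + rng.standard_normal((n_participants, 8)) @ chol.T
    k = gp.n_directions
    theta_draws = gp.theta_mean.ravel() + rng.standard_normal(
        (n_participants, 2 * k)
    ) * gp.theta_sd.ravel()

    observers = []
    for i in range(n_participants):
        core = {}
        direction = {}
        for c, cond in enumerate(gp.conditions):
            vals = core_draws[i, 4 * c : 4 * (c + 1)]
            core[cond] = CoreParams(*vals)
            th = theta_draws[i, k * c : k * (c + 1)]
            direction[cond] = DirectionParams(theta=tuple(th), kappa=gp.kappa)
        observers.append(ObserverParams(observer=i, core=core, direction=direction))
    return observers


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

def generate_stimulus(
    n_items: int = 40,
    n_cols: int = 8,
    n_rows: int = 5,
    jitter_sd: float = 10.0,
    class_ratio: float = 0.5,
    seed=None,
    display: tuple = (1280.0, 720.0),
) -> Stimulus:
    """Place two-class target items on a jittered cardinal grid.

    Items sit at the centres of grid cells spanning the display, displaced
    by isotropic Gaussian jitter.  Class A is assigned to
    ``round(class_ratio * n_items)`` randomly chosen positions.
    """
    if n_items > n_cols * n_rows:
        raise InvalidParameterError(
            f"cannot place {n_items} items on a {n_cols}x{n_rows} grid"
        )
    if n_items < 1:
        raise InvalidParameterError("n_items must be >= 1")
    if not 0.0 <= class_ratio <= 1.0:
        raise InvalidParameterError("class_ratio must be in [0, 1]")
    rng = as_rng(seed)
    width, height = display
    cx = (np.arange(n_cols) + 0.5) * width / n_cols
    cy = (np.arange(n_rows) + 0.5) * height / n_rows
    gx, gy = np.meshgrid(cx, cy)
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    if n_items < len(cells):
        keep = rng.choice(len(cells), size=n_items, replace=False)
        cells = cells[np.sort(keep)]
    xy = cells + rng.normal(0.0, jitter_sd, size=cells.shape)
    n_a = int(round(class_ratio * n_items))
    classes = np.array(["B"] * n_items)
    classes[rng.choice(n_items, size=n_a, replace=False)] = "A"
    return Stimulus.from_arrays(
        xy[:, 0], xy[:, 1], classes, display_bounds=(0.0, 0.0, width, height)
    )


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def predict_next(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    state: SelectionState,
    stimulus: Stimulus,
    seed,
) -> int:
    """Draw the next selected item id from the model's selection
    distribution (the item-wise prediction P)."""
    rng = as_rng(seed)
    probs = selection_probabilities(cp, dp, cfg, state, stimulus)
    idx = rng.choice(stimulus.n_items, p=probs)
    return int(stimulus.ids[idx])


class _TrialEngine:
    """Precomputed pairwise geometry for fast sequential simulation on one
    stimulus."""

    def __init__(self, stimulus, cp, dp, cfg):
        self.stimulus = stimulus
        self.cp = cp
        self.cfg = cfg
        xy = stimulus.xy
        diff = xy[None, :, :] - xy[:, None, :]
        self.dist = np.hypot(diff[..., 0], diff[..., 1]) / cfg.delta0
        with np.errstate(invalid="ignore"):
            self.phi = np.arctan2(diff[..., 1], diff[..., 0])
        is_a = stimulus.is_a
        self.log_pa = np.where(
            is_a, np.log(expit(cp.b_a)), np.log1p(-expit(cp.b_a))
        )
        # log stick weight of candidate j given current item i: (N, N)
        same = is_a[:, None] == is_a[None, :]
        self.log_ps = np.where(
            same, np.log(expit(cp.b_s)), np.log1p(-expit(cp.b_s))
        )
        self.gain = None
        if cfg.n_abs_directions and dp is not None:
            n = stimulus.n_items
            basis = _von_mises_basis(
                self.phi.ravel(), cfg.n_abs_directions, dp.kappa
            ).reshape(n, n, -1)
            self.gain = basis @ dp.theta_array()
            np.fill_diagonal(self.gain, 0.0)

    def log_weights(self, selected: list[int]) -> np.ndarray:
        """Log selection weights over stimulus indices given the indices
        selected so far."""
        log_w = self.log_pa.copy()
        if selected:
            cur = selected[-1]
            log_w += self.log_ps[cur]
            log_w += -self.cp.rho_delta * self.dist[cur]
            if self.gain is not None:
                log_w += self.gain[cur]
            if self.cfg.include_rel_dir and len(selected) >= 2:
                prev = selected[-2]
                heading = self.phi[prev, cur]
                delta = np.abs(
                    (self.phi[cur] - heading + np.pi) % (2 * np.pi) - np.pi
                )
                log_w += self.cp.rho_psi * (1.0 - delta / np.pi)
        log_w[selected] = -np.inf
        return log_w


def simulate_trial(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    stimulus: Stimulus,
    fix_first: int | None = None,
    n_select: int | None = None,
    seed=None,
) -> list[int]:
    """Simulate a trial: the ordered list of selected item ids.

    By default the run is exhaustive (all items collected, so the output is
    a permutation of the stimulus ids); ``n_select`` truncates it at a fixed
    length.  The first item is sampled from the class weights alone unless
    ``fix_first`` pins it to a given item id.
    """
    rng = as_rng(seed)
    n = stimulus.n_items
    if n_select is None:
        n_select = n
    if not 1 <= n_select <= n:
        raise InvalidParameterError(f"n_select must be in [1, {n}]")
    engine = _TrialEngine(stimulus, cp, dp, cfg)
    selected_idx: list[int] = []
    if fix_first is not None:
        selected_idx.append(stimulus.index_of(fix_first))
    while len(selected_idx) < n_select:
        log_w = engine.log_weights(selected_idx)
        log_w -= log_w.max()
        w = np.exp(log_w)
        probs = w / w.sum()
        selected_idx.append(int(rng.choice(n, p=probs)))
    return [int(stimulus.ids[i]) for i in selected_idx]


# ---------------------------------------------------------------------------
# Whole synthetic studies
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A synthetic multilevel foraging study.

    ``trials`` is the long-format table (one row per item per trial; rows
    with ``order == 0`` are inventory items that were never selected).
    ``truth`` records each observer's generating parameters for recovery
    tests.
    """

    trials: pd.DataFrame
    truth: pd.DataFrame
    group: GroupParams
    observers: list
    seed: int | None
    version: str = "v1.3"

    @property
    def config(self) -> ModelConfig:
        return self.group.model_config(self.version)


def _truth_table(observers, gp: GroupParams) -> pd.DataFrame:
    rows = []
    for obs in observers:
        for cond in gp.conditions:
            cp = obs.core[cond]
            row = {"observer": obs.observer, "condition": cond}
            row.update(dict(zip(CORE_PARAM_NAMES, cp.as_array())))
            for k, t in enumerate(obs.direction[cond].theta):
                row[f"theta_{k + 1}"] = t
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_dataset(
    gp: GroupParams,
    n_participants: int = 30,
    n_trials: int = 10,
    n_items: int = 40,
    n_cols: int = 8,
    n_rows: int = 5,
    jitter_sd: float = 10.0,
    class_ratio: float = 0.5,
    n_select: int | None = None,
    version: str = "v1.3",
    seed: int | None = 0,
) -> SimulatedDataset:
    """Simulate a full study: every observer forages ``n_trials`` trials in
    each condition, each on a freshly generated jittered grid."""
    rng = as_rng(seed)
    cfg = gp.model_config(version)
    observers = sample_population(gp, n_participants, rng)
    records = []
    for obs in observers:
        for cond in gp.conditions:
            cp = obs.core[cond]
            dp = obs.direction[cond] if cfg.n_abs_directions else None
            for trial in range(1, n_trials + 1):
                stim = generate_stimulus(
                    n_items=n_items,
                    n_cols=n_cols,
                    n_rows=n_rows,
                    jitter_sd=jitter_sd,
                    class_ratio=class_ratio,
                    seed=rng,
                )
                order = simulate_trial(
                    cp, dp, cfg, stim, n_select=n_select, seed=rng
                )
                rank = {item_id: r + 1 for r, item_id in enumerate(order)}
                for idx, item_id in enumerate(stim.ids):
                    records.append(
                        (
                            obs.observer,
                            cond,
                            trial,
                            rank.get(int(item_id), 0),
                            int(item_id),
                            stim.xy[idx, 0],
                            stim.xy[idx, 1],
                            stim.classes[idx],
                        )
                    )
    trials = pd.DataFrame(
        records,
        columns=[
            "observer",
            "condition",
            "trial",
            "order",
            "item_id",
            "x",
            "y",
            "item_class",
        ],
    )
    return SimulatedDataset(
        trials=trials,
        truth=_truth_table(observers, gp),
        group=gp,
        observers=observers,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        version=version,
    )
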