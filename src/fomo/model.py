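"""Core selection model: item weights and selection probabilities.

The model treats a foraging trial as weighted sampling without replacement.
After ``i`` selections, every remaining item ``j`` receives an unnormalised
weight

    w(j | i) = p_a(c_j) * p_s(c_j | c_i) * exp(-rho_delta * delta_j
                                               + rho_psi * psi_j)
               * exp(sum_k theta_k * vM(phi_j; mu_k, kappa))

where ``c_j`` is the item's class, ``delta_j`` its rescaled distance from the
current item, ``psi_j`` the alignment of the candidate direction with the
previous movement direction (1 = straight ahead, 0.5 = perpendicular,
0 = reversal), and ``phi_j`` its absolute compass bearing scored against a
mixture of von Mises components centred on the cardinal (and, optionally,
oblique) directions.  Normalising the weights over the remaining items gives
the selection probabilities.

Conventions (documented choices, unit-tested):

* psi = 1 - Delta/pi with a ``+rho_psi * psi`` exponent, so positive
  ``rho_psi`` encodes a forward-momentum preference.  This is
  probability-identical to putting the raw shortest angular difference in a
  negative exponent (the constant cancels in the normalisation) but rescales
  the parameter by pi.
* The directional gain is log-linear, ``exp(theta . vM)``, so positive
  ``theta_k`` attracts selections toward direction ``mu_k``.
* The class weight applies to the *candidate* item.
* First selection of a trial: class weights only (no spatial terms exist).
  Second selection: the psi term is dropped (no previous movement vector).
* y increases upward (mathematical convention); screen-coordinate data must
  be flipped by the reader.

Everything here is pure and side-effect free; all I/O lives in ``fomo.io``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, i0e, logsumexp

__all__ = [
    "FomoError",
    "InvalidParameterError",
    "InvalidStateError",
    "DataValidationError",
    "UnsupportedVersionError",
    "DegenerateWeightsError",
    "Item",
    "Stimulus",
    "SelectionState",
    "CoreParams",
    "DirectionParams",
    "ModelVersion",
    "ModelConfig",
    "CandidateFeatures",
    "MODEL_VERSIONS",
    "build_model",
    "class_weight",
    "stick_weight",
    "scaled_distance",
    "absolute_angle",
    "relative_direction",
    "direction_means",
    "von_mises_density",
    "direction_gain",
    "item_weight",
    "selection_log_weights",
    "selection_distribution",
    "selection_probabilities",
    "candidate_features",
    "trial_feature_tensor",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class FomoError(Exception):
    """Base class for all model errors."""


class InvalidParameterError(FomoError, ValueError):
    """A model parameter is outside its valid domain (non-finite, etc.)."""


class InvalidStateError(FomoError, ValueError):
    """A selection state is inconsistent with the requested operation."""


class DataValidationError(FomoError, ValueError):
    """Observed trial data violate the format contract."""


class UnsupportedVersionError(FomoError, ValueError):
    """The requested model version is not implemented."""


class DegenerateWeightsError(FomoError, ValueError):
    """All remaining candidate weights are zero; no distribution exists."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

CLASSES = ("A", "B")


@dataclass(frozen=True)
class Item:
    """A single target item: position plus class label ('A' or 'B')."""

    id: int
    x: float
    y: float
    item_class: str

    def __post_init__(self) -> None:
        if self.item_class not in CLASSES:
            raise DataValidationError(
                f"item class must be one of {CLASSES}, got {self.item_class!r}"
            )
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise DataValidationError(f"item {self.id}: coordinates must be finite")


class Stimulus:
    """An ordered collection of items forming one foraging display.

    Items may carry arbitrary (unique) integer ids; internally positions and
    classes are stored as arrays in item order.
    """

    def __init__(self, items: list[Item], display_bounds: tuple | None = None):
        if len(items) < 1:
            raise DataValidationError("a stimulus needs at least one item")
        ids = [it.id for it in items]
        if len(set(ids)) != len(ids):
            raise DataValidationError("item ids must be unique within a stimulus")
        self.items = list(items)
        self.display_bounds = display_bounds
        self.ids = np.asarray(ids, dtype=int)
        self.xy = np.array([[it.x, it.y] for it in items], dtype=float)
        self.classes = np.array([it.item_class for it in items])
        self.is_a = self.classes == "A"
        self._index = {int(i): k for k, i in enumerate(self.ids)}

    @property
    def n_items(self) -> int:
        return len(self.items)

    def index_of(self, item_id: int) -> int:
        try:
            return self._index[int(item_id)]
        except KeyError:
            raise InvalidStateError(f"unknown item id {item_id}") from None

    @classmethod
    def from_arrays(cls, x, y, item_class, ids=None, display_bounds=None) -> "Stimulus":
        x = np.asarray(x, dtype=float)
        if ids is None:
            ids = np.arange(len(x))
        items = [
            Item(int(i), float(xi), float(yi), str(c))
            for i, xi, yi, c in zip(ids, x, np.asarray(y, dtype=float), item_class)
        ]
        return cls(items, display_bounds=display_bounds)


@dataclass
class SelectionState:
    """Which items have been taken so far (ordered) and which remain."""

    selected: list[int]
    remaining: set[int]

    @classmethod
    def initial(cls, stimulus: Stimulus) -> "SelectionState":
        return cls(selected=[], remaining=set(int(i) for i in stimulus.ids))

    @classmethod
    def from_selected(cls, stimulus: Stimulus, selected) -> "SelectionState":
        selected = [int(s) for s in selected]
        if len(set(selected)) != len(selected):
            raise InvalidStateError("selected sequence contains duplicates")
        all_ids = set(int(i) for i in stimulus.ids)
        extra = set(selected) - all_ids
        if extra:
            raise InvalidStateError(f"selected ids not in stimulus: {sorted(extra)}")
        return cls(selected=selected, remaining=all_ids - set(selected))

    def advance(self, item_id: int) -> None:
        item_id = int(item_id)
        if item_id not in self.remaining:
            raise InvalidStateError(f"item {item_id} is not available for selection")
        self.remaining.discard(item_id)
        self.selected.append(item_id)


@dataclass(frozen=True)
class CoreParams:
    """Per-observer, per-condition core parameters (all on unbounded scales).

    b_a        class bias (logit scale; >0 favours class A)
    b_s        stick/switch bias (logit scale; >0 favours repeating the class)
    rho_delta  proximity tuning per rescaled-distance unit (>0 favours near)
    rho_psi    relative-direction tuning (>0 favours continuing straight)
    """

    b_a: float = 0.0
    b_s: float = 0.0
    rho_delta: float = 0.0
    rho_psi: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.b_a, self.b_s, self.rho_delta, self.rho_psi)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"core parameters must be finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.b_a, self.b_s, self.rho_delta, self.rho_psi])


def direction_means(n_components: int) -> np.ndarray:
    """Equally spaced component directions starting at 0 (radians).

    4 components -> the cardinals (0, pi/2, pi, 3pi/2); 8 adds the obliques.
    """
    if n_components not in (4, 8):
        raise InvalidParameterError("number of direction components must be 4 or 8")
    return 2.0 * np.pi * np.arange(n_components) / n_components


@dataclass(frozen=True)
class DirectionParams:
    """Absolute-direction mixture weights with a shared, fixed concentration.

    theta[k] weights a von Mises component with mean ``mu[k]``; kappa is a
    hyperparameter (not fitted) controlling how tightly each component hugs
    its direction.
    """

    theta: tuple
    kappa: float = 20.0

    def __post_init__(self) -> None:
        theta = tuple(float(t) for t in self.theta)
        object.__setattr__(self, "theta", theta)
        if len(theta) not in (4, 8):
            raise InvalidParameterError("theta must have 4 or 8 components")
        if not all(np.isfinite(t) for t in theta):
            raise InvalidParameterError("theta components must be finite")
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise InvalidParameterError(f"kappa must be positive, got {self.kappa}")

    @property
    def K(self) -> int:
        return len(self.theta)

    @property
    def mu(self) -> np.ndarray:
        return direction_means(self.K)

    def theta_array(self) -> np.ndarray:
        return np.asarray(self.theta, dtype=float)


@dataclass(frozen=True)
class ModelVersion:
    """Which optional components a model version switches on."""

    id: str
    include_rel_dir: bool
    n_abs_directions: int


MODEL_VERSIONS: dict[str, ModelVersion] = {
    "v1.0": ModelVersion("v1.0", include_rel_dir=True, n_abs_directions=0),
    "v1.2": ModelVersion("v1.2", include_rel_dir=False, n_abs_directions=0),
    "v1.3": ModelVersion("v1.3", include_rel_dir=True, n_abs_directions=4),
    "v1.4": ModelVersion("v1.4", include_rel_dir=True, n_abs_directions=8),
    "v1.5": ModelVersion("v1.5", include_rel_dir=False, n_abs_directions=4),
}


def build_model(version_id: str) -> ModelVersion:
    """Resolve a version id to its component flags.

    v1.1 (an alternative distance computation defined only in an external
    code base) is deliberately unsupported.
    """
    if version_id == "v1.1":
        raise UnsupportedVersionError(
            "v1.1 uses an alternative distance computation that is not part of "
            "this package; use v1.0 or one of v1.2-v1.5"
        )
    try:
        return MODEL_VERSIONS[version_id]
    except KeyError:
        raise UnsupportedVersionError(
            f"unknown model version {version_id!r}; "
            f"available: {sorted(MODEL_VERSIONS)}"
        ) from None


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters shared across observers.

    delta0  distance rescaling constant: all Euclidean distances are divided
            by it so rho_delta lives on the same scale as the other
            parameters (default 20 display units).
    """

    version: str = "v1.0"
    delta0: float = 20.0
    kappa: float = 20.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta0) and self.delta0 > 0):
            raise InvalidParameterError(f"delta0 must be positive, got {self.delta0}")
        build_model(self.version)

    @property
    def flags(self) -> ModelVersion:
        return build_model(self.version)

    @property
    def include_rel_dir(self) -> bool:
        return self.flags.include_rel_dir

    @property
    def n_abs_directions(self) -> int:
        return self.flags.n_abs_directions


@dataclass(frozen=True)
class CandidateFeatures:
    """Derived features and weight for one remaining candidate item."""

    item_id: int
    delta_j: float
    phi_j: float | None
    psi_j: float | None
    omega_j: float
    p_j: float


# ---------------------------------------------------------------------------
# Elementary weight components
# ---------------------------------------------------------------------------

def _check_finite_scalar(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value}")
    return value


def _check_class(c, name: str) -> str:
    if c not in CLASSES:
        raise DataValidationError(f"{name} must be 'A' or 'B', got {c!r}")
    return c


def class_weight(b_a: float, item_class: str) -> float:
    """Weight contribution of item class: invlogit(b_a) for A, complement for B."""
    b_a = _check_finite_scalar(b_a, "b_a")
    _check_class(item_class, "item_class")
    p = expit(b_a)
    return float(p if item_class == "A" else 1.0 - p)


def stick_weight(b_s: float, prev_class: str, cand_class: str) -> float:
    """Weight contribution of repeating vs. switching the previous class."""
    b_s = _check_finite_scalar(b_s, "b_s")
    _check_class(prev_class, "prev_class")
    _check_class(cand_class, "cand_class")
    p = expit(b_s)
    return float(p if prev_class == cand_class else 1.0 - p)


def scaled_distance(p, q, delta0: float = 20.0) -> float:
    """Euclidean distance between two points divided by delta0."""
    if not (np.isfinite(delta0) and delta0 > 0):
        raise InvalidParameterError(f"delta0 must be positive, got {delta0}")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.hypot(*(q - p)) / delta0)


def absolute_angle(p, q) -> float:
    """Bearing of q from p in radians, in (-pi, pi], angle 0 along +x.

    y is taken to increase upward, so pi/2 points up.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    if d[0] == 0.0 and d[1] == 0.0:
        raise InvalidStateError("angle undefined for coincident points")
    return float(np.arctan2(d[1], d[0]))


def _wrap_to_half_turn(angle_diff) -> np.ndarray:
    """Shortest angular difference |d| in [0, pi] for any raw difference."""
    return np.abs((np.asarray(angle_diff) + np.pi) % (2.0 * np.pi) - np.pi)


def relative_direction(prev, cur, cand) -> float:
    """Alignment of cur->cand with the previous movement prev->cur, in [0, 1].

    1 = candidate continues straight ahead, 0.5 = perpendicular turn,
    0 = full reversal.
    """
    heading = absolute_angle(prev, cur)
    bearing = absolute_angle(cur, cand)
    delta = _wrap_to_half_turn(bearing - heading)
    return float(1.0 - delta / np.pi)


def von_mises_density(phi, mu, kappa: float) -> np.ndarray:
    """von Mises density exp(kappa*cos(phi-mu)) / (2*pi*I0(kappa)).

    Computed with the exponentially scaled Bessel function so large kappa
    does not overflow.
    """
    if not (np.isfinite(kappa) and kappa > 0):
        raise InvalidParameterError(f"kappa must be positive, got {kappa}")
    phi = np.asarray(phi, dtype=float)
    return np.exp(kappa * (np.cos(phi - mu) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def _von_mises_basis(phi, n_components: int, kappa: float) -> np.ndarray:
    """Matrix of component densities, shape (len(phi), K)."""
    mu = direction_means(n_components)
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    return np.stack(
        [von_mises_density(phi, m, kappa) for m in mu], axis=-1
    )


def direction_gain(dp: DirectionParams, phi) -> np.ndarray:
    """Multiplicative gain exp(sum_k theta_k * vM(phi; mu_k, kappa)).

    theta = 0 gives gain 1 everywhere; positive theta_k boosts weights for
    candidates lying near direction mu_k.
    """
    basis = _von_mises_basis(phi, dp.K, dp.kappa)
    gain = np.exp(basis @ dp.theta_array())
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(gain[0])
    return gain


# ---------------------------------------------------------------------------
# Item weights and selection probabilities
# ---------------------------------------------------------------------------

def _spatial_log_terms(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    state: SelectionState,
    stimulus: Stimulus,
) -> np.ndarray:
    """Log of the distance, direction and relative-direction factors for all
    items (array over the stimulus; entries for selected items are arbitrary).

    Requires at least one previous selection.
    """
    cur = stimulus.xy[stimulus.index_of(state.selected[-1])]
    diff = stimulus.xy - cur
    dist = np.hypot(diff[:, 0], diff[:, 1]) / cfg.delta0
    log_terms = -cp.rho_delta * dist

    with np.errstate(invalid="ignore"):
        phi = np.arctan2(diff[:, 1], diff[:, 0])  # undefined only at cur itself

    if cfg.include_rel_dir and len(state.selected) >= 2:
        prev = stimulus.xy[stimulus.index_of(state.selected[-2])]
        heading = absolute_angle(prev, cur)
        psi = 1.0 - _wrap_to_half_turn(phi - heading) / np.pi
        log_terms = log_terms + cp.rho_psi * psi

    if cfg.n_abs_directions and dp is not None:
        basis = _von_mises_basis(phi, cfg.n_abs_directions, dp.kappa)
        log_terms = log_terms + basis @ dp.theta_array()

    return log_terms


def item_weight(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    state: SelectionState,
    stimulus: Stimulus,
    cand_id: int,
) -> float:
    """Unnormalised selection weight of one remaining candidate.

    Requires at least one previous selection (the first selection has no
    spatial reference point; its distribution uses class weights only and is
    handled by :func:`selection_log_weights`).
    """
    cand_id = int(cand_id)
    if cand_id in state.selected:
        raise InvalidStateError(f"item {cand_id} has already been selected")
    if cand_id not in state.remaining:
        raise InvalidStateError(f"item {cand_id} is not part of the remaining set")
    if not state.selected:
        raise InvalidStateError(
            "item_weight needs at least one previous selection; "
            "use selection_log_weights for the first selection"
        )
    j = stimulus.index_of(cand_id)
    prev_class = stimulus.classes[stimulus.index_of(state.selected[-1])]
    w = class_weight(cp.b_a, stimulus.classes[j])
    w *= stick_weight(cp.b_s, prev_class, stimulus.classes[j])
    log_spatial = _spatial_log_terms(cp, dp, cfg, state, stimulus)[j]
    return float(w * np.exp(log_spatial))


def selection_log_weights(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    state: SelectionState,
    stimulus: Stimulus,
) -> np.ndarray:
    """Log selection weights over all items (``-inf`` for selected items).

    Handles the first selection (class weights only) and the second
    selection (no relative-direction term) automatically.
    """
    if not state.remaining:
        raise InvalidStateError("no items remain to be selected")
    log_w = np.where(
        stimulus.is_a,
        np.log(expit(cp.b_a)),
        np.log1p(-expit(cp.b_a)),
    )
    if state.selected:
        prev_is_a = stimulus.is_a[stimulus.index_of(state.selected[-1])]
        same = stimulus.is_a == prev_is_a
        log_w = log_w + np.where(same, np.log(expit(cp.b_s)), np.log1p(-expit(cp.b_s)))
        log_w = log_w + _spatial_log_terms(cp, dp, cfg, state, stimulus)
    selected_idx = [stimulus.index_of(s) for s in state.selected]
    log_w[selected_idx] = -np.inf
    return log_w


def selection_distribution(weights, state: SelectionState) -> np.ndarray:
    """Normalise nonnegative weights into selection probabilities.

    ``weights`` is aligned with the stimulus item order used to build
    ``state``; previously selected items get probability exactly 0 and the
    remaining entries sum to 1.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or np.any(np.isnan(weights)):
        raise InvalidParameterError("weights must be nonnegative and not NaN")
    if not state.remaining:
        raise InvalidStateError("no items remain to be selected")
    probs = weights.copy()
    # positions of selected items: indices not in remaining
    n = len(weights)
    remaining_mask = np.zeros(n, dtype=bool)
    # state stores ids; caller guarantees id == position alignment OR passes
    # weights already in stimulus order.  We only need the mask, which the
    # caller encodes by the ids when ids are 0..n-1; otherwise use
    # selection_probabilities which handles the mapping.
    for item_id in state.remaining:
        if not 0 <= item_id < n:
            raise InvalidStateError(
                "selection_distribution requires ids aligned with weight "
                "positions; use selection_probabilities for arbitrary ids"
            )
        remaining_mask[item_id] = True
    probs[~remaining_mask] = 0.0
    total = probs.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise DegenerateWeightsError("all remaining candidate weights are zero")
    return probs / total


def selection_probabilities(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    state: SelectionState,
    stimulus: Stimulus,
) -> np.ndarray:
    """Selection probabilities over all items in stimulus order."""
    log_w = selection_log_weights(cp, dp, cfg, state, stimulus)
    log_norm = logsumexp(log_w)
    if not np.isfinite(log_norm):
        raise DegenerateWeightsError("all remaining candidate weights are zero")
    return np.exp(log_w - log_norm)


def candidate_features(
    cp: CoreParams,
    dp: DirectionParams | None,
    cfg: ModelConfig,
    state: SelectionState,
    stimulus: Stimulus,
) -> list[CandidateFeatures]:
    """Per-candidate derived features, weights and probabilities (diagnostics)."""
    if not state.selected:
        raise InvalidStateError("candidate features need at least one selection")
    probs = selection_probabilities(cp, dp, cfg, state, stimulus)
    cur = stimulus.xy[stimulus.index_of(state.selected[-1])]
    heading = None
    if len(state.selected) >= 2:
        prev = stimulus.xy[stimulus.index_of(state.selected[-2])]
        heading = absolute_angle(prev, cur)
    out = []
    for item_id in sorted(state.remaining):
        j = stimulus.index_of(item_id)
        delta = scaled_distance(cur, stimulus.xy[j], cfg.delta0)
        phi = absolute_angle(cur, stimulus.xy[j])
        psi = None
        if heading is not None:
            psi = float(1.0 - _wrap_to_half_turn(phi - heading) / np.pi)
        out.append(
            CandidateFeatures(
                item_id=item_id,
                delta_j=delta,
                phi_j=phi,
                psi_j=psi,
                omega_j=item_weight(cp, dp, cfg, state, stimulus, item_id),
                p_j=float(probs[j]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Design tensor for likelihood evaluation and fitting
# ---------------------------------------------------------------------------
#
# In the softmax the class and stick/switch normalising constants cancel, so
# the linear predictor of candidate j at step i is exactly
#
#   eta_j = b_a*[c_j = A] + b_s*[c_j = c_prev] - rho_delta*delta_j
#           + rho_psi*psi_j + sum_k theta_k * vM(phi_j)
#
# which makes every selection a conditional-logit observation.  The fitter
# exploits this: the per-observer log-likelihood is concave with analytic
# gradient and Hessian.

def feature_names(version: ModelVersion) -> list[str]:
    names = ["b_a", "b_s", "rho_delta"]
    if version.include_rel_dir:
        names.append("rho_psi")
    names += [f"theta_{k + 1}" for k in range(version.n_abs_directions)]
    return names


def trial_feature_tensor(
    stimulus: Stimulus,
    order,
    version: ModelVersion,
    delta0: float = 20.0,
    kappa: float = 20.0,
):
    """Precompute conditional-logit features for one observed trial.

    Parameters
    ----------
    order
        The observed selection sequence (item ids), length k >= 1.

    Returns
    -------
    X : array, shape (k, N, P)
        Feature values for every candidate at every selection step.  The
        columns follow :func:`feature_names`; the distance column is
        ``-delta_j`` so all parameters enter with a positive sign.
    mask : bool array, shape (k, N)
        Which items were still available at each step.
    obs : int array, shape (k,)
        Stimulus index of the item actually selected at each step.
    """
    order = [int(o) for o in order]
    if len(set(order)) != len(order):
        raise DataValidationError("selection order contains repeated items")
    n = stimulus.n_items
    k = len(order)
    names = feature_names(version)
    p = len(names)
    X = np.zeros((k, n, p))
    mask = np.ones((k, n), dtype=bool)
    obs = np.array([stimulus.index_of(o) for o in order])

    col = {name: i for i, name in enumerate(names)}
    # the class feature is active at every step; all spatial columns stay
    # zero at step 0 (class-only first selection)
    X[:, :, col["b_a"]] = stimulus.is_a.astype(float)
    for i in range(1, k):
        cur_idx = obs[i - 1]
        mask[i] = mask[i - 1].copy()
        mask[i, cur_idx] = False
        cur = stimulus.xy[cur_idx]
        diff = stimulus.xy - cur
        with np.errstate(invalid="ignore"):
            phi = np.arctan2(diff[:, 1], diff[:, 0])
        X[i, :, col["b_s"]] = (stimulus.is_a == stimulus.is_a[cur_idx]).astype(float)
        X[i, :, col["rho_delta"]] = -np.hypot(diff[:, 0], diff[:, 1]) / delta0
        if version.include_rel_dir and i >= 2:
            prev = stimulus.xy[obs[i - 2]]
            heading = absolute_angle(prev, cur)
            X[i, :, col["rho_psi"]] = 1.0 - _wrap_to_half_turn(phi - heading) / np.pi
        if version.n_abs_directions:
            basis = _von_mises_basis(phi, version.n_abs_directions, kappa)
            basis[cur_idx] = 0.0  # phi undefined at the current item
            for kk in range(version.n_abs_directions):
                X[i, :, col[f"theta_{kk + 1}"]] = basis[:, kk]
    return X, mask, obs
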