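"""Latent Markov model for multivariate categorical panel data.

The model: a first-order latent Markov chain with k states, a free initial
distribution pi, one transition matrix per time step (time-heterogeneous), and
conditionally independent categorical emissions per PHQ-9 item given the state
(local independence).  Estimation is maximum likelihood via EM with scaled
forward-backward recursions; model comparison uses BIC with the number of
patients as the sample size.

Patients observed only once contribute to the initial distribution and the
emission profiles; time steps no patient reaches leave the corresponding
transition matrix at its previous value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import numbers
from typing import Sequence

import numpy as np

from .cohort import Cohort, N_CATEGORIES, N_ITEMS, T_MAX

logger = logging.getLogger(__name__)

#: probability floor applied after each M-step (then renormalized); prevents
#: absorbing zeros in emission/transition estimates
PROB_FLOOR = 1e-6

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclasses.dataclass(frozen=True)
class LMParameters:
    """Parameters of a k-state latent Markov model.

    pi : (k,) initial state probabilities.
    Pi : (T_MAX-1, k, k) transition matrices, Pi[t][u, v] = P(state v at t+2
         | state u at t+1); rows are stochastic.
    Phi : (k, 9, 4) emission probabilities, Phi[u, j, y] = P(item j scores y
          | state u).
    """

    pi: np.ndarray
    Pi: np.ndarray
    Phi: np.ndarray

    @property
    def k(self) -> int:
        return len(self.pi)

    def validate(self, atol: float = 1e-10) -> None:
        k = self.k
        for name, arr, shape in (
                ("pi", self.pi, (k,)),
                ("Pi", self.Pi, (T_MAX - 1, k, k)),
                ("Phi", self.Phi, (k, N_ITEMS, N_CATEGORIES))):
            arr = np.asarray(arr)
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name}: probabilities outside [0,1]")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=atol):
                raise ValueError(f"{name}: stochastic constraint violated")

    def permute(self, order: Sequence[int]) -> "LMParameters":
        """Relabel states: new state i is old state order[i]."""
        order = np.asarray(order)
        return LMParameters(
            pi=self.pi[order],
            Pi=self.Pi[:, order][:, :, order],
            Phi=self.Phi[order],
        )

    def to_json(self, path) -> None:
        payload = {
            "format": "depstates.LMParameters",
            "layout": "row-major nested lists",
            "k": self.k,
            "T_max": T_MAX,
            "n_items": N_ITEMS,
            "n_categories": N_CATEGORIES,
            "pi": self.pi.tolist(),
            "Pi": self.Pi.tolist(),
            "Phi": self.Phi.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LMParameters":
        with open(path) as fh:
            d = json.load(fh)
        params = cls(pi=np.asarray(d["pi"], dtype=float),
                     Pi=np.asarray(d["Pi"], dtype=float),
                     Phi=np.asarray(d["Phi"], dtype=float))
        params.validate(atol=1e-8)
        return params


@dataclasses.dataclass
class FitResult:
    params: LMParameters
    loglik: float
    n_params: int
    bic: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    init: str = ""
    seed: int | None = None

    def relabeled(self, order: Sequence[int]) -> "FitResult":
        return dataclasses.replace(self, params=self.params.permute(order))


@dataclasses.dataclass(frozen=True)
class ForwardBackwardResult:
    loglik: float
    state_posteriors: np.ndarray   # (T, k)
    pair_posteriors: np.ndarray    # (T-1, k, k)


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

def _coerce_items(items) -> np.ndarray:
    """To an int array with -1 for missing; validates the 0..3 range."""
    arr = np.asarray(items, dtype=object)
    out = np.full(arr.shape, -1, dtype=np.int64)
    flat_in, flat_out = arr.ravel(), out.ravel()
    for i, v in enumerate(flat_in):
        if v is None or (isinstance(v, numbers.Real) and np.isnan(v)):
            continue
        iv = int(v)
        if iv == -1:
            continue
        if iv != v or not 0 <= iv < N_CATEGORIES:
            raise ValueError(f"item score {v!r} outside {{0..{N_CATEGORIES - 1}}}")
        flat_out[i] = iv
    return out


def emission_logprob(Phi: np.ndarray, phq_items) -> np.ndarray:
    """Per-state log-probability of one session's item responses.

    Missing items are skipped (missing-at-random); an all-missing observation
    yields the zero vector (an empty product).
    """
    y = _coerce_items(phq_items)
    if y.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} item scores, got shape {y.shape}")
    obs = y >= 0
    if not obs.any():
        return np.zeros(Phi.shape[0])
    logphi = np.log(Phi[:, obs, y[obs]])
    return logphi.sum(axis=1)


# ---------------------------------------------------------------------------
# Packed cohort and batched recursions
# ---------------------------------------------------------------------------

class _Packed:
    """Cohort re-packed for vectorized EM: patients grouped by sequence
    length, item responses one-hot encoded (missing rows all-zero)."""

    def __init__(self, Y: np.ndarray, lengths: np.ndarray):
        self.n = len(lengths)
        self.lengths = lengths
        self.groups: list[tuple[int, np.ndarray, np.ndarray]] = []
        for L in np.unique(lengths):
            idx = np.flatnonzero(lengths == L)
            yg = Y[idx, :L]                                     # (n_g, L, 9)
            onehot = np.zeros((len(idx), L, N_ITEMS, N_CATEGORIES))
            obs = yg >= 0
            gi, ti, ji = np.nonzero(obs)
            onehot[gi, ti, ji, yg[gi, ti, ji]] = 1.0
            self.groups.append((int(L),
                                idx,
                                onehot.reshape(len(idx), L, N_ITEMS * N_CATEGORIES)))

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "_Packed":
        return cls(*cohort.item_arrays())


def _group_posteriors(pi, Pi, logphi_flat, onehot):
    """Scaled forward-backward for one same-length group.

    Returns (loglik per patient, gamma (n,L,k), xi (n,L-1,k,k))."""
    n, L, _ = onehot.shape
    k = len(pi)
    logB = onehot @ logphi_flat                        # (n, L, k)
    m = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - m)

    alpha = np.empty((n, L, k))
    c = np.empty((n, L))
    a = pi[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, L):
        a = (alpha[:, t - 1] @ Pi[t - 1]) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = np.log(c).sum(axis=1) + m[:, :, 0].sum(axis=1)

    beta = np.empty((n, L, k))
    beta[:, L - 1] = 1.0
    xi = np.empty((n, L - 1, k, k)) if L > 1 else np.empty((n, 0, k, k))
    for t in range(L - 2, -1, -1):
        w = B[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]   # (n, k)
        beta[:, t] = w @ Pi[t].T
        xi[:, t] = alpha[:, t, :, None] * Pi[t][None] * w[:, None, :]
    gamma = alpha * beta
    return loglik, gamma, xi


def forward_backward(params: LMParameters, sequence) -> ForwardBackwardResult:
    """Posterior state and transition probabilities for one item-score
    sequence (shape (T, 9), missing entries None/NaN/-1)."""
    Y = np.stack([_coerce_items(row) for row in sequence])
    T = Y.shape[0]
    if not 1 <= T <= T_MAX:
        raise ValueError(f"sequence length {T} outside 1..{T_MAX}")
    packed = _Packed(np.pad(Y[None], ((0, 0), (0, T_MAX - T), (0, 0)),
                            constant_values=-1),
                     np.array([T]))
    logphi_flat = np.log(params.Phi).reshape(params.k, -1).T
    _, idx, onehot = packed.groups[0]
    ll, gamma, xi = _group_posteriors(params.pi, params.Pi, logphi_flat, onehot)
    xi_norm = xi[0]
    if T > 1:
        xi_norm = xi_norm / xi_norm.sum(axis=(1, 2), keepdims=True)
    return ForwardBackwardResult(float(ll[0]), gamma[0], xi_norm)


def loglikelihood(params: LMParameters, cohort: Cohort) -> float:
    """Total log-likelihood of the cohort (sum over patients)."""
    if cohort.n_patients == 0 or len(cohort.data) == 0:
        return 0.0
    packed = _Packed.from_cohort(cohort)
    logphi_flat = np.log(params.Phi).reshape(params.k, -1).T
    total = 0.0
    for L, idx, onehot in packed.groups:
        ll, _, _ = _group_posteriors(params.pi, params.Pi, logphi_flat, onehot)
        total += ll.sum()
    return float(total)


# ---------------------------------------------------------------------------
# Model size and BIC
# ---------------------------------------------------------------------------

def count_parameters(k: int, n_items: int = N_ITEMS,
                     n_categories: int = N_CATEGORIES,
                     T_max: int = T_MAX) -> int:
    """Free parameters: (k-1) initial + k(k-1) per transition step +
    k * n_items * (n_categories-1) emission."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return (k - 1) + k * (k - 1) * (T_max - 1) + k * n_items * (n_categories - 1)


def bic(loglik: float, n_params: int, n_patients: int) -> float:
    """Bayesian Information Criterion, -2*loglik + n_params*ln(n); the sample
    size n is the number of patients."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_patients)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _floor_normalize(arr: np.ndarray, floor: float = PROB_FLOOR) -> np.ndarray:
    arr = np.maximum(arr, floor)
    return arr / arr.sum(axis=-1, keepdims=True)


def init_params(cohort: Cohort, k: int, strategy: str = "severity_quantile",
                seed: int | None = None) -> LMParameters:
    """Starting values for EM.

    severity_quantile : patients are binned into k groups by baseline PHQ-9
        total; emission profiles come from bin-wise item-category frequencies,
        the initial distribution from bin sizes, transitions are
        near-diagonal.
    random : Dirichlet(1) rows throughout.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(k))
        Pi = rng.dirichlet(np.ones(k), size=(T_MAX - 1, k))
        Phi = rng.dirichlet(np.ones(N_CATEGORIES), size=(k, N_ITEMS))
        return LMParameters(pi, Pi, Phi)
    if strategy != "severity_quantile":
        raise ValueError(f"unknown init strategy {strategy!r}")

    Y, lengths = cohort.item_arrays()
    first = Y[:, 0].astype(float)                      # (n, 9)
    first[first < 0] = np.nan
    base = np.nanmean(first, axis=1)
    base = np.where(np.isnan(base), np.nanmedian(base), base) * N_ITEMS
    order = np.argsort(base, kind="stable")
    bins = np.array_split(order, k)

    Phi = np.empty((k, N_ITEMS, N_CATEGORIES))
    pi = np.empty(k)
    for u, idx in enumerate(bins):
        pi[u] = max(len(idx), 1)
        yb = Y[idx].reshape(-1, N_ITEMS)
        counts = np.zeros((N_ITEMS, N_CATEGORIES))
        for c in range(N_CATEGORIES):
            counts[:, c] = (yb == c).sum(axis=0)
        Phi[u] = _floor_normalize(counts + 0.5)
    pi = pi / pi.sum()
    Pi = np.full((T_MAX - 1, k, k), 0.2 / max(k - 1, 1))
    ii = np.arange(k)
    Pi[:, ii, ii] = 0.8 if k > 1 else 1.0
    Pi = Pi / Pi.sum(axis=-1, keepdims=True)
    return LMParameters(pi, Pi, Phi)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def em_fit(cohort: Cohort, k: int, init: LMParameters | None = None,
           tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
           floor: float = PROB_FLOOR, init_label: str = "",
           seed: int | None = None) -> FitResult:
    """Fit the k-state model by EM.

    E-step: scaled forward-backward per patient (batched by sequence length).
    M-step: closed-form updates -- pi from first-session posteriors, each
    Pi[t] from normalized summed pair posteriors at step t, Phi from expected
    item-category counts over non-missing items.  Stops when the relative
    log-likelihood change drops below ``tol``.
    """
    if cohort.n_patients == 0:
        raise ValueError("cohort is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    if init is None:
        init = init_params(cohort, k, "severity_quantile")
        init_label = init_label or "severity_quantile"
    if init.k != k:
        raise ValueError(f"init has k={init.k}, expected {k}")

    packed = _Packed.from_cohort(cohort)
    n = packed.n
    pi, Pi, Phi = init.pi.copy(), init.Pi.copy(), init.Phi.copy()

    max_len = int(packed.lengths.max())
    unreachable = [t for t in range(T_MAX - 1) if t >= max_len - 1]
    if unreachable:
        logger.warning(
            "no patient reaches time steps %s; their transition matrices stay "
            "at the initial values", [t + 1 for t in unreachable])

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logphi_flat = np.log(Phi).reshape(k, -1).T
        ll_total = 0.0
        pi_acc = np.zeros(k)
        trans_acc = np.zeros((T_MAX - 1, k, k))
        phi_acc = np.zeros((N_ITEMS * N_CATEGORIES, k))
        for L, idx, onehot in packed.groups:
            ll, gamma, xi = _group_posteriors(pi, Pi, logphi_flat, onehot)
            ll_total += ll.sum()
            pi_acc += gamma[:, 0].sum(axis=0)
            if L > 1:
                trans_acc[:L - 1] += xi.sum(axis=0)
            phi_acc += onehot.reshape(-1, N_ITEMS * N_CATEGORIES).T @ \
                gamma.reshape(-1, k)
        trace.append(ll_total)

        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll_total - prev) <= tol * abs(prev):
                converged = True
                break

        # M-step
        pi = _floor_normalize(pi_acc / n, floor)
        rowsums = trans_acc.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            newPi = trans_acc / rowsums
        keep = (rowsums[..., 0] <= 0)
        newPi[keep] = Pi[keep]
        Pi = _floor_normalize(newPi, floor)
        counts = phi_acc.T.reshape(k, N_ITEMS, N_CATEGORIES)
        csum = counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            newPhi = counts / csum
        newPhi[(csum[..., 0] <= 0)] = Phi[(csum[..., 0] <= 0)]
        Phi = _floor_normalize(newPhi, floor)

    params = LMParameters(pi, Pi, Phi)
    if not converged:
        # the loop exhausted max_iter after an M-step; report the final
        # parameters' own log-likelihood
        trace.append(loglikelihood(params, cohort))
    loglik = trace[-1]
    npar = count_parameters(k)
    return FitResult(
        params=params,
        loglik=float(loglik),
        n_params=npar,
        bic=float(bic(loglik, npar, n)),
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
        init=init_label,
        seed=seed,
    )
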