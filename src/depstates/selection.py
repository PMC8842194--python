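"""Model selection, canonical state labelling, global decoding and fold
replication for the latent Markov model.

The number of states is chosen by scanning a range of k, fitting each with a
multistart EM (one severity-quantile start plus random restarts) and taking
the BIC minimizer.  Fitted states are relabelled into increasing expected
PHQ-9 severity so that "state 1" is always the least severe.  Decoding is
global (Viterbi): the jointly most probable path per patient.  Replication
fits the same k on disjoint patient folds and aligns states across folds by
optimal assignment on emission-profile distance.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cohort import Cohort, N_CATEGORIES, T_MAX
from .lmm import (FitResult, LMParameters, _coerce_items, count_parameters,
                  em_fit, init_params)

logger = logging.getLogger(__name__)

#: multistart schedule: every start is run for this many EM iterations, then
#: only the best start (by log-likelihood) is refined to full convergence
SHORT_RUN_ITER = 50


@dataclasses.dataclass(frozen=True)
class DecodedCohort:
    """Per-patient globally decoded state paths.

    ``paths`` is a long DataFrame with columns patient_id, session_index and
    state (1-based labels, following the clinical convention that state 1 is
    the least severe once the fit is canonically relabelled).
    """

    paths: pd.DataFrame
    k: int

    def start_states(self) -> pd.Series:
        """State at the first session, per patient (1-based)."""
        return self.paths.groupby("patient_id", sort=False)["state"].first()

    def path_of(self, patient_id) -> np.ndarray:
        sel = self.paths.loc[self.paths["patient_id"] == patient_id, "state"]
        return sel.to_numpy()


# ---------------------------------------------------------------------------
# Multistart fitting over a range of k
# ---------------------------------------------------------------------------

def fit_k(cohort: Cohort, k: int, n_starts: int = 10, seed: int | None = None,
          tol: float = 1e-8, max_iter: int = 1000,
          short_iter: int = SHORT_RUN_ITER) -> FitResult:
    """Best-of-``n_starts`` EM fit at a fixed k.

    Start 1 uses the severity-quantile initializer; the rest are random.
    Every start is advanced ``short_iter`` EM iterations; the start with the
    highest log-likelihood is then run to full convergence (the standard
    short-run multistart strategy).
    """
    ss = np.random.SeedSequence(0 if seed is None else seed)
    child = ss.spawn(max(n_starts, 1))
    candidates: list[FitResult] = []
    for s in range(max(n_starts, 1)):
        strategy = "severity_quantile" if s == 0 else "random"
        rng_seed = int(child[s].generate_state(1)[0] % (2 ** 31))
        init = init_params(cohort, k, strategy, seed=rng_seed)
        fit = em_fit(cohort, k, init=init, tol=tol, max_iter=short_iter,
                     init_label=strategy, seed=rng_seed)
        candidates.append(fit)
    best = max(candidates, key=lambda f: f.loglik)
    if not best.converged:
        refined = em_fit(cohort, k, init=best.params, tol=tol,
                         max_iter=max_iter, init_label=best.init,
                         seed=best.seed)
        refined = dataclasses.replace(
            refined,
            n_iter=best.n_iter + refined.n_iter,
            loglik_trace=np.concatenate([best.loglik_trace,
                                         refined.loglik_trace]))
        best = refined
    return best


def fit_range(cohort: Cohort, k_min: int, k_max: int, n_starts: int = 10,
              seed: int | None = None, tol: float = 1e-8,
              max_iter: int = 1000, short_iter: int = SHORT_RUN_ITER,
              ) -> tuple[pd.DataFrame, dict[int, FitResult]]:
    """Fit every k in [k_min, k_max]; returns the selection table and the
    best fit per k.  A failing k is recorded in the table (NaN row) without
    aborting the scan."""
    if not 1 <= k_min <= k_max:
        raise ValueError("require 1 <= k_min <= k_max")
    ss = np.random.SeedSequence(0 if seed is None else seed)
    child = ss.spawn(k_max - k_min + 1)
    rows = []
    fits: dict[int, FitResult] = {}
    n = cohort.n_patients
    for i, k in enumerate(range(k_min, k_max + 1)):
        kseed = int(child[i].generate_state(1)[0] % (2 ** 31))
        try:
            fit = fit_k(cohort, k, n_starts=n_starts, seed=kseed, tol=tol,
                        max_iter=max_iter, short_iter=short_iter)
        except Exception as exc:  # record and continue the scan
            logger.warning("fit failed for k=%d: %s", k, exc)
            rows.append({"k": k, "loglik": np.nan,
                         "n_params": count_parameters(k), "bic": np.nan,
                         "n_starts": n_starts, "converged": False,
                         "error": str(exc)})
            continue
        fits[k] = fit
        rows.append({"k": k, "loglik": fit.loglik, "n_params": fit.n_params,
                     "bic": fit.bic, "n_starts": n_starts,
                     "converged": fit.converged, "error": ""})
    table = pd.DataFrame(rows)
    return table, fits


def select_by_bic(table: pd.DataFrame) -> int:
    """BIC-minimizing k; ties resolved toward the smallest k."""
    valid = table.dropna(subset=["bic"])
    if valid.empty:
        raise ValueError("selection table has no successful fits")
    best = valid["bic"].min()
    return int(valid.loc[valid["bic"] == best, "k"].min())


# ---------------------------------------------------------------------------
# Canonical labelling
# ---------------------------------------------------------------------------

def expected_severity(Phi: np.ndarray) -> np.ndarray:
    """Expected total PHQ-9 score per state (range 0..27)."""
    return (Phi @ np.arange(N_CATEGORIES)).sum(axis=1)


def canonical_relabel(fit: FitResult) -> FitResult:
    """Permute states into non-decreasing expected severity (stable on ties);
    the likelihood is unchanged."""
    order = np.argsort(expected_severity(fit.params.Phi), kind="stable")
    return fit.relabeled(order)


# ---------------------------------------------------------------------------
# Global decoding
# ---------------------------------------------------------------------------

def viterbi_decode(params: LMParameters, sequence) -> np.ndarray:
    """Jointly most probable state path (0-based indices) for one sequence.

    Log-domain dynamic programming; ties break toward the lowest state
    index."""
    Y = np.stack([_coerce_items(row) for row in np.asarray(sequence, dtype=object)])
    T = Y.shape[0]
    if not 1 <= T <= T_MAX:
        raise ValueError(f"sequence length {T} outside 1..{T_MAX}")
    k = params.k
    logphi = np.log(params.Phi)
    logB = np.zeros((T, k))
    for t in range(T):
        obs = Y[t] >= 0
        if obs.any():
            logB[t] = logphi[:, obs, Y[t, obs]].sum(axis=1)
    logPi = np.log(params.Pi)

    delta = np.log(params.pi) + logB[0]
    back = np.zeros((T, k), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logPi[t - 1]        # (from, to)
        back[t] = np.argmax(scores, axis=0)           # first max = lowest index
        delta = scores[back[t], np.arange(k)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def decode_cohort(params: LMParameters, cohort: Cohort) -> DecodedCohort:
    """Viterbi-decode every patient; states reported as 1-based labels."""
    Y, lengths = cohort.item_arrays()
    states = []
    for i, L in enumerate(lengths):
        states.append(viterbi_decode(params, Y[i, :L]) + 1)
    out = cohort.data[["patient_id", "session_index"]].copy()
    out["state"] = np.concatenate(states)
    return DecodedCohort(paths=out, k=params.k)


# ---------------------------------------------------------------------------
# Folds and replication
# ---------------------------------------------------------------------------

def split_folds(cohort: Cohort, n_folds: int = 3,
                seed: int | None = None) -> list[Cohort]:
    """Disjoint, exhaustive patient-level partition; fold sizes differ by at
    most one."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = np.asarray(cohort.patient_ids)
    if len(ids) < n_folds:
        raise ValueError("need at least one patient per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [cohort.subset(ids[np.sort(perm[f::n_folds])]) for f in range(n_folds)]


def match_states(fit_a: FitResult, fit_b: FitResult,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Align fit_b's states to fit_a's by optimal (Hungarian) assignment on
    emission-profile distance.

    The distance between two states is the L1 distance between their
    category distributions, averaged over the nine items (range [0, 2]).
    Returns (perm, dist) where perm[u] is the fit_b state matched to fit_a
    state u, and dist is the full k x k distance matrix."""
    if fit_a.params.k != fit_b.params.k:
        raise ValueError("state counts differ; cannot match")
    A, B = fit_a.params.Phi, fit_b.params.Phi
    dist = np.abs(A[:, None] - B[None, :]).sum(axis=3).mean(axis=2)
    row, col = linear_sum_assignment(dist)
    return col, dist


@dataclasses.dataclass
class ReplicationReport:
    k: int
    n_folds: int
    fits: list[FitResult]
    emission_distance: pd.DataFrame    # per fold (vs fold 1), per state L1
    transition_discrepancy: pd.DataFrame

    def max_emission_distance(self) -> float:
        return float(self.emission_distance["l1_distance"].max())

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "n_folds": self.n_folds,
            "emission_distance": self.emission_distance.to_dict("records"),
            "transition_discrepancy":
                self.transition_discrepancy.to_dict("records"),
        }


def replicate_across_folds(cohort: Cohort, k: int, n_folds: int = 3,
                           n_starts: int = 4, seed: int | None = None,
                           tol: float = 1e-8, max_iter: int = 1000,
                           ) -> ReplicationReport:
    """Fit the k-state model independently on each fold, canonically relabel,
    align states to fold 1, and report per-state emission L1 distances and
    per-edge transition-probability discrepancies."""
    ss = np.random.SeedSequence(0 if seed is None else seed)
    fold_seed, *fit_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                             for c in ss.spawn(n_folds + 1)]
    folds = split_folds(cohort, n_folds, seed=fold_seed)
    fits = [canonical_relabel(
        fit_k(f, k, n_starts=n_starts, seed=s, tol=tol, max_iter=max_iter))
        for f, s in zip(folds, fit_seeds)]

    ref = fits[0]
    emis_rows, trans_rows = [], []
    aligned = [ref]
    for f_idx, fit in enumerate(fits[1:], start=2):
        perm, dist = match_states(ref, fit)
        fit_aligned = fit.relabeled(perm)
        aligned.append(fit_aligned)
        for u in range(k):
            emis_rows.append({"fold": f_idx, "state": u + 1,
                              "l1_distance": dist[u, perm[u]]})
        diff = np.abs(ref.params.Pi - fit_aligned.params.Pi)
        for u in range(k):
            for v in range(k):
                trans_rows.append({"fold": f_idx, "from_state": u + 1,
                                   "to_state": v + 1,
                                   "max_abs_diff": float(diff[:, u, v].max()),
                                   "mean_abs_diff": float(diff[:, u, v].mean())})
    return ReplicationReport(
        k=k, n_folds=n_folds, fits=aligned,
        emission_distance=pd.DataFrame(emis_rows),
        transition_discrepancy=pd.DataFrame(trans_rows),
    )
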