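import itertools

import numpy as np
import pandas as pd
import pytest

import depstates as ds


@pytest.fixture(scope="session")
def default_spec():
    return ds.default_truth_spec(seed=1)


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """300 patients from the default truth, with demographics."""
    cohort, truth = ds.simulate_cohort(default_spec, 300, seed=7)
    return cohort, truth


@pytest.fixture(scope="session")
def two_state_spec():
    """A well-separated 2-state truth used for recovery experiments."""
    low = np.stack([ds.cohort.binomial_item_profile(0.3) for _ in range(9)])
    high = np.stack([ds.cohort.binomial_item_profile(2.5) for _ in range(9)])
    profiles = np.stack([low, high])
    k = 2
    Pi = np.tile(np.array([[0.85, 0.15], [0.30, 0.70]]), (ds.T_MAX - 1, 1, 1))
    spec = ds.TruthSpec(
        n_states=k,
        item_profiles=profiles,
        initial_probs=np.array([0.5, 0.5]),
        transition_mats=Pi,
        length_dist=ds.cohort._default_length_dist(),
        gad_levels=np.array([0.2, 0.7]),
        seed=0,
    )
    spec.validate()
    return spec


def random_params(rng, k, T=ds.T_MAX):
    """Random valid LMParameters."""
    return ds.LMParameters(
        pi=rng.dirichlet(np.ones(k)),
        Pi=rng.dirichlet(np.ones(k), size=(ds.T_MAX - 1, k)),
        Phi=rng.dirichlet(np.ones(4), size=(k, 9)),
    )


def brute_force_loglik(params, Y):
    """Exhaustive-path log-likelihood of one sequence (rows = sessions,
    -1 = missing)."""
    Y = np.asarray(Y)
    T, k = Y.shape[0], params.k
    total = 0.0
    for path in itertools.product(range(k), repeat=T):
        p = params.pi[path[0]]
        for t in range(1, T):
            p *= params.Pi[t - 1, path[t - 1], path[t]]
        for t in range(T):
            for j in range(9):
                if Y[t, j] >= 0:
                    p *= params.Phi[path[t], j, Y[t, j]]
        total += p
    return np.log(total)


def brute_force_map_path(params, Y):
    """Exhaustive most-probable path; lexicographically smallest on ties."""
    Y = np.asarray(Y)
    T, k = Y.shape[0], params.k
    best, best_lp = None, -np.inf
    for path in itertools.product(range(k), repeat=T):
        lp = np.log(params.pi[path[0]])
        for t in range(1, T):
            lp += np.log(params.Pi[t - 1, path[t - 1], path[t]])
        for t in range(T):
            for j in range(9):
                if Y[t, j] >= 0:
                    lp += np.log(params.Phi[path[t], j, Y[t, j]])
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return np.array(best)


def make_null_two_state_cohort(rng, n_per_state=400, engage_p=0.7,
                               change_p=0.5, states=(3, 5)):
    """Synthetic two-group cohort whose outcomes are independent of the
    (assigned) starting state; used for null calibration of the post-hoc
    chi-square battery."""
    rows, decoded_rows = [], []
    for i in range(2 * n_per_state):
        state = states[0] if i < n_per_state else states[1]
        engaged = rng.random() < engage_p
        T = 3 if engaged else 1
        phq0 = int(rng.integers(8, 24))
        delta = int(rng.integers(-8, 11)) if rng.random() < change_p else 0
        phq1 = int(np.clip(phq0 - delta, 0, 27))
        gad0 = int(rng.integers(5, 15))
        totals = np.linspace(phq0, phq1, T).round().astype(int)
        for t in range(T):
            item_base = np.full(9, totals[t] // 9)
            item_base[:totals[t] % 9] += 1
            row = {"patient_id": f"p{i}", "session_index": t + 1,
                   "gad_total": gad0}
            for j in range(9):
                row[f"phq{j + 1}"] = item_base[j]
            rows.append(row)
            decoded_rows.append({"patient_id": f"p{i}",
                                 "session_index": t + 1, "state": state})
    cohort = ds.Cohort.from_frame(pd.DataFrame(rows))
    decoded = ds.DecodedCohort(paths=pd.DataFrame(decoded_rows), k=7)
    return cohort, decoded


def make_cohort(records):
    """Cohort from a list of (patient_id, [session item-rows]) with optional
    per-record gad totals: records = {pid: (items (T,9), gad (T,))}."""
    rows = []
    for pid, (items, gad) in records.items():
        items = np.asarray(items, dtype=float)
        for t in range(items.shape[0]):
            row = {"patient_id": pid, "session_index": t + 1,
                   "gad_total": gad[t] if gad is not None else np.nan}
            for j in range(9):
                row[f"phq{j + 1}"] = items[t, j]
            rows.append(row)
    return ds.Cohort.from_frame(pd.DataFrame(rows))
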