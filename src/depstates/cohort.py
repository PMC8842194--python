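"""Synthetic PHQ-9 panel cohorts.

Generates long-format panel data with the statistical structure the latent
Markov analysis assumes: per patient, an ordered run of 1-10 sessions, each
carrying the nine PHQ-9 item scores (0-3), a GAD-7 total (0-21), and
patient-level demographic covariates whose distribution may depend on the
patient's (latent) starting state.

The default generating truth is a 7-state model whose emission profiles follow
the qualitative severity ordering used throughout the package: two low-severity
states, a cognitive/affective state peaking on the mood, energy and self-esteem
items, a hybrid evenly-moderate state, a somatic state peaking on sleep, energy
and appetite items, and two uniformly high-severity states.  The numeric
profile values are a design choice of this package, not published data.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

T_MAX = 10
N_ITEMS = 9
N_CATEGORIES = 4
PHQ_MAX = N_ITEMS * (N_CATEGORIES - 1)  # 27
GAD_MAX = 21

PHQ_ITEM_COLS = [f"phq{j}" for j in range(1, N_ITEMS + 1)]
BASE_COLS = ["patient_id", "session_index", *PHQ_ITEM_COLS, "gad_total"]


class CohortValidationError(ValueError):
    """Raised when panel data violate the cohort contract."""


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Cohort:
    """Long-format panel of PHQ-9 item responses.

    One row per patient per session; rows for a patient are consecutive and in
    session order.  Missing item scores and missing GAD-7 totals are NA.
    Columns beyond the base schema are patient-level covariates (constant
    within patient).
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        df = _validate_frame(df)
        return cls(df)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data["patient_id"].unique()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in BASE_COLS]

    def lengths(self) -> pd.Series:
        """Number of records per patient, in patient order."""
        return self.data.groupby("patient_id", sort=False).size()

    def item_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (N, T_MAX, 9) int array of item scores (-1 = missing) and
        the (N,) array of sequence lengths."""
        lengths = self.lengths().to_numpy()
        n = len(lengths)
        items = self.data[PHQ_ITEM_COLS].to_numpy(dtype=float)
        y = np.full((n, T_MAX, N_ITEMS), -1, dtype=np.int64)
        pos = np.concatenate([np.arange(L) for L in lengths])
        row = np.repeat(np.arange(n), lengths)
        vals = np.where(np.isnan(items), -1, items).astype(np.int64)
        y[row, pos] = vals
        return y, lengths

    def totals(self) -> pd.DataFrame:
        """First/last PHQ-9 and GAD-7 totals per patient.

        PHQ totals are the item sum and are NA if any item of that record is
        missing; GAD totals come straight from the records.
        """
        d = self.data
        phq = d[PHQ_ITEM_COLS].sum(axis=1, skipna=False)
        tmp = pd.DataFrame({
            "patient_id": d["patient_id"],
            "phq_total": phq,
            "gad_total": d["gad_total"],
        })
        g = tmp.groupby("patient_id", sort=False)
        out = pd.DataFrame({
            "n_records": g.size(),
            "phq_first": g["phq_total"].first(),
            "phq_last": g["phq_total"].last(),
            "gad_first": g["gad_total"].first(),
            "gad_last": g["gad_total"].last(),
        })
        return out

    def covariates(self) -> pd.DataFrame:
        """Patient-level covariate table (first record per patient)."""
        cols = ["patient_id", *self.covariate_names]
        return (self.data[cols].groupby("patient_id", sort=False)
                .first())

    def subset(self, patient_ids: Iterable) -> "Cohort":
        ids = pd.Index(patient_ids)
        mask = self.data["patient_id"].isin(ids)
        return Cohort(self.data.loc[mask].reset_index(drop=True))

    def __len__(self) -> int:
        return self.n_patients


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BASE_COLS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    df = df.reset_index(drop=True)

    items = df[PHQ_ITEM_COLS].to_numpy(dtype=float)
    bad = ~(np.isnan(items) | ((items >= 0) & (items <= 3) & (items == np.floor(items))))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise CohortValidationError(
            f"row {r}: {PHQ_ITEM_COLS[c]}={items[r, c]} outside {{0..3}}")
    gad = df["gad_total"].to_numpy(dtype=float)
    badg = ~(np.isnan(gad) | ((gad >= 0) & (gad <= GAD_MAX) & (gad == np.floor(gad))))
    if badg.any():
        r = int(np.argwhere(badg)[0][0])
        raise CohortValidationError(f"row {r}: gad_total={gad[r]} outside 0..{GAD_MAX}")

    for pid, g in df.groupby("patient_id", sort=False):
        si = g["session_index"].to_numpy()
        if len(si) > T_MAX:
            raise CohortValidationError(
                f"patient {pid!r} has {len(si)} sessions; at most {T_MAX} "
                f"records per patient are allowed")
        if np.any(np.diff(si) <= 0):
            raise CohortValidationError(
                f"patient {pid!r}: session_index not strictly increasing")
        if si[0] < 1:
            raise CohortValidationError(f"patient {pid!r}: session_index must be >= 1")
    return df


# ---------------------------------------------------------------------------
# Generating truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TruthSpec:
    """Parameters of the generating latent Markov process.

    ``length_dist`` is either a length-``T_MAX`` probability vector shared by
    all patients, or an ``(n_states, T_MAX)`` matrix of per-starting-state
    length distributions (used to emulate state-linked dropout).
    ``covariate_effects`` maps a covariate name to
    ``{"base": log-odds, "state_shifts": length-k list}`` for binary
    covariates sampled from a logistic model on the starting state.
    """

    n_states: int
    item_profiles: np.ndarray       # (k, 9, 4)
    initial_probs: np.ndarray       # (k,)
    transition_mats: np.ndarray     # (T_MAX-1, k, k)
    length_dist: np.ndarray         # (T_MAX,) or (k, T_MAX)
    gad_levels: np.ndarray          # (k,) success prob for Binomial(21, .)
    covariate_effects: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        k = self.n_states
        _check_prob("item_profiles", self.item_profiles, (k, N_ITEMS, N_CATEGORIES))
        _check_prob("initial_probs", self.initial_probs, (k,))
        _check_prob("transition_mats", self.transition_mats, (T_MAX - 1, k, k))
        if self.length_dist.ndim == 1:
            _check_prob("length_dist", self.length_dist, (T_MAX,))
        else:
            _check_prob("length_dist", self.length_dist, (k, T_MAX))
        if self.gad_levels.shape != (k,) or np.any(
                (self.gad_levels < 0) | (self.gad_levels > 1)):
            raise CohortValidationError("gad_levels must be k probabilities in [0,1]")
        for name, eff in self.covariate_effects.items():
            shifts = np.asarray(eff["state_shifts"], dtype=float)
            if shifts.shape != (k,):
                raise CohortValidationError(
                    f"covariate_effects[{name!r}]: state_shifts must have length {k}")

    def expected_item_scores(self) -> np.ndarray:
        """(k, 9) expected item score per state."""
        return self.item_profiles @ np.arange(N_CATEGORIES)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("item_profiles", "initial_probs", "transition_mats",
                    "length_dist", "gad_levels"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthSpec":
        spec = cls(
            n_states=int(d["n_states"]),
            item_profiles=np.asarray(d["item_profiles"], dtype=float),
            initial_probs=np.asarray(d["initial_probs"], dtype=float),
            transition_mats=np.asarray(d["transition_mats"], dtype=float),
            length_dist=np.asarray(d["length_dist"], dtype=float),
            gad_levels=np.asarray(d["gad_levels"], dtype=float),
            covariate_effects=dict(d.get("covariate_effects", {})),
            seed=int(d.get("seed", 0)),
        )
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "TruthSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_prob(name: str, arr: np.ndarray, shape: tuple) -> None:
    arr = np.asarray(arr)
    if arr.shape != shape:
        raise CohortValidationError(f"{name}: expected shape {shape}, got {arr.shape}")
    if np.any((arr < 0) | (arr > 1)):
        raise CohortValidationError(f"{name}: entries must lie in [0,1]")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise CohortValidationError(f"{name}: probability vectors must sum to 1")


# Expected item scores (0-3 scale) per state and item; rows are states in
# increasing overall severity.  Values are this package's design choice,
# spaced so that adjacent states are well separated (with the default
# concentration, the Jensen-Shannon divergence between any two states'
# 9-item emission distributions is >= ~0.6 nats, close to the ln 2 ceiling).
_DEFAULT_ITEM_LOCATIONS = np.array([
    # items:  1     2     3     4     5     6     7     8     9
    [0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.05],  # 1 minimal
    [0.75, 0.75, 0.75, 0.75, 0.75, 0.75, 0.75, 0.75, 0.55],  # 2 mild
    [0.90, 2.40, 0.90, 2.40, 0.90, 2.40, 0.90, 0.90, 0.70],  # 3 cognitive/affective
    [1.55, 1.55, 1.55, 1.55, 1.55, 1.55, 1.55, 1.55, 1.25],  # 4 hybrid moderate
    [0.90, 0.90, 2.40, 2.40, 2.40, 0.90, 0.90, 0.90, 0.70],  # 5 somatic
    [2.20, 2.20, 2.20, 2.20, 2.20, 2.20, 2.20, 2.20, 1.90],  # 6 moderately severe
    [2.85, 2.85, 2.85, 2.85, 2.85, 2.85, 2.85, 2.85, 2.60],  # 7 severe
])

#: sharpening exponent for the default emission profiles; 1.0 is a plain
#: binomial, larger values concentrate mass around the location
_DEFAULT_CONCENTRATION = 2.0

_DEFAULT_INITIAL_PROBS = np.array([0.14, 0.12, 0.17, 0.13, 0.13, 0.16, 0.15])

# Binary covariates enriched in the somatic state (index 4, i.e. state 5).
_DEFAULT_COVARIATE_EFFECTS = {
    "female": {"base": 0.6, "state_shifts": [0, 0, 0, 0, 0.8, 0, 0]},
    "long_term_condition": {"base": -1.0, "state_shifts": [0, 0, 0, 0, 0.8, 0, 0]},
    "psychotropic_medication": {"base": -0.5, "state_shifts": [0, 0, 0, 0, 0.8, 0, 0]},
}


def binomial_item_profile(location: float,
                          concentration: float = _DEFAULT_CONCENTRATION,
                          ) -> np.ndarray:
    """Category probabilities over {0,1,2,3} for one item: a tempered
    Binomial(3, loc/3), i.e. pmf proportional to the binomial pmf raised to
    ``concentration``.

    A single location parameter (roughly the expected score) yields an
    ordered, unimodal categorical distribution with full support for
    locations in (0, 3); the concentration controls how sharply mass piles
    up around the location.
    """
    p = np.clip(location / 3.0, 0.02, 0.98)
    w = stats.binom.pmf(np.arange(N_CATEGORIES), N_CATEGORIES - 1, p)
    w = w ** concentration
    return w / w.sum()


def _default_length_dist() -> np.ndarray:
    # ~30% single-record patients (the non-engaged analogue); remaining mass
    # decays geometrically over lengths 2..10.
    w = 0.85 ** np.arange(T_MAX - 1)
    dist = np.empty(T_MAX)
    dist[0] = 0.30
    dist[1:] = 0.70 * w / w.sum()
    return dist


def _default_transition_mats(k: int) -> np.ndarray:
    """Time-heterogeneous transitions favouring severity decrease.

    Self-transition probability rises over the course of treatment (movement
    stabilises around session 6); of the leaving mass, 80% flows to
    lower-severity states and 20% to higher ones, both decaying geometrically
    with state distance.
    """
    mats = np.empty((T_MAX - 1, k, k))
    for t in range(T_MAX - 1):
        stay = 0.70 + 0.03 * min(t, 5)
        move = 1.0 - stay
        M = np.zeros((k, k))
        for u in range(k):
            down = np.array([0.6 ** (u - v) for v in range(u)])
            up = np.array([0.6 ** (v - u) for v in range(u + 1, k)])
            row = np.zeros(k)
            row[u] = stay
            if down.size:
                row[:u] = 0.8 * move * down / down.sum()
            else:
                row[u] += 0.8 * move
            if up.size:
                row[u + 1:] = 0.2 * move * up / up.sum()
            else:
                row[u] += 0.2 * move
            M[u] = row / row.sum()
        mats[t] = M
    return mats


def default_truth_spec(seed: int = 0) -> TruthSpec:
    """The package's default 7-state generating truth.

    Emission profiles follow the qualitative structure of the seven depressive
    states (minimal, mild, cognitive/affective, hybrid, somatic, moderately
    severe, severe); the numeric values are a documented design choice.
    """
    locs = _DEFAULT_ITEM_LOCATIONS
    k = locs.shape[0]
    profiles = np.stack([
        np.stack([binomial_item_profile(locs[u, j]) for j in range(N_ITEMS)])
        for u in range(k)
    ])
    sev = (profiles @ np.arange(N_CATEGORIES)).sum(axis=1)
    gad_levels = np.clip(0.05 + 0.80 * sev / PHQ_MAX, 0.0, 0.95)
    spec = TruthSpec(
        n_states=k,
        item_profiles=profiles,
        initial_probs=_DEFAULT_INITIAL_PROBS.copy(),
        transition_mats=_default_transition_mats(k),
        length_dist=_default_length_dist(),
        gad_levels=gad_levels,
        covariate_effects={n: dict(e) for n, e in _DEFAULT_COVARIATE_EFFECTS.items()},
        seed=int(seed),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _categorical_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One draw per row from row-wise categorical distributions."""
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1])
    draw = (u[..., None] > cum).sum(axis=-1)
    return np.minimum(draw, probs.shape[-1] - 1)


def sample_cohort(spec: TruthSpec, n_patients: int, seed: int | None = None,
                  ) -> tuple[Cohort, pd.DataFrame]:
    """Sample a cohort from the generating truth.

    Returns the cohort (without demographics; see :func:`attach_demographics`)
    and the hidden true state paths as a long DataFrame with columns
    ``patient_id, session_index, state`` (states 1-based).

    The seed is expanded into independent child streams for state paths,
    sequence lengths, item responses and GAD-7 totals, so downstream additions
    do not perturb the paths.
    """
    spec.validate()
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    rng_path, rng_len, rng_item, rng_gad, _rng_demo = (
        np.random.default_rng(s) for s in ss.spawn(5))

    k = spec.n_states
    # state paths over the full horizon
    states = np.empty((n_patients, T_MAX), dtype=np.int64)
    states[:, 0] = _categorical_rows(
        rng_path, np.broadcast_to(spec.initial_probs, (n_patients, k)))
    for t in range(1, T_MAX):
        states[:, t] = _categorical_rows(rng_path, spec.transition_mats[t - 1][states[:, t - 1]])

    # sequence lengths, possibly linked to the starting state
    if spec.length_dist.ndim == 1:
        ldist = np.broadcast_to(spec.length_dist, (n_patients, T_MAX))
    else:
        ldist = spec.length_dist[states[:, 0]]
    lengths = _categorical_rows(rng_len, ldist) + 1

    # item responses: independent per item given the state
    u = rng_item.random((n_patients, T_MAX, N_ITEMS))
    cum = np.cumsum(spec.item_profiles, axis=-1)          # (k, 9, 4)
    items = (u[..., None] > cum[states]).sum(axis=-1)     # (n, T, 9)
    items = np.minimum(items, N_CATEGORIES - 1)

    gad = rng_gad.binomial(GAD_MAX, spec.gad_levels[states])

    row = np.repeat(np.arange(n_patients), lengths)
    pos = np.concatenate([np.arange(L) for L in lengths])
    width = len(str(n_patients))
    pid = np.array([f"P{i:0{width}d}" for i in range(n_patients)])
    df = pd.DataFrame({
        "patient_id": pid[row],
        "session_index": pos + 1,
    })
    for j, col in enumerate(PHQ_ITEM_COLS):
        df[col] = items[row, pos, j]
    df["gad_total"] = gad[row, pos]
    truth = pd.DataFrame({
        "patient_id": df["patient_id"],
        "session_index": df["session_index"],
        "state": states[row, pos] + 1,
    })
    return Cohort.from_frame(df), truth


def attach_demographics(cohort: Cohort, true_start_states: np.ndarray,
                        effects: Mapping | None = None,
                        seed: int | None = None) -> Cohort:
    """Attach patient-level covariates sampled from logistic models on the
    (true) starting state.

    ``true_start_states`` gives one 1-based state per patient, in cohort
    patient order.  Each binary covariate ``c`` is Bernoulli with
    logit = base + state_shifts[start_state].  A continuous ``age`` column
    (years, no state link) is always added.
    """
    if effects is None:
        effects = _DEFAULT_COVARIATE_EFFECTS
    start = np.asarray(true_start_states, dtype=np.int64) - 1
    n = cohort.n_patients
    if start.shape != (n,):
        raise CohortValidationError(
            f"expected one start state per patient ({n}), got shape {start.shape}")
    reserved = set(BASE_COLS)
    ss = np.random.SeedSequence(0 if seed is None else seed)
    rng = np.random.default_rng(ss.spawn(5)[4])  # demographics stream

    cov = {}
    for name, eff in effects.items():
        if name in reserved:
            raise CohortValidationError(f"covariate name {name!r} collides with a base column")
        shifts = np.asarray(eff["state_shifts"], dtype=float)
        if start.max() >= len(shifts):
            raise CohortValidationError(
                f"covariate_effects[{name!r}]: state_shifts too short for state "
                f"{start.max() + 1}")
        logit = eff["base"] + shifts[start]
        p = 1.0 / (1.0 + np.exp(-logit))
        cov[name] = (rng.random(n) < p).astype(np.int64)
    cov["age"] = np.clip(np.round(rng.normal(41, 13, size=n)), 18, 90).astype(np.int64)

    per_patient = pd.DataFrame(cov, index=pd.Index(cohort.patient_ids, name="patient_id"))
    df = cohort.data.drop(columns=[c for c in per_patient.columns
                                   if c in cohort.data.columns])
    df = df.merge(per_patient, left_on="patient_id", right_index=True, how="left")
    return Cohort.from_frame(df)


def simulate_cohort(spec: TruthSpec, n_patients: int, seed: int | None = None,
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Sample a cohort and attach demographics in one call."""
    cohort, truth = sample_cohort(spec, n_patients, seed=seed)
    start = truth.groupby("patient_id", sort=False)["state"].first().to_numpy()
    if seed is None:
        seed = spec.seed
    cohort = attach_demographics(cohort, start, spec.covariate_effects, seed=seed)
    return cohort, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> None:
    """Write the long-format CSV (missing items as empty cells)."""
    df = cohort.data.copy()
    for col in PHQ_ITEM_COLS + ["gad_total"]:
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read and validate a long-format cohort CSV."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise CohortValidationError(f"cannot read cohort CSV: {exc}") from exc
    for col in PHQ_ITEM_COLS + ["gad_total"]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return Cohort.from_frame(df)
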