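"""Post-hoc comparisons between starting states: Pearson chi-square tests on
outcome rates, and logistic regression of starting-state membership on
patient demographics with scaling, dummy coding and a variance-inflation
screen.

The chi-square test is uncorrected by default (a Yates continuity correction
is available behind a flag), always on a 2x2 table with one degree of
freedom; df and N are reported separately.  No multiple-testing correction is
applied; significance is two-tailed at a configurable alpha.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort
from .outcomes import compute_outcomes
from .selection import DecodedCohort


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows are the two groups, columns outcome yes/no."""

    a: int   # group A, outcome yes
    b: int   # group A, outcome no
    c: int   # group B, outcome yes
    d: int   # group B, outcome no

    def as_array(self) -> np.ndarray:
        arr = np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.sum() <= 0:
            raise ValueError("table total must be positive")
        return arr


@dataclasses.dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float
    n: int


@dataclasses.dataclass
class LogisticFit:
    table: pd.DataFrame          # coef, se, z, p per predictor
    vif: pd.Series
    scaling: dict                # means/SDs used for continuous predictors
    converged: bool
    n: int


def chisq_test(table: ContingencyTable2x2,
               continuity_correction: bool = False) -> ChisqResult:
    """Pearson chi-square test of independence on a 2x2 table."""
    arr = table.as_array()
    rows, cols = arr.sum(axis=1), arr.sum(axis=0)
    if np.any(rows == 0):
        raise ValueError(f"zero row margin (group {int(np.argmax(rows == 0)) + 1})")
    if np.any(cols == 0):
        which = "yes" if cols[0] == 0 else "no"
        raise ValueError(f"zero column margin (outcome {which})")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return ChisqResult(float(stat), int(dof), float(p), int(arr.sum()))


def scale_center(X: pd.DataFrame, continuous: list[str],
                 ) -> tuple[pd.DataFrame, dict]:
    """Standardize the named continuous columns to zero mean and unit SD
    (ddof=1, as in R's scale); other columns pass through unchanged."""
    out = X.copy()
    meta = {}
    for col in continuous:
        x = out[col].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot scale")
        out[col] = (x - mu) / sd
        meta[col] = {"mean": float(mu), "sd": float(sd)}
    return out, meta


def build_design(df: pd.DataFrame, continuous: list[str] | None = None,
                 categorical_refs: dict[str, object] | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Design matrix: scaled/centred continuous columns and dummy-coded
    categoricals with the stated reference level dropped."""
    continuous = continuous or []
    categorical_refs = categorical_refs or {}
    parts = []
    if continuous:
        scaled, meta = scale_center(df[continuous], continuous)
        parts.append(scaled)
    else:
        meta = {}
    other = [c for c in df.columns if c not in continuous]
    for col in other:
        s = df[col]
        if col in categorical_refs or s.dtype == object or isinstance(
                s.dtype, pd.CategoricalDtype):
            ref = categorical_refs.get(col)
            dummies = pd.get_dummies(s, prefix=col, dtype=float)
            refcol = f"{col}_{ref}" if ref is not None else dummies.columns[0]
            if refcol in dummies.columns:
                dummies = dummies.drop(columns=[refcol])
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    return X, meta


def logistic_fit(y, X: pd.DataFrame, scaling: dict | None = None,
                 maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Raises on non-convergence or (quasi-)separation, reporting the offending
    predictors where detectable.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    if len(y) != len(X):
        raise ValueError("y and X length mismatch")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=0, maxiter=maxiter)
    except Exception as exc:
        raise RuntimeError(f"logistic regression failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic regression did not converge "
                           f"(after {maxiter} iterations)")
    big = res.params.abs() > 15
    if big.any():
        raise RuntimeError(
            "possible separation: extreme coefficients for "
            f"{list(res.params.index[big])}")
    table = pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "z": res.tvalues,
        "p": res.pvalues,
    })
    vifs = vif(X) if X.shape[1] >= 2 else pd.Series(np.nan, index=X.columns)
    return LogisticFit(table=table, vif=vifs, scaling=scaling or {},
                       converged=True, n=len(y))


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1/(1-R^2_j) from regressing each predictor
    on the others (with intercept).  Perfect collinearity yields inf."""
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    arr = X.to_numpy()
    for j, col in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(len(yj)), others])
        coef, _, _, _ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclasses.dataclass
class StateComparisonReport:
    state_a: int
    state_b: int
    n_all: int
    n_engaged: int
    tables: dict[str, ContingencyTable2x2]
    tests: dict[str, ChisqResult]
    regression: LogisticFit | None

    def to_json_dict(self) -> dict:
        d = {
            "state_a": self.state_a, "state_b": self.state_b,
            "n_all": self.n_all, "n_engaged": self.n_engaged,
            "tests": {name: dataclasses.asdict(t)
                      for name, t in self.tests.items()},
            "tables": {name: dataclasses.asdict(t)
                       for name, t in self.tables.items()},
        }
        if self.regression is not None:
            d["regression"] = {
                "coefficients": self.regression.table.to_dict("index"),
                "vif": self.regression.vif.to_dict(),
                "scaling": self.regression.scaling,
                "n": self.regression.n,
            }
        return d


def _two_group_table(flags: pd.DataFrame, col: str, state_a: int,
                     state_b: int) -> ContingencyTable2x2:
    ga = flags.loc[flags["start_state"] == state_a, col].dropna()
    gb = flags.loc[flags["start_state"] == state_b, col].dropna()
    if len(ga) == 0 or len(gb) == 0:
        empty = state_a if len(ga) == 0 else state_b
        raise ValueError(f"no patients with defined {col!r} in state {empty}")
    return ContingencyTable2x2(
        a=int(ga.sum()), b=int(len(ga) - ga.sum()),
        c=int(gb.sum()), d=int(len(gb) - gb.sum()))


def compare_states_report(cohort: Cohort, decoded: DecodedCohort,
                          state_a: int, state_b: int,
                          covariates: list[str] | None = None,
                          continuous: list[str] | None = None,
                          categorical_refs: dict | None = None,
                          mode: str = "loose",
                          continuity_correction: bool = False,
                          include_baseline_severity: bool = True,
                          ) -> StateComparisonReport:
    """Full two-state comparison: chi-square tests of engagement (all
    starters) and of reliable/per cent improvement and deterioration (engaged
    starters), plus an optional logistic regression of state membership
    (state_a = 1, state_b = 0) on demographics.

    ``covariates`` selects patient-level columns for the regression; if None,
    the regression is skipped.  Baseline PHQ-9 and GAD-7 totals are added as
    scaled continuous predictors unless disabled.
    """
    flags = compute_outcomes(cohort, mode=mode)
    starts = decoded.start_states()
    flags = flags.join(starts.rename("start_state"), how="left")
    both = flags[flags["start_state"].isin([state_a, state_b])]
    for s in (state_a, state_b):
        if (both["start_state"] == s).sum() == 0:
            raise ValueError(f"no patients start in state {s}")

    tables = {"engagement": _two_group_table(
        both.assign(engaged_flag=both["engaged"]), "engaged_flag",
        state_a, state_b)}
    engaged = both[both["engaged"]]
    for col in ("reliable_improvement", "deterioration", "percent_improvement"):
        tables[col] = _two_group_table(engaged, col, state_a, state_b)
    tests = {name: chisq_test(t, continuity_correction=continuity_correction)
             for name, t in tables.items()}

    regression = None
    if covariates is not None:
        cov = cohort.covariates().loc[both.index, list(covariates)].copy()
        continuous = list(continuous or [c for c in covariates
                                         if cov[c].dtype.kind in "if"
                                         and cov[c].nunique() > 2])
        if include_baseline_severity:
            cov["phq_baseline"] = both["phq_first"].astype(float)
            cov["gad_baseline"] = both["gad_first"].astype(float)
            continuous = continuous + ["phq_baseline", "gad_baseline"]
        keep = cov.notna().all(axis=1)
        X, meta = build_design(cov.loc[keep], continuous, categorical_refs)
        y = (both.loc[keep, "start_state"] == state_a).astype(float)
        regression = logistic_fit(y, X, scaling=meta)

    return StateComparisonReport(
        state_a=state_a, state_b=state_b,
        n_all=len(both), n_engaged=len(engaged),
        tables=tables, tests=tests, regression=regression)
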