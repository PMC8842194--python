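"""Binary clinical outcomes from first/last PHQ-9 and GAD-7 totals, following
the IAPT conventions.

A patient is *engaged* once enough sessions exist for pre/post scores (two or
more records by default; a strict mode requires two or more post-assessment
treatment sessions, i.e. three records).  *Reliable improvement* is a drop of
at least 6 PHQ-9 points or 4 GAD-7 points without a reliable increase on the
other scale; *deterioration* is a reliable increase on either scale; *per
cent improvement* replaces the absolute thresholds by 25% of the baseline
score.  All thresholds are inclusive.  Improvement and deterioration flags
are only defined for engaged patients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort, GAD_MAX, PHQ_MAX
from .selection import DecodedCohort

PHQ_RELIABLE_CHANGE = 6
GAD_RELIABLE_CHANGE = 4
PERCENT_CHANGE = 0.25


def _check_range(name, value, hi):
    value = np.asarray(value, dtype=float)
    if np.any(np.isnan(value)) or np.any((value < 0) | (value > hi)):
        raise ValueError(f"{name} outside 0..{hi}")
    return value


def engagement(n_records: int, mode: str = "loose") -> bool:
    """True if the patient attended enough sessions to count as engaged.

    loose (default): two or more records, the minimum for a pre/post change
    score.  strict: the first record is the assessment, so two or more
    *treatment* sessions means three or more records.
    """
    if n_records < 1:
        raise ValueError("patients have at least one record")
    if mode == "loose":
        return n_records >= 2
    if mode == "strict":
        return n_records >= 3
    raise ValueError(f"unknown engagement mode {mode!r}")


def reliable_improvement(phq_first, phq_last, gad_first, gad_last):
    """Reliable decrease on either scale with no reliable increase on either."""
    p0 = _check_range("phq_first", phq_first, PHQ_MAX)
    p1 = _check_range("phq_last", phq_last, PHQ_MAX)
    g0 = _check_range("gad_first", gad_first, GAD_MAX)
    g1 = _check_range("gad_last", gad_last, GAD_MAX)
    dp, dg = p1 - p0, g1 - g0
    out = ((dp <= -PHQ_RELIABLE_CHANGE) | (dg <= -GAD_RELIABLE_CHANGE)) \
        & ~(dp >= PHQ_RELIABLE_CHANGE) & ~(dg >= GAD_RELIABLE_CHANGE)
    return bool(out) if out.ndim == 0 else out


def deterioration(phq_first, phq_last, gad_first, gad_last):
    """Reliable increase on either scale."""
    p0 = _check_range("phq_first", phq_first, PHQ_MAX)
    p1 = _check_range("phq_last", phq_last, PHQ_MAX)
    g0 = _check_range("gad_first", gad_first, GAD_MAX)
    g1 = _check_range("gad_last", gad_last, GAD_MAX)
    out = ((p1 - p0) >= PHQ_RELIABLE_CHANGE) | ((g1 - g0) >= GAD_RELIABLE_CHANGE)
    return bool(out) if out.ndim == 0 else out


def percent_improvement(phq_first, phq_last, gad_first, gad_last):
    """A >=25% decrease on either scale with no >=25% increase on either.

    A scale with baseline 0 can neither qualify nor disqualify via a
    percentage change.
    """
    p0 = _check_range("phq_first", phq_first, PHQ_MAX)
    p1 = _check_range("phq_last", phq_last, PHQ_MAX)
    g0 = _check_range("gad_first", gad_first, GAD_MAX)
    g1 = _check_range("gad_last", gad_last, GAD_MAX)
    dp, dg = p1 - p0, g1 - g0
    p_dec = (p0 > 0) & (dp <= -PERCENT_CHANGE * p0)
    g_dec = (g0 > 0) & (dg <= -PERCENT_CHANGE * g0)
    p_inc = (p0 > 0) & (dp >= PERCENT_CHANGE * p0)
    g_inc = (g0 > 0) & (dg >= PERCENT_CHANGE * g0)
    out = (p_dec | g_dec) & ~p_inc & ~g_inc
    return bool(out) if out.ndim == 0 else out


def compute_outcomes(cohort: Cohort, mode: str = "loose") -> pd.DataFrame:
    """Per-patient outcome flags.

    Returns a DataFrame indexed by patient_id with the first/last totals,
    the engagement flag, and (for engaged patients with complete totals)
    the three change outcomes; non-engaged patients get NA there.
    """
    totals = cohort.totals()
    n_rec = totals["n_records"].to_numpy()
    min_records = 2 if mode == "loose" else 3
    if mode not in ("loose", "strict"):
        raise ValueError(f"unknown engagement mode {mode!r}")
    engaged = n_rec >= min_records

    out = totals.copy()
    out["engaged"] = engaged
    for col in ("reliable_improvement", "deterioration", "percent_improvement"):
        out[col] = pd.array([pd.NA] * len(out), dtype="boolean")

    complete = engaged & totals[["phq_first", "phq_last", "gad_first",
                                 "gad_last"]].notna().all(axis=1).to_numpy()
    if complete.any():
        sub = totals.loc[complete]
        args = (sub["phq_first"].to_numpy(), sub["phq_last"].to_numpy(),
                sub["gad_first"].to_numpy(), sub["gad_last"].to_numpy())
        out.loc[complete, "reliable_improvement"] = reliable_improvement(*args)
        out.loc[complete, "deterioration"] = deterioration(*args)
        out.loc[complete, "percent_improvement"] = percent_improvement(*args)
    return out


def outcome_table(cohort: Cohort, decoded: DecodedCohort,
                  mode: str = "loose") -> pd.DataFrame:
    """Counts and rates of the four outcomes, grouped by decoded starting
    state.  Engagement rates are over all starters; improvement and
    deterioration rates are among engaged patients only."""
    flags = compute_outcomes(cohort, mode=mode)
    starts = decoded.start_states()
    flags = flags.join(starts.rename("start_state"), how="left")
    if flags["start_state"].isna().any():
        raise ValueError("decoded cohort does not cover every patient")

    rows = []
    for s, grp in flags.groupby("start_state", sort=True):
        eng = grp[grp["engaged"]]
        row = {"start_state": int(s), "n": len(grp), "n_engaged": len(eng),
               "engagement_rate": len(eng) / len(grp)}
        for col in ("reliable_improvement", "deterioration",
                    "percent_improvement"):
            vals = eng[col].dropna()
            row[f"n_{col}"] = int(vals.sum()) if len(vals) else 0
            row[f"{col}_rate"] = float(vals.mean()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
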