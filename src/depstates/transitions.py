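"""Trajectory summaries: state occupancy over time by starting state, the
thresholded transition graph, and per-state symptom-profile summaries.

Occupancy follows the convention that a patient who leaves treatment remains
at the last decoded state for all later time points (last observation carried
forward), so every time row is a proper distribution over states.  The
transition graph keeps an edge only if its probability reaches the threshold
for at least half of the time steps.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import N_CATEGORIES, N_ITEMS, T_MAX
from .selection import DecodedCohort, expected_severity

#: default PHQ-9 item factor assignment; items 7-9 (concentration,
#: psychomotor, self-harm) are deliberately left unassigned
DEFAULT_ITEM_GROUPS = {
    "cognitive_affective": (1, 2, 6),
    "somatic": (3, 4, 5),
}


@dataclasses.dataclass(frozen=True)
class OccupancyMatrix:
    """occupancy[s] is the (T_max, k) matrix of state proportions over time
    among patients who started in state s+1; rows sum to 1."""

    occupancy: np.ndarray      # (k_start, T_max, k)
    counts: np.ndarray         # patients per starting state
    k: int

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.occupancy.shape[0]):
            for t in range(self.occupancy.shape[1]):
                for v in range(self.k):
                    rows.append({"start_state": s + 1, "time": t + 1,
                                 "state": v + 1,
                                 "proportion": self.occupancy[s, t, v]})
        return pd.DataFrame(rows)


def occupancy_by_start(decoded: DecodedCohort, T_max: int = T_MAX,
                       ) -> OccupancyMatrix:
    """State occupancy over time, per starting state, from decoded paths with
    last-state carry-forward."""
    if decoded.paths.empty:
        raise ValueError("decoded cohort is empty")
    k = decoded.k
    g = decoded.paths.groupby("patient_id", sort=False)["state"]
    starts = g.first().to_numpy() - 1
    lengths = g.size().to_numpy()
    n = len(starts)
    full = np.empty((n, T_max), dtype=np.int64)
    pos = 0
    states = decoded.paths["state"].to_numpy() - 1
    for i, L in enumerate(lengths):
        Lc = min(L, T_max)
        full[i, :Lc] = states[pos:pos + Lc]
        full[i, Lc:] = states[pos + Lc - 1]     # carry the last state forward
        pos += L
    occ = np.zeros((k, T_max, k))
    counts = np.zeros(k, dtype=np.int64)
    for s in range(k):
        grp = full[starts == s]
        counts[s] = len(grp)
        if counts[s] == 0:
            occ[s, :, s] = 1.0                  # empty group: degenerate row
            continue
        for t in range(T_max):
            occ[s, t] = np.bincount(grp[:, t], minlength=k) / counts[s]
    return OccupancyMatrix(occupancy=occ, counts=counts, k=k)


def transition_edge_summary(Pi: np.ndarray, threshold: float = 0.05,
                            ) -> pd.DataFrame:
    """Summary of every ordered state pair across time steps.

    An edge is retained iff its transition probability is >= ``threshold``
    for at least half of the time steps (self-loops included).  Columns:
    from_state, to_state, p_min, p_max, frac_ge_threshold, retained.
    """
    Pi = np.asarray(Pi)
    n_steps, k, _ = Pi.shape
    rows = []
    for u in range(k):
        for v in range(k):
            p = Pi[:, u, v]
            frac = float((p >= threshold).mean())
            rows.append({
                "from_state": u + 1, "to_state": v + 1,
                "p_min": float(p.min()), "p_max": float(p.max()),
                "frac_ge_threshold": frac,
                "retained": frac >= 0.5,
            })
    return pd.DataFrame(rows)


def expected_state_severity(Phi: np.ndarray) -> np.ndarray:
    """Expected total PHQ-9 score per state, in [0, 27]."""
    return expected_severity(np.asarray(Phi))


def state_profile_report(Phi: np.ndarray,
                         item_groups: dict[str, tuple[int, ...]] | None = None,
                         margin: float = 0.2) -> pd.DataFrame:
    """Per-state expected item scores with factor-group means and a dominant
    factor flag.

    ``item_groups`` maps a factor name to 1-based PHQ-9 item numbers; groups
    must not overlap.  A state is flagged with the factor whose group-mean
    expected score exceeds every other group's by more than ``margin``
    (0-3 scale), else "balanced".
    """
    if item_groups is None:
        item_groups = DEFAULT_ITEM_GROUPS
    used: set[int] = set()
    for name, items in item_groups.items():
        s = set(items)
        if not s or not s <= set(range(1, N_ITEMS + 1)):
            raise ValueError(f"item group {name!r} has items outside 1..{N_ITEMS}")
        if used & s:
            raise ValueError(f"item group {name!r} overlaps another group")
        used |= s
    Phi = np.asarray(Phi)
    expected = Phi @ np.arange(N_CATEGORIES)          # (k, 9)
    rows = []
    for u in range(Phi.shape[0]):
        row = {"state": u + 1,
               "expected_total": float(expected[u].sum())}
        for j in range(N_ITEMS):
            row[f"item{j + 1}"] = float(expected[u, j])
        means = {name: float(expected[u, [i - 1 for i in items]].mean())
                 for name, items in item_groups.items()}
        for name, m in means.items():
            row[f"{name}_mean"] = m
        ranked = sorted(means.items(), key=lambda kv: kv[1], reverse=True)
        if len(ranked) >= 2 and ranked[0][1] - ranked[1][1] > margin:
            row["dominant"] = ranked[0][0]
        else:
            row["dominant"] = "balanced"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plotting (optional)
# ---------------------------------------------------------------------------

def plot_occupancy(occ: OccupancyMatrix, start_state: int, ax=None):
    """Stacked-area occupancy plot for one starting state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = occ.occupancy[start_state - 1]
    t = np.arange(1, data.shape[0] + 1)
    ax.stackplot(t, data.T, labels=[f"state {v + 1}" for v in range(occ.k)])
    ax.set_xlabel("session")
    ax.set_ylabel("proportion of patients")
    ax.set_title(f"starting state {start_state}")
    ax.set_xlim(1, data.shape[0])
    ax.set_ylim(0, 1)
    ax.legend(fontsize="x-small", ncol=2)
    return ax


def plot_transition_graph(summary: pd.DataFrame, ax=None):
    """Directed graph of retained edges; edge width scales with the maximum
    transition probability across time."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots()
    G = nx.DiGraph()
    states = sorted(set(summary["from_state"]) | set(summary["to_state"]))
    G.add_nodes_from(states)
    kept = summary[summary["retained"] & (summary["from_state"] != summary["to_state"])]
    for _, r in kept.iterrows():
        G.add_edge(int(r["from_state"]), int(r["to_state"]), weight=r["p_max"])
    pos = nx.circular_layout(G)
    widths = [3.0 * G.edges[e]["weight"] + 0.3 for e in G.edges]
    nx.draw_networkx(G, pos=pos, ax=ax, node_color="lightsteelblue",
                     width=widths, arrows=True, connectionstyle="arc3,rad=0.1")
    ax.set_axis_off()
    return ax
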