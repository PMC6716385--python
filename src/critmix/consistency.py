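"""Descriptive two-session analyses: inconsistency rates and criterion changes.

An *inconsistent* response is any change of answer to the same membership
question across the two sessions — yes/no, yes/unknown or no/unknown; an
unchanged answer (including unknown on both occasions) is consistent.
Criterion changes are participants whose posterior-mode group differs between
their session-1 and session-2 entries; their prevalence is reported both over
all participants and over participants with at least one inconsistency in the
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RESPONSE_TOKENS, ResponseTable
from .model import AssignmentResult


def classify_pair(r1: str, r2: str) -> str:
    """Classify one session pair as ``consistent`` or ``inconsistent``."""
    for r in (r1, r2):
        if r not in RESPONSE_TOKENS:
            raise ValueError(f"invalid response token {r!r}")
    return "inconsistent" if r1 != r2 else "consistent"


@dataclass
class ConsistencyReport:
    """Per-pair, per-participant, per-item inconsistency bookkeeping."""

    pairs: pd.DataFrame                # participant, category, item, r1, r2, inconsistent
    per_participant: pd.DataFrame      # participant: proportion overall + per block
    per_participant_category: pd.DataFrame  # participant x category proportions
    per_item: pd.DataFrame             # category, item: proportion of participants
    fully_consistent: pd.DataFrame     # participant x category flag
    zero_inconsistency_items: list
    overall_proportion: float
    include_unknown_pairs: bool = True

    def participants_with_inconsistency(self, category: str) -> set:
        df = self.per_participant_category
        sel = (df["category"] == category) & (df["n_inconsistent"] > 0)
        return set(df.loc[sel, "participant"])


def _session_pairs(new_data: ResponseTable) -> pd.DataFrame:
    df = new_data.df
    s1 = df[df["session"] == 1]
    s2 = df[df["session"] == 2]
    pairs = s1.merge(s2, on=["participant", "category", "item"],
                     suffixes=("_1", "_2"), validate="one_to_one")
    counts1 = s1.groupby(["participant", "category"]).size()
    counts2 = s2.groupby(["participant", "category"]).size()
    if not counts1.index.equals(counts2.index):
        raise ValueError("every participant must have both sessions for every category")
    pairs = pairs.rename(columns={"response_1": "r1", "response_2": "r2"})
    pairs["inconsistent"] = pairs["r1"] != pairs["r2"]
    return pairs[["participant", "category", "item", "r1", "r2", "inconsistent"]]


def build_consistency_report(
    new_data: ResponseTable,
    block_map: dict[str, str],
    include_unknown_pairs: bool = True,
) -> ConsistencyReport:
    """Classify every session pair and aggregate the proportions.

    ``block_map`` assigns each category to a block (e.g. ``nominal`` /
    ``ad hoc``).  ``include_unknown_pairs=False`` removes unknown/unknown
    pairs from all denominators (the alternative reading of the task's
    three-option design).
    """
    pairs = _session_pairs(new_data)
    unmapped = set(pairs["category"]) - set(block_map)
    if unmapped:
        raise ValueError(f"categories missing from block_map: {sorted(unmapped)}")
    if not include_unknown_pairs:
        pairs = pairs[~((pairs["r1"] == "unknown") & (pairs["r2"] == "unknown"))]
    pairs = pairs.copy()
    pairs["block"] = pairs["category"].map(block_map)

    per_pc = (pairs.groupby(["participant", "category"], as_index=False)
              .agg(n_pairs=("inconsistent", "size"),
                   n_inconsistent=("inconsistent", "sum")))
    per_pc["proportion"] = per_pc["n_inconsistent"] / per_pc["n_pairs"]

    per_participant = (pairs.groupby("participant")
                       .agg(proportion=("inconsistent", "mean")))
    by_block = (pairs.groupby(["participant", "block"])["inconsistent"].mean()
                .unstack())
    per_participant = per_participant.join(
        by_block.rename(columns=lambda b: f"proportion_{b}")).reset_index()

    per_item = (pairs.groupby(["category", "item"], as_index=False)
                .agg(n_pairs=("inconsistent", "size"),
                     n_inconsistent=("inconsistent", "sum")))
    per_item["proportion"] = per_item["n_inconsistent"] / per_item["n_pairs"]

    fully = per_pc.assign(fully_consistent=per_pc["n_inconsistent"] == 0)[
        ["participant", "category", "fully_consistent"]]
    zero_items = [
        (c, i) for c, i, n in per_item[["category", "item", "n_inconsistent"]]
        .itertuples(index=False) if n == 0
    ]
    return ConsistencyReport(
        pairs=pairs, per_participant=per_participant,
        per_participant_category=per_pc, per_item=per_item,
        fully_consistent=fully, zero_inconsistency_items=zero_items,
        overall_proportion=float(pairs["inconsistent"].mean()),
        include_unknown_pairs=include_unknown_pairs,
    )


def assign_sessions(assignments: AssignmentResult,
                    entry_index: pd.DataFrame) -> pd.DataFrame:
    """Pair each two-session participant's session-wise modal groups.

    Archival entries are excluded.  Returns one row per participant with
    1-based ``group_s1``/``group_s2``, both assignment-probability vectors
    and a ``changed`` flag.
    """
    idx = entry_index.reset_index(drop=True)
    rows = []
    for pid, grp in idx[idx["provenance"] != "archival"].groupby("participant"):
        if sorted(grp["session"]) != [1, 2]:
            raise ValueError(f"participant {pid!r} does not have exactly two session entries")
        e1 = grp[grp["session"] == 1].index[0]
        e2 = grp[grp["session"] == 2].index[0]
        g1 = int(assignments.modal_group[e1])
        g2 = int(assignments.modal_group[e2])
        rows.append({
            "participant": pid, "group_s1": g1 + 1, "group_s2": g2 + 1,
            "prob_s1": assignments.prob[e1].tolist(),
            "prob_s2": assignments.prob[e2].tolist(),
            "tie_s1": bool(assignments.tie_flag[e1]),
            "tie_s2": bool(assignments.tie_flag[e2]),
            "changed": g1 != g2,
        })
    return pd.DataFrame(rows)


@dataclass
class GroupChangeReport:
    """Criterion-change prevalence with both denominators."""

    per_participant_category: pd.DataFrame  # participant, category, groups, changed
    per_category: pd.DataFrame  # n_changed, n_participants, n_with_inconsistency, rates
    per_participant_counts: pd.DataFrame    # participant, n_categories_changed
    change_count_distribution: dict         # {"0": k0, "1": k1, "2": k2, "3+": k3}


def build_group_change_report(
    session_pairs: dict[str, pd.DataFrame] | pd.DataFrame,
    consistency: ConsistencyReport,
) -> GroupChangeReport:
    """Count criterion changes per category and per participant.

    ``session_pairs`` maps category to the output of :func:`assign_sessions`
    (or is a single frame with a ``category`` column).  The restricted
    denominator counts only participants with at least one inconsistency in
    that category.
    """
    if isinstance(session_pairs, dict):
        frames = [df.assign(category=cat) for cat, df in session_pairs.items()]
        pairs = pd.concat(frames, ignore_index=True)
    else:
        pairs = session_pairs.copy()
        if "category" not in pairs.columns:
            raise ValueError("session_pairs frame needs a category column")

    cons_participants = set(consistency.per_participant["participant"])
    if not set(pairs["participant"]) <= cons_participants:
        raise ValueError("session pairs contain participants missing from the consistency report")

    cat_rows = []
    for cat, grp in pairs.groupby("category"):
        with_inc = consistency.participants_with_inconsistency(cat)
        changed = grp[grp["changed"]]
        n_changed_inc = int(changed["participant"].isin(with_inc).sum())
        cat_rows.append({
            "category": cat,
            "n_participants": len(grp),
            "n_changed": int(grp["changed"].sum()),
            "n_with_inconsistency": len(with_inc),
            "n_changed_with_inconsistency": n_changed_inc,
            "change_rate_all": float(grp["changed"].mean()) if len(grp) else np.nan,
            "change_rate_among_inconsistent": (
                n_changed_inc / len(with_inc) if with_inc else np.nan),
        })
    per_category = pd.DataFrame(cat_rows)

    counts = (pairs.groupby("participant")["changed"].sum().astype(int)
              .rename("n_categories_changed").reset_index())
    dist = {"0": 0, "1": 0, "2": 0, "3+": 0}
    for n in counts["n_categories_changed"]:
        dist[str(n) if n < 3 else "3+"] += 1
    return GroupChangeReport(
        per_participant_category=pairs,
        per_category=per_category,
        per_participant_counts=counts,
        change_count_distribution=dist,
    )


def block_prevalence_summary(report, block_map: dict[str, str]) -> pd.DataFrame:
    """Per-block descriptive rates with participant-level dispersion.

    For a :class:`ConsistencyReport` the unit is a participant's inconsistency
    proportion within the block; for a :class:`GroupChangeReport` it is a
    participant's change rate over the block's categories.  Blocks without any
    categories in the data get an explicit empty row rather than NaN noise.
    """
    if isinstance(report, ConsistencyReport):
        unit = report.per_participant_category.copy()
        unit["rate"] = unit["proportion"]
    elif isinstance(report, GroupChangeReport):
        unit = report.per_participant_category.copy()
        unit["rate"] = unit["changed"].astype(float)
    else:
        raise TypeError("report must be a ConsistencyReport or GroupChangeReport")
    unit["block"] = unit["category"].map(block_map)
    unmapped = unit["category"][unit["block"].isna()].unique()
    if len(unmapped):
        raise ValueError(f"categories missing from block_map: {sorted(unmapped)}")

    per_part = unit.groupby(["block", "participant"])["rate"].mean().reset_index()
    rows = []
    for block in sorted(set(block_map.values())):
        r = per_part.loc[per_part["block"] == block, "rate"]
        if r.empty:
            rows.append({"block": block, "n_participants": 0, "empty": True,
                         "mean": None, "sd": None, "q1": None, "median": None,
                         "q3": None})
            continue
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        rows.append({"block": block, "n_participants": int(r.size), "empty": False,
                     "mean": float(r.mean()),
                     "sd": float(r.std(ddof=1)) if r.size > 1 else 0.0,
                     "q1": float(q1), "median": float(med), "q3": float(q3)})
    out = pd.DataFrame(rows)
    stat_cols = ["mean", "sd", "q1", "median", "q3"]
    out[stat_cols] = out[stat_cols].astype(object).where(~out["empty"], None)
    return out
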