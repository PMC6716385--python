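"""Long-format categorization response tables and the merged entry-by-item matrix.

Responses to a repeated categorization task are kept in long format, one row
per (participant, category, item, session) with a three-valued answer
(``yes`` / ``no`` / ``unknown``).  Before model fitting, the two sessions of
each participant are stacked as *independent* respondent entries alongside any
single-session archival respondents, giving a binary matrix with missing cells
where the answer was ``unknown``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONSE_TOKENS = ("yes", "no", "unknown")
PROVENANCE_TOKENS = ("new", "archival", "synthetic")

REQUIRED_COLUMNS = ("participant", "category", "item", "session", "response")


class FormatError(ValueError):
    """A file does not have the required tabular layout."""


@dataclass
class ResponseTable:
    """Long-format categorization responses.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``participant``, ``category``, ``item``, ``session`` (1 or 2),
        ``response`` (``yes`` / ``no`` / ``unknown``) and optionally
        ``provenance`` (``new`` / ``archival`` / ``synthetic``; default
        ``new``).

    Missing answers are encoded as ``unknown`` rows, never as absent rows:
    within a category every item is expected for every participant-session.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        if "provenance" not in df.columns:
            df["provenance"] = "new"
        for col in ("participant", "category", "item"):
            df[col] = df[col].astype(str)
        df["session"] = df["session"].astype(int)
        df["response"] = df["response"].astype(str).str.strip().str.lower()
        bad = ~df["response"].isin(RESPONSE_TOKENS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unrecognized response token {df['response'].iloc[row]!r} at row {row}"
            )
        bad_prov = ~df["provenance"].isin(PROVENANCE_TOKENS)
        if bad_prov.any():
            raise ValueError("provenance must be one of " + ", ".join(PROVENANCE_TOKENS))
        if not df["session"].isin((1, 2)).all():
            raise ValueError("session must be 1 or 2")
        if (df.loc[df["provenance"] == "archival", "session"] != 1).any():
            raise ValueError("archival records must have session = 1")
        key = ["participant", "category", "item", "session"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValueError(f"duplicate record for {tuple(first)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def categories(self) -> list[str]:
        return sorted(self.df["category"].unique())

    def participants(self, category: str | None = None) -> list[str]:
        df = self.df if category is None else self.df[self.df["category"] == category]
        return sorted(df["participant"].unique())

    def subset(self, category: str) -> "ResponseTable":
        return ResponseTable(self.df[self.df["category"] == category].copy())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def concat(cls, tables: list["ResponseTable"]) -> "ResponseTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


def read_responses(path, provenance: str | None = None) -> ResponseTable:
    """Read a long-format response CSV.

    The header must name ``participant,category,item,session,response``
    (``session`` may be absent for archival files, defaulting to 1).
    ``provenance`` overrides / supplies the provenance column.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    if "session" not in df.columns:
        df["session"] = 1
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if provenance is not None:
        df["provenance"] = provenance
    return ResponseTable(df)


@dataclass
class MergedMatrix:
    """Entry-by-item binary matrix for one category.

    Each entry is either one (participant, session) pair of the two-session
    data, treated as an independent respondent, or one archival participant.
    ``x`` holds 1 for *yes*, 0 for *no*, NaN for *unknown*.  Items are ordered
    lexicographically so parameter indexing is reproducible.
    """

    category_id: str
    items: list[str]
    x: np.ndarray  # (n_entries, n_items) float, values in {0.0, 1.0, nan}
    entry_index: pd.DataFrame = field(repr=False)  # entry_id, participant, session, provenance

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be 2-dimensional")
        if self.x.shape != (len(self.entry_index), len(self.items)):
            raise ValueError("x shape does not match entry_index / items")
        vals = self.x[~np.isnan(self.x)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("x must contain only 0, 1 or NaN")

    @property
    def n_entries(self) -> int:
        return self.x.shape[0]

    @property
    def n_items(self) -> int:
        return self.x.shape[1]


_CODE = {"yes": 1.0, "no": 0.0, "unknown": np.nan}


def merge_sessions(
    new_data: ResponseTable,
    archival_data: ResponseTable | None,
    category_id: str,
) -> MergedMatrix:
    """Stack both sessions of the repeated task plus archival respondents.

    Every participant in ``new_data`` for the category must have completed
    both sessions (the analysis is restricted to completers); each of their
    sessions becomes a separate entry.  Archival respondents contribute one
    entry each.  *Unknown* answers become missing cells.
    """
    new_df = new_data.df[new_data.df["category"] == category_id]
    if new_df.empty and (archival_data is None or archival_data.df.empty):
        raise ValueError(f"no data for category {category_id!r}")

    frames = []
    for pid, grp in new_df.groupby("participant", sort=True):
        sessions = set(grp["session"])
        if sessions != {1, 2}:
            raise ValueError(
                f"participant {pid!r} lacks a complete session pair in {category_id!r}"
            )
        frames.append(grp)
    new_df = pd.concat(frames) if frames else new_df

    items = set(new_df["item"].unique())
    arch_df = None
    if archival_data is not None:
        arch_df = archival_data.df[archival_data.df["category"] == category_id]
        items |= set(arch_df["item"].unique())
    items = sorted(items)

    rows, index_rows = [], []
    def add_entry(pid: str, session: int, provenance: str, grp: pd.DataFrame) -> None:
        answered = dict(zip(grp["item"], grp["response"]))
        extra = set(answered) - set(items)
        if extra:
            raise ValueError(f"unexpected item(s) {sorted(extra)} for {pid!r}")
        rows.append([_CODE[answered.get(it, "unknown")] for it in items])
        index_rows.append((f"{pid}:s{session}" if provenance != "archival" else pid,
                           pid, session, provenance))

    for (pid, session), grp in new_df.groupby(["participant", "session"], sort=True):
        add_entry(pid, int(session), str(grp["provenance"].iloc[0]), grp)
    if arch_df is not None:
        for pid, grp in arch_df.groupby("participant", sort=True):
            add_entry(pid, 1, "archival", grp)

    entry_index = pd.DataFrame(
        index_rows, columns=["entry_id", "participant", "session", "provenance"]
    )
    x = np.asarray(rows, dtype=float) if rows else np.empty((0, len(items)))
    return MergedMatrix(category_id=category_id, items=list(items), x=x,
                        entry_index=entry_index)


def write_matrix(m: MergedMatrix, path) -> None:
    """Serialize a merged matrix as CSV; missing cells are written as ``NA``."""
    df = m.entry_index.copy()
    for j, item in enumerate(m.items):
        df[item] = m.x[:, j]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# category={m.category_id}\n")
        df.to_csv(fh, index=False, na_rep="NA", float_format="%.0f")


def read_matrix(path) -> MergedMatrix:
    """Inverse of :func:`write_matrix`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# category="):
            raise FormatError(f"{path}: missing category header line")
        category_id = header.split("=", 1)[1]
        body = fh.read()
    df = pd.read_csv(io.StringIO(body), dtype={"participant": str, "entry_id": str})
    meta_cols = ["entry_id", "participant", "session", "provenance"]
    if [c for c in meta_cols if c not in df.columns]:
        raise FormatError(f"{path}: missing entry-index columns")
    items = [c for c in df.columns if c not in meta_cols]
    x = df[items].to_numpy(dtype=float) if items else np.empty((len(df), 0))
    entry_index = df[meta_cols].copy()
    entry_index["session"] = entry_index["session"].astype(int)
    return MergedMatrix(category_id=category_id, items=items, x=x,
                        entry_index=entry_index)
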