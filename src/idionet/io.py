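"""Read and write diaries, networks, and result tables as flat CSV.

Diary CSV dialects
------------------
long
    Columns ``participant_id, date, item_id, score``; one row per observation.
wide
    Columns ``participant_id, date`` plus one column per item; empty cells are
    missing items.

Dates are ISO-8601 calendar dates.  Networks are written as edge lists
(``node_i, node_j, weight``) storing each unordered pair once with
``node_i < node_j`` lexicographically and omitting zero edges and the
diagonal; weights are formatted with 17 significant digits so a read-back is
bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import (
    Cohort,
    DataIntegrityError,
    DiaryMatrix,
    ItemSchema,
    SchemaError,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_network",
    "read_network",
    "write_results",
]

_LONG_COLUMNS = ("participant_id", "date", "item_id", "score")


def _reject(report: list[dict], row_number, participant, reason: str) -> None:
    report.append(
        {"row": row_number, "participant_id": participant, "reason": reason}
    )


def read_cohort(
    diary_path, labels_path, schema: ItemSchema
) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort from diary + labels CSVs.

    The diary CSV may be in long or wide format (detected from the header).
    Rows with unparseable dates or out-of-range scores are rejected and
    listed, one row per rejection, in the returned report DataFrame
    (columns ``row, participant_id, reason``).  Duplicate participant-days
    raise :class:`DataIntegrityError`; unknown items or missing required
    columns raise :class:`SchemaError`.

    Returns
    -------
    (cohort, rejected_rows_report)
    """
    raw = pd.read_csv(diary_path, dtype=str, keep_default_na=False)
    cols = set(raw.columns)
    if {"participant_id", "date"} - cols:
        raise SchemaError(
            "diary CSV must have participant_id and date columns; "
            f"found {sorted(cols)}"
        )
    report: list[dict] = []
    if {"item_id", "score"} <= cols:
        wide = _long_to_wide(raw, schema, report)
    else:
        item_cols = cols - {"participant_id", "date"}
        unknown = item_cols - set(schema.item_ids)
        if unknown:
            raise SchemaError(f"unknown item columns: {sorted(unknown)}")
        missing_items = set(schema.item_ids) - item_cols
        if missing_items:
            raise SchemaError(f"missing item columns: {sorted(missing_items)}")
        wide = _clean_wide(raw, schema, report)

    diaries: dict[str, DiaryMatrix] = {}
    for pid, grp in wide.groupby("participant_id", sort=True):
        if grp["date"].duplicated().any():
            dup = grp.loc[grp["date"].duplicated(), "date"].iloc[0]
            raise DataIntegrityError(
                f"duplicate diary day for participant {pid}: {dup.date()}"
            )
        scores = (
            grp.set_index("date")[list(schema.item_ids)]
            .sort_index()
            .astype(float)
        )
        scores.index.name = None
        scores.columns.name = None
        diaries[str(pid)] = DiaryMatrix(str(pid), scores)

    labels = _read_labels(labels_path)
    missing = set(labels) - set(diaries)
    if missing:
        raise DataIntegrityError(
            f"labelled participants without diary rows: {sorted(missing)}"
        )
    cohort = Cohort(schema=schema, diaries=diaries, relapse_labels=labels)
    report_df = pd.DataFrame(report, columns=["row", "participant_id", "reason"])
    return cohort, report_df


def _parse_scores(
    values: pd.Series, schema: ItemSchema
) -> tuple[pd.Series, pd.Series]:
    """Return (numeric scores with NaN, bad-value mask). Empty cells are missing."""
    stripped = values.str.strip()
    num = pd.to_numeric(stripped.replace({"": None, "NA": None, "nan": None}),
                        errors="coerce")
    bad = num.notna() & ((num < schema.scale_min) | (num > schema.scale_max))
    unparseable = num.isna() & ~stripped.isin(["", "NA", "nan"])
    return num, bad | unparseable


def _clean_wide(raw: pd.DataFrame, schema: ItemSchema, report: list[dict]) -> pd.DataFrame:
    dates = pd.to_datetime(raw["date"].str.strip(), format="ISO8601", errors="coerce")
    keep = np.ones(len(raw), dtype=bool)
    for i in np.flatnonzero(dates.isna().to_numpy()):
        _reject(report, i + 2, raw["participant_id"].iloc[i], "unparseable date")
        keep[i] = False
    out = raw.loc[keep].copy()
    out["date"] = dates[keep]
    bad_row = np.zeros(len(out), dtype=bool)
    for item in schema.item_ids:
        num, bad = _parse_scores(out[item], schema)
        for i in np.flatnonzero(bad.to_numpy()):
            _reject(
                report,
                bad.index[i] + 2,
                out["participant_id"].iloc[i],
                f"invalid score for {item}",
            )
        bad_row |= bad.to_numpy()
        out[item] = num
    return out.loc[~bad_row]  # a row with any invalid score is rejected whole


def _long_to_wide(raw: pd.DataFrame, schema: ItemSchema, report: list[dict]) -> pd.DataFrame:
    missing_cols = set(_LONG_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise SchemaError(f"long diary CSV missing columns: {sorted(missing_cols)}")
    unknown = set(raw["item_id"].str.strip()) - set(schema.item_ids)
    if unknown:
        raise SchemaError(f"unknown item_id values: {sorted(unknown)}")
    dates = pd.to_datetime(raw["date"].str.strip(), format="ISO8601", errors="coerce")
    num, bad = _parse_scores(raw["score"], schema)
    keep = np.ones(len(raw), dtype=bool)
    for i in np.flatnonzero(dates.isna().to_numpy()):
        _reject(report, i + 2, raw["participant_id"].iloc[i], "unparseable date")
        keep[i] = False
    for i in np.flatnonzero(bad.to_numpy() & keep):
        _reject(
            report,
            i + 2,
            raw["participant_id"].iloc[i],
            f"invalid score for {raw['item_id'].iloc[i].strip()}",
        )
        keep[i] = False
    clean = pd.DataFrame(
        {
            "participant_id": raw["participant_id"][keep].str.strip(),
            "date": dates[keep],
            "item_id": raw["item_id"][keep].str.strip(),
            "score": num[keep],
        }
    )
    dup = clean.duplicated(subset=["participant_id", "date", "item_id"], keep=False)
    if dup.any():
        r = clean.loc[dup].iloc[0]
        raise DataIntegrityError(
            f"duplicate diary entry for participant {r['participant_id']} "
            f"on {r['date'].date()} ({r['item_id']})"
        )
    wide = clean.pivot(
        index=["participant_id", "date"], columns="item_id", values="score"
    )
    for item in schema.item_ids:  # items never observed still need a column
        if item not in wide.columns:
            wide[item] = np.nan
    return wide.reset_index()[["participant_id", "date", *schema.item_ids]]


def _read_labels(labels_path) -> dict[str, bool]:
    lab = pd.read_csv(labels_path, dtype=str)
    if {"participant_id", "relapsed"} - set(lab.columns):
        raise SchemaError(
            "labels CSV must have participant_id and relapsed columns"
        )
    truthy = {"1", "true", "yes"}
    falsy = {"0", "false", "no"}
    out: dict[str, bool] = {}
    for _, row in lab.iterrows():
        pid = str(row["participant_id"]).strip()
        val = str(row["relapsed"]).strip().lower()
        if val in truthy:
            out[pid] = True
        elif val in falsy:
            out[pid] = False
        else:
            raise SchemaError(f"non-binary relapse label for {pid}: {row['relapsed']!r}")
        if pid in out and list(lab["participant_id"].str.strip()).count(pid) > 1:
            raise DataIntegrityError(f"duplicate label rows for {pid}")
    return out


def write_cohort(cohort: Cohort, diary_path, labels_path, fmt: str = "wide") -> None:
    """Write a cohort back to diary + labels CSVs (``fmt`` 'wide' or 'long')."""
    rows = []
    for pid, diary in cohort.diaries.items():
        df = diary.scores.copy()
        df.insert(0, "date", df.index.strftime("%Y-%m-%d"))
        df.insert(0, "participant_id", pid)
        rows.append(df)
    wide = pd.concat(rows, axis=0, ignore_index=True)
    for item in cohort.schema.item_ids:  # integers where observed
        wide[item] = wide[item].map(lambda v: "" if pd.isna(v) else str(int(v)))
    if fmt == "wide":
        wide.to_csv(diary_path, index=False)
    elif fmt == "long":
        long = wide.melt(
            id_vars=["participant_id", "date"], var_name="item_id", value_name="score"
        )
        long = long[long["score"] != ""].sort_values(
            ["participant_id", "date", "item_id"], kind="stable"
        )
        long.to_csv(diary_path, index=False)
    else:
        raise ValueError(f"unknown diary format {fmt!r}")
    pd.DataFrame(
        {
            "participant_id": list(cohort.relapse_labels),
            "relapsed": [int(v) for v in cohort.relapse_labels.values()],
        }
    ).to_csv(labels_path, index=False)


def write_network(network, path) -> None:
    """Write a network as an edge-list CSV (node_i < node_j, nonzero edges only)."""
    items = list(network.items)
    w = np.asarray(network.w)
    lines = ["node_i,node_j,weight"]
    order = sorted(range(len(items)), key=lambda i: items[i])
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            if w[i, j] != 0.0:
                lines.append(f"{items[i]},{items[j]},{format(w[i, j], '.17g')}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network(path, items: Sequence[str] | None = None):
    """Read an edge-list CSV back into a :class:`~idionet.network.SymptomNetwork`.

    If ``items`` is omitted the node set is inferred from the edges (isolated
    nodes are then unrecoverable).
    """
    from .network import SymptomNetwork  # local import to avoid a cycle

    df = pd.read_csv(path, dtype={"node_i": str, "node_j": str, "weight": float})
    if items is None:
        items = sorted(set(df["node_i"]) | set(df["node_j"]))
    items = list(items)
    pos = {it: k for k, it in enumerate(items)}
    w = np.zeros((len(items), len(items)))
    for _, row in df.iterrows():
        i, j = pos[row["node_i"]], pos[row["node_j"]]
        w[i, j] = w[j, i] = row["weight"]
    return SymptomNetwork(items=tuple(items), w=w, provenance={"source": str(path)})


def write_results(
    networks: Iterable,
    tables: dict[str, pd.DataFrame],
    out_dir,
    metadata: dict | None = None,
) -> list[Path]:
    """Write networks (edge lists), result tables (CSV) and a JSON summary.

    ``tables`` maps a short name (e.g. ``"comparison"``) to a DataFrame; each
    is written as ``<name>.csv``.  ``metadata`` (seed, config hash, warnings)
    goes to ``summary.json``.  Returns the list of paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for net in networks:
        pid = net.provenance.get("participant_id", "network")
        p = net_dir / f"network_{pid}.csv"
        write_network(net, p)
        written.append(p)
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    summary = out / "summary.json"
    summary.write_text(
        json.dumps(metadata or {}, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    written.append(summary)
    return written
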