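"""Extraction of ordered dyadic association events from RFID visit streams.

The raw data are perch-occupancy records: one row per second during which a
tagged bird sat on a perch of a feeder unit.  A dyadic association event
begins when both perches of one unit are occupied by distinct individuals and
ends when either bird leaves (or is replaced by another forager, which closes
the event and opens a new one).  The first bird of the dyad to arrive is the
"source", the joiner the "target"; arrival latency is the difference between
their arrival times within the ongoing occupancy bout.  The outcome of an
event is determined entirely by the treatment classes of the participants:
same-class dyads succeed, different-class dyads fail.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VISIT_COLUMNS",
    "EVENT_COLUMNS",
    "read_visits",
    "extract_events",
    "read_events",
    "write_events",
    "class_map_from",
    "affiliate_pairs_from",
]

VISIT_COLUMNS = ("tag_id", "day", "feeder", "perch", "time")
EVENT_COLUMNS = (
    "index",
    "day",
    "feeder",
    "source",
    "target",
    "start",
    "latency",
    "duration",
    "outcome",
    "is_same_class",
    "is_affiliate",
)


def class_map_from(individuals: pd.DataFrame) -> dict[str, str]:
    """``id -> treatment_class`` mapping from an individuals table."""
    return dict(zip(individuals["id"], individuals["treatment_class"]))


def affiliate_pairs_from(affiliations: pd.DataFrame | None) -> set[frozenset]:
    """Set of unordered affiliated dyads from an edge list."""
    if affiliations is None or len(affiliations) == 0:
        return set()
    return {
        frozenset((a, b)) for a, b in zip(affiliations["id1"], affiliations["id2"])
    }


def read_visits(path) -> pd.DataFrame:
    """Read and validate a per-second visit CSV.

    Rows are returned time-sorted regardless of input order.  Missing columns
    or unparseable / negative timestamps are rejected with the offending row
    numbers (1-based, excluding the header).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in VISIT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"visit file missing column(s): {missing}")
    out = raw.loc[:, list(VISIT_COLUMNS)].copy()
    for col in ("day", "feeder", "perch", "time"):
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() | (parsed < 0) | (parsed != parsed.round())
        if bad.any():
            rows = (out.index[bad] + 1).tolist()[:20]
            raise ValueError(f"unparseable {col} in row(s) {rows}")
        out[col] = parsed.astype(int)
    out = out.sort_values(
        ["day", "feeder", "perch", "time", "tag_id"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def _runs(times: np.ndarray, tags: np.ndarray) -> list[tuple[str, int, int]]:
    """Compress per-second occupancy of one perch into (tag, start, end) runs.

    ``end`` is exclusive.  A new run starts whenever the tag changes or the
    second counter jumps (a raw read gap splits the run; gaps are bridged
    later, at the event level, by ``gap_tolerance``).
    """
    runs: list[tuple[str, int, int]] = []
    if len(times) == 0:
        return runs
    start = prev = times[0]
    tag = tags[0]
    for t, g in zip(times[1:], tags[1:]):
        if g != tag or t != prev + 1:
            runs.append((tag, int(start), int(prev) + 1))
            start, tag = t, g
        prev = t
    runs.append((tag, int(start), int(prev) + 1))
    return runs


def extract_events(
    visits: pd.DataFrame,
    individuals: pd.DataFrame,
    affiliations: pd.DataFrame | None = None,
    *,
    gap_tolerance: int = 2,
    test_tags: Iterable[str] = (),
) -> pd.DataFrame:
    """Turn validated visit records into the ordered association-event list.

    Parameters
    ----------
    visits
        Per-second records with columns ``tag_id, day, feeder, perch, time``.
    individuals
        Table with ``id`` and ``treatment_class``; every tag in the stream
        must map to a known individual (after test-tag removal).
    affiliations
        Optional edge list (``id1, id2, relation``) marking long-term
        affiliated dyads (mates, parent-offspring, siblings).
    gap_tolerance
        Consecutive co-occupancy bouts by the same dyad separated by at most
        this many seconds are merged into one event, bridging isolated missed
        RFID reads.  Set to 0 to keep every raw overlap separate.
    test_tags
        Tag ids of the spare test tags used for daily functionality checks;
        their records are removed before extraction.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be non-negative")
    test_tags = set(test_tags)
    v = visits[~visits["tag_id"].isin(test_tags)]
    known = set(individuals["id"])
    unknown = sorted(set(v["tag_id"]) - known)
    if unknown:
        raise ValueError(f"unknown tag id(s) in visit stream: {unknown[:10]}")

    # exact duplicate reads are harmless; collapse them first
    v = v.drop_duplicates(subset=["day", "feeder", "perch", "time", "tag_id"])

    # physical impossibilities: one bird on both perches of one unit at once,
    # or two birds on one perch in the same second
    dup = v.duplicated(subset=["day", "feeder", "time", "tag_id"], keep=False)
    if dup.any():
        offender = v[dup].iloc[0]
        raise ValueError(
            "individual "
            f"{offender['tag_id']!r} recorded on both perches of feeder "
            f"{offender['feeder']} at day {offender['day']} t={offender['time']}"
        )
    crowd = v.duplicated(subset=["day", "feeder", "perch", "time"], keep=False)
    if crowd.any():
        offender = v[crowd].iloc[0]
        raise ValueError(
            "two tags recorded on one perch in the same second "
            f"(feeder {offender['feeder']}, day {offender['day']}, "
            f"t={offender['time']})"
        )

    class_of = class_map_from(individuals)
    affiliates = affiliate_pairs_from(affiliations)

    raw: list[tuple] = []
    for (day, feeder), grp in v.groupby(["day", "feeder"], sort=True):
        perch_runs: dict[int, list[tuple[str, int, int]]] = {}
        for perch, pgrp in grp.groupby("perch", sort=True):
            pgrp = pgrp.sort_values("time", kind="mergesort")
            perch_runs[perch] = _runs(
                pgrp["time"].to_numpy(), pgrp["tag_id"].to_numpy()
            )
        perches = sorted(perch_runs)
        for pi in range(len(perches)):
            for pj in range(pi + 1, len(perches)):
                for tag_a, s_a, e_a in perch_runs[perches[pi]]:
                    for tag_b, s_b, e_b in perch_runs[perches[pj]]:
                        lo, hi = max(s_a, s_b), min(e_a, e_b)
                        if hi <= lo or tag_a == tag_b:
                            continue
                        if s_a < s_b or (s_a == s_b and tag_a < tag_b):
                            src, tgt, lat = tag_a, tag_b, s_b - s_a
                        else:
                            src, tgt, lat = tag_b, tag_a, s_a - s_b
                        raw.append((day, feeder, src, tgt, lo, lat, hi - lo))

    raw.sort(key=lambda r: (r[0], r[4], r[1], r[2], r[3]))

    merged: list[list] = []
    for rec in raw:
        day, feeder, src, tgt, start, lat, dur = rec
        if merged:
            m = merged[-1]
            same_dyad = {m[2], m[3]} == {src, tgt}
            gap = start - (m[4] + m[6])
            if (
                m[0] == day
                and m[1] == feeder
                and same_dyad
                and 0 <= gap <= gap_tolerance
            ):
                m[6] = start + dur - m[4]  # extend through the bridged gap
                continue
        merged.append([day, feeder, src, tgt, start, lat, dur])

    events = pd.DataFrame(
        merged,
        columns=["day", "feeder", "source", "target", "start", "latency", "duration"],
    )
    events = events.sort_values(
        ["day", "start", "feeder", "source", "target"], kind="mergesort"
    ).reset_index(drop=True)
    events.insert(0, "index", np.arange(1, len(events) + 1))
    if len(events):
        same = np.array(
            [
                class_of[s] == class_of[t]
                for s, t in zip(events["source"], events["target"])
            ]
        )
        events["outcome"] = np.where(same, "success", "fail")
        events["is_same_class"] = same
        events["is_affiliate"] = [
            frozenset((s, t)) in affiliates
            for s, t in zip(events["source"], events["target"])
        ]
    else:
        events["outcome"] = pd.Series(dtype=str)
        events["is_same_class"] = pd.Series(dtype=bool)
        events["is_affiliate"] = pd.Series(dtype=bool)
    return events[list(EVENT_COLUMNS)]


def write_events(events: pd.DataFrame, path) -> None:
    """Write the event list in the package's stable CSV dialect."""
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


def read_events(
    path,
    individuals: pd.DataFrame | None = None,
    affiliations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read a previously extracted event CSV.

    If an individuals table is supplied, class-match and outcome columns are
    recomputed from it (and affiliate flags from the edge list), overriding
    whatever the file carries.
    """
    ev = pd.read_csv(path)
    required = {"index", "day", "feeder", "source", "target", "start", "latency", "duration"}
    missing = required - set(ev.columns)
    if missing:
        raise ValueError(f"event file missing column(s): {sorted(missing)}")
    if individuals is not None:
        class_of = class_map_from(individuals)
        unknown = sorted(
            (set(ev["source"]) | set(ev["target"])) - set(class_of)
        )
        if unknown:
            raise ValueError(f"unknown individual(s) in event file: {unknown[:10]}")
        same = np.array(
            [class_of[s] == class_of[t] for s, t in zip(ev["source"], ev["target"])],
            dtype=bool,
        )
        ev["is_same_class"] = same
        ev["outcome"] = np.where(same, "success", "fail")
        affiliates = affiliate_pairs_from(affiliations)
        ev["is_affiliate"] = [
            frozenset((s, t)) in affiliates
            for s, t in zip(ev["source"], ev["target"])
        ]
    return ev.sort_values("index", kind="mergesort").reset_index(drop=True)
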