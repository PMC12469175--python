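"""Canonical data model for single-cell lineage-tracking experiments.

A tracked experiment is a forest of cells: each :class:`CellRecord` carries
its identity, parent, founder-lineage label (which doubles as a barcode),
birth and end times in hours from experiment start, and how it ended
(division, death, or censoring at the end of observation).  Two tracking
modes are supported: ``full_tree`` (both daughters of every division
tracked, HCT116-style) and ``forward_lineage`` (one randomly chosen daughter
tracked per division, U2OS-style; the untracked daughter is kept as a stub
record with ``tracked=False`` so divisions remain countable).

Time conventions: continuous hours, experiment start at 0, drug added at
``t_drug``; events at exactly ``t_drug`` count as post-drug.  Cells alive at
``t_end`` are censored there ("persisters" downstream are cells censored at
``t_end``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CellRecord",
    "ExperimentConfig",
    "ExperimentTable",
    "ExclusionReport",
    "SummaryCounts",
    "DurationObs",
    "LineageValidationError",
    "read_cell_table",
    "write_cell_table",
    "apply_exclusions",
    "extract_durations",
    "population_curve",
    "summary_counts",
]

END_EVENTS = ("division", "death", "censored")
_TIME_TOL = 1e-6


class LineageValidationError(ValueError):
    """A table violated a structural invariant; names the offending cell."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment layout: drug timing, horizon, imaging cadence, tracking."""

    t_drug: float = 48.0
    t_end: float = 120.0
    snapshot_interval: float = 0.5
    tracking_mode: str = "full_tree"
    concentration_label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.t_drug < self.t_end):
            raise ValueError("require 0 < t_drug < t_end")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be > 0")
        if self.tracking_mode not in ("full_tree", "forward_lineage"):
            raise ValueError(f"unknown tracking_mode {self.tracking_mode!r}")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = open(path).read()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(**data)


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    parent_id: str | None
    lineage_id: str
    birth_time: float
    end_time: float
    end_event: str
    tracked: bool = True

    def __post_init__(self) -> None:
        if self.end_event not in END_EVENTS:
            raise ValueError(f"cell {self.cell_id}: bad end_event {self.end_event!r}")
        if self.end_time < self.birth_time - _TIME_TOL:
            raise ValueError(f"cell {self.cell_id}: end_time < birth_time")

    @property
    def duration(self) -> float:
        return self.end_time - self.birth_time

    @property
    def is_founder(self) -> bool:
        return self.parent_id is None


@dataclass
class ExclusionReport:
    n_total: int
    n_never_dividers: int
    n_pre_drug_deaths: int
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_never_dividers + self.n_pre_drug_deaths

    @property
    def n_included(self) -> int:
        return self.n_total - self.n_excluded


@dataclass
class SummaryCounts:
    """Dataset summary around drug addition (Table-1-style)."""

    n_at_drug: int
    n_divided: int
    n_died: int
    n_survived: int
    pairs_both_survived: int | None
    pairs_split: int | None
    pairs_both_died: int | None

    @property
    def death_fraction(self) -> float | None:
        """Fraction of drug-time cells whose sub-lineage fully dies.

        Counts cells that die outright plus divisions where both daughter
        sub-lineages die, over the number of cells at drug time.  Requires
        full-tree pair statistics.
        """
        if self.pairs_both_died is None or self.n_at_drug == 0:
            return None
        return (self.n_died + self.pairs_both_died) / self.n_at_drug

    @property
    def persister_fraction(self) -> float | None:
        df = self.death_fraction
        return None if df is None else 1.0 - df


class DurationObs(NamedTuple):
    duration: float
    censored: bool
    straddles_drug: bool


class ExperimentTable:
    """A validated collection of cell records plus the experiment config."""

    def __init__(self, records: Iterable[CellRecord], config: ExperimentConfig,
                 validate: bool = True, strict: bool = True):
        self.records: list[CellRecord] = list(records)
        self.config = config
        self._by_id = {r.cell_id: r for r in self.records}
        self._children: dict[str, list[str]] = {}
        for r in self.records:
            if r.parent_id is not None:
                self._children.setdefault(r.parent_id, []).append(r.cell_id)
        if validate:
            self.validate(strict=strict)

    # -- basic access -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, cell_id: str) -> CellRecord:
        return self._by_id[cell_id]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._by_id

    def children(self, cell_id: str) -> list[CellRecord]:
        return [self._by_id[c] for c in self._children.get(cell_id, ())]

    @property
    def founders(self) -> list[CellRecord]:
        return [r for r in self.records if r.is_founder]

    def tracked_records(self) -> list[CellRecord]:
        return [r for r in self.records if r.tracked]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [r.cell_id for r in self.records],
                "parent_id": [r.parent_id or "" for r in self.records],
                "lineage_id": [r.lineage_id for r in self.records],
                "birth_time": [r.birth_time for r in self.records],
                "end_time": [r.end_time for r in self.records],
                "end_event": [r.end_event for r in self.records],
                "tracked": [r.tracked for r in self.records],
            }
        )

    def extant_at(self, t: float) -> list[CellRecord]:
        """Tracked cells alive at time ``t``; censored cells count through
        ``t_end`` inclusive."""
        out = []
        for r in self.records:
            if not r.tracked:
                continue
            if r.birth_time <= t and (
                r.end_time > t or (r.end_event == "censored" and r.end_time >= t)
            ):
                out.append(r)
        return out

    def extant_at_drug(self) -> list[CellRecord]:
        """Tracked cells present when the drug is added.

        A cell whose event falls exactly at ``t_drug`` counts as extant (its
        event is post-drug); a daughter born exactly at ``t_drug`` does not.
        """
        td = self.config.t_drug
        return [
            r
            for r in self.records
            if r.tracked and r.birth_time < td and r.end_time >= td
        ]

    # -- validation -------------------------------------------------------
    def validate(self, strict: bool = True) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.cell_id in seen:
                raise LineageValidationError(f"duplicate cell_id {r.cell_id!r}")
            seen.add(r.cell_id)
        for r in self.records:
            if r.birth_time < -_TIME_TOL or r.end_time > self.config.t_end + _TIME_TOL:
                raise LineageValidationError(
                    f"cell {r.cell_id}: times outside [0, t_end]"
                )
            if r.tracked and r.end_event == "censored" and not np.isclose(
                r.end_time, self.config.t_end, atol=_TIME_TOL
            ):
                raise LineageValidationError(
                    f"cell {r.cell_id}: censored but end_time != t_end"
                )
            if r.parent_id is not None:
                parent = self._by_id.get(r.parent_id)
                if parent is None:
                    raise LineageValidationError(
                        f"cell {r.cell_id}: dangling parent_id {r.parent_id!r}"
                    )
                if parent.end_event != "division":
                    raise LineageValidationError(
                        f"cell {r.cell_id}: parent {parent.cell_id} did not divide"
                    )
                if abs(parent.end_time - r.birth_time) > _TIME_TOL:
                    raise LineageValidationError(
                        f"cell {r.cell_id}: birth_time {r.birth_time} != parent "
                        f"end_time {parent.end_time}"
                    )
                if r.lineage_id != parent.lineage_id:
                    raise LineageValidationError(
                        f"cell {r.cell_id}: lineage_id differs from parent's"
                    )
        # forest: walk each cell to its root with a step bound
        n = len(self.records)
        for r in self.records:
            cur, steps = r, 0
            while cur.parent_id is not None:
                cur = self._by_id[cur.parent_id]
                steps += 1
                if steps > n:
                    raise LineageValidationError(
                        f"cell {r.cell_id}: cycle in parent graph"
                    )
        if strict:
            full = self.config.tracking_mode == "full_tree"
            for r in self.records:
                if r.end_event != "division":
                    continue
                kids = self.children(r.cell_id)
                n_tracked = sum(k.tracked for k in kids)
                if full and len(kids) != 2:
                    raise LineageValidationError(
                        f"cell {r.cell_id}: division with {len(kids)} children "
                        "(expected 2 in full_tree mode)"
                    )
                if not full and n_tracked != 1:
                    raise LineageValidationError(
                        f"cell {r.cell_id}: division with {n_tracked} tracked "
                        "children (expected 1 in forward_lineage mode)"
                    )


# --------------------------------------------------------------------------
# I/O

_COLUMNS = ["cell_id", "parent_id", "lineage_id", "birth_time", "end_time",
            "end_event", "tracked"]


def read_cell_table(path, config: ExperimentConfig,
                    strict: bool = True) -> ExperimentTable:
    """Read a UTF-8 cell-record CSV and return a validated table.

    Malformed rows, duplicate ids, dangling parents and time inconsistencies
    raise :class:`LineageValidationError` naming the offending cell.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str,
                                  "lineage_id": str}, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LineageValidationError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                CellRecord(
                    cell_id=row.cell_id,
                    parent_id=row.parent_id or None,
                    lineage_id=row.lineage_id,
                    birth_time=float(row.birth_time),
                    end_time=float(row.end_time),
                    end_event=row.end_event,
                    tracked=_parse_bool(row.tracked),
                )
            )
        except (ValueError, TypeError) as exc:
            raise LineageValidationError(f"{path} row {i + 2}: {exc}") from exc
    return ExperimentTable(records, config, strict=strict)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "t", "yes")


def write_cell_table(table: ExperimentTable, path) -> None:
    """Write the documented CSV dialect (times with 6 decimals)."""
    df = table.to_frame()
    df["birth_time"] = df["birth_time"].map(lambda x: f"{x:.6f}")
    df["end_time"] = df["end_time"].map(lambda x: f"{x:.6f}")
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# exclusion filters


def apply_exclusions(table: ExperimentTable) -> tuple[ExperimentTable, ExclusionReport]:
    """Apply the standard pre-analysis filters.

    Removes (a) never-dividers — founders with no division over their whole
    observed trajectory, together with their single-node lineage — and
    (b) cells that die before drug addition (their record only).  Idempotent.
    """
    never_ids = {
        r.cell_id
        for r in table.founders
        if r.tracked and r.end_event != "division"
    }
    pre_death_ids = {
        r.cell_id
        for r in table.records
        if r.cell_id not in never_ids
        and r.tracked
        and r.end_event == "death"
        and r.end_time < table.config.t_drug
    }
    excluded = never_ids | pre_death_ids
    kept = [r for r in table.records if r.cell_id not in excluded]
    report = ExclusionReport(
        n_total=len(table.records),
        n_never_dividers=len(never_ids),
        n_pre_drug_deaths=len(pre_death_ids),
        excluded_ids=sorted(excluded),
    )
    # pre-drug-death removal can leave a parent with one child, so the
    # two-children check is relaxed on the filtered table
    return ExperimentTable(kept, table.config, strict=False), report


# --------------------------------------------------------------------------
# durations, population curve, summaries


def extract_durations(table: ExperimentTable, window: str,
                      event: str = "any") -> list[DurationObs]:
    """Cell-event durations (end - birth) in the pre- or post-drug window.

    ``window='pre'`` keeps cells whose event falls strictly before
    ``t_drug``; ``window='post'`` keeps cells whose event (or censoring
    time) falls at or after ``t_drug``, flagging straddlers born pre-drug.
    Censored cells are returned only with ``event='any'``.  Untracked stub
    records never contribute.
    """
    if window not in ("pre", "post"):
        raise ValueError(f"window must be 'pre' or 'post', got {window!r}")
    if event not in ("division", "death", "any"):
        raise ValueError(f"bad event filter {event!r}")
    td = table.config.t_drug
    out = []
    for r in table.records:
        if not r.tracked:
            continue
        in_window = r.end_time < td if window == "pre" else r.end_time >= td
        if not in_window:
            continue
        if event != "any" and r.end_event != event:
            continue
        if event == "any" and r.end_event == "censored":
            pass
        elif r.end_event == "censored":
            continue
        out.append(
            DurationObs(
                duration=r.duration,
                censored=r.end_event == "censored",
                straddles_drug=window == "post" and r.birth_time < td,
            )
        )
    return out


def population_curve(table: ExperimentTable, time_grid=None,
                     normalize_by: float | None = None):
    """Number of tracked cells alive at each grid time.

    A cell counts at ``t`` if ``birth_time <= t < end_time``; censored cells
    additionally count at ``t_end`` itself.  ``normalize_by`` divides counts
    (e.g. number of fields of view) for per-field averages.

    Returns ``(times, counts)`` arrays.
    """
    if time_grid is None:
        cfg = table.config
        time_grid = np.arange(0.0, cfg.t_end + cfg.snapshot_interval / 2,
                              cfg.snapshot_interval)
    t = np.asarray(time_grid, dtype=float)
    recs = table.tracked_records()
    birth = np.array([r.birth_time for r in recs])
    end = np.array([r.end_time for r in recs])
    cens = np.array([r.end_event == "censored" for r in recs])
    alive = (birth[None, :] <= t[:, None]) & (
        (end[None, :] > t[:, None]) | (cens[None, :] & (end[None, :] >= t[:, None]))
    )
    counts = alive.sum(axis=1).astype(float)
    if normalize_by:
        counts = counts / float(normalize_by)
    return t, counts


def _subtree_survives(table: ExperimentTable, cell: CellRecord) -> bool:
    """True if the cell or any descendant is censored alive at t_end."""
    stack = [cell]
    while stack:
        r = stack.pop()
        if r.end_event == "censored" and r.tracked:
            return True
        stack.extend(table.children(r.cell_id))
    return False


def summary_counts(table: ExperimentTable) -> SummaryCounts:
    """Drug-time census and post-drug fate tallies (Table-1-style).

    Expects exclusions to have been applied already.  Daughter-pair fates
    are only available in full-tree mode (``None`` otherwise); a daughter
    "survives" if its sub-lineage reaches ``t_end``.
    """
    at_drug = table.extant_at_drug()
    n_div = sum(r.end_event == "division" for r in at_drug)
    n_die = sum(r.end_event == "death" for r in at_drug)
    n_surv = sum(r.end_event == "censored" for r in at_drug)
    full = table.config.tracking_mode == "full_tree"
    if not full:
        return SummaryCounts(len(at_drug), n_div, n_die, n_surv, None, None, None)
    both_s = split = both_d = 0
    td = table.config.t_drug
    for r in table.records:
        if r.end_event != "division" or r.end_time < td:
            continue
        kids = table.children(r.cell_id)
        if len(kids) != 2:
            continue
        s = sum(_subtree_survives(table, k) for k in kids)
        if s == 2:
            both_s += 1
        elif s == 1:
            split += 1
        else:
            both_d += 1
    return SummaryCounts(len(at_drug), n_div, n_die, n_surv, both_s, split, both_d)
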