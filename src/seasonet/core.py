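"""Dated visitation records and seasonal bipartite network assembly.

The atomic observation is a dated plant–pollinator visit.  Records are
aggregated into bipartite networks per period (a calendar month, a season,
or the whole sampling year); a species belongs to a period's community only
if it was involved in at least one interaction there.  Interaction
frequency divides a link's visit total by the number of distinct days on
which its plant was visited by any bee within the period, a proxy for that
plant's flowering activity.
"""

from __future__ import annotations

import datetime as dt
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RAINY = "rainy"
DRY = "dry"

__all__ = [
    "RAINY",
    "DRY",
    "VisitRecord",
    "SeasonCalendar",
    "DEFAULT_CALENDAR",
    "BipartiteNetwork",
    "FrequencyTable",
    "read_visit_records",
    "assign_season",
    "build_network",
    "interaction_frequency",
    "monthly_series",
    "network_from_edge_list",
]


@dataclass(frozen=True)
class VisitRecord:
    """One dated observation of a bee visiting a plant.

    Parameters
    ----------
    date : datetime.date
        Day of the observation.
    plant, pollinator : str
        Species identifiers; opaque, case-sensitive, and drawn from
        disjoint namespaces (a label cannot denote both a plant and a bee).
    count : int
        Number of visits recorded in this observation (default 1).
    """

    date: dt.date
    plant: str
    pollinator: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"visit count must be >= 1, got {self.count}")
        if not self.plant or not self.pollinator:
            raise ValueError("plant and pollinator identifiers must be non-empty")


@dataclass(frozen=True)
class SeasonCalendar:
    """Month-of-year to season mapping.

    The default follows the central-Brazil bi-seasonal climate: rainy from
    October through March, dry from April through September, with the
    transitional months April and October assigned to the dry and rainy
    seasons respectively.
    """

    month_to_season: Mapping[int, str]

    def __post_init__(self) -> None:
        months = set(self.month_to_season)
        if months != set(range(1, 13)):
            missing = sorted(set(range(1, 13)) - months)
            raise ValueError(f"calendar must map every month 1-12; missing {missing}")

    @classmethod
    def cerrado_default(cls) -> "SeasonCalendar":
        mapping = {m: (RAINY if m in (10, 11, 12, 1, 2, 3) else DRY) for m in range(1, 13)}
        return cls(month_to_season=mapping)

    @classmethod
    def from_json(cls, path: str | Path) -> "SeasonCalendar":
        raw = json.loads(Path(path).read_text())
        return cls(month_to_season={int(k): str(v) for k, v in raw.items()})

    def season_of_month(self, month: int) -> str:
        return self.month_to_season[month]

    @property
    def seasons(self) -> frozenset[str]:
        return frozenset(self.month_to_season.values())


DEFAULT_CALENDAR = SeasonCalendar.cerrado_default()


def assign_season(date: dt.date, cal: SeasonCalendar = DEFAULT_CALENDAR) -> str:
    """Season label of ``date``; the month alone decides."""
    return cal.season_of_month(date.month)


@dataclass(frozen=True)
class BipartiteNetwork:
    """A bipartite plant–pollinator network for one period.

    ``visits`` maps each realized (plant, pollinator) link to its visit
    total; ``active_days`` maps each plant to the number of distinct dates
    on which it received at least one visit within the period.
    """

    visits: Mapping[tuple[str, str], int]
    active_days: Mapping[str, int]
    period_label: str = "all"

    def __post_init__(self) -> None:
        plants_seen = {p for p, _ in self.visits}
        if plants_seen != set(self.active_days):
            raise ValueError("active_days keys must equal the set of linked plants")
        for (p, b), v in self.visits.items():
            if v < 1:
                raise ValueError(f"link ({p}, {b}) has non-positive visit total {v}")
        for p, d in self.active_days.items():
            if d < 1:
                raise ValueError(f"plant {p} has non-positive active-day count {d}")
        overlap = self.plants & self.pollinators
        if overlap:
            raise ValueError(
                f"identifiers used as both plant and pollinator: {sorted(overlap)[:5]}"
            )

    @property
    def plants(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.visits)

    @property
    def pollinators(self) -> frozenset[str]:
        return frozenset(b for _, b in self.visits)

    @property
    def links(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.visits)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinators)

    @property
    def n_links(self) -> int:
        return len(self.visits)

    @property
    def n_visits(self) -> int:
        return sum(self.visits.values())

    @property
    def is_empty(self) -> bool:
        return not self.visits

    def plant_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for p, _ in self.visits:
            deg[p] = deg.get(p, 0) + 1
        return deg

    def pollinator_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for _, b in self.visits:
            deg[b] = deg.get(b, 0) + 1
        return deg

    def incidence_frame(self) -> pd.DataFrame:
        """Binary plant (rows) × pollinator (columns) incidence matrix."""
        plants = sorted(self.plants)
        bees = sorted(self.pollinators)
        frame = pd.DataFrame(0, index=plants, columns=bees, dtype=int)
        for p, b in self.visits:
            frame.at[p, b] = 1
        return frame

    def summary(self) -> dict:
        return {
            "period": self.period_label,
            "network_size": self.n_plants + self.n_pollinators,
            "n_plants": self.n_plants,
            "n_pollinators": self.n_pollinators,
            "n_links": self.n_links,
            "n_visits": self.n_visits,
        }

    def to_edge_list(self) -> pd.DataFrame:
        """Edge list with visits and interaction frequency, one row per link."""
        rows = []
        for (p, b), v in sorted(self.visits.items()):
            rows.append(
                {
                    "plant": p,
                    "pollinator": b,
                    "visits": v,
                    "frequency": v / self.active_days[p],
                }
            )
        return pd.DataFrame(rows, columns=["plant", "pollinator", "visits", "frequency"])

    def write_edge_list(self, path: str | Path) -> None:
        self.to_edge_list().to_csv(path, sep="\t", index=False)


def network_from_edge_list(source: str | Path | io.TextIOBase, period_label: str = "all") -> BipartiteNetwork:
    """Rebuild a network from an exported edge-list TSV.

    Per-plant active-day counts are recovered from visits/frequency, which
    is exact because every link of a plant shares the plant's denominator.
    """
    frame = pd.read_csv(source, sep="\t")
    visits: dict[tuple[str, str], int] = {}
    active: dict[str, int] = {}
    for row in frame.itertuples(index=False):
        visits[(str(row.plant), str(row.pollinator))] = int(row.visits)
        active[str(row.plant)] = int(round(row.visits / row.frequency))
    return BipartiteNetwork(visits=visits, active_days=active, period_label=period_label)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-link interaction frequency F[plant, pollinator] = visits / active days of the plant."""

    F: Mapping[tuple[str, str], float]

    def plant_weighted_degree(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (p, _), f in self.F.items():
            out[p] = out.get(p, 0.0) + f
        return out

    def pollinator_weighted_degree(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (_, b), f in self.F.items():
            out[b] = out.get(b, 0.0) + f
        return out

    @property
    def total(self) -> float:
        return sum(self.F.values())


_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_REQUIRED = ("date", "plant", "pollinator")


def _sniff_sep(header_line: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if "\t" in header_line else ","


def read_visit_records(
    source: str | Path | io.TextIOBase,
    sep: str | None = None,
) -> list[VisitRecord]:
    """Parse a delimited visits table into records.

    The table must carry a header naming ``date``, ``plant`` and
    ``pollinator`` columns (any order); an optional ``count`` column
    defaults to 1.  Dates must be ISO-8601 (YYYY-MM-DD).  Errors are
    addressed by 1-based data-row number.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if not text.strip():
        raise ValueError("empty input: no header line")
    header_line = text.splitlines()[0]
    sep = _sniff_sep(header_line, sep)
    header = [h.strip() for h in header_line.split(sep)]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ValueError(f"duplicate header column(s): {sorted(dupes)}")
    missing = [c for c in _REQUIRED if c not in header]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    records: list[VisitRecord] = []
    has_count = "count" in frame.columns
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw_date = getattr(row, "date").strip()
        if not _DATE_RE.match(raw_date):
            raise ValueError(f"row {i}: date {raw_date!r} is not ISO-8601 (YYYY-MM-DD)")
        try:
            date = dt.date.fromisoformat(raw_date)
        except ValueError as exc:
            raise ValueError(f"row {i}: invalid date {raw_date!r}: {exc}") from None
        count = 1
        if has_count:
            raw_count = getattr(row, "count").strip()
            if raw_count:
                try:
                    count = int(raw_count)
                except ValueError:
                    raise ValueError(f"row {i}: count {raw_count!r} is not an integer") from None
        try:
            records.append(
                VisitRecord(date=date, plant=getattr(row, "plant").strip(), pollinator=getattr(row, "pollinator").strip(), count=count)
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    _check_namespaces(records)
    return records


def _check_namespaces(records: Iterable[VisitRecord]) -> None:
    plants = {r.plant for r in records}
    bees = {r.pollinator for r in records}
    overlap = plants & bees
    if overlap:
        raise ValueError(f"identifiers used as both plant and pollinator: {sorted(overlap)[:5]}")


_MONTH_RE = re.compile(r"^\d{4}-\d{2}$")


def _period_filter(period: str, cal: SeasonCalendar):
    if period == "all":
        return lambda r: True
    if period in cal.seasons:
        return lambda r: cal.season_of_month(r.date.month) == period
    if _MONTH_RE.match(period):
        year, month = int(period[:4]), int(period[5:7])
        return lambda r: r.date.year == year and r.date.month == month
    raise ValueError(f"unknown period {period!r}; use 'all', a season name, or YYYY-MM")


def build_network(
    records: Sequence[VisitRecord],
    period: str = "all",
    cal: SeasonCalendar = DEFAULT_CALENDAR,
) -> BipartiteNetwork:
    """Aggregate records matching ``period`` into a bipartite network.

    Duplicate (date, plant, pollinator) observations are summed.  A period
    with no matching records yields an explicitly empty network and a
    logged warning.
    """
    keep = _period_filter(period, cal)
    selected = [r for r in records if keep(r)]
    _check_namespaces(selected)
    if not selected:
        logger.warning("no visit records in period %r; returning empty network", period)
        return BipartiteNetwork(visits={}, active_days={}, period_label=period)
    visits: dict[tuple[str, str], int] = {}
    plant_days: dict[str, set[dt.date]] = {}
    for r in selected:
        key = (r.plant, r.pollinator)
        visits[key] = visits.get(key, 0) + r.count
        plant_days.setdefault(r.plant, set()).add(r.date)
    active = {p: len(days) for p, days in plant_days.items()}
    return BipartiteNetwork(visits=visits, active_days=active, period_label=period)


def interaction_frequency(net: BipartiteNetwork) -> FrequencyTable:
    """Interaction frequency per link: visits divided by the plant's active days."""
    if net.is_empty:
        raise ValueError("no links: interaction frequency undefined on an empty network")
    F = {(p, b): v / net.active_days[p] for (p, b), v in net.visits.items()}
    return FrequencyTable(F=F)


def monthly_series(
    records: Sequence[VisitRecord],
    cal: SeasonCalendar = DEFAULT_CALENDAR,
) -> list[BipartiteNetwork]:
    """One network per calendar month from the earliest to the latest month present.

    Intervening months without records yield empty networks (with a warning)
    so that month-to-month indexing stays uniform.
    """
    if not records:
        raise ValueError("no records: cannot build a monthly series")
    months = sorted({(r.date.year, r.date.month) for r in records})
    (y0, m0), (y1, m1) = months[0], months[-1]
    series: list[BipartiteNetwork] = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        series.append(build_network(records, period=f"{y:04d}-{m:02d}", cal=cal))
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return series
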