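"""Synthetic seasonal plant–pollinator communities with known ground truth.

The generator emulates a weekly-sampled bi-seasonal (rainy/dry) community:
most species are active only within a contiguous phenology window inside
one season, while a configurable minority — the social-bee analogue — is
aseasonal and active year-round.  Pair propensities are the product of
lognormal species abundances and a heavy-tailed compatibility factor,
which yields truncated-power-law-like degree tails; daily visit totals
are Poisson with the day rate calibrated so the expected annual total
matches the configured target.  Everything is deterministic given a seed.

Also provided are deterministic fixture builders that realize exact
published marginal counts (species, link and visit totals) with arbitrary
wiring, for metric-fidelity checks that depend only on the marginals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_CALENDAR,
    RAINY,
    DRY,
    BipartiteNetwork,
    SeasonCalendar,
    VisitRecord,
    build_network,
    monthly_series,
)

__all__ = [
    "CommunityConfig",
    "GroundTruth",
    "default_sampling_days",
    "generate_community",
    "generator_selfcheck",
    "network_with_marginals",
    "seasonal_networks_with_overlap",
]

ASEASONAL = "aseasonal"


def default_sampling_days(
    start: dt.date = dt.date(2008, 10, 1),
    end: dt.date = dt.date(2009, 9, 30),
    n_days: int = 47,
) -> tuple[dt.date, ...]:
    """``n_days`` sampling dates spread evenly across a 12-month study year."""
    span = (end - start).days
    offsets = np.unique(np.round(np.linspace(0, span, n_days)).astype(int))
    return tuple(start + dt.timedelta(days=int(o)) for o in offsets)


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the seasonal community generator.

    Defaults emulate the study-year scale of a campo-sujo Cerrado
    community: 93 plants, 111 bees, 968 visits over 47 weekly sampling
    days, with ~30% aseasonal pollinators and few aseasonal plants.
    """

    n_plants: int = 93
    n_pollinators: int = 111
    frac_aseasonal_pollinators: float = 0.30
    frac_aseasonal_plants: float = 0.05
    calendar: SeasonCalendar = DEFAULT_CALENDAR
    sampling_days: tuple[dt.date, ...] = field(default_factory=default_sampling_days)
    target_total_visits: int = 968
    abundance_sigma: float = 1.0  # log-scale sd of species abundances
    compat_tail_exponent: float = 1.5  # Pareto tail of the pair-compatibility factor
    compat_cutoff: float = 20.0  # cap on the compatibility factor (soft degree cutoff)
    window_weeks: tuple[int, int] = (4, 16)  # phenology window length range, weeks
    rainy_fraction_seasonal: float = 0.6  # share of seasonal species assigned to rainy

    def __post_init__(self) -> None:
        for name in ("frac_aseasonal_pollinators", "frac_aseasonal_plants", "rainy_fraction_seasonal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_plants, self.n_pollinators, self.target_total_visits) < 1:
            raise ValueError("species counts and visit target must be positive")
        if not self.sampling_days:
            raise ValueError("need at least one sampling day")
        if self.window_weeks[0] < 1 or self.window_weeks[0] > self.window_weeks[1]:
            raise ValueError("window_weeks must be an increasing positive range")


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind a generated record set, for recovery tests."""

    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    plant_season: Mapping[str, str]  # rainy | dry | aseasonal
    pollinator_season: Mapping[str, str]
    plant_abundance: Mapping[str, float]
    pollinator_abundance: Mapping[str, float]
    plant_window: Mapping[str, tuple[dt.date, dt.date]]
    pollinator_window: Mapping[str, tuple[dt.date, dt.date]]
    propensity: np.ndarray = field(repr=False)  # n_plants × n_pollinators


def _season_blocks(days: Sequence[dt.date], cal: SeasonCalendar) -> dict[str, tuple[dt.date, dt.date]]:
    """First/last calendar date of each season's block within the study year."""
    start, end = min(days), max(days)
    blocks: dict[str, list[dt.date]] = {}
    d = start
    while d <= end:
        blocks.setdefault(cal.season_of_month(d.month), []).append(d)
        d += dt.timedelta(days=1)
    return {s: (min(ds), max(ds)) for s, ds in blocks.items()}


def _assign_seasons(
    rng: np.random.Generator, n: int, frac_aseasonal: float, rainy_fraction: float
) -> list[str]:
    n_aseasonal = int(round(frac_aseasonal * n))
    n_seasonal = n - n_aseasonal
    n_rainy = int(round(rainy_fraction * n_seasonal))
    labels = [ASEASONAL] * n_aseasonal + [RAINY] * n_rainy + [DRY] * (n_seasonal - n_rainy)
    return [labels[i] for i in rng.permutation(n)]


def _draw_window(
    rng: np.random.Generator,
    label: str,
    blocks: Mapping[str, tuple[dt.date, dt.date]],
    window_weeks: tuple[int, int],
    year_span: tuple[dt.date, dt.date],
) -> tuple[dt.date, dt.date]:
    if label == ASEASONAL:
        return year_span
    if label not in blocks:
        raise ValueError(
            f"infeasible configuration: season {label!r} has no days within the sampling span"
        )
    lo, hi = blocks[label]
    block_days = (hi - lo).days + 1
    length = 7 * int(rng.integers(window_weeks[0], window_weeks[1] + 1))
    length = min(length, block_days)
    start_off = int(rng.integers(0, block_days - length + 1))
    start = lo + dt.timedelta(days=start_off)
    return start, start + dt.timedelta(days=length - 1)


def generate_community(
    config: CommunityConfig, seed: int | None = None
) -> tuple[list[VisitRecord], GroundTruth]:
    """Simulate one study year of dated visit records plus its ground truth.

    Raises if no plant–pollinator pair is ever co-active on any sampling
    day (an infeasible configuration).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    plants = tuple(f"P{i + 1:03d}" for i in range(cfg.n_plants))
    polls = tuple(f"B{i + 1:03d}" for i in range(cfg.n_pollinators))
    year_span = (min(cfg.sampling_days), max(cfg.sampling_days))
    blocks = _season_blocks(cfg.sampling_days, cfg.calendar)

    pl_season = dict(zip(plants, _assign_seasons(rng, cfg.n_plants, cfg.frac_aseasonal_plants, cfg.rainy_fraction_seasonal)))
    po_season = dict(zip(polls, _assign_seasons(rng, cfg.n_pollinators, cfg.frac_aseasonal_pollinators, cfg.rainy_fraction_seasonal)))
    pl_window = {p: _draw_window(rng, pl_season[p], blocks, cfg.window_weeks, year_span) for p in plants}
    po_window = {b: _draw_window(rng, po_season[b], blocks, cfg.window_weeks, year_span) for b in polls}

    pl_abund = dict(zip(plants, np.exp(rng.normal(0.0, cfg.abundance_sigma, cfg.n_plants))))
    po_abund = dict(zip(polls, np.exp(rng.normal(0.0, cfg.abundance_sigma, cfg.n_pollinators))))
    # heavy-tailed compatibility: Pareto(alpha) capped at compat_cutoff
    compat = (1.0 - rng.random((cfg.n_plants, cfg.n_pollinators))) ** (-1.0 / cfg.compat_tail_exponent)
    compat = np.minimum(compat, cfg.compat_cutoff)
    propensity = (
        np.array([pl_abund[p] for p in plants])[:, None]
        * np.array([po_abund[b] for b in polls])[None, :]
        * compat
    )

    pl_active_by_day = []
    po_active_by_day = []
    for day in cfg.sampling_days:
        pl_active_by_day.append(np.array([pl_window[p][0] <= day <= pl_window[p][1] for p in plants]))
        po_active_by_day.append(np.array([po_window[b][0] <= day <= po_window[b][1] for b in polls]))
    feasible_days = [
        i for i in range(len(cfg.sampling_days))
        if pl_active_by_day[i].any() and po_active_by_day[i].any()
    ]
    if not feasible_days:
        raise ValueError("infeasible configuration: no co-active plant–pollinator pair on any sampling day")

    day_rate = cfg.target_total_visits / len(feasible_days)
    records: list[VisitRecord] = []
    for i in feasible_days:
        day = cfg.sampling_days[i]
        sub = propensity[np.ix_(pl_active_by_day[i], po_active_by_day[i])]
        pl_idx = np.flatnonzero(pl_active_by_day[i])
        po_idx = np.flatnonzero(po_active_by_day[i])
        weights = sub.ravel() / sub.sum()
        n_visits = int(rng.poisson(day_rate))
        if n_visits == 0:
            continue
        draws = rng.choice(sub.size, size=n_visits, replace=True, p=weights)
        for cell in draws:
            p = plants[pl_idx[cell // len(po_idx)]]
            b = polls[po_idx[cell % len(po_idx)]]
            records.append(VisitRecord(date=day, plant=p, pollinator=b, count=1))

    truth = GroundTruth(
        plant_ids=plants,
        pollinator_ids=polls,
        plant_season=pl_season,
        pollinator_season=po_season,
        plant_abundance=pl_abund,
        pollinator_abundance=po_abund,
        plant_window=pl_window,
        pollinator_window=po_window,
        propensity=propensity,
    )
    return records, truth


def generator_selfcheck(
    records: Sequence[VisitRecord], truth: GroundTruth, config: CommunityConfig
) -> dict:
    """Diagnostics on a generated dataset; reports pass/fail without raising.

    Checks that (a) aseasonal pollinators are over-represented at the top
    of the cumulative degree ranking, (b) pooled degrees rank the
    truncated power law first, and (c) monthly interaction turnover is
    high (median β_int > 0.5).  Raises only on a records/truth mismatch
    or an empty record list.
    """
    from .metrics import fit_degree_models  # deferred: avoids cycle at import time
    from .turnover import beta_series

    if not records:
        raise ValueError("empty record list")
    known_pl, known_po = set(truth.plant_ids), set(truth.pollinator_ids)
    for r in records:
        if r.plant not in known_pl or r.pollinator not in known_po:
            raise ValueError(f"record species {r.plant!r}/{r.pollinator!r} unknown to ground truth")
        if not (truth.plant_window[r.plant][0] <= r.date <= truth.plant_window[r.plant][1]):
            raise ValueError(f"plant {r.plant} visited outside its phenology window")
        if not (truth.pollinator_window[r.pollinator][0] <= r.date <= truth.pollinator_window[r.pollinator][1]):
            raise ValueError(f"pollinator {r.pollinator} active outside its window")

    net = build_network(records, period="all", cal=config.calendar)
    po_deg = net.pollinator_degree()
    ranked = sorted(po_deg, key=po_deg.get, reverse=True)
    top = ranked[: max(1, len(ranked) // 10)]
    frac_top_aseasonal = np.mean([truth.pollinator_season[b] == ASEASONAL for b in top])
    frac_overall = np.mean(
        [truth.pollinator_season[b] == ASEASONAL for b in po_deg]
    )
    aseasonal_top = bool(frac_top_aseasonal > frac_overall)

    pooled = list(net.plant_degree().values()) + list(po_deg.values())
    try:
        fits = fit_degree_models(pooled)
        tpl_first = fits[0].model == "truncated power-law"
    except ValueError:
        tpl_first = False

    betas = [r.beta_int for r in beta_series(monthly_series(records, config.calendar)) if r.defined]
    high_turnover = bool(np.median(betas) > 0.5) if betas else False

    return {
        "aseasonal_pollinators_top_ranked": aseasonal_top,
        "frac_top_decile_aseasonal": float(frac_top_aseasonal),
        "frac_aseasonal_overall": float(frac_overall),
        "truncated_powerlaw_first": tpl_first,
        "high_monthly_turnover": high_turnover,
        "median_beta_int": float(np.median(betas)) if betas else float("nan"),
    }


# --- deterministic fixture builders ------------------------------------------

def network_with_marginals(
    n_plants: int,
    n_pollinators: int,
    n_links: int,
    n_visits: int | None = None,
    seed: int | None = None,
    period_label: str = "fixture",
) -> BipartiteNetwork:
    """A network realizing exact marginal counts with arbitrary wiring.

    Synthetic stand-in for a field interaction matrix whose published
    marginals (species, link and visit totals) are known but whose wiring
    is not; suitable only for metrics that depend on the marginals alone.
    Every node is covered, so ``n_links`` must be at least
    ``max(n_plants, n_pollinators)``.
    """
    if n_links < max(n_plants, n_pollinators):
        raise ValueError("n_links too small to involve every species in a link")
    if n_links > n_plants * n_pollinators:
        raise ValueError("n_links exceeds the number of plant×pollinator cells")
    rng = np.random.default_rng(seed)
    links: set[tuple[int, int]] = set()
    for i in range(max(n_plants, n_pollinators)):  # cover both guilds first
        links.add((i % n_plants, i % n_pollinators))
    all_cells = rng.permutation(n_plants * n_pollinators)
    for cell in all_cells:
        if len(links) >= n_links:
            break
        links.add((int(cell) // n_pollinators, int(cell) % n_pollinators))
    visits = {(f"P{i + 1:03d}", f"B{j + 1:03d}"): 1 for i, j in sorted(links)}
    if n_visits is not None:
        if n_visits < n_links:
            raise ValueError("n_visits must be >= n_links (every link has >= 1 visit)")
        extra = rng.multinomial(n_visits - n_links, np.full(n_links, 1.0 / n_links))
        for key, add in zip(sorted(visits), extra):
            visits[key] += int(add)
    active = {p: 1 for p, _ in visits}
    return BipartiteNetwork(visits=visits, active_days=active, period_label=period_label)


def seasonal_networks_with_overlap(
    n_links_a: int,
    n_links_b: int,
    n_shared: int,
    seed: int | None = None,
) -> tuple[BipartiteNetwork, BipartiteNetwork]:
    """Two networks whose link sets share exactly ``n_shared`` links.

    Synthetic fixture for overlap statistics that depend only on link-set
    cardinalities; species identities are arbitrary.
    """
    if n_shared > min(n_links_a, n_links_b):
        raise ValueError("shared links cannot exceed either link count")
    total = n_links_a + n_links_b - n_shared
    side = int(np.ceil(np.sqrt(total))) + 1
    rng = np.random.default_rng(seed)
    cells = rng.choice(side * side, size=total, replace=False)
    pool = [(f"P{c // side + 1:03d}", f"B{c % side + 1:03d}") for c in cells]
    shared = pool[:n_shared]
    only_a = pool[n_shared : n_shared + (n_links_a - n_shared)]
    only_b = pool[n_shared + (n_links_a - n_shared) :]

    def _net(link_list: list[tuple[str, str]], label: str) -> BipartiteNetwork:
        visits = {link: 1 for link in link_list}
        active = {p: 1 for p, _ in visits}
        return BipartiteNetwork(visits=visits, active_days=active, period_label=label)

    return _net(shared + only_a, "season_a"), _net(shared + only_b, "season_b")
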