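"""Interaction β-diversity: Whittaker dissimilarity, its partition into
species turnover versus rewiring, and Monte-Carlo nulls for correlations.

For two consecutive monthly networks, interaction dissimilarity β_int is
Whittaker's presence-based index over link sets: with ``a`` links shared
and ``b``, ``c`` unique to each month,

    β = (a + b + c) / ((2a + b + c) / 2) − 1  =  (b + c) / (2a + b + c).

β_rw applies the same index to the link sets restricted to species present
in both months (rewiring among shared species), and β_st = β_int − β_rw is
the part of interaction dissimilarity attributable to species turnover.
β_S, β_pl and β_po apply the index to species sets (all, plants,
pollinators).

Because network turnover between adjacent month pairs is serially
dependent, correlation p-values between turnover measures come from a
constrained Monte-Carlo null: every monthly network is replaced by one
with the same numbers of plants, pollinators and links (species drawn
uniformly from the year's pools, links wired uniformly at random), which
also keeps connectance constant, and the rank correlation is recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .core import BipartiteNetwork

__all__ = [
    "TurnoverRecord",
    "whittaker_beta",
    "beta_series",
    "seasonal_turnover_fraction",
    "link_overlap_fraction",
    "spearman_rank",
    "NullCorrelationResult",
    "null_correlation_test",
    "draw_null_months",
    "months_correlation",
    "empirical_p",
    "BETA_MEASURES",
]

BETA_MEASURES = ("beta_int", "beta_rw", "beta_st", "beta_S", "beta_pl", "beta_po")


def whittaker_beta(a: int, b: int, c: int) -> float:
    """Whittaker presence-based dissimilarity from shared/unique element counts."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError("element counts must be non-negative")
    if a + b + c == 0:
        raise ValueError("undefined dissimilarity: both element sets are empty")
    return (a + b + c) / ((2 * a + b + c) / 2) - 1


def _beta_sets(set_a: frozenset | set, set_b: frozenset | set) -> float:
    a = len(set_a & set_b)
    return whittaker_beta(a, len(set_a - set_b), len(set_b - set_a))


@dataclass(frozen=True)
class TurnoverRecord:
    """Dissimilarity measures for one pair of consecutive periods.

    ``defined`` is False when either period is empty, in which case the
    measures are NaN rather than 0 or 1.
    """

    label: str
    a: int
    b: int
    c: int
    beta_int: float
    beta_rw: float
    beta_st: float
    beta_S: float
    beta_pl: float
    beta_po: float
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "pair": self.label,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "defined": self.defined,
            **{m: getattr(self, m) for m in BETA_MEASURES},
        }


def _pair_measures(
    plants_a: frozenset,
    polls_a: frozenset,
    links_a: frozenset,
    plants_b: frozenset,
    polls_b: frozenset,
    links_b: frozenset,
) -> dict:
    """The six β measures from raw species and link sets of two periods."""
    beta_int = _beta_sets(links_a, links_b)
    shared_pl = plants_a & plants_b
    shared_po = polls_a & polls_b
    rest_a = {l for l in links_a if l[0] in shared_pl and l[1] in shared_po}
    rest_b = {l for l in links_b if l[0] in shared_pl and l[1] in shared_po}
    if rest_a or rest_b:
        beta_rw = _beta_sets(rest_a, rest_b)
    else:
        # no links among shared species in either period: nothing can rewire
        beta_rw = 0.0
    species_a = {("pl", p) for p in plants_a} | {("po", b) for b in polls_a}
    species_b = {("pl", p) for p in plants_b} | {("po", b) for b in polls_b}
    return {
        "a": len(links_a & links_b),
        "b": len(links_a - links_b),
        "c": len(links_b - links_a),
        "beta_int": beta_int,
        "beta_rw": beta_rw,
        "beta_st": beta_int - beta_rw,
        "beta_S": _beta_sets(species_a, species_b),
        "beta_pl": _beta_sets(plants_a, plants_b),
        "beta_po": _beta_sets(polls_a, polls_b),
    }


def beta_series(series: Sequence[BipartiteNetwork]) -> list[TurnoverRecord]:
    """Turnover records for every consecutive pair of a monthly series.

    Pairs involving an empty month yield a record flagged undefined
    (NaN measures) instead of an arbitrary 0 or 1.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 consecutive networks for turnover")
    out: list[TurnoverRecord] = []
    for left, right in zip(series[:-1], series[1:]):
        label = f"{left.period_label}->{right.period_label}"
        if left.is_empty or right.is_empty:
            nan = float("nan")
            out.append(
                TurnoverRecord(label, 0, 0, 0, nan, nan, nan, nan, nan, nan, defined=False)
            )
            continue
        m = _pair_measures(
            left.plants, left.pollinators, left.links,
            right.plants, right.pollinators, right.links,
        )
        out.append(TurnoverRecord(label=label, defined=True, **m))
    return out


def seasonal_turnover_fraction(set_a: set | frozenset, set_b: set | frozenset) -> float:
    """Percentage of the union unique to a single set (species turnover between seasons)."""
    union = set(set_a) | set(set_b)
    if not union:
        raise ValueError("both sets are empty: turnover undefined")
    unique = len(union) - len(set(set_a) & set(set_b))
    return 100.0 * unique / len(union)


def link_overlap_fraction(net_a: BipartiteNetwork, net_b: BipartiteNetwork) -> float:
    """Percentage of the union of link sets shared by both networks."""
    union = net_a.links | net_b.links
    if not union:
        raise ValueError("both networks are empty: overlap undefined")
    return 100.0 * len(net_a.links & net_b.links) / len(union)


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's r_s: Pearson correlation of mid-ranks (ties allowed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant series")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


@dataclass(frozen=True)
class NullCorrelationResult:
    measure_x: str
    measure_y: str
    r_s: float
    n_sim: int
    p_two: float
    p_one: float
    seed: int | None
    null_r: np.ndarray


def _measure_vector(records: Sequence[TurnoverRecord], measure: str) -> np.ndarray:
    if measure not in BETA_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {BETA_MEASURES}")
    vals = [getattr(r, measure) for r in records if r.defined]
    return np.asarray(vals, dtype=float)


_MAX_NULL_REDRAWS = 1000

#: a month as raw sets: (plants, pollinators, links); None marks an empty month
Month = tuple[frozenset, frozenset, frozenset] | None


def draw_null_months(
    dims: Sequence[tuple[int, int, int]],
    pool_sizes: tuple[int, int],
    rng: np.random.Generator,
) -> list[Month]:
    """One constrained randomization of a monthly series.

    For each month's (n_plants, n_pollinators, n_links), species are drawn
    uniformly without replacement from integer pools of the given sizes
    and the links are wired uniformly at random among the drawn species as
    distinct cells; the species sets of the null month are the drawn sets,
    so the month's dimensions — and therefore its connectance — are kept
    exactly constant.  Months with zero links stay empty (None).
    """
    n_pool_pl, n_pool_po = pool_sizes
    months: list[Month] = []
    for n_pl, n_po, L in dims:
        if L == 0:
            months.append(None)
            continue
        if n_pl > n_pool_pl or n_po > n_pool_po:
            raise ValueError("a month requires more species than the year pool holds")
        pl_ids = rng.choice(n_pool_pl, size=n_pl, replace=False)
        po_ids = rng.choice(n_pool_po, size=n_po, replace=False)
        cells = rng.choice(n_pl * n_po, size=L, replace=False)
        links = frozenset(
            (int(pl_ids[cell // n_po]), -1 - int(po_ids[cell % n_po])) for cell in cells
        )
        # pollinators carry negative codes so the two namespaces stay disjoint
        months.append(
            (
                frozenset(int(i) for i in pl_ids),
                frozenset(-1 - int(i) for i in po_ids),
                links,
            )
        )
    return months


def months_correlation(months: Sequence[Month], pair: tuple[str, str]) -> float:
    """Spearman r_s between two turnover measures over a raw-set monthly series."""
    mx, my = pair
    xs, ys = [], []
    for left, right in zip(months[:-1], months[1:]):
        if left is None or right is None:
            continue
        m = _pair_measures(left[0], left[1], left[2], right[0], right[1], right[2])
        xs.append(m[mx])
        ys.append(m[my])
    return spearman_rank(xs, ys)


def _null_ensemble(
    dims: Sequence[tuple[int, int, int]],
    pool_sizes: tuple[int, int],
    pair: tuple[str, str],
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    null_r = np.empty(n_sim)
    done = 0
    redraws = 0
    while done < n_sim:
        try:
            null_r[done] = months_correlation(draw_null_months(dims, pool_sizes, rng), pair)
        except ValueError:  # degenerate (constant) measure series: redraw
            redraws += 1
            if redraws > _MAX_NULL_REDRAWS:
                raise RuntimeError("null correlation degenerate on too many draws") from None
            continue
        done += 1
    return null_r


def empirical_p(null_r: np.ndarray, observed: float) -> tuple[float, float]:
    """Two-tailed and one-tailed (1 + hits)/(1 + n) empirical p-values."""
    n = null_r.size
    p_two = (1 + int(np.sum(np.abs(null_r) >= abs(observed)))) / (1 + n)
    if observed >= 0:
        p_one = (1 + int(np.sum(null_r >= observed))) / (1 + n)
    else:
        p_one = (1 + int(np.sum(null_r <= observed))) / (1 + n)
    return p_two, p_one


def null_correlation_test(
    series: Sequence[BipartiteNetwork],
    pair: tuple[str, str] = ("beta_int", "beta_S"),
    n_sim: int = 100_000,
    seed: int | None = None,
) -> NullCorrelationResult:
    """Monte-Carlo significance of the rank correlation between two turnover measures.

    Each simulation replaces every monthly network with a constrained
    randomization of identical dimensions (see ``draw_null_months``),
    recomputes the turnover series and the Spearman correlation between
    the chosen pair of measures.  Two-tailed p compares |r| against the
    null ensemble; a one-tailed p in the direction of the observed sign is
    reported alongside.  Null draws on which the correlation is degenerate
    (a constant measure series) are redrawn, with a cap.
    """
    if n_sim < 99:
        raise ValueError("n_sim must be >= 99")
    records = beta_series(series)
    if sum(r.defined for r in records) < 3:
        raise ValueError("need >= 3 defined consecutive-pair records")
    mx, my = pair
    observed = spearman_rank(_measure_vector(records, mx), _measure_vector(records, my))

    nonempty = [net for net in series if not net.is_empty]
    plant_pool = set().union(*(net.plants for net in nonempty))
    poll_pool = set().union(*(net.pollinators for net in nonempty))
    dims = [(net.n_plants, net.n_pollinators, net.n_links) for net in series]
    rng = np.random.default_rng(seed)
    null_r = _null_ensemble(dims, (len(plant_pool), len(poll_pool)), pair, n_sim, rng)
    p_two, p_one = empirical_p(null_r, observed)
    return NullCorrelationResult(
        measure_x=mx, measure_y=my, r_s=observed, n_sim=n_sim,
        p_two=p_two, p_one=p_one, seed=seed, null_r=null_r,
    )
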