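"""Link-based rarefaction: accumulation curves of network features.

The sampling unit is the unique plant–pollinator link (first record of
each pair); repeat visits to an already-seen pair do not advance the
curve.  This avoids confounding by uneven per-day sampling effort.  The
recorded sequence of unique links is shuffled ``n_rand`` times and each
feature is evaluated on the growing network, giving a mean curve and a
95% percentile envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import VisitRecord
from .metrics import nodf as _nodf

__all__ = ["RarefactionCurve", "link_accumulation", "asymptote_reached", "FEATURES"]


@dataclass(frozen=True)
class RarefactionCurve:
    feature: str
    x: np.ndarray  # number of unique links sampled, 1..L
    values: np.ndarray = field(repr=False)  # n_rand × L
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_randomizations: int
    seed: int | None


def _unique_links(records: Sequence[VisitRecord]) -> list[tuple[str, str]]:
    seen: dict[tuple[str, str], None] = {}
    for r in records:
        seen.setdefault((r.plant, r.pollinator), None)
    return list(seen)


def _feature_curves_for_order(
    links: list[tuple[str, str]], features: Sequence[str]
) -> dict[str, np.ndarray]:
    L = len(links)
    plants_seen: set[str] = set()
    polls_seen: set[str] = set()
    n_pl = np.empty(L)
    n_po = np.empty(L)
    for i, (p, b) in enumerate(links):
        plants_seen.add(p)
        polls_seen.add(b)
        n_pl[i] = len(plants_seen)
        n_po[i] = len(polls_seen)
    xs = np.arange(1, L + 1, dtype=float)
    out: dict[str, np.ndarray] = {}
    for feat in features:
        if feat == "plant_richness":
            out[feat] = n_pl
        elif feat == "pollinator_richness":
            out[feat] = n_po
        elif feat == "mean_partners_plant":
            out[feat] = xs / n_pl
        elif feat == "mean_partners_pollinator":
            out[feat] = xs / n_po
        elif feat == "connectance":
            out[feat] = 2.0 * xs / (n_pl * n_po)
        elif feat == "nodf":
            out[feat] = _nodf_curve(links)
        else:  # pragma: no cover - guarded upstream
            raise AssertionError(feat)
    return out


def _nodf_curve(links: list[tuple[str, str]]) -> np.ndarray:
    vals = np.empty(len(links))
    plants: dict[str, int] = {}
    polls: dict[str, int] = {}
    rows: list[list[int]] = []
    M = np.zeros((0, 0))
    for i, (p, b) in enumerate(links):
        if p not in plants:
            plants[p] = len(plants)
        if b not in polls:
            polls[b] = len(polls)
        A = np.zeros((len(plants), len(polls)), dtype=int)
        for j, (pp, bb) in enumerate(links[: i + 1]):
            A[plants[pp], polls[bb]] = 1
        try:
            vals[i] = _nodf(A)
        except ValueError:  # fewer than 2 rows or columns yet
            vals[i] = np.nan
    return vals


FEATURES = (
    "plant_richness",
    "pollinator_richness",
    "mean_partners_plant",
    "mean_partners_pollinator",
    "connectance",
    "nodf",
)


def link_accumulation(
    records: Sequence[VisitRecord],
    features: Sequence[str] = ("plant_richness", "pollinator_richness", "mean_partners_pollinator"),
    n_rand: int = 100,
    seed: int | None = None,
) -> list[RarefactionCurve]:
    """Accumulation curves over randomized unique-link orders.

    At x = L every randomization equals the full-network value exactly, so
    the envelope closes to zero width there.
    """
    unknown = [f for f in features if f not in FEATURES]
    if unknown:
        raise ValueError(f"unknown feature(s) {unknown}; valid features: {list(FEATURES)}")
    links = _unique_links(records)
    L = len(links)
    if L < 2:
        raise ValueError("need >= 2 unique links for an accumulation curve")
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    rng = np.random.default_rng(seed)
    per_feature: dict[str, list[np.ndarray]] = {f: [] for f in features}
    for _ in range(n_rand):
        order = [links[i] for i in rng.permutation(L)]
        curves = _feature_curves_for_order(order, features)
        for f in features:
            per_feature[f].append(curves[f])
    out = []
    x = np.arange(1, L + 1)
    for f in features:
        V = np.vstack(per_feature[f])
        out.append(
            RarefactionCurve(
                feature=f,
                x=x,
                values=V,
                mean=np.nanmean(V, axis=0),
                ci_low=np.nanpercentile(V, 2.5, axis=0),
                ci_high=np.nanpercentile(V, 97.5, axis=0),
                n_randomizations=n_rand,
                seed=seed,
            )
        )
    return out


def asymptote_reached(
    curve: RarefactionCurve, window: float = 0.1, tol: float = 0.005
) -> tuple[bool, dict]:
    """Heuristic saturation test on a mean accumulation curve.

    True when the average relative change per step of the mean curve over
    the final ``window`` fraction of x falls below ``tol``.  Returns the
    decision and diagnostics (the measured relative slope and the window).
    """
    y = np.asarray(curve.mean, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 10:
        raise ValueError("curve too short: need >= 10 points")
    w = max(2, int(np.ceil(window * y.size)))
    tail = y[-w:]
    steps = np.abs(np.diff(tail))
    scale = max(abs(float(np.mean(tail))), np.finfo(float).eps)
    rel_slope = float(np.mean(steps) / scale)
    return rel_slope < tol, {"relative_slope": rel_slope, "window_points": w, "tol": tol}
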