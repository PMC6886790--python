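#!/usr/bin/env python
"""Extinction-cascade robustness of the cumulative and seasonal networks:
targeted (decreasing/increasing degree) and random removals of plants and
pollinators, unweighted (species-loss) and weighted (visitation-flow)
accounting, AUC with percentile CIs, and loss after removal of half the
target guild.

Writes results/robustness.csv."""

import argparse
from pathlib import Path

import pandas as pd

import seasonet as sn
from seasonet.robustness import RemovalScenario

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_records(seed: int):
    path = RESULTS / "visits.csv"
    if path.exists():
        return sn.read_visit_records(path)
    records, _ = sn.generate_community(sn.CommunityConfig(), seed=seed)
    return records


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--iterations", type=int, default=100)
    args = parser.parse_args()

    records = load_records(args.seed)
    rows = []
    for period in ("all", "rainy", "dry"):
        net = sn.build_network(records, period=period)
        freqs = sn.interaction_frequency(net)
        for side in ("pollinators", "plants"):
            for order in ("decreasing", "increasing", "random"):
                for mode in ("species", "flow"):
                    scenario = RemovalScenario(
                        side=side,
                        order=order,
                        weighted=(mode == "flow"),
                        mode=mode,
                        iterations=args.iterations,
                        seed=args.seed,
                    )
                    curve = sn.robustness_experiment(net, scenario, freqs=freqs)
                    rows.append(
                        {
                            "period": period,
                            "side": side,
                            "order": order,
                            "mode": mode,
                            "auc": round(curve.auc, 3),
                            "auc_ci_low": round(curve.auc_ci[0], 3),
                            "auc_ci_high": round(curve.auc_ci[1], 3),
                            "remaining_at_half": round(curve.remaining_at_half, 3),
                            "rem_half_ci_low": round(curve.remaining_at_half_ci[0], 3),
                            "rem_half_ci_high": round(curve.remaining_at_half_ci[1], 3),
                        }
                    )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "robustness.csv", index=False)
    print(table.to_string(index=False))

    flow = table.query("order == 'decreasing' and mode == 'flow' and period == 'all'")
    po = flow.query("side == 'pollinators'").auc.iloc[0]
    pl = flow.query("side == 'plants'").auc.iloc[0]
    print(
        f"\nweighted robustness, cumulative network: pollinator-removal AUC {po:.3f} "
        f"{'<' if po < pl else '>='} plant-removal AUC {pl:.3f} "
        "(the aseasonal bee hubs concentrate visitation flow)"
    )
    dry_auc = table.query(
        "period == 'dry' and side == 'pollinators' and order == 'decreasing' and mode == 'species'"
    ).auc.iloc[0]
    rainy_auc = table.query(
        "period == 'rainy' and side == 'pollinators' and order == 'decreasing' and mode == 'species'"
    ).auc.iloc[0]
    print(f"dry-season AUC {dry_auc:.3f} vs rainy-season AUC {rainy_auc:.3f} (pollinator removal)")


if __name__ == "__main__":
    main()
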