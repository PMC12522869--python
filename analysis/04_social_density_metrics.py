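#!/usr/bin/env python
"""Descriptive oviposition metrics across social densities and time.

Computes per-treatment laying likelihood, eggs per female, clustering
proportions over time, cluster counts/sizes, latency, viability, and the
sampling-effort rebalanced subsample.

Writes results/social_summary.csv, results/social_by_treatment.csv,
results/viability.csv and results/rebalanced_vials.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import eggcluster as ec

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 20250104


def main() -> None:
    config = ec.SyntheticConfig()
    obs, via, _ = ec.generate_social_density_experiment(config, seed=SEED)

    by_vial: dict[str, list] = {}
    for o in obs:
        by_vial.setdefault(o.vial_id, []).append(o)
    tables = []
    for series in by_vial.values():
        s = ec.vial_summary(series)
        t = s.table.copy()
        t["latency_h"] = s.latency_h if s.latency_h is not None else np.nan
        tables.append(t)
    summary = pd.concat(tables, ignore_index=True).sort_values(
        ["vial_id", "timepoint_h"], ignore_index=True
    )
    summary.to_csv(OUT / "social_summary.csv", index=False)

    final = summary[summary["timepoint_h"] == 24]
    by_treatment = (
        final.groupby("group_size")
        .agg(
            laying_likelihood=("n_eggs", lambda s: float((s > 0).mean())),
            mean_eggs_per_female=("eggs_per_female", "mean"),
            sd_eggs_per_female=("eggs_per_female", "std"),
            mean_prop_clustered=("prop_clustered", "mean"),
            mean_n_clusters=("n_clusters", "mean"),
            mean_largest=("largest_cluster", "mean"),
            median_latency_h=("latency_h", "median"),
            n_vials=("vial_id", "count"),
        )
        .round(3)
        .reset_index()
    )
    by_treatment.to_csv(OUT / "social_by_treatment.csv", index=False)
    print(by_treatment.to_string(index=False))

    viability = ec.viability_metrics(via)
    viability.to_csv(OUT / "viability.csv", index=False)
    laid = viability[viability["n_eggs"] > 0]
    r = np.corrcoef(laid["viability"], laid["prop_clustered_final"])[0, 1]
    print(f"\nviability vs clustering correlation: r = {r:.3f} (n = {len(laid)})")

    roster = {o.vial_id: o.group_size for o in obs if o.timepoint_h == 24}
    chosen = ec.rebalance_subsample(roster, seed=SEED)
    pd.DataFrame({"vial_id": chosen}).to_csv(OUT / "rebalanced_vials.csv", index=False)
    print(
        f"rebalanced subsample: {len(chosen)} vials "
        "(30/15/8/4 per treatment, approx. equal flies per treatment)"
    )
    print(
        "\nFinding: larger groups lay more eggs per female, lay sooner, and put a "
        "larger share of their eggs into clusters; viability is unrelated to "
        "clustering, as generated."
    )


if __name__ == "__main__":
    main()
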