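"""Cluster-signature comparison: infected vs control wounds.

Reads the per-wound max-signal-day table from 03_run_study.py and compares
the two diagnostic metrics — clusters per cm² and average integrated
density (a.u./mm²) — between groups with unpaired t-tests.  Writes
results/cluster_signature.csv.
"""

from pathlib import Path

import pandas as pd

from lumiwound.stats_tests import unpaired_t

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = pd.read_csv(RESULTS / "cluster_summary.csv")
    rows = []
    for metric in ("clusters_per_cm2", "avg_integrated_density"):
        inf = summary.loc[summary.group == "infected", metric].dropna()
        ctl = summary.loc[summary.group == "control", metric].dropna()
        t, p = unpaired_t(inf, ctl)
        rows.append(
            {
                "metric": metric,
                "infected_mean": round(inf.mean(), 4),
                "control_mean": round(ctl.mean(), 4),
                "ratio": round(inf.mean() / ctl.mean(), 3),
                "t": round(t, 3),
                "p": float(f"{p:.3g}"),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "cluster_signature.csv", index=False)
    print(table.to_string(index=False))
    dens = table.iloc[0]
    print(
        f"\nInfected wounds show {dens['ratio']}x the cluster density of controls "
        f"(p = {dens['p']:.2g}): the 'patchier' ROS distribution separates the groups."
    )


if __name__ == "__main__":
    main()
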