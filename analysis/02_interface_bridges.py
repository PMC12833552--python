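#!/usr/bin/env python
"""Water-mediated bridge statistics of the forged apo/holo study.

Reads the multi-model trajectories written by 01_forge_trajectories.py,
detects hydrogen bonds (3.0 A donor-acceptor, 120 deg D-H-A), enumerates
water bridges of order <= 2 across the A/B interface, computes per-pair
occupancy and frequency of occurrence per replica, applies the 20%
persistence filter and writes the apo/holo comparison table (and a
Figure-style frequency bar chart) under results/tables/.
"""

import argparse
from pathlib import Path

import numpy as np

from gluebridge import forge
from gluebridge.bridgestats import compare_apo_holo, stats_to_frame
from gluebridge.pipeline import analyze_replica
from gluebridge.structio import read_multimodel_pdb

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--traj", type=Path, default=ROOT / "results" / "trajectories")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    ap.add_argument("--threshold", type=float, default=0.20)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    per_condition = {}
    direct = {}
    for condition in ("apo", "holo"):
        spec = forge.paper_like_scenario(condition)
        model = forge.build_interface_topology(spec)
        reps = []
        for pdb in sorted(args.traj.glob(f"{condition}_rep*.pdb")):
            topo, traj = read_multimodel_pdb(pdb)
            assert topo.n_atoms == model.topology.n_atoms
            stats, d = analyze_replica(model, traj.coords,
                                       replica=pdb.stem.split("_")[-1],
                                       condition=condition)
            reps.append(stats)
            direct.setdefault(condition, []).append(float(d.mean()))
        if not reps:
            raise SystemExit(f"no trajectories found under {args.traj}; run 01 first")
        per_condition[condition] = reps
        frame = stats_to_frame([s for rep in reps for s in rep])
        frame.to_csv(args.out / f"pair_statistics_{condition}.tsv", sep="\t", index=False)

    table = compare_apo_holo(per_condition["apo"], per_condition["holo"],
                             persistence_threshold=args.threshold)
    table.to_csv(args.out / "comparison_apo_holo.tsv", sep="\t")

    print(f"persistent pairs (>= {args.threshold:.0%} of frames in >= 1 replica): "
          f"{len(table)}")
    print(table[["apo_freq_mean", "apo_freq_sd", "holo_freq_mean", "holo_freq_sd",
                 "dfreq_mean"]].round(3).to_string())
    for condition in ("apo", "holo"):
        print(f"direct inter-protein H-bonds per frame ({condition}): "
              f"{np.mean(direct[condition]):.3f}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 3.2))
        x = np.arange(len(table))
        ax.bar(x - 0.2, table["apo_freq_mean"], 0.4, yerr=table["apo_freq_sd"],
               label="apo", color="tab:gray")
        ax.bar(x + 0.2, table["holo_freq_mean"], 0.4, yerr=table["holo_freq_sd"],
               label="holo", color="tab:blue")
        ax.set_xticks(x, table.index, rotation=45, ha="right")
        ax.set_ylabel("frequency of occurrence")
        ax.axhline(1.0, lw=0.5, color="k", ls=":")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(args.out / "frequency_apo_holo.png", dpi=150)
        print(f"figure: {args.out / 'frequency_apo_holo.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
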