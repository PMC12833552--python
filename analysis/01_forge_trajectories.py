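#!/usr/bin/env python
"""Forge the synthetic apo/holo interface study.

Builds the two-chain solvated interface in both conditions (apo: sparse,
weakly occupied water bridges; holo: more bridges at higher occupancy,
emulating a glue-stabilized interface), draws three replica bridge
schedules per condition, renders the trajectories and writes multi-model
PDBs plus ground-truth manifests under results/trajectories/.
"""

import argparse
from pathlib import Path

from gluebridge import forge

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--frames", type=int, default=200)
    ap.add_argument("--replicas", type=int, default=3)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "trajectories")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for ci, condition in enumerate(("apo", "holo")):
        spec = forge.paper_like_scenario(condition)
        model = forge.build_interface_topology(spec)
        planted = {}
        for rep in range(1, args.replicas + 1):
            seed = (args.seed * 1000 + ci * 10 + rep) % (2 ** 31 - 1)
            manifest = forge.simulate_bridge_schedule(spec.bridges, args.frames, seed)
            pdb = args.out / f"{condition}_rep{rep}.pdb"
            forge.render_trajectory(model, manifest, out_path=pdb)
            manifest.save(args.out / f"{condition}_rep{rep}.manifest.txt")
            for label, (occ, freq) in forge.manifest_pair_statistics(manifest, model).items():
                planted.setdefault(label, []).append(occ)
        print(f"{condition}: {len(spec.bridges)} planted bridges, "
              f"{args.replicas} replicas x {args.frames} frames "
              f"({model.topology.n_atoms} atoms)")
        for label, occs in sorted(planted.items()):
            mean = sum(occs) / len(occs)
            print(f"  {label}: realized occupancy {mean:.3f} (per replica: "
                  + ", ".join(f"{o:.3f}" for o in occs) + ")")
    print(f"wrote trajectories + manifests to {args.out}")


if __name__ == "__main__":
    main()
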