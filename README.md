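# gluebridge

Post-simulation analysis of molecular-glue ternary complexes: water-mediated
hydrogen bonds across a protein–protein interface, interface flexibility, and
binding/cooperativity free-energy bookkeeping — with a synthetic-trajectory
generator that plants ground-truth bridges so every stage is testable without
running molecular dynamics.

## The problem

Molecular glues (e.g. rapamycin, WDB002) are small molecules that stabilize
the interface between an effector protein (FKBP12) and a target protein
(FRAP's kinase domain, CEP250), forming a ternary complex. Two observables
characterise how a glue reshapes such an interface in MD trajectories:

1. **Water-mediated hydrogen bonds of order ≤ 2** — paths
   `A·····w·····B` or `A·····w₁·····w₂·····B` connecting an atom of each
   protein through one or two water molecules, where every link is a
   geometric hydrogen bond (donor–acceptor distance ≤ 3.0 Å, D–H–A angle
   ≥ 120° at the hydrogen). Per residue pair the **occupancy** is the
   fraction of frames with at least one path and the **frequency of
   occurrence** is the mean number of distinct water paths per frame
   (frequency > 1 ⇒ two waters bridge the same pair simultaneously). Only
   pairs persisting ≥ 20% of the simulation are reported, and apo
   (glue-free) vs holo (glue-bound) conditions are compared per replica.
2. **Flexibility and proximity** — per-residue backbone RMSF after Kabsch
   superposition on one protein's backbone, per-frame RMSD, and the minimum
   inter-protein atom distance.

The thermodynamics stage covers the closed-form bookkeeping around such
studies: `ΔG⁰ = RT ln(Kd/c⁰)` (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, c⁰ = 1 M,
25 °C) with first-order error propagation, and the cooperative free energy

```
ΔG⁰coop = ΔGbind(ternary) − ΔGbind(target–glue binary),   σ² = σ²ternary + σ²binary
```

where negative ΔG⁰coop means the glue makes protein–protein association more
favourable.

## Layout

```
src/gluebridge/
  structio.py     multi-model PDB I/O, atom selection, H-attachment inference
  hbond.py        geometric H-bond detection (3.0 Å / 120°; heavy-atom mode)
  bridges.py      water-bridge enumeration (order ≤ 2), direct-contact counts
  bridgestats.py  occupancy / frequency, persistence filter, apo–holo tables
  flex.py         Kabsch superposition, RMSD/RMSF, minimum inter-chain distance
  thermo.py       Kd → ΔG conversion, cooperative free energy
  crystal.py      hydrogen-free (crystal) bridge inventory
  forge.py        synthetic interface trajectories with planted ground truth
  pipeline.py     config-driven orchestration of the whole study
analysis/         numbered drivers: 01 forge → 02 bridges → 03 flexibility →
                  04 thermodynamics → 05 crystal inventory
data/             printed thermodynamic inputs of the two reference complexes
```

## Worked example

```
python analysis/01_forge_trajectories.py --frames 120
python analysis/02_interface_bridges.py
python analysis/04_thermodynamics.py
```

`01` forges a two-chain solvated interface in apo and holo conditions
(3 replicas × 120 frames each) with planted bridge schedules; `02` re-detects
them from the written trajectories. Output of `02`:

```
persistent pairs (>= 20% of frames in >= 1 replica): 5
           apo_freq_mean  apo_freq_sd  holo_freq_mean  holo_freq_sd  dfreq_mean
Glx2-Glx2          0.331        0.043           1.311         0.019       0.981
Glx3-Glx3          0.000        0.000           0.594         0.010       0.594
Glx4-Glx4          0.150        0.008           0.514         0.061       0.364
Glx5-Glx5          0.000        0.000           0.372         0.054       0.372
Glx6-Glx6          0.058        0.008           0.269         0.027       0.211
direct inter-protein H-bonds per frame (apo): 0.000
direct inter-protein H-bonds per frame (holo): 0.000
```

Reading: the holo interface carries five persistent water bridges versus one
in apo; the Glx2–Glx2 frequency of 1.31 > 1 reflects the two planted water
paths on that pair, and direct protein–protein hydrogen bonds stay at zero in
both conditions (the chains only touch through water). `04` prints the
thermodynamics table:

```
                label    quantity  mean_kcal_mol  sd_kcal_mol         provenance
FKBP12-rapamycin-FRAP dG_bind(Kd)         -10.80         0.04   computed-from-Kd
 FKBP12-WDB002-CEP250 dG_bind(Kd)         -10.07         0.08   computed-from-Kd
FKBP12-rapamycin+FRAP     dG_coop         -26.33         5.35 printed-components
 FKBP12-WDB002+CEP250     dG_coop         -42.52         1.80 printed-components
```

Both cooperative free energies are negative: the glues stabilise their
ternary complexes.

With a user-supplied deposited structure (e.g. the FKBP12–rapamycin–FRAP
crystal, PDB id 1FAP), `analysis/05_crystal_inventory.py --structure
1fap.pdb --chains A B` lists the crystallographic water bridges between the
two proteins under a 3.5 Å heavy-atom criterion.

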