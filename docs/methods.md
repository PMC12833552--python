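# Methods

## Hydrogen-bond model

A hydrogen bond is purely geometric: donor and acceptor are N/O/S heavy
atoms, the donor carries at least one covalently attached hydrogen (one
donor entry per hydrogen), acceptors are all O/S plus any nitrogen with
fewer than four bonded partners (heavy neighbours counted by a 1.75 Å
distance rule plus attached hydrogens; quaternary N has no lone pair).
Water oxygen is both a double donor and an acceptor. The criteria are a
donor–acceptor distance ≤ 3.0 Å and a D–H–A angle ≥ 120° with the vertex at
the hydrogen (180° = linear). Both cutoffs are **inclusive**; the angle
convention and inclusivity are configuration (`HBondCriteria`), fixed this
way for determinism since trajectory toolkits differ. Minimum-image
distances are used only when an orthorhombic box is present. A KD-tree
prunes candidate pairs; by construction the pruning radius equals the
cutoff, so acceleration cannot change the result set (tested against an
all-pairs reference).

For hydrogen-free structures (crystals) a heavy-only mode replaces the pair
test by `2.0 Å ≤ d(D,A) ≤ 3.5 Å` between polar heavy atoms, excluding
same-residue pairs; 3.5 Å is the standard crystallographic cutoff, looser
than 3.0 Å because no hydrogen position can tighten the geometry, and the
2.0 Å floor removes covalent/1-3 contacts that a distance-only criterion
would otherwise admit.

## Water bridges of order ≤ 2

A bridge of order *k* joins an atom of protein group 1 to an atom of group 2
through *k* intervening water molecules, each consecutive link being a
hydrogen bond in that frame. Orders 1 and 2 are enumerated; chains of three
or more waters are never bridges. Donor/acceptor direction along the path
is ignored (the interaction names an atom pair, not a directed chain);
directionality can be re-imposed upstream by filtering the bond list. For
order 2 the two waters must be hydrogen-bonded to each other (chain
interpretation); the alternative shared-fork reading — two waters bonded to
opposite proteins without a mutual bond — is available as
`require_water_water_link=False`. Paths may not reuse a water (simple
paths). Each distinct (endpoint pair, water set) counts once per frame; an
order-1 and an order-2 path through the same first water are distinct.

Statistics aggregate at residue level: a path connects a residue pair if it
connects any atoms of the two residues, and within a frame distinctness is
judged by the water set. Per pair and replica:
`occupancy = #frames with ≥ 1 path / n_frames`,
`frequency = Σ distinct paths per frame / n_frames` (≥ occupancy; > 1 means
multiple simultaneous waters). The persistence filter keeps pairs with
occupancy ≥ 0.20 (inclusive), reading "persisted for ≥ 20% of the
simulation" as total occupancy, the standard practice; a longest-contiguous-
run variant is provided (`mode="longest_run"`). Replicas are never pooled:
frequencies are reported per replica with across-replica mean ± SD (ddof=1),
and apo/holo tables outer-join pairs with zeros for absences, keeping any
pair that passes the filter in at least one replica of either condition.

## Flexibility and proximity

Superposition is the Kabsch SVD solution with the determinant correction
(always a proper rotation, det = +1), equal weights, reference = frame 0 of
each replica by default (a crystal reference can be passed explicitly).
RMSD is computed over the alignment selection; the backbone is N, CA, C, O.
RMSF_i = √⟨|x_i − ⟨x_i⟩|²⟩ after aligning on the backbone of one chain,
reported per residue as the mean over its backbone atoms, full-length (no
terminal trimming). Proximity is the per-frame minimum over all
cross-group atom pairs, summarised as mean ± SD (ddof=1) over frames.
Because the reference frame carries its own noise and remote chains pick up
rotational lever-arm jitter from the fit, RMSD/RMSF of noisy synthetic data
sit slightly above the per-atom noise floor σ√3 — an expected property of
superposition-based profiling, not an artefact.

## Thermodynamics

ΔG⁰ = R·T·ln(Kd/c⁰) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and c⁰ = 1 M;
sd(ΔG⁰) = R·T·sd(Kd)/Kd to first order; rounding only at presentation
(2 dp). The default temperature is **298.0 K**: with the usual whole-kelvin
rounding of 25 °C, the reference conversions 12.0 ± 0.8 nM → −10.80 ± 0.04
and 41.2 ± 5.7 nM → −10.07 ± 0.08 kcal mol⁻¹ are reproduced exactly at two
decimals, whereas 298.15 K would give −10.81/−10.08. ΔG⁰coop is the ternary
binding free energy minus that of the target–glue binary complex; SDs
combine in quadrature (independent errors), which uniquely reproduces the
reference ±5.35 and ±1.80 from their components. MM/GBSA energies
themselves are inputs (printed numbers in `data/`), not computed here.

## The synthetic-data generator (forge)

The forge emulates only the *features the detectors measure*: two
protein-like chains facing each other across a solvated gap, polar sites
pointing into the gap, and water bridges with known per-frame schedules.

Geometry. Chains A and B are rows of minimal polar residues (backbone
N/H/CA/C/O plus side-chain oxygens) spaced 3.8 Å, separated by 9.0 Å
(> 2 × the 3 Å cutoff, so no direct inter-protein bonds can form). Each
interface residue carries two site oxygens in well-separated lateral planes
(4.5 Å apart); a second bridge planted on the same residue pair uses the
second site, which realises frequency > 1 without the two water paths
interfering, while residue-level aggregation merges them. Donor sites add a
hydroxyl hydrogen; acceptor sites are bare oxygens.

Planted bridges. When "on", an order-1 water sits on the site-pair axis
(links of 2.7 Å); an order-2 path bows 2.48 Å off-axis with 2.8 Å links and
the two waters mutually bonded. All links sit ≥ 0.1 Å / ≥ 10° inside the
criteria — safe margins against the default thermal jitter. Hydrogens are
oriented per frame: waters donate along their path links, spare hydrogens
point along the chain direction where no acceptor can sit at the 3.8 Å
residue spacing, and a donor site serving several on-waters aims its single
hydrogen at their angular bisector. When "off", the dedicated water parks
far outside the interface (≥ 2 Å beyond cutoff on every link), keeping the
atom count constant across frames. A build-time self-check detects the
all-on noiseless frame and requires the detected inventory to equal the
planted one exactly, rejecting layouts with accidental or missing links.

Schedules. Per-frame independent Bernoulli draws by default (the model
implies no kinetics); a two-state Markov chain (p_on, p_off) whose
stationary occupancy must equal the target within 1e-9 is available for
dwell-time sensitivity. The realized on/off record per bridge is saved in a
plain-text manifest sufficient to recompute every planted statistic without
the trajectory.

Noise. Isotropic Gaussian jitter (default σ = 0.05 Å) is added to every
atom; an optional rigid-body wobble translates chain B *before* waters are
placed, so planted bridges survive wobbles small relative to the cutoff
margin (≈ 0.2 Å amplitude; larger wobbles stretch the endpoint gap beyond
the margin and planted occupancy decays — measured ≈ 0.98 at 0.3 Å, ≈ 0.84
at 0.5 Å). Manifest-recomputed statistics equal full-pipeline statistics
exactly at σ = 0; at the default σ the per-link flip probability is ≲ 0.2%
per frame, well inside the binomial 99% CI used for recovery checks.

What the forge does **not** emulate: water exchange and residence kinetics,
real rotamer chemistry, periodic boundaries, correlated backbone motions,
or force-field energetics. Passing the planted-truth suites therefore
demonstrates correctness of the *measurement machinery*, not realism of the
synthetic ensemble; on real trajectories the same code paths apply, but
occupancies reflect actual water dynamics.

Default study conditions. The bundled apo/holo scenario plants six holo
bridges (occupancy targets 0.85/0.60/0.50/0.45/0.35/0.25, mixed orders, one
residue pair carrying two paths) against three weak apo bridges
(0.30/0.15/0.08) on a 6-residue-per-chain interface with 8 bulk waters —
a glue-stabilised interface is wetter and its bridges more persistent,
while the apo interface keeps a sparse remnant. These values are fixed
package defaults chosen to span the persistence threshold from both sides.

## Problem sizes and numerical choices

Synthetic systems are 110–140 atoms; validation suites use 2000-frame
trajectories (binomial CI half-width ≈ 0.029 at occupancy 0.5), ≥ 20 random
planted configurations, 50-frame oracle-equivalence batches, and
three-replica apo/holo studies — sizes at which every statistic is stable
yet the whole suite runs in minutes on one core. Random draws all flow
from explicit `numpy.random.default_rng` seeds; pipeline replica seeds are
derived as `seed·1000 + condition·10 + replica` (< 2³¹). Ties at criteria
boundaries are made deterministic by inclusive cutoffs; coordinates written
to PDB round to 3 decimals, so tests comparing against external readers
compare both sides on the file, not on memory.

## Known limitations

- Order ≥ 3 bridges, water residence times and hydration-site densities are
  out of scope.
- The PDB reader handles fixed-column ATOM/HETATM/MODEL records with
  highest-occupancy altloc resolution; mmCIF and chemistry headers (SSBOND,
  LINK) are not parsed.
- Heavy-only crystal mode cannot distinguish donor from acceptor and will
  report any polar–polar contact in range as a candidate link; its bridge
  inventory is a superset of what hydrogen-aware criteria would give.
- No significance testing of apo/holo frequency differences is performed;
  the comparison reports per-replica values and mean ± SD only.
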