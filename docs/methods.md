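# Methods

This document describes the model implemented by `hydropack`: the
energy terms, the two-stage water placement protocol, the evaluation
metrics, and every tunable parameter with its default and rationale.

## 1. Structures and polar groups

Structures are read and written as PDB via `gemmi`. On input, alternate
locations resolve to the highest-occupancy conformer, waters are
flagged, and a clash guard rejects non-bonded heavy atoms closer than
1.0 Å. Missing polar hydrogens are built at ideal covalent geometry
(amide H at 1.01 Å in the peptide plane; hydroxyl, amine and water
hydrogens from standard bond lengths and angles; proline N gets none).

Every hydrogen-bond-capable heavy atom becomes a `PolarGroup`: the
heavy atom, its base atom(s) (one for sp2, the two bound atoms for sp3
acceptors), any donor hydrogens, its hybridization, and an `atom_class`
label (`bb_N`, `bb_O`, `hydroxyl`, `carboxylate`, `water_O`, ...) that
keys both the statistical tables and the desolvation parameters.

Each group also defines **ideal hydration sites**: for a donor, the
point 1.9 Å beyond each hydrogen along the X–H bond; for an sp2
acceptor, points 2.8 Å from the acceptor along the two lone-pair
directions (120° from the base bond, in plane); for sp3 acceptors, the
tetrahedral directions. These sites drive both the bridging energy term
and candidate-site generation.

Interfaces are defined by two chain sets; interface residues have a Cβ
(Cα for glycine) within 8 Å of the other partner, and the buried area
is (SASA_A + SASA_B − SASA_complex)/2 from an internal Shrake–Rupley
implementation (960 sphere points), validated in the tests against an
independent library.

## 2. Implicit energy model

The pairwise model sums, per polar-group/atom pair within a 14 Å
centroid reach:

| term | form | weight |
|---|---|---|
| `lj` | 12-6 Lennard-Jones on heavy atoms (σ scaled by 0.89, capped) | 1.0 |
| `elec` | Coulomb with distance-dependent dielectric (1/4r²) | 0.25 |
| `lk_iso` | isotropic Gaussian-exclusion desolvation | 1.0 |
| `lk_ball` | anisotropic desolvation referenced to the hydration sites | 0.5 |
| `lk_bridge` | bridging-water refund (below) | **−1.0** |
| `hbond` | distance × directional hydrogen-bond potential | 2.0 |

1-2/1-3 bonded pairs are excluded. Explicit waters are *solvent*: pairs
involving a water contribute no `lk_iso`, `lk_ball` or `lk_bridge` —
a water occupying a hydration site must not be charged for
"desolvating" the solute it hydrates. (Without this exclusion a water
at an ideal bridging site scores ≈ +3.7 kcal/mol and the packer
correctly places nothing; see the limitations section.)

**Bridging term.** For polar groups *i*, *j* with ideal hydration sites
{b} and base distance d_base = |x_i − x_j|:

```
lk_bridge(i,j) = |E_lk(i,j)| · G(max(min_kl |b_k − b_l| − D0_len, 0); S0_len)
                             · G(d_base − D0_angle; S0_angle)
```

with the quartic bump kernel `G(x; S0) = (1 − (x²/S0²)²)²` on
[−S0, S0] and 0 outside — even, continuous, 1 at x = 0. Parameters:
D0_len = 0.5 Å, S0_len = 1.61 Å, D0_angle = 4.33 Å, S0_angle = 2.69 Å.
The raw value is a positive magnitude; its score weight of −1.0 turns
it into a partial refund of the pair's desolvation penalty whenever
their hydration sites nearly coincide at water-bridging geometry.

**sp3 acceptors.** Water and hydroxyl oxygens have no single lone-pair
plane, so the base-angle potential is a softmax over both atoms bound
to the acceptor:

```
E = M · log Σ_k exp(E_BAH(b_k, a, h) / M),   M = 0.4
```

which is exactly symmetric under swapping the two base atoms (water
hydrogens), bounded between max_k E_BAH and max_k E_BAH + M·ln 2, and
smooth. The hydrogen-bond well depth is 1.0 kcal/mol (≈ 2 kcal/mol
after the term weight), a typical magnitude for a good hydrogen bond.

## 3. Statistical point-water potential

Stage 1 treats candidate waters as uncharged points. The energy of an
active point water w_i given the active set W and the polar groups is

```
E_i = Σ_j −log[ P_class(d_ij, θ_ij) / P_ref(d_ij, θ_ij) ]
      − K · Σ_{k≠i} exp( −(|w_i − w_k| − d_ww)² / σ² )
      + E_pwat_bulk
```

with K = 0.52 kcal/mol, σ = 0.24 Å, d_ww = 2.7 Å,
E_pwat_bulk = 2.71 kcal/mol. θ is the water–heavy-atom–base angle.
Consequences pinned by tests: an isolated point water costs exactly
2.71 kcal/mol, and the water–water pair term has its unique interior
minimum at exactly 2.7 Å.

**Tables.** P ratios are binned (distance 2.0–3.6 Å in 0.1 Å steps;
angle 0–180° in 5° steps), shell-normalized by d² sin θ, given a
pseudocount of 1, clamped to ±3, and serialized as TSV. Classes with
fewer than 500 observations are skipped. Because the nonpolar reference
probe is isotropic, its distance and angle are independent: the
reference density is estimated as the product of its two marginal
histograms, which has far lower per-bin variance than a joint 2-D
histogram of the same sample. The default tables shipped with the
package are fitted to synthetic observations drawn around each class's
ideal hydration geometry against a shell-uniform synthetic reference;
the fitting code is data-agnostic and accepts real observation sets.

## 4. Candidate sites (stage 0)

- **Backbone N–H**: one site per single-amide-hydrogen residue, 1.9 Å
  beyond the H (N-terminal ammonium groups are a separate class and get
  no single-NH site; proline gets none).
- **Backbone C=O**: a 10-point template per carbonyl, computed at
  runtime by k-means (fixed seed) on densely sampled ideal sp2
  hydrogen-bond geometry with angular jitter, radii 2.6–3.0 Å.
- **Side-chain overlaps**: pairs of side-chain hydration sites (over
  the rotamer library) closer than 0.75 Å, found with a spatial hash
  (verified against brute force), yield midpoint sites with two parent
  groups.

Sites clashing with protein heavy atoms (< 2.0 Å) are removed, sites
are clustered by single linkage at 1.35 Å (= d_ww/2) so at most one
member of a cluster can be occupied, and, when an interface is given,
sites farther than 6 Å from any interface-residue Cβ are dropped.

## 5. Two-stage Monte Carlo packing

Both stages share one discrete pairwise (Potts) problem class and one
Metropolis annealer, which alternates high-temperature spikes
(RT_high = 100) with long low-temperature phases (RT_low = 0.3);
per-state **dwell counts** accumulate during low-T steps after the
first sixth of each cycle is discarded as burn-in. The annealer is
exactly reproducible from its seed, and the test suite checks it
against a brute-force enumeration oracle both for the global optimum
and for exact Boltzmann dwell occupancies.

- **Stage 1 (point waters).** Positions are site clusters (one "off"
  state plus one state per member site), optionally joined by flexible
  side-chain positions near the sites. Sites whose dwell occupancy is
  ≥ 2% survive; occupancy is recorded and carried to the output as the
  water's occupancy field.
- **Stage 2 (explicit waters).** Each survivor becomes a water with
  270 orientation states (45 quasi-uniform axis directions × 6 spins in
  [0°, 180°), the C2 quotient of a 30° SO(3) grid) plus a virtual
  returned-to-bulk state costing E_bulk = 1.22 kcal/mol; moves propose
  the virtual state 50% of the time at water positions. Energies are
  the full explicit model of §2; water–water state matrices are
  computed by a broadcast-vectorized path that the tests pin to the
  scalar path at 1e-9. Waters still present at the end are emitted.

## 6. Evaluation layer

- **Water recovery**: a reference water is recovered if a predicted
  oxygen lies within 0.5 Å, or if a predicted oxygen is coordinated by
  the identical, non-empty set of polar atoms within 3.2 Å. Matching is
  one-to-one (greedy by distance, then coordination). Reports include
  precision and per-class breakdowns: buriedness by the count of Cβ
  atoms within 10 Å (≤15 exposed, ≤25 partially buried, >25 buried) and
  contact type (backbone-only, side-chain-only, mixed, uncoordinated),
  plus waters per 1000 Å² of buried interface area.
- **Binding energy**: ΔG_bind = E(bound, re-solvated) − Σ E(partner,
  isolated and re-solvated). Scoring a partner as an isolated structure
  is mathematically identical to separating the partners infinitely.
- **Decoy discrimination**: given per-decoy (ΔG, RMSD-to-native)
  records, the discrimination score is the Boltzmann weight (kT = 1) of
  the near-native set (CA-RMSD ≤ 2.0 Å for protein partners; 1.0 Å
  heavy-atom for ligands) after subtracting the minimum energy — a
  number in [0, 1], invariant under uniform energy shifts. Percent
  correct asks whether the lowest-energy record is near-native.
- **Rotamer recovery**: fraction of χ angles farther than 20° from the
  reference, with terminal 180° symmetry handled for the symmetric
  side chains.

## 7. Synthetic fixtures

All test data is generated programmatically: (a) observation samplers
with a planted (d*, θ*) mode, phase-space weighted so the fitted table
minimum recovers the mode; (b) a **bridged dimer** — two tripeptides
rigidly arranged so a backbone carbonyl acceptor site of chain A and a
backbone amide donor site of chain B coincide at one point, with the
approach directions at the 104.5° water angle, searched over azimuth
and spin for maximal inter-chain clearance (≥ 2.4 Å); at zero jitter
both bridging kernels evaluate to 1.0 exactly; (c) rigid-body decoy
sets with exact, independently recomputable RMSD labels and at least
one near-native pose; (d) a brute-force packing oracle returning the
exact optimum and exact Boltzmann marginals on enumerable problems.

## 8. Numerical and reproducibility choices

- All randomness flows from explicit integer seeds in [0, 2³¹); the CLI
  refuses to run stochastic commands without `--seed` and echoes the
  resolved configuration.
- Continuous minimization is replaced everywhere by fine discrete
  sampling (0.001 Å scans, 30° orientation grids, discrete rotamers);
  all reported optima are grid argmins.
- Problem sizes in the test suite (tripeptides, tetrapeptides,
  3-residue dimers, ≤ 12 decoys, ≤ 8-position packing problems) are the
  package's own choice: large enough to exercise every term, small
  enough that the full suite runs in well under a minute per file.

## 9. Limitations

- The default statistical tables are synthetic: they encode ideal
  hydrogen-bond geometry, not a survey of experimental structures. Fit
  real tables with `hydropack fit-tables` when observation data exist.
- The rotamer library is compact (top rotamers per residue type) —
  adequate for small systems and co-packing around waters, not a
  replacement for a full library.
- The implicit model is a reduced form (no full force-field
  nonbonded parameterization); absolute totals are not comparable to
  other scoring functions, only differences within this model.
- Excluding waters from the desolvation terms and the 1.0 kcal/mol
  hydrogen-bond depth were balance decisions made from first-principles
  diagnostics on the fixtures (see the repository history); other
  balances are possible and configurable via the weight map.
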