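# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `zndesign` toolkit.

## The design model

The toolkit targets minimal peptides that fold around a tetrahedrally
coordinated Zn(II) ion through a Cys₂His₂ (C2H2) site. Its working
hypothesis is that a viable scaffold can be composed from fragments of
experimentally determined protein structures: if each fragment already
places two metal anchors at a workable distance, and consecutive
fragments agree geometrically at the anchor they share, then the merged
chain inherits locally realistic backbone conformations while presenting
four donor atoms around a common point.

A *fragment* is a contiguous stretch of one chain whose terminal residues
are His or Cys with complete donor atoms (Sγ; Nδ1 and Nε2), with 2–20
interior residues, and whose terminal donor atoms approach within
6.5 Å. The donor distance is the **minimum over donor-atom pairs** of the
two anchors: a coordinating imidazole can present either nitrogen, and
the admission rule should not depend on an arbitrary nitrogen choice.
Contiguity requires strictly increasing author numbering and every
adjacent C(i)–N(i+1) distance below 2.0 Å, so chain breaks and gapped
numbering never produce spurious fragments. Fragments are directional
(N→C); a reversed pair is not a separate fragment.

Merging proceeds in two stages. In stage one the start anchor of a
candidate fragment is superposed onto the end anchor of the growing
peptide by a Kabsch least-squares fit over the anchor backbone (N, Cα,
C); the *alignment RMSD* reported for ranking additionally includes the
donor atoms, matched by name, so that side-chain placement participates
in compatibility. Only the best *k* = 10 alignments per fragment are
merged, and only the first copy of the shared anchor is kept. In stage
two, two three-anchor peptides that share their middle fragment
*sequence-wise* are joined: the right peptide is superposed over the
backbone of the entire shared fragment, its shared residues are
discarded (the left copy supplies the coordinates — one of several
defensible conventions; averaging was rejected to keep every output
conformation a rigid composition of real fragment geometries), and its
tail is appended.

Candidate sites are accepted when all six pairwise donor distances fall
inside 1.5–5.5 Å (bounds inclusive — the rule is stated as a closed
interval and measured distances at the printed precision should not fail
by a rounding hair) and the anchor composition is exactly two Cys and two
His. For each His the evaluated nitrogen is the one minimising the total
pairwise donor distance of the site, exhaustively over the ≤ 2⁴
combinations; the original protocol does not fix this choice, and the
minimising combination is the most permissive deterministic reading. A
tetrahedrality score (variance of the six donor–centroid–donor angles
about 109.47°) is reported as a diagnostic but never used as a filter.

Secondary-structure screening keeps candidates that begin and end
helical, tolerating at most four coil residues outside the terminal
helices. The per-residue assigner is a backbone-dihedral windower: helix
when (φ, ψ) lies within 30° of (−63°, −42°) for at least four consecutive
residues, strand within 40° of (−120°, 135°) for at least three, coil
otherwise (termini lacking a dihedral are coil). A hydrogen-bond-based
assigner (STRIDE/DSSP class) is deliberately not re-implemented — the
screening *rule* is the contribution here, not the assigner — and
per-residue labels from an external assigner can be imported instead,
with the usual 7→3-state collapse (G, H, I → H; E, B → E; rest → C).
Duplicate sequences (abundant when mining redundant structure sets)
collapse to the representative with the smallest accumulated merge RMSD.

### Parameters

| parameter | default | units | note |
|---|---|---|---|
| `max_donor_distance_A` | 6.5 | Å | fragment admission, minimum over donor pairs, inclusive |
| `n_interior_min/max` | 2 / 20 | residues | interior length bounds (1 < n < 21) |
| `site_window_A` | 1.5–5.5 | Å | pairwise donor window, inclusive |
| `top_k_alignments` | 10 | — | alignments merged per fragment |
| `max_terminal_coil` | 4 | residues | coil allowance outside terminal helices |
| `anchor_merge_rmsd_A` | 0.5 | Å | stage-one acceptance ceiling |
| `final_merge_rmsd_A` | 1.0 | Å | stage-two overlap ceiling |
| `reject_clashes` | off | — | optional < 2.0 Å heavy-atom clash filter |

The two merge ceilings are this package's own operating points: the
protocol being implemented bounds merging only by "best 10 alignments",
which on a large library implies sub-Ångström agreement anyway; explicit
ceilings make behaviour on small libraries predictable. They are
configurable and loose enough never to reject an exact-overlap merge. No
steric-clash filter is applied by default (candidate relaxation is the
job of downstream simulation); an optional flag rejects designs with any
non-bonded heavy-atom pair under 2.0 Å.

Candidate ranking is implemented as an exact nearest-neighbour scan.
Approximate indexing (the LSH-forest family) is an acceleration for
database-scale libraries; the alignment RMSD, computed after a per-pair
rigid fit, is not a vector-space metric, so any index would need an
embedding whose correctness is defined against the exact scan — which is
the contract implemented and tested here.

## ITC proton-linkage analysis

Zn(II) binding at constant pH displaces protons (notably from the
coordinating cysteine thiols), so the calorimetric enthalpy observed in a
buffer contains that buffer's ionization enthalpy:

ΔH_obs = ΔH_bind + n_H⁺ · ΔH_ion.

Titrating in several buffers of distinct ΔH_ion identifies both terms by
ordinary least squares: the intercept is the buffer-corrected binding
enthalpy (kcal/mol) and the slope the signed mean number of exchanged
protons (negative = released). The fit (via statsmodels OLS) reports
standard errors and residuals; at least two distinct ΔH_ion values are
required, and a rank-deficient design (all buffers equal) is an error.

Equilibrium algebra uses ΔG_bind = RT ln K_D with
R = 1.98720425×10⁻³ kcal/(mol·K) and T defaulting to 298.15 K. Written
with the dissociation constant, the sign convention sometimes appears
flipped in the literature; this package fixes the convention that
nanomolar dissociation gives a negative binding free energy (220 nM ↔
−9.1 kcal/mol at 298.15 K), with K_A·K_D = 1 and −TΔS = ΔG − ΔH enforced
as invariants.

The shipped buffer ionization enthalpies (ACES 7.27, HEPES 4.88, PIPES
2.68, sodium cacodylate −0.72 kcal/mol at 298.15 K) are literature values
from Goldberg, Kishore & Lennen, *J. Phys. Chem. Ref. Data* 31, 231
(2002), provided as an editable default table — they are calibration
inputs, not measurements made by this package.

## The synthetic-structure generator

All tests run on structures generated in-package; nothing is downloaded.

Backbones are built from ideal internal coordinates (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å, standard angles, ω = 180°) by natural-extension
(NeRF) placement with per-residue (φ, ψ); the ideal helix uses
(−57°, −47°). His and Cys side chains are idealized stubs with fixed
internal coordinates (Cβ–Sγ 1.81 Å; planar imidazole with ~2.1 Å between
ring nitrogens); in engineered scenes the stub is oriented so its donor
lies at a solved target point. Stubs are geometrically, not chemically,
faithful — sufficient for every rule the pipeline applies, none of which
inspects chemistry beyond residue and atom names.

Engineered scenes make pipeline outcomes true by construction. The
positive scene is a 20-residue helix–loop–helix (helices 1–8 and 13–20)
with anchors H1, C5, H16, C20. Its loop torsions are a canonical set
found once by constrained least squares (hinge residuals on the
anchor-Cβ reachability conditions), frozen as constants with ≥ 1.7 Å of
margin to every admission bound; per-seed variation jitters these
torsions (σ = 3°, annealed to 0° if a draw leaves the feasible pocket),
then re-solves the four donor directions on their "reach spheres" by
least squares so that all six pairwise donor distances land inside an
inner band (2.4–4.8 Å) of the admission window, and finally re-verifies
the evaluator's own nitrogen-choice logic against 1.7–5.3 Å. Negative
scenes each violate exactly one rule: the N-terminal His donors re-aimed
beyond 6.6 Å from every other donor; a single helix whose only anchor
pair has 25 interior residues; anchors H, C, H, H; and a coil–helix
variant (residues 1–12 coil) whose leading coil exceeds the four-residue
allowance while its site geometry still passes. Random scenes (30–60
residues, ~24 % His/Cys, mixed helix/extended/random torsions) exercise
the mining and ranking oracles without engineered outcomes.

What the generator does *not* emulate: side-chain rotamer statistics,
sterics and packing, solvent, real loop geometry, crystallographic
artifacts (altloc disorder beyond synthetic cases, missing atoms), and
the redundancy structure of real sequence databases. Passing tests
therefore certify the combinatorial and geometric rules and their
boundary behaviour — not that mining a real structure snapshot
reproduces any particular candidate count.

The ITC generator draws ΔH_obs from the linkage forward model with
seeded Gaussian noise (default σ = 0.1 kcal/mol, the scale of the
reported enthalpy uncertainties) over the four shipped buffers.

## Numerical choices

* Kabsch fits forbid reflections (smallest singular direction flipped
  when the optimal orthogonal matrix is improper); fewer than three or
  collinear points raise a degenerate-geometry error rather than
  returning an arbitrary rotation.
* Ranking ties: alignment RMSDs are quantized to 10⁻⁹ Å for ordering and
  broken lexicographically by (source, chain, start, end residue), so
  exactly tied candidates (identical local geometry) order identically
  across runs and implementations.
* His ring-flip equivalence is not applied in alignment RMSD: nitrogens
  match by name. This keeps scoring deterministic; a flip-aware score
  would only lower RMSDs for near-symmetric ring placements.
* Altloc resolution keeps the highest occupancy (ties → altloc 'A');
  only the first model of multi-model files is read; non-standard
  residues map to 'X' and are never anchors. The asymmetric unit is
  taken as given — no assembly expansion.
* PDB coordinates round-trip at the format's 10⁻³ Å precision; every
  engineered scene keeps ≥ 0.1 Å margin to each admission bound so
  quantization cannot flip an outcome.
* Within-fragment permutation uses one seeded generator, segments
  processed N→C; an identity permutation is redrawn (up to 100 times)
  unless the segment has fewer than two distinct letters, so controls
  differ from designs wherever possible.

## Problem sizes

The shipped validation exercises fixture-scale inputs: single chains of
20–60 residues, libraries of up to a few dozen fragments, 20-seed scene
sweeps, and 200-replicate titration simulations — sizes chosen so the
whole suite certifies exact oracle equivalence rather than sampled
agreement. The mining and assembly code paths are the same ones a
database-scale run would use; only the exact top-k scan (quadratic in
library size) would warrant an approximate index there.

## Known limitations

* Candidate counts from mining a full homology-reduced PDB snapshot are
  not reproducible here: they depend on that specific database.
* Molecular-dynamics screening, quantum-chemical affinity prediction and
  experimental structure determination are outside scope; the pipeline
  exports candidates in PDB format for such downstream work.
* The dihedral secondary-structure assigner is stricter than
  hydrogen-bond-based assigners on distorted helices; imported labels
  are the recommended path for real structures.
* Multi-site binding (stoichiometries above one) is not modelled in the
  ITC module; the linkage fit assumes a single dominant binding event.
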