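# Methods

This note documents the models, geometric criteria, parameter choices
and known limitations of `loxpharm`. Values quoted here are defaults;
all of them are exposed as function parameters or config dataclasses.

## Superposition

Rigid superposition uses the Kabsch SVD solution on paired atoms
(backbone N, CA, C, O by default; CA-only as an option). Outlier
rejection runs for up to 5 cycles with a rejection multiplier of 2.0:
after each least-squares fit, atom pairs deviating by more than
2.0 × the current RMSD are discarded and the fit repeated until no
pair is removed. These defaults mirror the documented behaviour of the
standard alignment tools structural biologists use for near-identical
chains; both are parameters because published RMSDs rarely state them,
and a reported backbone RMSD can shift by a few hundredths of an
Ångström depending on the convention. `rmsd_kept` is the RMSD over
retained pairs, `rmsd_all` over all initial pairs under the final
transform; with an infinite multiplier the two coincide.

Residue pairing uses global sequence alignment (match +1, mismatch −1,
gap −2) and keeps only identity-matched columns. The chains this
package targets are near-identical engineered variants of one protein,
so the scoring scheme is not sensitive; it is configurable in code.

## Loop grafting

A gap is any run of construct-sequence positions absent from the
model, including termini. Anchor windows (default 4 residues, searched
within 8 residues of each gap edge) are chosen to minimize the
target-vs-donor backbone RMSD, ties going to the window nearest the
gap; the copied donor segment spans from the start of the pre-window
to the end of the post-window, so grafts deliberately extend beyond
the strict gap into well-overlapping flanking regions. The donor
segment is refitted rigidly onto the target anchors before insertion
rather than energy-minimized: the package is force-field-free by
design, which keeps grafting exactly reproducible and makes
pristine-donor recovery a machine-precision identity. Side chains are
copied verbatim; rotamer repair is out of scope.

Junction acceptance uses standard stereochemistry: CA–CA ∈ [2.9, 4.1] Å
and peptide C–N ∈ [1.2, 1.5] Å. Clashes are heavy-atom pairs from
non-adjacent residues closer than the sum of Bondi van der Waals radii
minus 0.4 Å.

## Ramachandran classification

Dihedrals are computed from atan2 of the standard vector construction;
chain breaks are declared when the peptide C–N distance exceeds 2.0 Å.
The bundled region maps are unions of rectangular φ/ψ boxes per
residue class (general, glycine, proline, pre-proline), with the
allowed region obtained by dilating the favored boxes by 20–25° plus a
left-handed-helix allowance. This reproduces the qualitative
favored/allowed/outlier structure of density-derived Ramachandran
tables but is *not* a re-derivation of any program's statistical
tables, so no quantitative claim is tied to exact favored percentages;
the classification is used as an internal sanity check of grafted
models (ideal secondary-structure fixtures classify 100% favored).

## Interaction detection and occupancy

Geometric criteria (heavy-atom based, hydrogens used when present):

| interaction | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor distance; D–H⋯A angle (X–D⋯A surrogate without H) | ≤ 3.5 Å, ≥ 120° |
| metal coordination | ligand O/N/S–metal distance | ≤ 2.6 Å |
| hydrophobic | apolar C – apolar C distance | ≤ 4.5 Å |

Donor capability requires an explicit hydrogen, or a hydroxyl-like
terminal oxygen (single heavy neighbour at > 1.32 Å — carbonyl oxygens
bond at ~1.23 Å and are excluded). Covalent neighbours are inferred
from distance (H < 1.3 Å, heavy < 1.85 Å, 1.95 Å with sulfur). Waters
are ignored entirely: only direct ligand–protein contacts are scored,
water-bridged interactions are out of scope by design. Occupancy is
bookkept per (ligand atom, protein residue) pair — not aggregated per
residue — as exact frame counts, and the persistence filter is strict
(> 25%).

The occupancies a 200 ns production simulation would give cannot be
recomputed here (no MD engine is in scope, and such trajectories are
not desk-scale); the planted-ensemble generator substitutes exact
ground truth, and tests verify exact recovery plus the qualitative
persistence pattern of a chelating inhibitor.

## Pharmacophore perception

Feature tolerances default to 1.5 Å for HBD/HBA/HYD/NI and 1.0 Å for
METAL; excluded volumes have radius 1.2 Å and are placed on protein
heavy atoms whose minimum distance to the ligand lies in [2.0, 5.0] Å,
skipping atoms already engaged as feature partners. These are the
knobs commercial perception tools set internally without printing
them; all live in `PerceptionConfig`. Hydrophobic features sit at
centroids of connected apolar fragments (≥ 3 heavy atoms, C/S/halogen,
polar-attached carbons removed) with at least one apolar protein
carbon in range. The negative-ionizable pattern list — carboxylate,
tetrazole, N-hydroxyurea N–OH, acylsulfonamide — covers the warheads
of the classic iron-chelating inhibitor series (zileuton-type
N-hydroxyureas included). Directional features store both a unit
direction and the partner's position so the consensus stage can
degrade them to spheres.

Labels (M1, D1, D2, …) are assigned per type by distance to the metal
anchor, then lexicographic coordinates: deterministic, idempotent and
order-independent. They will not reproduce the subscripts of any
hand-curated figure, only types, counts and provenance.

## Consensus

Correspondence is greedy closest-pairs grouping per feature type
(union by ascending cross-model distance, at most one member per
source model, all pairwise distances within the 2.0 Å match radius).
A brute-force minimal-total-distance assignment is kept as a test
oracle; on pocket-scale models (≤ 13 features) the two agree on every
fixture tried, and a single code path is easier to reason about.
Retention: present in all models → required; in exactly two of three →
optional; rarer → dropped. Merged centers are member means; merged
tolerance is the largest member tolerance plus half the maximal
pairwise spread, so every member sphere is covered. Donor arrows are
converted to non-directional spheres. Excluded volumes survive only as
mutually overlapping triples (center distance < sum of radii across
all models), merged at the mean center with the *smallest* member
radius — features interpolate, volumes intersect, because excluding
space all models do not agree on would over-restrict the pocket.

The acceptor features of the reference inventories are dropped by the
presence rules alone (they occur in a single complex); no special
handling of the variable deep-pocket region is needed.

`loxpharm.datasets` transcribes the published per-complex feature
inventories of the NDGA / zileuton / BW B70C complexes onto synthetic
coordinates (an invented but internally consistent pocket layout,
flagged as such in the module). The required features were placed
non-coplanar deliberately: near-coplanar required sets admit an
approximate flip pose that can defeat excluded-volume checks, which is
a real geometric property of pharmacophore matching worth avoiding in
a reference layout.

## Screening and scoring

Matching enumerates all injective, type-compatible assignments of
required features to ligand points; each candidate is aligned by
Kabsch (translation-only below three points) and accepted if every
required deviation is within tolerance and — when enabled — no ligand
heavy atom lies strictly inside an excluded volume (atom centers vs
sphere radius, no van-der-Waals inflation). Optional features add
score but never veto. The fit score, 10 per matched feature minus
deviation/tolerance summed, is this package's own definition (the
commercial one is unpublished); it preserves the orderings screening
relies on — more features beat fewer, tighter beats looser — and no
quantitative claim depends on its absolute values. Metal-capable
ligand points (catechol OH, hydroxamate, N-hydroxyurea oxygens) are
valid assignments for METAL features; consensus features carry no
directionality at screening time, so there is no angular term.

Ligand conformers are an input; a convenience wrapper embeds 25
conformers per compound with ETKDG (seed 2021). Pseudo-ligands from
the synthetic generator carry precomputed feature points so planted
truth stays purely geometric.

## Benchmarking

Decoy selection windows: molecular weight ± 25 Da, logP ± 1.0,
H-bond donors/acceptors ± 1, net charge exact; 2-D path-fingerprint
Tanimoto to every active ≤ 0.7 — reasonable defaults in the absence of
published settings for decoy web services. Non-matching compounds
enter the ROC at score 0 as a tie group; midrank handling keeps the
AUC equal to the Mann–Whitney statistic (verified by brute force in
tests). The enrichment factor is the whole-dataset hit-list form
(TP/hits)/(A/N): with 11 actives all retrieved, 108 false-positive
decoys and 511 compounds it evaluates to 4.3, which a top-x% EF
definition does not reproduce from the same counts.

## Synthetic data

Generators are pure functions of (parameters, seed). Toy proteins are
built from ideal internal coordinates by NeRF chain extension
(torsions are therefore recovered exactly by the dihedral code).
Planted complexes place one interaction per site, 12 Å apart so sites
cannot cross-talk, with geometric margins of ≥ 0.2 Å from every
cutoff so boundary conventions never matter. Ensembles break a contact
by translating the partner residue 8 Å along the interaction axis in
exactly the scheduled frames. Screen-set decoys are sabotaged actives:
a required feature type removed, all points of a required type
collapsed onto one far location (single displaced points are *not*
guaranteed non-matches when surplus same-type points exist — a
property of match-all semantics, not a bug), or an atom planted inside
an excluded volume with exact required points so the recovery pose is
unique and the violation certain.

What the fixtures do not emulate: real packing density (toy pockets
are sparse, so excluded-volume counts are small), chemical diversity
(pseudo-ligands are geometric scaffolds), conformational strain, or
force-field energetics. Passing tests therefore demonstrate
correctness of the geometry, bookkeeping and statistics — not
screening performance on real chemical libraries.

## Problem sizes

The shipped tests and the acceptance script use a 60–120 residue toy
protein, 100–1000 frame ensembles, 100 random graft draws and an
11-active / 500-decoy screen — sizes chosen to make every planted
check exact while keeping the whole suite in seconds on one core.

## Known limitations

- No energy minimization or rotamer repair after grafting; junction
  quality is asserted geometrically, not energetically.
- Ramachandran regions are coarse boxes; percentages are not
  comparable to density-based validators beyond the qualitative level.
- Hydrogen-bond role assignment without explicit hydrogens relies on
  the terminal-oxygen heuristic; unusual protonation states are not
  modelled (no pKa machinery).
- The matcher's assignment enumeration is exponential in features per
  type; it is sized for pocket-scale models (≤ ~8 features per type),
  not dense feature maps.
- mmCIF writing, assembly expansion and tautomer/protomer enumeration
  are out of scope.
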