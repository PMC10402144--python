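# Methods

## Confidence metrics and the routing gate

A predicted complex is partitioned into receptor and ligand chains by a
spec string such as `AB_C`. Interface residues are those with any heavy
atom strictly within 8 Å of the other partner (predicted models carry no
hydrogens, and "within" is read as `<`; a flag flips to `≤`, which can
differ only on measure-zero boundaries). Interface contacts are
cross-partner residue pairs with Cβ–Cβ distance < 5 Å, with Cα standing
in for glycine. Interface-pLDDT is the unweighted mean pLDDT over the
union of both partners' interface residue sets; per-residue pLDDT is the
Cα B-factor. The routing gate sends interface-pLDDT ≤ 85 (or an empty
interface) to global docking and > 85 to local refinement; the boundary
is closed on the global side. Mobile residues for backbone sampling are
maximal runs of consecutive residues (within a chain, by author
numbering) with pLDDT < 80; runs shorter than 3 residues are discarded
because the backbone operator needs at least one interior residue
between its two anchors.

Discriminator evaluation computes four candidate metrics per model
(interface residue count, interface contact count, average pLDDT,
interface-pLDDT), labels each model near-native when its iRMSD against
the native is ≤ 4 Å, and reports per-metric ROC/AUC (rank-based, equal
to the Mann–Whitney statistic; scikit-learn backend, cross-checked in
the tests against a brute-force pairwise oracle) plus the 85-threshold
confusion matrix. The interface-pLDDT–vs–DockQ trend can be summarized
with a 4-parameter logistic fit (least squares, deterministic
initialization: midpoint = median x, slope 0.1, floor = min y,
ceiling = max y; non-convergence returns the initialization flagged).

## Flexibility metrics

Residue correspondence between two conformers comes from global sequence
alignment per chain (match +1, mismatch −1, gap open −10, extend −0.5).
Terminal gaps are penalized lightly (open −1, extend −0.5) so terminal
overhangs are trimmed out of the correspondence instead of being forced
into a mismatched register; aligned mismatches (point mutations between
crystal forms) are kept and logged. Per-residue RMSD superposes the
mobile conformer onto the reference over all paired Cα atoms (Kabsch,
SVD with the reflection branch removed) and reports each pair's Cα
deviation. LDDT uses Cα–Cα distances only: for every ordered pair
(i, j), i ≠ j, with reference distance below the 10 Å inclusion radius,
the pair scores 0.25 per tolerance t ∈ {0.5, 1, 2, 4} Å with
|d_ref − d_model| < t (strict, so boundary values do not score); the
overall score is the mean over in-scope ordered pairs and per-residue
values are row means (undefined rows are reported missing). No
superposition is involved, which is the point: hinge motions leave
intra-domain distances intact, so LDDT separates genuinely flexible
residues from rigid domains that merely move together. An all-heavy-atom
variant is deliberately not the default; Cα-only matches the flexibility
analysis the rest of the package performs.

## Docking quality

DockQ follows the published constants: f_nat counts 5 Å heavy-atom
cross-partner residue contacts; iRMSD is the backbone (N, Cα, C, O) RMSD
over native interface residues (10 Å heavy-atom criterion) after
superposing those residues; LRMSD superposes receptor backbones and
measures the ligand backbone RMSD without further fitting;
DockQ = (f_nat + s(iRMSD, 1.5) + s(LRMSD, 8.5))/3, s(x, d) = 1/(1+(x/d)²).
A DockQ of exactly 0.23 counts as acceptable (success). Chains must be
pre-matched by id between model and native.

## The sampling engine

Global docking runs `n_trajectories` independent trajectories (default
8). Each randomizes the ligand: a uniform random rotation about its
centroid, then placement along a uniform random direction from the
receptor centroid at contact distance (minimum cross-partner atom
distance in [3, 5] Å, found by bisection). Each trajectory holds three
replicas at inverse temperatures 1/1.5, 1/3, 1/5 (kcal/mol)⁻¹. A rigid
move rotates the ligand about its centroid by a uniform axis and an
angle uniform in [0, 8°] and translates it along a uniform direction by
a magnitude uniform in [0, 4 Å] (drawing the magnitude uniformly, rather
than uniformly in the ball, keeps a usable fraction of small refining
moves). Moves are accepted by the Metropolis criterion at the replica's
β. Every 10 trials, adjacent replica pairs (alternating even/odd)
attempt a temperature swap with probability
min(1, exp((βᵢ−βⱼ)(Eᵢ−Eⱼ))); only temperature labels move, so the
configuration multiset is conserved. Every 50 accepted moves each
replica snapshots its configuration as a scored decoy (a flag restricts
snapshots to the coldest replica). Frequent exchanges cost almost
nothing here and measurably improve annealing within the short
trajectories; 2000 trials per replica per trajectory is the default
budget, chosen to keep a full study on one CPU in minutes.

Local docking starts from a putative binding orientation; each trial is,
with probability 0.75, a backrub move on a uniformly chosen mobile
segment — all atoms of the segment's interior rotate rigidly about the
axis through the first and last Cα by an angle ~ N(0, 2.5°) capped at
±10°, leaving the anchors and the anchor Cα–Cα distance exactly fixed —
and otherwise a small rigid move (1 Å / 3°). The start configuration is
always retained as a candidate decoy, and final snapshots are polished
by coordinate descent over the ligand's six rigid degrees of freedom
(step-halving line search, 50 iterations), a deliberately simple
stand-in for side-chain repacking and minimization.

The default energy is a coarse cross-partner Cβ contact score
(Cα for glycine): E = 10·Σ max(0, 3.5 − d)² − Σ S(d), with S = 1 on
[4, 6] Å and cosine-switched to 0 over [3.5, 4] and [6, 8] Å. It is
deterministic, rigid-motion invariant and strictly finite-range, so the
interface score (complex minus separated partners) equals the score
itself. Any callable `(Structure, Partition) -> float` can replace it;
the generic interface score then subtracts the score at 500 Å ligand
separation. Score units are abstract; the weights were set so that the
printed β ladder produces non-trivial acceptance rates.

Decoys are ranked by interface score (ties broken by trajectory and
step for determinism) and clustered greedily: best decoy seeds cluster
one, each next decoy joins the first center within 5 Å ligand-Cα RMSD
(after receptor superposition) or seeds a new cluster; the first five
centers — each by construction the lowest-score member of its cluster —
go forward. All sampling is bit-reproducible from the master seed;
per-trajectory seeds are `seed + trajectory index`.

## The synthetic fixture

`toys.generate_toy_complex` builds idealized helices (1.5 Å rise, 100°
twist, 2.3 Å Cα radius; N, C, O, Cβ placed from local helical frames).
The receptor (24 residues) is folded 150° about an offset axis into two
arms flanking an open V-groove (10 Å gap); the ligand (9 residues) has a
glycine half with no Cβ and an alanine half with Cβ, which breaks the
end-for-end flip degeneracy a symmetric helix would have under the
contact score. The planted bound pose is the global minimum of the
coarse score; for the default geometry it was located once by an
exhaustive seeded search with rigid minimization and ships as a frozen
rigid transform that construction re-settles with a short deterministic
minimization (non-default geometries fall back to a placement grid plus
minimization, which may only find a local optimum). The unbound
conformer rotates the ligand hinge segment's interior about its anchor
Cα axis — exactly the move the local-docking operator performs, so the
induced-fit motion is invertible by sampling. The model carries the
unbound backbone at the planted pose with synthetic pLDDT: baseline 95,
displaced residues (maximum atom displacement > 0.5 Å, dilated by one
residue so the low-confidence run spans the hinge pivots, as real
predictors blur confidence across a flexible region) depressed to
uniform [60, 75], Gaussian jitter σ = 3, clipped to [0, 100]. A truth
table records per-residue Cα displacement both raw (exactly zero outside
the hinge) and after a global Cα superposition (what per-residue RMSD
reports), plus the per-residue pLDDT.

What the fixture does not emulate: real side chains and packing, hence
no steric specificity beyond the Cβ cloud; sequence-dependent energetics
(the score is composition-blind apart from glycine's missing Cβ);
crystallographic artifacts, missing density, or chains differing by more
than a hinge. Passing tests therefore demonstrate the mechanics and the
statistics of the protocol, not benchmark-scale docking accuracy on real
complexes.

## Numerical and design choices

* Strict `<` at every distance cutoff and LDDT tolerance; boundary
  values do not count.
* Kabsch rejects N < 3 and collinear inputs; reflections are excluded
  via the determinant branch.
* pLDDT lives on the Cα B-factor; if atoms of a residue disagree, Cα
  wins. Altlocs resolve to highest occupancy; modified residues with a
  standard parent (MSE, SEP, …) map to it, others are dropped with a
  warning.
* The gate boundary is ≤ 85 → global (the closed side is global).
* Cluster count K = 5 and 5 Å cluster radius; per-center local budgets
  split the configured local step count evenly.
* The pipeline applies the gate once, on the input model; post-docking
  confidence is reported but never re-routes.
* Problem sizes in the shipped study (24+9-residue fixture, 8×3×2000
  global trials, 1000 local trials, 60-model cohort) keep the full
  acceptance run around a minute on one CPU.

## Known limitations

The coarse contact score is orientation-blind with a 2 Å-wide flat
attraction plateau, so docking basins are energetically flat over pose
displacements of several Å: sampled minima within half a score unit of
the planted global minimum can lie 5–7 Å away in ligand RMSD. Global
docking therefore reliably relocates the planted binding *site* while
the precise pose within the basin varies between seeds; tight pose
convergence requires a shape-specific (e.g., all-atom) scoring function
plugged in through the score contract. Loop-closure (kinematic) backbone
moves and explicit side-chain packing are out of scope; the single
backrub operator covers hinge-like motions only. Only two-partner
docking is supported, and chains must share identifiers between model
and native.
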