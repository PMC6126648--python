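# Methods

## Model of the problem

An unmodeled internal stretch of a protein chain is detected from a
case-coded construct sequence: uppercase positions have a complete modeled
main chain (N, CA, C, O, each above occupancy 0.01 in at least one
alt-loc), lowercase positions are missing or incomplete. An internal run
of lowercase positions of length ≤ 30 with at least five consecutive
modeled residues on both sides is a candidate gap. Terminal runs are never
gaps (terminus extension is a different problem with much weaker prior
information). Stretches modeled entirely at occupancy ≤ 0.01 are treated
as unmodeled, but the existing coordinates are admitted to the candidate
pool as one extra candidate. Partially modeled residues at the gap edge
are lowercase by the coding rule and are therefore replaced together with
the loop. Gaps whose flanking five residues carry non-CA backbone
alternates are skipped — the alignment target is ambiguous; CA-only
alternates (common with alternate side chains) are tolerated by taking the
first conformer.

## Donor selection and superposition

Donor chains are paired to the target construct by global Needleman–Wunsch
alignment (BLOSUM62, affine 11/1). A donor is eligible for a gap when its
whole-chain identity is ≥ 70%, it covers the loop, the two gap-adjacent
residues and all eight anchors with a complete backbone, and its identity
over the loop and over the anchors is at least 50% (single-residue loops
are exempt from the loop rule). Backbone alternates inside the donor loop
are expanded into separate candidates; donors with several disjoint
alternate stretches are excluded rather than enumerating combinations.

Of the five modeled residues per side, the gap-adjacent one is remodeled
with the loop; the remaining eight are superposed by the closed-form
quaternion (Horn) solution — the optimal rotation is the principal
eigenvector of the 4×4 key matrix of the centered covariance, always a
proper rotation. Backbone atoms always enter the fit; side chains join for
identical residue pairs, with chemically equivalent Asp/Glu/Phe/Tyr labels
swapped when a provisional backbone-only fit shows the swap reduces the
summed squared distance. The reported RMSD is over backbone atoms only,
and grafting requires RMSD < 2.0 Å.

A graft copies the donor residues into the target frame, sets all
occupancies to 1.00, multiplies each B factor by the ratio of model-mean
protein B factors (target/donor), crops mutated side chains to CB, and
converts MET↔MSE to the target's prevailing methionine type. Candidate
pairs closer than 0.1 Å loop-backbone RMSD keep only the better-aligned
member; the ten best candidates by alignment RMSD proceed.

## Clash adjudication

Contacts below 2.6 Å between candidate atoms and retained model atoms
(including symmetry images within a 5 Å margin of the candidate bounding
box; hydrogens ignored) are classified heavy (< 2.1 Å) or small. CB counts
as main chain because its position is fixed by the backbone. The verdict
hierarchy: a heavy clash of loop main chain with existing main chain or a
retained ligand discards the candidate; glycerol, ethanol, 1,2-ethanediol
and PEG-like polymers (configurable code list) are instead deleted;
existing side chains heavy-clashing with the loop backbone are deleted
unless the side chain is a disulfide-bonded Cys (SG–SG < 2.5 Å), which
vetoes the candidate; loop side chains heavy-clashing with anything but
water are cropped from the γ atom; waters and atoms at occupancy ≤ 0.01
are deleted on any clash. Atom pairs across the graft junction (candidate
terminal residue against its bonded anchor residue) form the peptide
linkage and are not clashes. Deletions are provisional per candidate and
are applied to the model only when that candidate is finally accepted, so
a discarded loop leaves the model untouched.

## Restrained real-space regularization

Each surviving candidate, plus one existing residue per side, is
regularized against the map by minimizing

```
E = w_geom · [bonds + angles + torsion tethers + ω + CA chirality + Rama]
    − w_map · Σ_atoms ρ(x)
```

with L-BFGS-B and analytic gradients for every term. Bond/angle targets
come from the bundled standard-geometry table (conventional refinement
values; e.g. C–N 1.329 ± 0.014 Å, N–CA–C 111.0 ± 2.7°). ω is restrained
to the nearer of 0/180° (σ 6°), so cis peptides stay cis; carbonyl-O
planarity is held by an improper torsion (target 180°, σ 3°) together with
the three angles around the carbonyl carbon — the validation module still
measures true least-squares plane deviations on the result. φ/ψ and
side-chain torsions are tethered to the start conformation with σ = 8°;
15° was tried first and let side-chain tips drift ~0.2 Å up the overlapping
Gaussian density of neighbors. The Ramachandran term is the negative
bilinear-interpolated log-odds of (φ, ψ) at weight 0.2. One further
residue per side participates in the restraints with pinned coordinates,
keeping the region covalently tethered to the fixed model — without it
the region ends crawl into the neighbors' density. ρ is the tricubic map
interpolant, differentiated analytically.

Defaults: w_geom : w_map = 1 : 3 on the synthetic map's native scale
(peak heights of order 1), convergence at gradient max-norm < 1e-3 within
1500 iterations (500 was insufficient for regions above ~8 residues at
this tolerance). Junction gaps wider than 1.6 Å have the loop-edge N
pulled to 1.40 Å from the anchor C before minimization; the bond restraint
then settles it at 1.33 Å.

Self-consistency behavior: an ideal-geometry segment placed exactly in its
own synthetic density converges with backbone shifts below 0.05 Å.
Side-chain tips equilibrate up to ~0.1 Å away because canonical-rotamer
atoms sit in overlapping neighbor density in the Gaussian map model; this
is a property of the synthetic maps, not of the optimizer, and real
(sharper, solvent-flattened) maps behave differently.

## Geometry and Ramachandran filters

RMSZ per restraint class is the root mean square of (observed − target)/σ:
bonds (three intra-residue plus the peptide bond), the six backbone
angles, CA chiral volume (target computed from the same table, σ 0.2 Å³),
least-squares peptide-plane deviations (σ 0.02 Å) and ω torsions (σ 6°).
A candidate is rejected when refinement did not converge, any
consecutive-residue C–N distance leaves [1.2, 1.5] Å, bond or angle
RMSZ > 1.2, chirality RMSZ > 1.5, plane or torsion RMSZ > 2.0, two or more
adjacent ω deviations exceed 30° from 0/180° (a single distortion is
tolerated — later refinement usually resolves it), or a cis peptide
appears whose donor peptide is not cis.

The Ramachandran score uses reference φ/ψ densities per residue class
(Gly, Pro, pre-Pro, Ile/Val, general), built as mixtures of wrapped
Gaussians over the canonical basins with a 0.5% uniform floor, discretized
once on a fixed 4° grid at import — the construction is deterministic, so
scoring is bit-for-bit reproducible without data files. The exact binning
and smoothing of the torsion-validation tools this emulates are not
recoverable from public descriptions; these tables are a documented
stand-in with the same qualitative basin structure, and absolute Z values
are not comparable across implementations. Per-residue score = log-odds
against uniform, nearest-bin lookup; class moments (μ, σ) are the
bin-mass-weighted moments of the log-odds under the reference density, so
a fragment drawn from the reference scores Z ~ N(0, 1) at any length under
the standard-error normalization Z = Σ(sᵢ − μ)/√(Σσ²). A candidate with
Z < −5 is rejected when it lies more than 2σ below the mean of either the
peer-candidate Z population or the donor-loop Z population (populations
under 3 are skipped — insufficient evidence). The fixed 2σ form is used
rather than the t-based critical value.

## Density acceptance

The synthetic map model is a periodic sum of isotropic atomic Gaussians,
width σ² = (B + b_blur)/8π², amplitude ∝ electron count × occupancy,
sampled at 0.7 Å. Interpolation is tensor-product four-point Lagrange
cubic: exact at nodes and for per-axis polynomials of degree ≤ 3,
C⁰-continuous. The density ratio compares loop main-chain atoms with the
control set of main-chain atoms ordered in every donor (fallback below 30
atoms: all non-loop main-chain atoms); acceptance requires ratio > 0.25.
RSCC/RSR are computed over grid nodes within 2.0 Å of the atom set;
chains with whole-chain RSCC < 0.80 are skipped up front, and an accepted
loop is finally re-checked at RSCC ≥ 0.60 against a calc map synthesized
from the updated model — failing that, the loop and all its deletions are
rolled back. The study this follows recalculates maps by reciprocal-space
re-refinement before the final check; that step is out of scope here, so
the final gate runs against the supplied map.

## Main-chain repair

The five atoms CAᵢ, Cᵢ, Oᵢ, Nᵢ₊₁, CAᵢ₊₁ of a trans peptide are coplanar
with fixed internal geometry. Whenever at least three are present, an
ideal planar template is rigidly fitted to them (same quaternion kernel)
and missing atoms are copied from the fitted template; passes repeat so a
reconstruction in one plane can enable the next. All sets of 1–3 backbone
atoms missing from a single residue resolve this way when the flanking
residues are modeled. The cross-residue trio (Cᵢ, Oᵢ, Nᵢ₊₁) is
underdetermined — the plane may rotate freely about the CAᵢ–CAᵢ₊₁ axis —
and is left unreconstructed. Rebuilt atoms take the mean B of the present
plane atoms and occupancy 1.0. OXT is added in the carboxylate plane
(C–OXT 1.25 Å, symmetric to O about the CA–C axis) only when a sequence
source (construct FASTA or SEQRES) shows the last modeled residue is the
true C-terminus and the residue is otherwise complete. Occupancy
normalization resets protein atoms to 1.0 when the residue has no
alternates and bonded neighbors are fully occupied; the carbonyl O needs
only its C. HETATM peptide ligands are skipped.

## Synthetic fixtures — what they do and do not show

The generator builds ideal-geometry backbones from a φ/ψ plan (helix,
strand, polyproline-II segments), attaches side chains at one canonical
rotamer per type (ring closure for Pro and aromatics is approximate — the
atoms are plausible for clash and density work, but this is not a rotamer
library), derives a target by deleting or zero-occupying a gap, derives
donors by seeded coordinate noise (default σ 0.15–0.3 Å), up to 3
mutations, a random rigid motion and a B-factor scale (default 1.5), and
synthesizes the map from the intact truth (b_blur 15 Ų). All randomness
flows from one seed; regeneration is bit-stable.

End-to-end tests use 20 such fixtures on a 50-residue chain with gap
lengths 1–14; recovery means the accepted loop's backbone RMSD to the
ground truth is below 0.5 Å, and zeroing the map in a 3 Å shell around the
true loop atoms must leave every candidate below the 0.25 density ratio.
Problem sizes (50 residues, 3 donors, 0.7 Å grids) were chosen so the
whole funnel exercises in seconds per fixture. Passing these tests shows
the bookkeeping, filters and numerics are correct under the stated noise
model; it does not show performance on real crystallographic maps, which
have solvent, model bias, anisotropy and genuinely different loop
conformations between crystal forms.

## Known limitations

- Donor retrieval is the caller's job (no sequence search); donors are
  files on disk.
- The regularizer is a stand-in for full torsion-space real-space
  refinement; no reciprocal-space step, no map recalculation.
- Ramachandran reference tables are parametric stand-ins (above).
- Chain RSCC uses a self-synthesized calc map rather than per-residue
  weighted density statistics; it is an approximation suitable for the
  0.80/0.60 gates.
- Multi-conformer grafting, side-chain completion and peptide-flip
  rebuilding are out of scope; residues with incomplete side chains are
  reported for downstream tools.
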