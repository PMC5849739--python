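# Methods

## Coordinate conventions and periodicity

All structures live in orthorhombic boxes with the membrane normal along
Z. Lateral distances use the minimum-image convention in X and Y; Z is
never imaged, because the periodic Z repeat of a bilayer simulation
contains solvent slabs that must not alias into the membrane. Intra-protein
distances (the ionic lock) are computed without any imaging. Residue
numbering is author/PDB numbering throughout; no renumbering is ever
applied. Structures are read through MDAnalysis (first model, alternate
locations restricted to '' and 'A'); multi-model PDB, DCD and XTC
trajectories are streamed frame by frame, so memory use is independent of
trajectory length. A header CRYST1 record applies to every model of a
multi-model PDB.

## Receptor-state metrics

Superposition uses the Kabsch algorithm (SVD of the weighted covariance
matrix with the determinant sign correction, so reflections are never
returned). A covariance of rank < 2 — collinear or degenerate point sets —
is an error rather than an arbitrary choice of rotation. Atoms of two
structures are paired by (residue number, atom name); unpaired atoms, e.g.
crystallographic gaps, are dropped pairwise with a logged count.

Fitting convention: whole-receptor and per-helix RMSD series are fitted on
TM-domain Cα atoms (helices 1–7 plus H8) and measured on backbone
N/CA/C/O. Local motifs — the triad core (all heavy atoms of I3.40, P5.50,
F6.44) and the NPxxY backbone (7.49–7.53) — are measured after the same
global TM fit *without re-fitting*: a local fit would hide exactly the
re-packing relative to the helix bundle that these motifs are meant to
report. The ionic lock is the Cα–Cα distance R3.50–E6.30. TM6 displacement
between two structures superposes on the Cα of TM1–TM5, TM7 and H8 (TM6
excluded so its own motion cannot bias the fit) and reports the movement
of the Cα of residue 6.30, the conventional intracellular-end marker of
TM6. Side-chain-to-lipid distances take the minimum over lipid
phosphate-group centres of mass (P plus its phosphate oxygens, per the
charge-rule table) of the minimum over the residue's terminal nitrogen
atoms (Arg NH1/NH2, Lys NZ).

The packaged β2AR annotation maps Ballesteros–Weinstein codes to author
numbering (R131=3.50, E268=6.30, I121=3.40, P211=5.50, F282=6.44, the four
TM6 lysines K263/K267/K270/K273, NPxxY 322–326) and records the six
protonated acidic residues (D79, E122, D130, D234, E237, E268).
"Protonated" acidic residues are treated as charge-neutral on their
carboxylate oxygens for contact counting — the electrostatic consequence
of carrying the extra proton. Histidine is neutral unless a residue is
explicitly listed as cationic. Annotations are external YAML, so any other
receptor can be analysed by supplying its own mapping.

## Membrane metrics

* **Thickness map** (grid cell 2.0 Å, smoothing radius 6.0 Å, both
  configurable): per frame and per grid cell, the mean Z of upper-leaflet
  phosphorus atoms within the smoothing radius of the cell centre minus
  the lower-leaflet equivalent, averaged over frames. Leaflets are
  assigned per frame from the phosphorus midplane (mean anchor Z). The
  map's reported "variation" is max − min over non-empty cells. Cells with
  no anchor in range contribute no sample and stay flagged empty.
* **Density profile**: mass histogram along Z relative to the phosphorus
  midplane, divided by L_x·L_y·bin_width; bin edges cover the whole box
  (extended when atoms lie outside), so the profile conserves the selected
  mass to within accumulation round-off (≪ 1e-6 relative).
* **Area per lipid**: (L_x·L_y − protein cross-section) / N_upper per
  frame. The protein cross-section is the 2D convex hull of protein heavy
  atoms whose Z lies between the two leaflet phosphorus planes, inflated
  by a 2.0 Å probe radius via the exact Minkowski-sum area (hull +
  perimeter·r + πr²). The hull is the simplest area consistent with a
  "cross-sectional area in the membrane plane"; per-lipid Voronoi APL is
  deliberately out of scope.
* **Electrostatic contacts**: unordered charged-protein × charged-lipid
  atom pairs with imaged distance strictly below the 4.5 Å cutoff, sampled
  every 4 ns (stride configurable). All charged–charged pairs are counted
  by default, with an `opposite_only` switch restricting to (+,−) pairs —
  the definition is atom pairs, not residue pairs. Empty charged sets give
  an all-zero series with a warning, since full neutralization is a
  legitimate outcome.
* **g(r)**: distance histogram normalized per frame by N_A · ρ_B · shell
  volume with ρ_B = N_B/V_box — the standard 3D whole-box convention. A
  lower-leaflet selection is quasi-two-dimensional, so the absolute g(r)
  scale is convention-dependent; comparisons *between* membranes, which is
  how the curves are used, are unaffected. The convention is recorded in
  the result metadata. Shared atoms between the two sets are excluded as
  self-pairs, and r_max must not exceed half the smallest lateral box
  edge.

A small estimator (`estimate_bulge`) summarises a localized thickening
from a map: amplitude = peak excess over the median cell value, radius =
twice the half-maximum radius of the radial excess profile — exact for the
generator's raised-cosine bump, whose half maximum sits at R/2.

## State landscape and classification

Each frame maps to (NPxxY backbone RMSD vs the inactive reference after a
TM-Cα fit, ionic-lock distance). The default analysis window is the final
half of the trajectory, with inclusive bounds at both ends; frame
membership is by frame time. Class boundaries (Å): lock < 9 →
very_inactive (taking precedence); lock > 15 and NPxxY ≥ 2.0 → active;
lock ≤ 12 and NPxxY ≤ 1.0 → inactive; otherwise intermediate. These
defaults interpolate the printed anchor distances (7.6 closed, 11.1
inactive-open, 18.9 active) and are fully configurable; no published
figure draws explicit boundaries, so they are package defaults rather than
literature constants, and no test depends on a specific boundary value
except through the anchors. Classification is a pure function and is
monotone: at fixed NPxxY, shortening the lock never yields a more active
label. Modal-state ties break toward the less active label — the
conservative call in a deactivation analysis.

## Synthetic data: what it emulates and what it does not

The generators provide *exact* ground truth rather than physical realism.

**Receptor**: eight ideal vertical helices (29 residues, 1.5 Å rise, 100°
twist, Cα radius 2.3 Å) on a 14 Å circle, with backbone N/CA/C/O plus a CB
bead and pseudo-side-chains (Arg NE/NH1/NH2, Glu OE1/OE2, Lys NZ) pointing
outward from the bundle. TM3 sits near azimuth 90° with TM6's base
opposite, and the sector around 0° is deliberately empty: solving the
inactive geometry pulls TM6 inward along the lock axis until
d(R3.50–E6.30) equals its target (11.1 Å by default), and the active state
swings TM6 rigidly about a hinge at its extracellular end. The swung tip
position is obtained by exact trilateration — the intersection of the
hinge sphere, the prescribed-displacement sphere (14 Å default) and the
prescribed-lock sphere (18.9 Å default) — which forces the swing to run
nearly perpendicular to the lock axis, through the empty sector. Both
intersection candidates are tried outward-first and checked sterically
(minimum atom separation 1 Å). The active TM7 intracellular tip (NPxxY)
shifts radially outward by 2.5 Å with a 10-residue taper so the backbone
is not torn. The two endpoints therefore differ *only* in TM6 and TM7, and
every prescribed quantity is recoverable by measurement.

**Paths**: frame k interpolates linearly at fraction k/(n−1) (or along a
piecewise-constant dwell schedule emulating metastable states) with
optional seeded Gaussian noise. Because the endpoints share the invariant
core, fitted RMSD along a noise-free path is exactly linear in the
fraction — a strong oracle for the series machinery.

**Bilayers**: nx × ny lipids per leaflet on a lattice of spacing a, so the
area per lipid is a² exactly; phosphorus sits at z = z_mid ± D(x, y)/2
with D(x, y) = D0 + A·cos²(πr/2R) inside radius R (raised cosine: smooth,
compactly supported, analytically known). The default bulge centre is the
lattice point nearest the box centre so the discrete system actually
samples the peak. Headgroup templates are 4-atom pseudo-groups (P, two
anionic phosphate oxygens, plus a cationic N for PC/PE or a neutral
glycerol carbon for PG) with 2 tail beads; the spacings √61, √68 and
√71 Å reproduce the reference areas per lipid of PE-, PC- and PG-like
membranes. Lateral jitter is applied *before* evaluating D, so jittered
phosphorus heights sample the field at their true positions; jitter
σ ≥ a/2 is rejected because the lattice identity is lost.

**Embedding**: the receptor is centred in the box, lipids whose phosphorus
falls within (receptor lateral extent + 6 Å) are removed — guaranteeing no
accidental contacts under the 4.5 Å cutoff — and exactly
`planted_contacts` charged lower-leaflet lipid atoms are relocated to
3.5–4.4 Å of randomly chosen charged TM6 atoms such that each is in range
of exactly one protein atom. Contact counting on the result must return
exactly the planted number.

Passing these tests shows the analytics are correct on their inputs; it
does not validate force fields, sampling convergence, or any physical
claim about real membranes. The pseudo-atom lipids carry no chemistry
beyond positions, masses and charge classes, the receptor has no loops
(ICL3 is absent from the toy bundle, so ICL3 RMSD is exercised only on
inputs that have one), and nothing diffuses.

## Numerical choices and degenerate inputs

Roots and intersections in the generator are solved to ≲1e-10 Å (brentq /
closed-form trilateration); jointly unreachable lock/displacement targets
raise an error instead of being approximated. Thickness cells and g(r)
bins with no data are flagged, not zero-filled (g(r) bins with no pairs
are genuinely zero). PDB coordinates round-trip at the format's 3-decimal
precision. The contact cutoff is a strict inequality (a pair at exactly
4.5 Å does not count). Leaflet ties (anchor exactly on the midplane) go to
the lower leaflet. All randomness flows through explicit integer seeds;
re-running any pipeline configuration reproduces every CSV bit-identically
because frame iteration order and reduction order are fixed.

Test problem sizes (8–32 lipids per leaflet edge, 6–50-frame paths,
10⁴-point g(r) samples over 20 frames) were chosen as the smallest systems
whose ground truth is unambiguous at the asserted tolerances; every
generator scales to larger systems through its spec.

## Known limitations

* The thickness algorithm is a re-specification of the usual
  grid-plus-smoothing approach with concrete defaults (2.0 Å cells, 6.0 Å
  smoothing); other tools' defaults will give comparable, not
  bit-identical, maps.
* g(r) of quasi-2D selections is comparable across systems but its
  absolute scale depends on the whole-box density convention.
* The crystal-structure checks require the published endpoint entries,
  which are not redistributed with the package.
* Only orthorhombic boxes are supported, and solvent is never analysed.
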