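# Methods

## Lattice arithmetic

A Caspar–Klug capsid is indexed by integer steps (h, k) on the
hexagonal lattice (basis vectors 60° apart) joining two nearby
pentamers; its triangulation number is the Diophantine form
T(h, k) = h² + hk + k².  The hexagonal point group (order 12: six
rotations by 60°, generated by (h, k) → (−k, h + k), times the mirror
(h, k) → (k, h)) leaves T invariant; the sector h ≥ k ≥ 0 is a
fundamental domain and is used as the canonical representative
throughout.  (h, k) and (k, h) are mirror images (laevo/dextro
handedness) and are counted as one architecture; a T-number with
several inequivalent canonical representations (first at T = 49 =
T(7,0) = T(5,3)) is one architecture record listing all of them.
Whether an integer is a T-number is decided by exhaustive search over
0 ≤ k ≤ h ≤ ⌈√T⌉ + 1 — at desk scale nothing faster is warranted, and
the exhaustive test is trivially auditable.

### The centered-hexamer criterion

The face of the icosahedron is the triangle spanned by A = (0,0),
B = (h,k) and C = (−k, h+k) (the 60° rotation of B).  Its centroid has
lattice coordinates ((h−k)/3, (h+2k)/3), which are integers iff
h ≡ k (mod 3).  Reducing T = h² + hk + k² modulo 3 over the nine
residue pairs shows h ≡ k (mod 3) ⇔ 3 | T.  Since the global 3-fold
axes pierce the capsid exactly at the 20 face centroids, a hexamer is
centered on a true 3-fold axis iff 3 | T — and then there are exactly
20 such hexamers, two per axis.  For 3 | T the centroid steps
(h_H, k_H) = ((h−k)/3, (h+2k)/3) satisfy 3·T(h_H, k_H) = T.

The inverse transformation used here is
(h, k) = (2h_H + k_H, k_H − h_H), which satisfies
T(2h_H + k_H, k_H − h_H) = 3(h_H² + h_H k_H + k_H²) identically; it is
one of six symmetry-equivalent forms (compose with any point-group
image).  A simpler-looking candidate, (h, k) = (h_H + k_H, k_H − h_H),
is **not** an inverse: it evaluates to h_H² + 3k_H², which equals
3·T(h_H, k_H) only when h_H = 0, and one sometimes sees it quoted from
the special case of an axis-aligned centered hexamer.  The implemented
form is validated two ways in the tests: algebraically (round-trip
with the centroid map for every T ≤ 300) and geometrically (the built
capsid for the tripled step always shows 20 hexamers on the 3-fold
axes).

Split or skew hexamers retain only 2-fold internal symmetry.  A 2-fold
hexamer is compatible with a global 2-fold axis but not with a global
3-fold axis, so a capsid can be tiled entirely with split/skew
hexamers iff it has hexamers and 3 ∤ T.  The package decides
*compatibility*; it does not construct an explicit orientation
assignment of the 2-fold tiles.

## 3-D construction

The scaffold is the regular icosahedron with vertices at the
normalized cyclic permutations of (0, ±1, ±φ), which puts the 15
two-fold axes on the coordinate axes and planes; vertices are sorted
lexicographically, faces wound outward, and the capsid center is the
origin with radius = center-to-vertex distance (default 300, in
arbitrary length units written verbatim to PDB; 300 keeps a ~60 nm
shell inside the fixed PDB field widths).

Each face carries a copy of the lattice triangle A, B, C above.  A
lattice point (i, j) has scaled barycentric coordinates
v = (i(h+k) + jk)/T and w = (hj − ki)/T relative to (A, B, C); the
numerators are integers, so face membership (u, v, w ≥ 0) is an exact
integer test with no inclusion epsilon.  Member points map to
V_A + v(V_B − V_A) + w(V_C − V_A) on the flat 3-D face.  The capsid is
kept faceted rather than projected to a sphere: on flat faces every
symmetry coincidence is exact up to floating rounding (≤ 1e−12
relative), which is what lets a distance threshold separate "on axis"
from "off axis" cleanly.

Sites shared between faces (edge and corner points) are merged with a
grid spatial hash at 1e−9 edge lengths — far above accumulated
rounding (~1e−15) and far below the minimum intersite distance
(~radius/√T).  The merged counts must come out at exactly 12 pentamers
(face corners, i.e. icosahedron vertices) and 10(T − 1) hexamers;
violation raises rather than warns.  Handedness: laevo (default) is
the (h, k) wrapping with faces wound counter-clockwise seen from
outside; dextro mirrors the final coordinates through the yz-plane,
which maps the vertex set of this icosahedron to itself, so the
scaffold, axes and classification are unchanged while chiral lattices
(h ≠ k, k ≠ 0) become their enantiomers.

### Symmetry classification, two routes

Exact route (assigned at build time from integer predicates): face
corner → pentamer on a 5-fold axis; scaled barycentric (T/3, T/3) →
hexamer on a 3-fold axis (exists iff 3 | T); an edge midpoint
(u, v, w a permutation of (½, ½, 0), a lattice point iff h and k are
both even) → hexamer on a 2-fold axis (exactly 30 when present);
anything else → general position (orbit size 60).

Geometric route: the 31 axes (6 five-fold through vertex pairs, 10
three-fold through opposite face centroids, 15 two-fold through
opposite edge midpoints) are recomputed from the polyhedron, and each
site is assigned the highest-order axis whose line passes within
tol × radius of it (default tol = 1e−6; genuine off-axis distances are
≥ 1e−2 × radius for T ≤ 300, so the band is six orders of magnitude
wide on either side).  The geometric route never looks at T.  The two
routes are compared site-by-site on every classification call;
disagreement raises `ClassificationMismatchError`.  `tol ≤ 0` is
rejected.

The survey builds every distinct T ≤ t_max (default 52, the range
observed for HK97-fold shells; the verification command extends to 300
in seconds) and reports, per T: both centered-hexamer verdicts, the
counts on 3-fold and 2-fold axes, and all-skew compatibility.  T = 1
appears as a row but is excluded from both summary counts because it
has no hexamers to be compatible or incompatible.

### Facet mesh

For export and rendering, each face's sites are triangulated by a
Delaunay triangulation *in the integer (v·T, w·T) coordinates* — all
orientation determinants are exact in double precision at these
magnitudes, so points collinear on face edges are handled without
epsilons and both faces sharing an edge subdivide it at the same
points — then glued through the same coincidence hash and wound
outward.  The result must be a closed surface (Euler characteristic
2); the tests cross-check watertightness and winding with trimesh.

## Stoichiometry and packing

A complete capsid has 60T MCPs = 5·12 + 6·10(T−1).  With
`portal=True` one pentameric vertex is occupied by the portal complex:
11 pentamers, 60T − 5 MCPs; the portal's own subunits are not MCPs and
are not counted (this convention reproduces the observed 415 MCPs of a
T = 7 phage capsid).  Accessory proteins are parameterized as copies
per hexamer (default 2, a chasm-bridging dimer; other stoichiometries
exist, hence a parameter rather than a constant) and bind hexamers
only.  Minor-protein trimer placement is out of scope: no lattice rule
determines those copy numbers from T alone.

Genome packing density is bp/nm³ over a spherical internal volume of
the stated internal diameter — a single-number model chosen because
capsid interiors are reported by one diameter; no faceting correction
is applied, so absolute densities are comparative, not volumetric
truth.  The percent change 100·(ρ_a/ρ_b − 1) reduces to the
genome-length ratio at equal diameters; for 70.5 vs 64.5 kb in a
63 nm interior this is +9.30% (densities 0.5385 and 0.4926 bp/nm³).

## Determinism and file formats

There is no randomness anywhere: identical inputs give byte-identical
CSV/JSON/PDB/OBJ/cxc output (fixed float formats, LF endings, no
timestamps), which the tests assert.  PDB is used as a coarse-model
carrier — one HETATM pseudo-atom per capsomer center, chain A, residue
index = site index, element C, occupancy 1.00, symmetry class in the
B-factor (0 pentamer, 1 general hexamer, 2 on a 2-fold, 3 on a
3-fold), conventions documented in REMARK 300 records — written with
gemmi and read back in tests with biotite as an independent parser.
Exit codes: 0 success, 2 invalid input, 3 verification failure, 4 I/O
error.

## Limitations

- All capsids are treated as isometric icosahedra; prolate/elongated
  (Q-number) shells and any axial extension are not modeled.
- Compatibility with all-skew tilings is decided from symmetry alone;
  no explicit skew-orientation field is produced.
- Local (quasi-) 3-fold positions are not classified; "on axis" refers
  to the 31 global axes only, so the centered-hexamer count reported
  for 3 | T is the exact global-axis count of 20.
- No atomic models, maps, or deposited structures are read or written;
  the PDB output is a pseudo-atom coarse model.
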