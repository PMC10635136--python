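# capsidlattice

Caspar–Klug icosahedral capsid lattices: explicit 3-D construction,
symmetry-axis classification of capsomers, and the split/skew-hexamer
compatibility criterion.

## The problem

Icosahedral virus capsids are classified by their triangulation number

    T(h, k) = h² + hk + k²,

where *(h, k)* are the integer steps on a hexagonal lattice joining two
nearby pentamers.  A complete capsid holds 60T major capsid proteins
(MCPs) in 12 pentamers (at the icosahedron vertices) and 10(T − 1)
hexamers.  In tailed bacteriophages the mature hexamers are usually
6-fold symmetric, but capsids built from **split or skew hexamers** —
hexamers retaining only 2-fold symmetry, with an accessory protein
bridging the chasm between the two halves — are geometrically possible
only if no hexamer center has to sit on a global 3-fold axis of the
icosahedron.  This package decides that question constructively:

> A capsid contains a hexamer centered on a true (global) 3-fold axis
> **iff** its T-number is a multiple of three.  Equivalently, a capsid
> can be built entirely from split/skew hexamers iff 3 ∤ T.

The criterion is implemented twice, by design:

1. **Exact lattice arithmetic** (`hexlattice`): the face centroid of
   the Caspar–Klug triangle is itself a lattice point iff h ≡ k
   (mod 3), which is equivalent to 3 | T.  For 3 | T the steps
   *(h_H, k_H)* from a pentamer to the centered hexamer satisfy
   T = 3 · T(h_H, k_H), and the inverse map
   (h, k) = (2h_H + k_H, k_H − h_H) triples any T-number.
2. **Brute-force 3-D geometry** (`capsid_builder` +
   `symmetry_census`): the capsid is actually built — a hexagonal net
   wrapped over the 20 flat faces of an icosahedron with exact rational
   barycentric coordinates — and every capsomer center is tested
   against the 31 global symmetry axes by point-to-line distance.  This
   route never consults the T-number, so it is an independent oracle
   for route 1; any disagreement raises an error.

Intended users: structural virologists and capsid engineers who want
per-T capsomer geometry, symmetry censuses, coarse-grained PDB/OBJ
models, or stoichiometry arithmetic (portal-vertex MCP counts,
accessory-protein copy numbers, genome packing densities) without
touching deposited maps.

## Worked example

Survey every distinct architecture up to T = 52 (the range observed
for HK97-fold shells):

```
$ capsidlattice survey --tmax 52 --csv report.csv
distinct T-numbers <= 52: 21
centered-hexamer capsids: 8 [3, 9, 12, 21, 27, 36, 39, 48]
all-skew-compatible capsids: 12 [4, 7, 13, 16, 19, 25, 28, 31, 37, 43, 49, 52]
```

Of the 20 hexamer-bearing architectures (T = 1 has no hexamers), the 8
with 3 | T require at least one 6-fold/3-fold symmetric hexamer on each
global 3-fold axis — exactly 20 such hexamers, two per axis — while the
other 12 (including the T = 7 typical of tailed phages) can be tiled
entirely with 2-fold hexamers.

Protein bookkeeping for a T = 7 phage whose portal complex replaces one
pentameric vertex, with a chasm-bridging accessory dimer per hexamer:

```
$ capsidlattice counts --t 7 --portal
{
  "T": 7,
  "portal_present": true,
  "mcp_count": 415,
  "pentamer_count": 11,
  "hexamer_count": 60,
  "accessory_per_hexamer": 2,
  "accessory_total": 120
}
```

60·7 = 420 MCPs minus the 5 of the portal vertex leaves 415; the 60
hexamers carry 120 accessory-protein copies.

Export a T = 12 lattice as a coarse model (one HETATM pseudo-atom per
capsomer; B-factor 0 = pentamer, 1 = general hexamer, 2 = on a 2-fold
axis, 3 = on a 3-fold axis) and verify the criterion geometrically far
beyond the surveyed range:

```
$ capsidlattice build --h 2 --k 2 --radius 300 --pdb t12.pdb --obj t12.obj
T=12 capsid: 122 capsomers (12 pentamers, 110 hexamers)
$ capsidlattice verify-theorem --tmax 300
...
all 93 distinct T <= 300 agree with the divisibility-by-three criterion
```

From Python:

```python
from capsidlattice import build_capsid, classify_sites, has_centered_hexamer

capsid = build_capsid((2, 2), radius=300.0)   # T = 12, 122 capsomers
has_centered_hexamer(capsid)                  # True (purely geometric)
sum(1 for c in classify_sites(capsid)
    if c.site.kind == "hexamer" and c.on_axis_order == 3)   # 20
```

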