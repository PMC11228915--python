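# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates.

## Model

A periodic point set is `S = M + Λ`: a motif `M` of `m` points given in
fractional coordinates of a unit cell `U` (basis vectors as matrix rows,
angstroms), repeated over the lattice `Λ` of all integer combinations of
the basis.  The cell is *any* valid description — primitive or not — and no
invariant in this package may depend on which description was chosen.  A
periodic crystal adds per-point chemistry (element, standard atomic weight,
occupancy); following common database practice for geometry-based
comparison, disordered structures (occupancy < 1) are rejected by default
and only kept as full points on explicit request.

## Exact periodic k-nearest neighbours

`knn_distances` must return distances in the **infinite** set; any fixed
cutoff radius or supercell reintroduces the discontinuities the invariants
exist to remove.  Motif translates are generated in growing L∞ shells of
integer lattice coefficients.  After shell `s`, a translate in any later
shell lies at Cartesian distance at least `(s+1)·w` from the home cell's
origin copy, where `w` is the minimal perpendicular width of the cell
(volume / largest facet volume); subtracting the largest Cartesian offset
between home-cell motif points gives a certified lower bound on every
remaining candidate distance.  Expansion stops only when each point's
current k-th smallest distance beats that bound, so the result is exact up
to floating-point rounding (verified against brute-force enumeration over
`[-6, 6]^3` to 1e-9).

Degenerate cells (volume below 1e-12 of the product of basis norms, or
vanishing perpendicular width) are rejected rather than silently looped on.

## PDD canonicalization and the collapse tolerance

Rows of `D(S;k)` are grouped, each group becoming one weighted row (weight
= group size / m, representative = group mean), and rows are sorted
lexicographically — a convenience only, since PDDs are *compared* as
unordered weighted distributions.

The default collapse tolerance is **1e-10 Å** rather than exact float
equality.  Motif points equivalent under symmetry produce rows that agree
only to ~1e-15: the same distance is assembled from differently rounded
coordinate differences.  1e-10 sits four orders of magnitude above that
noise and six below typical coordinate precision in CIFs, so it merges
exactly what symmetry merges and nothing else.  `collapse_tol=0` (bitwise
equality) and larger physical tolerances (single linkage on row-wise L∞)
remain available; near-equal rows at physically meaningful separations are
genuine near-duplicates and are *not* merged by default.

A practical consequence of floating point is that the lexicographic row
order can flip when two rows tie in their leading entries to ~1e-16; tests
therefore compare PDDs with EMD (the metric on unordered rows), never by
row-wise array equality.

## Derived invariants

* `AMD_j` = weighted mean of PDD column `j`; equals the plain mean of
  `d_j(p)` over motif points.  Nondecreasing in `j` by construction.
* `PPC = (Vol(U)/(m·V_n))^(1/n)` with `V_n = π^(n/2)/Γ(n/2+1)`.
* `ADA_j = AMD_j − PPC·j^(1/n)`; `NDA_j = ADA_j / PPC`.  The asymptote
  `AMD_k → PPC·k^(1/n)` is the unique dimensionally consistent curve with
  the correct large-k density limit; the NDA normalization by PPC is the
  only unitless form built from these quantities.  The suite checks the
  limit empirically: |NDA| at k ≈ 400 is well below its small-k head for
  both lattices and random sets (the decay is slow, roughly following
  lattice point-counting fluctuations, so no test demands NDA → 0 tightly).
* `ρ = mass(U)/Vol(U) · 1.66053906660 g·Å³/cm³/u`, `ATM = mass(U)/m`.
  Both intensive; at fixed composition `ρ·PPC³ = ATM/V₃ · const`, tested to
  1e-6 relative across scale families.

## Earth Mover's Distance

EMD between PDDs is the transportation problem: minimize `Σ f_ij·d_ij`
with row/column marginals equal to the two weight vectors, `d_ij` the `L∞`
gap between rows (any `L_p` is configurable).  It is solved with the HiGHS
simplex through `scipy.optimize.linprog`, which returns a vertex optimum —
approximate solvers would break the coincidence axiom (EMD = 0 must hold
exactly on equal PDDs) and the 1e-9 triangle-inequality checks.  One
marginal constraint is dropped to keep the equality system full rank.
Tests cross-check against an independent oracle: since weights from `pdd`
are multiples of `1/m`, each PDD expands into unit-weight rows on a common
denominator and the optimum equals a minimum-cost perfect matching
(`linear_sum_assignment`) divided by that denominator.

AMD vectors are the weight-averaged PDD columns, so by convexity
`max_j |AMD_j(a) − AMD_j(b)| ≤ EMD(PDD_a, PDD_b)`.  The near-duplicate
search uses this gap as its only *pruning* bound; the PPC gap (no proven
relation to EMD) merely pre-sorts the candidate list.  With pruning the
report is provably identical to the full all-vs-all computation, which the
suite confirms directly.

## Synthetic generators

The generators define the conditions every guarantee is tested under:

* random sets — cell lengths uniform in [1, 3] Å, angles in [60, 120]°
  (excluding near-degenerate cells that only slow the oracles), motif of
  `m ≤ 6` points rejection-sampled to ≥ 0.3 Å periodic separation.  These
  emulate the size and point density of small-molecule cells, not chemical
  realizability: no bonding, no composition, no space-group statistics.
* uniform-ball perturbation — each point independently displaced by a
  vector uniform in the ε-ball (radius ∝ U^(1/n)); the exact hypothesis of
  the `2ε` Lipschitz guarantee.
* cell-extension perturbation — motif duplicated into a doubled cell, one
  copy of one atom moved by ε: the minimal construction whose *description*
  changes arbitrarily while the point set moves ≤ ε.
* the square-lattice worked example — integer grid; in even columns only,
  each vertical pair is pushed apart by 0.1.  "Every other pair" is
  realized as alternating columns: that is the only reading under which
  the primitive cell quadruples *and* the PDD has exactly two rows; the
  all-columns reading merely doubles the cell and keeps one orbit.

Passing tests on these generators shows the mathematical guarantees hold
for arbitrary geometry at desk scale; it says nothing about disorder,
hydrogen placement noise, or database-scale throughput.

## CIF dialect

Supported tags: `_cell_length_{a,b,c}`, `_cell_angle_{alpha,beta,gamma}`,
an `_atom_site_` loop with `fract_{x,y,z}`, `type_symbol` and/or `label`,
optional `occupancy`, and either `_symmetry_equiv_pos_as_xyz` or
`_space_group_symop_operation_xyz`.  Low-level document and operator
parsing uses `gemmi`; the policy layer is ours.  A space-group *symbol*
without operators falls back to P1 with a warning — symbol-to-operator
tables are large and error-prone, and nothing downstream needs the group.
Generated positions are merged by single linkage at 1e-3 fractional per
axis (typical CIF coordinate precision is 1e-4 to 1e-5).  The writer emits
P1 with full-precision (`repr`) coordinates so geometry round-trips
bit-exactly.

## Maps

`coordinate_table` is deterministic and order-independent; per-structure
failures are logged and skipped so one bad block cannot kill a batch run.
Rasters use strictly half-open bins `[e_i, e_{i+1})` with out-of-range
records counted, so totals are conserved; the published density cutoff of
4.5 g/cm³ is the default clip constant offered for (ρ, ·) maps.  Rendering
uses log(1 + count) colour by default — a linear scale hides either the
dense core or the sparse tails — and is byte-deterministic for fixed input.

## Problem sizes and parameters

Defaults: `k = 100` for database-style invariant tables (the CLI default);
the guarantee suites run at `k = 10` (Lipschitz, 200 sets × 3 ε values),
`k = 20` (kNN oracle, 50 sets), `k = 5..8` (EMD oracle and invariance, 200
pairs / 100 sets).  These sizes make every suite a property check over
hundreds of independent random instances while keeping a full run in tens
of seconds.  Seeds are fixed in tests and derived from `--seed` in
`scripts/acceptance.py`.

## Known limitations

* Completeness is property-tested, not certified; pathological sets with
  equal PDDs at the tested `k` exist in theory.
* The EMD solver is dense LP — fine for motifs of tens of orbits, not for
  million-row comparisons; no streamed or approximate mode is provided.
* No space-group inference, cell reduction, Wyckoff assignment, or
  reconstruction of a set from its PDD.
* 2D and 3D geometry only (general n works for the geometry types and
  PPC, but CIF I/O and the generators are 2D/3D).
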