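# Methods

`dixpol` reconstructs and measures helical homopolymers of DIX domains from
crystal structures.  DIX domains (~80 residues, ubiquitin-like fold: strands
β1–β5 plus one α-helix) polymerize head-to-tail: strand β4 of one subunit
forms a parallel intermolecular β-bridge with strand β2 of the next.  In a
crystal this polymer is generated by the space-group symmetry, so the
deposited asymmetric unit plus the operators contain everything needed to
rebuild the filament, measure its screw geometry and quantify its
interfaces.  This note records the model, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## Assembly model

A crystal is parsed into chains/residues/atoms with the unit cell and the
space-group operators (gemmi supplies parsing and the operator tables;
closure and screw-composition identities are unit-tested).  Alternate
locations are reduced to the highest-occupancy conformer, ties broken by
altloc label, so all geometry is single-conformer.  Symmetry expansion
places every operator/lattice-translation copy of every chain whose nearest
heavy atom lies within a configurable radius (default 60 Å) of the
asymmetric unit, each copy tagged with its generator `(chain, operator,
lattice shift)`.

A head-to-tail edge between two copies requires main-chain N···O hydrogen
bonds (≤ 3.5 Å) linking the β4 strand of one copy to the β2 strand of the
other, with parallel strand directions.  The canonical β-bridge carries
three such bonds; edges are accepted at two or more.  A weaker tier exists
for robustness: a candidate with a single qualifying bond is accepted only
when it joins two otherwise free filament ends, and never where it would
create a branch.  This hysteresis reflects how filaments with one locally
distorted interface should still be read as one filament; genuinely
ambiguous packing (a copy with two head partners) is a hard error.  Strand
residue ranges come from a small per-protein table (β1, loop β1–β2, β2, β3,
loop β3–β4, β4, β5), YAML-overridable; ranges for the two Ccd1 orthologs
and the synthetic toy subunit ship as defaults.

Maximal paths in the head-to-tail graph are the protofilaments.  Copies of
distinct protofilaments with any heavy-atom pair within 4.5 Å are joined by
inter-filament edges.  Architecture classification looks at the
contact-connected component holding the most subunits (symmetry expansion
legitimately produces distant disconnected repeats of the same filament):
one protofilament alone is *single*; exactly two protofilaments with helix
axes within 10° of parallel and at least two inter-filament edges are
*double*; anything else is *irregular*.  Inter-filament contacts are typed
by the dominant region pairing of their contact atoms: loop β1–β2 against
loop β3–β4 is type I, loop β1–β2 against the β1–β5–β3–β4 sheet is type II.

## Screw geometry

Superposition is Kabsch (SVD with reflection correction); the test suite
checks it against an independent quaternion-eigenvalue solver at 1e-9.  The
transform between consecutive subunits is decomposed into screw form: angle
from the trace, axis from the antisymmetric part (eigen-decomposition near
180°), rise as the translation component along the axis.  The axis is
oriented so the rise is non-negative; the signed twist follows the
right-hand rule, and a filament is called **left-handed** when the twist is
negative — successive subunits advance clockwise viewed down the advance
direction.  Per-protofilament parameters average the rise arithmetically
and the twist circularly (angles wrap); a twist spread beyond 15° raises
"not a regular helix" rather than reporting a meaningless mean.  Derived
quantities are `pitch = rise · 360/|twist|` and `subunits/turn =
360/|twist|`, identities enforced by construction.

Dimer-rotation comparison superposes two head-to-tail dimers on an anchor
subunit (default the tail, which donates the β2–β1–β5 sheet; `head` is
available since published comparisons rarely state their anchor) and
reports the angle of the residual rotation mapping the other subunit of one
dimer onto the other.  Cross-species residue pairing comes from the
sequences module (global alignment, BLOSUM62, gap open −10 / extend −0.5
via Biopython; CA atoms of non-gap columns).

## Interfaces

SASA uses probe-sphere sampling with a deterministic golden-spiral lattice
(default 960 points/atom; radii C 1.70, N 1.55, O 1.52, S 1.80, probe
1.4 Å, fallback 1.70 Å with a warning).  Coordinates are first moved into a
canonical frame built from the molecule's principal axes with third-moment
sign fixing; because the frame is equivariant, the point lattice rotates
with the molecule and SASA is rigid-motion invariant to floating-point
precision (asserted at 1e-9 relative).  Buried surface area of a pair
evaluates parts and complex in one shared frame, so atoms far from the
interface cancel exactly and separated partners give exactly zero.  BSA is
reported as the two-side sum ΔASA_A + ΔASA_B, with per-side values always
carried alongside, because published interface areas are quoted in both
conventions.

Contact typing is heavy-atom and distance-only — the target crystal models
(3.0 and 1.96 Å resolution) carry no hydrogens, so donor/acceptor roles are
assigned from atom identity (backbone N donor / O acceptor, plus a
side-chain role table) and no angular criteria are applied.  Cutoffs:
hydrogen bonds 3.5 Å, salt bridges (Asp/Glu side-chain O vs Lys/Arg/His
side-chain N) 4.0 Å, hydrophobic side-chain C···C 4.5 Å, water-mediated
bridges 3.5 Å per leg with chaining depth 1 by default (depth 2 finds
two-water bridges).  All detectors are verified against exhaustive
all-pairs scans on small toys.

## Synthetic crystals and what they show

The generator emulates the measurement situation, not protein chemistry: a
rigid pseudo-domain (jittered lattice, gyration radius ~8 Å, compressed
along the filament axis to the stacking distance because a subunit's axial
extent cannot exceed its rise) is repeated along an ideal screw at a stated
rise and signed twist, at cylinder radius 18 Å.  Each subunit carries an
idealized β-bridge placed so that exactly three main-chain N···O bonds of
2.9 Å link consecutive subunits.  Double-helical specs add a second
protofilament (default: 180° phase, half-rise axial offset) and plant a
known inter-filament inventory — a type II-style salt bridge (Lys NZ/Asp
OD1, 3.0 Å) toward the nearest partner subunit and a type I-style
hydrophobic pair (Leu CD1/Leu CD1, 4.0 Å) toward the next one up — so an
interior subunit has two typed neighbors with known labels.  Optional
isotropic Gaussian noise (seeded) perturbs every atom.  Fixtures are P1
crystals; when a full cell of subunits rotates by a multiple of 360° the c
edge equals the filament repeat and lattice translation genuinely extends
the filament through the crystallographic code path; incommensurate specs
get a padded cell that simply contains the filament.

The validation grid runs the whole pipeline over rises {5, 11.43, 20} Å,
twists {±30, ±51.43, ±60}°, single and double architecture, and noise σ ∈
{0, 0.2} Å with seeds derived from one base seed: 72 cells, each checked
for architecture, rise and twist against the generator's exact ground
truth.  Noise-free recovery is exact to machine precision; noisy recovery
is required within 3σ/√n (n = consecutive-pair screws averaged), the
standard-error scaling for a mean of noisy rigid-body estimates.  The grid
runs in memory; coordinate files round-trip at the formats' 3-decimal
precision and are tested separately at that tolerance.

Passing this grid demonstrates that the pipeline's geometry, graph assembly
and classification are correct on rigid bodies with known symmetry.  It
does not demonstrate robustness to what real crystals add: conformational
heterogeneity, missing residues and loops, alternate packing contacts of
comparable size to the true interfaces, and solvent structure.  The strand
range table and the two-tier edge acceptance are the knobs a real-data user
should expect to adjust first.

## Defaults worth knowing

| parameter | default | unit | note |
|---|---|---|---|
| expansion radius | 60 | Å | covers ≥1 helical turn at pitch ~145 Å |
| H-bond cutoff | 3.5 | Å | heavy-atom, no angle term |
| salt-bridge cutoff | 4.0 | Å | side-chain O vs N |
| contact / hydrophobic cutoff | 4.5 | Å | van der Waals contact distance |
| min. β-bridge H-bonds | 2 (1 to extend free ends) | – | canonical bridge has 3 |
| SASA points/atom | 960 | – | <0.5 % change on doubling |
| probe radius | 1.4 | Å | water-sized probe |
| twist-spread limit | 15 | ° | "regular helix" guard |
| axis parallelism (double) | 10 | ° | classification |

## Known limitations

* No hydrogen placement or angular hydrogen-bond criteria; inventories on
  real structures will differ from geometry-aware tools at the margins.
* Secondary-structure regions are supplied, not assigned; an incorrect
  strand table silently shifts the site typing.
* Architecture classification assumes at most two zipped protofilaments;
  higher-order bundles come back "irregular".
* The P6₁ / P2₁2₁2₁ code paths are exercised through operator algebra and
  synthetic P1 crystals; no deposited coordinates ship with the package, so
  published values for specific entries are not asserted anywhere.
* Solution-state oligomer behaviour (gel filtration, light scattering) is
  outside the model: the package measures crystal-packing polymers only.
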