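# Methods

This note records the models, conventions, numerical choices and known
limitations behind each stage of the pipeline, in the order the stages run.

## Solvent-accessible surface area

SASA is computed by the Shrake–Rupley construction: each atom's van der
Waals sphere is expanded by the probe radius (default 1.4 Å, a water
molecule), a set of test points is placed on the expanded sphere, and the
accessible area is the fraction of points not contained in any
neighbouring expanded sphere times the expanded-sphere area.

Numerical choices:

- **Quadrature** is a deterministic golden-section spiral lattice
  (default 960 points/atom). There is no RNG, so results are exactly
  reproducible and invariant across runs; they are *not* exactly invariant
  under rotation (the lattice is orientation-fixed), with observed
  rotation sensitivity well under 0.5% at 960 points and under 0.1% at
  5000. Tests that assert rotation invariance use the denser lattice.
- **Radii** are a Bondi-type element set (C 1.70, N 1.55, O 1.52, S 1.80,
  H 1.20, P 1.80, Se 1.90 Å) with a configurable 1.8 Å fallback; the
  fallback can be disabled, in which case unknown elements are an error
  listing the offending atoms.
- **Hydrogens** are parsed and retained in the model but excluded from
  SASA and contacts by default, so files with and without protons give
  consistent areas.
- An independent **Monte-Carlo estimator** samples uniformly on each
  expanded sphere and reports a per-atom binomial standard error. It is
  used as a statistical oracle for the lattice implementation (agreement
  within 3σ) and in tests against the closed-form single-sphere and
  two-sphere (spherical-cap) areas: for equal expanded radii R at centre
  distance d < 2R, each sphere loses a cap of area 2πR(R − d/2).

Relative solvent accessibility is RSA = 100 · area / reference_max. The
default reference is the theoretical per-residue-type maximum of Tien et
al. (2013, Gly-X-Gly); an alternative mode normalises by the maximum
observed area of the same residue type within the structure itself, for
workflows that define exposure relative to the molecule at hand. The
exposure rule is strict: RSA must exceed the threshold (default 20%), so a
residue at exactly 20% is not selected.

## Fv annotation and scan design

Chothia CDR spans are hardcoded from the standard table (H1 26–32,
H2 52–56, H3 95–102, L1 24–34, L2 50–56, L3 89–97) and are overridable.
Residue numbers are taken to be Chothia numbers already (from the input
model or a user-supplied numbering table); automatic sequence→scheme
renumbering is out of scope because mature external tools exist and the
mapping is error-prone to re-derive. Insertion-coded residues (e.g. H52A)
belong to their parent number's span. Everything outside the six CDRs is
framework (FW_H / FW_L).

Scan design selects solvent-exposed residues over all CDR loops plus a
configurable number of framework residues flanking each loop (default 2
per side — framework positions immediately adjacent to CDRs frequently
contribute to binding). Alanine, glycine and proline positions are
excluded from proposals: alanine self-mutation is uninformative, and G/P
substitutions confound binding effects with backbone structure.

CDR net charge counts D/E as −1 and K/R as +1; histidine's charge is a
parameter (default 0, i.e. neutral at assay pH). The polar/charged residue
set used for composition statistics is {D,E,K,R,H,N,Q,S,T,Y,W,C} and is
recorded in the module because published percentages rarely state their
set.

## Binding curves and fold changes

Indirect-ELISA titrations are fitted with the four-parameter logistic
A450(x) = bottom + (top − bottom)/(1 + (EC50/x)^hill); the EC50 serves as
an apparent K<sub>d</sub>. This is a pragmatic proxy: a bivalent antibody
on a coated plate has avidity, so EC50 ratios are interpreted as fold
changes in apparent affinity, not intrinsic site K<sub>d</sub>.

Fitting uses least squares with heuristic initialisation (bottom = min
signal, top = max signal, hill = 1, EC50 = concentration nearest the
half-range signal) and hill bounded to [0.2, 5]. A fit is declared
unconverged when the optimiser fails, the fitted amplitude is below 0.1
A450 (flat curve — no measurable binding), or the EC50 exceeds 10× the top
tested concentration (the midpoint is not bracketed by the design). Fold
changes from unconverged mutant fits are right-censored and reported as
">bound" (default bound 100), never as a number.

Fold-decrease bins follow the asterisk convention: none [1, 2), \* [2, 10],
\*\* (10, 100], \*\*\* (>100 or censored). The low edge of each bin is
inclusive, matching "2 to tenfold" phrasing; improvements (fold < 1) fall
in the none bin. Replicates are pooled into one fit by default, with the
replicate id retained on the curve.

For two-point spot ELISAs the fold is the wild-type/mutant signal ratio at
a single concentration; when two spot concentrations are available the
higher one is used by default (the low-concentration point is noisier),
selectable in config.

Restraint scenarios are built as one scenario per epitope hotspot group
plus their union, with the paratope restraint set held constant; grouping
lets geometrically distinct epitope patches (e.g. patches facing different
receptor domains) be tested separately and jointly. Export is a
deterministic plain-text active-residue list.

## Interface analysis

A residue is at the interface when its SASA in the isolated binding
partner exceeds its SASA in the complex by at least 0.1 Å² (the threshold
suppresses quadrature noise). Buried surface area uses the PISA half-sum
convention, BSA = (SASA_antigen + SASA_antibody − SASA_complex)/2, so
values are comparable to PISA "interface area" numbers.

Region percentages partition the **antibody-side** buried area across the
six CDRs and framework, so %CDR + %FWR = 100 by construction; a config
switch normalises by both sides instead. Antigen sub-domain labels
(strand/hairpin names) are user-supplied interval annotations, not
computed secondary structure.

Atom contacts across the interface are typed geometrically with a fixed
precedence — salt bridge (opposite formal charges within 4.0 Å) >
hydrogen bond (donor/acceptor within 3.5 Å) > attractive charge (opposite
charges within 5.6 Å) > nonpolar (C–C within 4.5 Å) — using standard
donor/acceptor/charged-atom dictionaries for the twenty amino acids.
π-system interactions (e.g. π-anion) are folded into the attractive-charge
class; ring-centroid geometry is deliberately out of scope, which is a
typology difference from commercial interaction viewers.

## Pose assessment and ranking

Receptor blockage superposes the pose's antigen onto the antigen of a
reference antigen–receptor complex (Kabsch over shared Cα atoms, matched
by residue number + insertion code so differing chain ids are tolerated).
The receptor footprint is the antigen side of the reference interface; the
antibody footprint is the antigen side of the pose interface. The report
carries overlap = |intersection| / |receptor footprint|, the atom-clash
count between the superposed antibody and the receptor (< 2.5 Å), and a
grade (high ≥ 0.5, medium ≥ 0.2, low otherwise — thresholds are config;
the grades discretise what publications describe qualitatively as "strong
blockage"). Only the overlap enters the default grade; clashes are
reported alongside.

Concordance with paratope scanning treats a tested residue as
experimentally positive when its bin is at least \* (configurable) and as
predicted positive when it lies on the antibody side of the pose
interface; the score is balanced agreement 100·(TP+TN)/tested. "Percent
correlation" is not given a formula in the scanning-vs-docking literature
we follow; balanced agreement was chosen because it is symmetric,
bounded, and penalises both missed hotspots and spurious interface
residues. A rank-correlation mode (ΔSASA vs log fold) can be derived from
the per-residue table the report retains.

Ranking is filter-then-lexicographic rather than a weighted composite:
hard filters (BSA > 800 Å² — interfaces below that are rarely native-like;
%CDR within [50, 95] — antibodies bind predominantly but not exclusively
through CDRs; minimum blockage grade for neutralising antibodies) remove
implausible poses with recorded reasons, and survivors are ordered by
(percent correlation desc, blockage desc, binding energy asc, BSA desc,
pose id). Poses lacking a binding energy sort after otherwise-equal poses
that have one. The full sort key of every pose is returned, so a ranking
is auditable and byte-reproducible; permuting the input order cannot
change it. Binding energies (e.g. docking scores) are consumed as input
metadata and never computed here.

## Cross-species analysis

Ortholog pairs are aligned globally with affine gap penalties
(BLOSUM62, open 10, extend 0.5 — standard protein defaults; end gaps are
penalised like internal ones). Identity is computed over aligned non-gap
columns, and that denominator choice is recorded because identity
percentages depend on it. Species differences are reported in reference
(binder-species) numbering; columns where one sequence is gapped are
reported separately, not as substitutions.

Back-mutation proposals restore the reference residue at selected
difference positions. Cumulative combination sets are the prefixes
(length ≥ 2) of a caller-given priority order, mirroring how a rescue
experiment is staged one mutation at a time.

## Synthetic fixtures

The generators exist so every stage is testable against constructed truth
without downloading structures or assay data:

- **Sphere pairs** have closed-form SASA/BSA (the spherical-cap formula)
  and anchor the surface-area code.
- **Mini Fv–antigen complexes** use a pseudo-side-chain representation
  (Cα + one centroid atom per residue) laid out as compact slabs: chosen
  paratope residues sit in a contact plane, antigen contact residues are
  placed directly above them at a set gap (default 4.5 Å), and everything
  else is recessed. The construction *is* the ground truth: the placed
  contact pairs are returned as the expected interface. Toy scale
  (30-residue antigen, 85-residue chains, ~400 atoms) keeps a full
  interface analysis under 0.1 s at 240 lattice points.
- **Pose sets** perturb the reference antibody by small rigid jiggles
  (defaults 0.8 Å, 4°; the compact ~45 Å slab keeps per-atom motion
  small) for near-native poses, and flip the antibody 180° about its own
  centroid — presenting the wrong face at the same stand-off — for
  decoys. Decoys therefore form real but wrong interfaces: framework
  residues contact the antigen, so they lose on scanning concordance and
  usually fail the %CDR filter, which is exactly the discrimination the
  ranking is supposed to make.
- **ELISA panels** generate 4PL curves on a three-fold serial dilution
  (ten points by default, ~4.3 decades) with Gaussian A450 noise
  (σ = 0.02 is used as the standard noise condition in tests); fold truth
  is K<sub>d,mut</sub>/K<sub>d,WT</sub>.
- **Ortholog pairs** plant differences at stated positions. Planted
  differences are kept scattered in the tests: a long contiguous run of
  mismatches can legitimately be aligned as a double gap instead of
  substitutions under affine scoring, which is a property of global
  alignment, not a bug.

Each generator draws from an RNG stream derived from (seed, generator
name), so fixtures for different stages never share randomness and every
output is byte-reproducible from its spec.

What the toys do **not** emulate: real backbone geometry and side-chain
packing, shape complementarity, avidity and plate effects in ELISA, and
real evolutionary substitution patterns. Passing tests therefore
demonstrate that the analysis machinery is correct and internally
consistent, not that any particular biological prediction is right.

## Problem sizes

The default test and acceptance runs use the toy scales above: 20-pose
sets, 20 replicates for the end-to-end recovery study, 50 simulated
curves for the 4PL recovery study, 960–5000 lattice points for
surface-area checks. These sizes were chosen as the smallest at which the
statistical checks (3σ oracle agreement, median-error bounds, ≥95%
recovery) are meaningful.

## Known limitations

- The lattice SASA is orientation-sensitive below ~0.5% at the default
  density; analyses comparing areas across rotated copies of a structure
  should use ≥5000 points.
- Chothia numbering must be supplied; no renumbering.
- Contact typing is distance-only (no angular criteria for hydrogen
  bonds, no ring geometry).
- The 4PL/EC50 K<sub>d</sub> proxy inherits ELISA's avidity effects.
- Blockage grades and the concordance formula are this package's
  conventions (recorded in config/report metadata), chosen to make
  qualitative published criteria reproducible.
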