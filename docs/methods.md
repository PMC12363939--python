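# Methods

This note records the models, conventions, numerical choices, and known
limitations behind each module, in the order data flows through the package.

## Atom-level representation and pipelines

The shared container is a pandas-backed `AtomTable` (atoms + bonds) inside a
`PipelineState` that also carries derived features (`extras`) and the run
seed. Three contracts hold everywhere:

- **Stable identity.** `atom_uid` is a surrogate integer assigned at
  ingestion and never reused after deletion; extras index atoms by uid,
  never by row position, so transforms may delete or reorder atoms freely.
- **Referential integrity.** Deleting atoms always deletes incident bonds;
  a validator (run after every stage when pipelines execute in validate
  mode) asserts uid uniqueness, occupancy ∈ [0,1], finite coordinates for
  resolved atoms, uniqueness of (chain, res_index, atom_name, altloc), and
  zero dangling bond endpoints.
- **Determinism.** One integer seed per run; each transform derives a
  sub-stream as `sha256(seed, transform_name) mod 2^31`. Identical
  (input, config, seed) gives byte-identical outputs across processes,
  which the test suite checks by running the full chain twice in separate
  interpreters.

Residue numbering follows `label_seq_id` (1-based) internally; author
numbering is carried only as far as non-polymer residue indices. Extras-key
collisions between two registered transforms are a configuration error, not
a silent overwrite: precedence rules are easy to get wrong silently, and an
error is recoverable while corrupted features are not.

## Structure I/O

gemmi's CIF reader/writer backs all parsing at the category level. The
supported categories are `atom_site`, `struct_conn`, `entity_poly_seq`,
`chem_comp_atom`, `chem_comp_bond`; everything else is ignored. Polymer
residues present in `entity_poly_seq` but absent from `atom_site` are
appended as placeholder atoms (full non-leaving heavy-atom set when a
component dictionary is supplied, else N/CA/C/O) with NaN coordinates and
`is_resolved = False`, so imputation and disorder extension have slots to
fill. On writing, atoms without coordinates are omitted from `atom_site`
but kept in `entity_poly_seq`, making the unresolved set round-trippable.
Polymer backbone links (C–N, O3′–P between consecutive residues) carry
provenance `inferred` and are not written to `struct_conn`; genuine
covalent links are. PDB format is read-only, with SSBOND/LINK mapped to
struct_conn-style records. Biological-assembly expansion is not performed.

## Sanitization

Canonical order (`sanitize_state`): altlocs → bond attachment → covalent
links → leaving groups → bond-order correction → formal charges → symmetry
ligands → imputation. The order is load-bearing: a peptide bond is satisfied
by losing OXT, not by demoting C=O, so leaving groups must depart before
valences are audited.

Choices worth recording:

- **Altlocs**: keep highest occupancy, tie → lexicographically smallest
  altloc id. Single-conformer training data is the use case; ensemble
  splitting is out of scope.
- **Leaving groups** are removed only at bonded linkage sites (CCD
  semantics); hydrogens riding on a departing heavy atom go with it, and
  leaving-flagged hydrogens at the link atom itself (e.g. a thiol H) are
  removed too.
- **Covalent-link inference** is off by default; `struct_conn` is
  authoritative. When enabled, ligand–polymer heavy-atom pairs bond if
  their distance is below the Cordero single-bond radii sum + 0.4 Å and
  both partners have free valence. `metalc` records become annotations,
  never bonds.
- **Bond-order correction** audits only atoms participating in
  inter-residue links. Excess valence demotes one double bond at the atom,
  preferring C=O, then C=N — the carbonyl is the usual target of
  nucleophilic addition. Excess with no demotable double bond is an error
  by design: it indicates broken upstream chemistry (a covalent
  modification whose departing hydrogen is not flagged as leaving), and
  guessing would hide the bug.
- **Formal charges**: charge = (bond-order sum + implicit H) − nearest
  allowed valence, with implicit hydrogens counted from the component
  template (leaving-flagged ones excluded at link atoms). Unbonded atoms
  (free ions) keep their deposited charge; elements outside the valence
  table raise only when bonded.
- **Symmetry ligands**: non-polymer copies with identical component code,
  mean occupancy ≤ 0.5, and centroids within 1.0 Å collapse to the
  highest-occupancy copy (tie → lowest res_index). Both thresholds are
  parameters.
- **Imputation** places missing heavy atoms by proper-rotation Kabsch
  superposition of ideal coordinates onto ≥ 3 resolved shared atoms;
  residues with fewer are reported and left alone.

All rules are idempotent, and no rule increases the atom count except
imputation.

## Chirality

The signed pyramidal angle θ = arcsin(u₁·(u₂×u₃)/|u₂×u₃|) is rotation- and
translation-invariant and flips sign under reflection; ideal tetrahedral
geometry gives |θ| = arcsin(√(2/3)). The gradient of E = (θ − θ_ideal)² is
implemented analytically (chain rule through the normalized cross product);
tests hold it to 1e−5 relative agreement against a Richardson-extrapolated
central-difference oracle. Plain central differences at h = 1e−4 are not
accurate enough for that tolerance near strongly distorted geometries —
the arcsin curvature grows toward |θ| → π/2 — hence the extrapolated oracle,
and the test restricts sampling to tetrahedral-like geometry (|θ| < 1.3 rad),
where the feature is actually consumed.

Neighbor ranking is one fixed, documented ordering: descending atomic
number, then descending sum of the branch atom's heavy neighbors' atomic
numbers taken from the *component template* (so an internal residue ranks
exactly like a terminal one), then ascending atom name. Branch
*equivalence* — what disqualifies a center as ambiguous — is decided
separately by a depth-2 structural signature, so a name tiebreak never
manufactures chirality out of two genuinely identical branches. This
self-consistent convention is deliberately backend-independent: the feature
writer and the accuracy metric must share one sign convention, and a
convention that switched with the presence of a perception library would
break cross-install determinism. CIP labels (R/S) are *not* reproduced;
for example an L-cysteine ranks its branches differently than CIP does, by
design, so that all L-amino acids share one CA sign.

Mirror augmentation inverts the whole structure (x → −x) with a seeded
Bernoulli draw at the study rate of 2 %; per-center inversion is physically
meaningless for bonded atoms and is not offered. The accuracy metric scores
a center as correct when the predicted sign matches the *reference
structure's* observed sign (not the component ideal's), so D-residues in
the reference are scored correctly; per-molecule percentages are averaged
within clusters and clusters averaged unweighted.

## Distance templating

Templates store all-by-all (or explicitly listed) pairwise distances with a
boolean mask. Adherence is the mean over masked pairs of the fraction of
{0.5, 1, 2, 4} Å thresholds the absolute deviation stays inside — the lDDT
convention, so a ligand-template adherence reads like ligand-only lDDT.
Binning for network consumption is half-open [lo, hi) with the boundary
value in the upper bin; default edges 3.25–50.75 Å in 1.25 Å steps, all
configurable. How a trainer noises or drops template entries is out of
scope here.

## Reference conformers

Conformers are built from the component graph only. Stereo is perceived
from ideal coordinates (AssignStereochemistryFrom3D) before a deterministic
ETKDGv3 embedding with chirality enforcement, then MMFF94 minimization
(UFF when MMFF parameters are missing), energies in kJ/mol (kcal × 4.184).
The minimizer cap is 2000 iterations. The test suite includes a
deliberately mis-annotated twin pair — ethylenediamine neutral vs. both
amines protonated — whose minimized energies must order correctly
(mis-charged higher); only the direction is asserted, since the magnitude
is force-field-specific.

## Metrics

- **lDDT**: reference pairs are heavy-atom pairs in different residues
  within a 15 Å inclusion radius in the reference; per-pair score is the
  fraction of {0.5, 1, 2, 4} Å thresholds matched; per-atom scores are
  pair means and the global score the mean over scored atoms. Equality
  with a brute-force all-pairs implementation is asserted exactly on
  randomized structures. Zero reference pairs raises rather than returning
  NaN, and "no interface" is an explicit error distinct from a 0 score.
  No stereochemistry penalty and no alternative chain-mapping (symmetry)
  correction are applied — a known gap versus benchmark-grade scorers.
- **Backbone RMSD** uses proper-rotation Kabsch superposition (reflections
  excluded), so mirror images of chiral structures score strictly positive.
- **SASA** is Shrake–Rupley with a deterministic golden-spiral point set
  (960 points by default), Bondi/Rowland vdW radii, 1.4 Å probe, heavy
  atoms only; it is implemented in-package and cross-checked against
  biotite's sampler at the few-percent level (the two samplers use
  different point sets). RASA normalizes residue SASA by Tien et al.
  extended Gly-X-Gly maxima, clipped to [0, 1].
- **Clustering**: non-polymers partition by exact component code; polymer
  sequences cluster greedily at ≥ 40 % global-alignment identity
  (Biopython PairwiseAligner; identity = matches / alignment length
  including gaps — the stricter denominator), processing members by
  descending length with ties on id. Reported numbers are unweighted means
  of within-cluster means.

## Disorder extension

The builder fills unresolved backbone atoms with ideal-geometry chains
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.0°, CA–C–N 117.2°,
C–N–CA 121.7°; φ=ψ=ω=180° by default — maximally extended, configurable to
strand values) grown by NeRF placement from the nearest resolved anchor.
Internal gaps and C-terminal tails grow from the N-side anchor; N-terminal
tails grow outward in reverse, with bond lengths/angles role-swapped and
φ/ψ traded, which the dihedral's invariance under order reversal makes
exact. No loop closure onto the far anchor is attempted: the builder exists
to produce realistic *exposure*, not gap-spanning geometry. Carbonyl O is
placed anti to the next nitrogen; side chains ride on the placed backbone
via ideal-coordinate superposition. A placed atom within 2.0 Å of a
resolved heavy atom triggers seeded ±20° φ/ψ perturbation, up to 10
retries, keeping the least-clashing attempt. Resolved coordinates are never
modified and the operation is idempotent.

## Synthetic fixtures

The fixture module generates everything at run time: a mini component
dictionary (ALA/GLY/CYS/SER, water, a 3-stereocenter triol ligand, ethanol,
a methyl ketone, acetate, and the ethylenediamine twins) with CCD-style
leaving flags and ideal coordinates embedded deterministically from seeded
SMILES; toy peptides from the internal-coordinate builder (default
α-helical torsions −57/−47/180) with optional local D-mirroring at CA
(side chain reflected through the N–CA–C plane) and optional unresolved
ranges; and six minimal pathological structures, each constructed so that
exactly one sanitization rule must fire, paired with a machine-readable
expectation.

What the fixtures do *not* emulate — and hence what passing tests do not
show about real data: crystallographic noise and B-factor anisotropy,
genuinely ambiguous altloc networks, nucleic acids, metals with partial
covalency, large proteins with non-trivial cores (fixture RASA contrasts
use helix bundles, not folded domains), and PDB-scale chemical diversity
(the force-field energy comparisons are per-fixture directions, not corpus
medians).

## Problem sizes

Test and acceptance runs use deliberately small problems — peptides of 5–30
residues, ligands under 20 atoms, 50 randomized structures of ≤ 200 atoms
for the lDDT oracle, 10,000 Bernoulli draws for the augmentation rate —
chosen so the full suite completes in well under a minute of CPU while
every assertion remains exact or statistically sharp (the 2 % rate check
uses a 3σ binomial band, σ ≈ 14 counts at n = 10,000).
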