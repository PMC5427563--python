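# Methods

## Scope and structure

`dockppi` implements the analysis stages of a docking-based interactome
pipeline. The stages an external engine would normally perform — monomer
modeling, FFT rigid-body docking, flexible interface refinement,
template-based re-ranking — are out of scope; their *outputs* (structures,
ranked decoys, per-model energy tables) are the package's inputs, and the
`decoys` and `features` modules provide in-repo stand-ins (a naive rigid
sampler and contact-derived surrogate energies) so that every downstream
stage can be exercised and tested without any engine installed. The
surrogates are clearly labeled as such and are never mixed with engine
values in one table.

## Structure model

Only the ATOM/TER/END subset of the PDB format is read. HETATM records,
waters and hydrogens are skipped: docked and refined models rarely carry
consistent hydrogens, so all distance rules operate on heavy atoms.
Residues are keyed by `(chain_id, res_seq)`; insertion codes are rejected
rather than silently renumbered (toy scope), and file-defined numbering is
preserved. Altloc duplicates keep the first occurrence. In a dimer the
*receptor* is the chain with more residues, the *ligand* the other; equal
lengths tie-break on the lexicographically smaller chain id. Role
assignment is therefore symmetric in its arguments.

## Quality metrics

* **Interface (10 Å rule).** A residue is interfacial when at least one of
  its heavy atoms lies within 10 Å of any heavy atom of the partner chain.
  Extraction is KD-tree accelerated and tested identical to the brute-force
  all-pair scan.
* **iRMSD.** The interface is defined on the *reference* complex; the
  metric is the Cα RMSD over the reference ligand's interface residues
  after the least-squares (Kabsch) superposition of the model receptor's Cα
  onto the reference receptor's. Superposition excludes reflections via the
  SVD sign correction; collinear or <3-point inputs error. Which complex
  defines the interface is a genuine design choice; fixing it on the
  reference makes the metric comparable across decoys of one target.
* **PCS.** Residue–residue contacts are heavy-atom pairs within a cutoff;
  the contact cutoff is a parameter with default 5.0 Å (a CAPRI-style
  value — the score's definition does not pin it down). PCS is the MCC of
  model contacts (predicted) against reference contacts (actual) over the
  full receptor × ligand residue-pair universe.
* **MCC convention.** The standard form
  (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0 whenever a
  denominator factor vanishes (e.g. an always-positive predictor).
* **Success rate and failure spectrum.** A target succeeds at threshold t
  when a model of quality ≥ t is ranked within the top k (default 10).
  Otherwise it is a *scoring* failure if such a model exists anywhere in
  the sampled pool (default cap 2,000) or a *sampling* failure if none was
  generated. The three fractions partition the targets at every threshold,
  and the success fraction is non-increasing in the threshold.
* **Acceptance criteria.** Correct models satisfy iRMSD ≤ 2.5 Å and
  PCS ≥ 0.65 when the reference is an experimental structure, and
  iRMSD ≤ 8.5 Å and PCS ≥ 0.30 when it is a computer-generated model.

## Decoy generation

`perturb_native` rotates the ligand about a random axis through its
centroid (axes uniform on the sphere via normalized Gaussian vectors,
seeded) and translates it along a random direction; a pure translation of
d Å yields iRMSD exactly d, which anchors the metric tests.

`naive_rigid_sample` is an exhaustive coarse sampler: a deterministic
quasi-uniform rotation set (Fibonacci-sphere axes × spaced angles) crossed
with a cubic translation grid around the receptor, scored by heavy-atom
pairs in the 4–6 Å contact shell minus `clash_weight` × pairs under 2.5 Å.
Two numerical choices matter:

* The grid is laid out in a **canonical receptor frame** (leading principal
  axis sign-fixed by the third moment; second axis from a smooth
  height-weighted radial moment that stays defined when the minor principal
  axes are degenerate, as for helices; right-handed completion), and the
  ligand is likewise canonicalized. Sampler output is therefore invariant
  under joint rigid transforms of the inputs.
* Integer contact counts tie constantly on a grid, so a small packing term
  (−10⁻⁴ × centroid separation) orders tied poses toward tighter packing;
  remaining exact ties (mirror-symmetric grid points) are ordered
  deterministically by rotation and grid index. Ranks are unique and
  contiguous; scores are non-increasing.

Poses are deduplicated at ligand-Cα RMSD < 1.0 Å.

## Energy features and the classifier

The feature vector has ten named terms (global energy, attractive/repulsive
van der Waals, atomic contact energy, internal energy, hydrogen bonds,
partial electrostatics, disulfide bonds, π-stacking, aliphatic contacts),
read from TSV with strict schema validation. Z-score normalization uses
training-split statistics only, returned for reuse on held-out data, to
avoid leakage; zero-variance columns normalize to zeros with a warning.
Both raw and Z-scored features can feed the classifier (default Z-scored in
documentation; the tables carry whatever the caller provides).

The classifier is a random forest (default 500 trees, seeded,
`min_samples_leaf=10` — vote fractions from fully grown trees are too
granular to rank pairs well, and a modest leaf-size floor smooths the
probability estimates). Cross-validation is stratified k-fold (default 10)
with every example scored exactly once out-of-fold. ROC/AUC use the full
threshold sweep with trapezoidal integration; an exhaustive
positive–negative pair-comparison oracle checks AUC in the tests.

The operating point scans unique score values and keeps the
MCC-maximizing threshold (ties → lowest). The pair decision is *strictly
greater than*: a pair is interacting when any of its top-n ranked models
(default threshold 0.13, default n = 3) exceeds the threshold. Because the
top-(n−1) positive set is a subset of the top-n set, TPR and FPR are
non-decreasing in n.

## Curation rules

Sequence identity is global-alignment identity (BLOSUM62, gap open −11 /
extend −1, end gaps penalized), matches / alignment length × 100 — a
transparent definition in place of word-based heuristic clustering tools.
Dimers with identity ≥ 85% between chains are homodimers (boundary
inclusive), below are heterodimers. Greedy clustering is longest-first at
80% identity against cluster representatives. Interface-redundancy removal
retains dimers greedily in input order, dropping any with interface-overlap
MCC > 0.5 against a retained one. The proteome filter keeps 50–600-residue
sequences (boundaries inclusive) and deduplicates identical sequences; the
interface filter keeps dimers with ≥ 20 interface residues counted over
both chains combined. Ligand-swap negatives draw seeded permutations until
a derangement avoiding known positive pairs is found (~e draws expected).

## Annotation filters

GO-slim mappings are flat TSV (protein, aspect ∈ {CC, BP, MF}, term); no
ontology traversal is performed. A pair passes an aspect when the two
proteins share ≥ 1 term; a pair with an unannotated member is a distinct
outcome governed by policy. The default policy is *drop* and the default
cascade CC → BP: cellular co-localization is a near-necessary condition for
physical interaction, shared biological process is highly sensitive, and MF
is implemented but excluded by default because interacting and
non-interacting pairs pass it at nearly the same rate. With a uniform
policy the cascade is order-independent (an intersection of per-aspect pass
sets); per-stage counts are reported.

## Network analysis

Graphs are undirected and simple; self-pairs are skipped with a count.
Mean degree is 2|E|/|V|; the diameter is computed on the largest connected
component (predicted networks need not be connected); the clustering
coefficient is the mean local (Watts–Strogatz) value with degree<2 nodes
contributing 0, with global transitivity also reported. The null model is
uniform G(n, m) with identical node and edge counts. Reference overlay
labels partition predicted ∪ reference into true positives, positive
predictions and false negatives. Hive-plot grouping bins nodes by degree
(low < 50, medium 50–80 inclusive, high > 80) and orders each axis by
ascending local clustering (ties → node id); rendering is out of scope —
the grouping table is the product.

## Synthetic data

Toy monomers are ideal α-helical Cα+Cβ traces (rise 1.5 Å, 100°/residue,
Cα radius 2.3 Å, Cβ 1.53 Å further out) with random seeded sequences —
biologically naive by design, since the pipeline under test is
geometry-agnostic. Toy dimers pack two helices at the smallest clash-free
axis separation (≥ 2.5 Å heavy-atom clearance) that preserves a ≥ 20-residue
interface.

Class-conditional energy features are asymmetric two-sided exponential
draws around per-term class medians (fair coin for the side, side-specific
exponential scales 0.35/0.45), so the population median equals the
configured value exactly. The discriminatory medians default to
(interacting / non-interacting): attractive vdW −0.230 / 0.214, repulsive
vdW −0.187 / −0.195, hydrogen bond −0.068 / 0.418 on the Z-score scale; the
remaining seven terms carry package-chosen defaults in the same spirit
(e.g. global energy −0.45 / 0.32). Only medians are calibrated and
asserted.

Synthetic GO annotations draw one slim term per aspect per protein from a
skewed distribution whose two-draw collision probability equals the
configured random-pair pass rate (dominant-term mass solved from a
quadratic); interacting pairs are then re-drawn to share (or differ) with
the probability that yields the configured interacting rate. Defaults:
CC 0.82/0.58, BP 0.93/0.35, MF 0.48/0.52 (the BP and MF negative-pair rates
are package choices). Overrides couple pairs that share proteins, which
biases rates slightly at high pair density; the CC calibration is the
asserted one.

The default scenario (seed-controlled) has 20 proteins of 50–120 residues,
15 planted interactions, labeled features for all 190 candidate pairs at 3
models each, decoy sets (including an exact native copy, so every decoy
pair has a model within the relaxed acceptance criteria) for a subset of
pairs, annotations and a ground-truth manifest. Problem sizes throughout
(20-protein scenarios, 10,000-draw calibrations, ≤ 200-node oracle graphs,
4-point superposition oracles) are chosen so the full suite runs in about a
minute while keeping Monte-Carlo tolerances honest.

## What passing tests do and do not show

The synthetic generator produces rigid, idealized, cleanly separated data:
no flexible interfaces, no homology-model noise, no correlated energy
terms, no incomplete or biased annotation coverage beyond the configured
rates, and planted interactions chosen uniformly rather than by biological
module structure. Passing recovery tests therefore demonstrates the
*correctness of the machinery* — metrics, rules, classifier plumbing,
filters, network analysis — not the real-world accuracy of docking-based
interactome prediction, which is bounded by the external engines and data
this package deliberately excludes.

## Known limitations

* PDB subset only; no mmCIF, no multi-model NMR, no insertion codes.
* The naive sampler is a coarse stand-in: no FFT correlation, no
  electrostatics, no flexibility; its poses are only as fine as its grids.
* Surrogate energies are contact counts in disguise; they preserve the
  schema and qualitative ordering (clashes raise repulsion, contacts deepen
  attraction), not physical energy scales.
* Interface-similarity scoring beyond iRMSD/PCS (e.g. alignment-based
  interface scores) is not implemented.
* G(n, m) is the only network null; degree-preserving configuration-model
  nulls are out of scope.
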