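# Methods

This note documents the models, conventions and numerical choices behind
`extpair`, in the order the pipeline applies them.

## Structure model and PDB conventions

The in-memory model keeps only what annotation needs: nucleotide residues
(chain, author number, insertion code, parent base, modified flag) with
named heavy atoms. Parsing is delegated to Biopython; on top of it the
package applies these conventions:

* **Multi-model files** — only the requested model is read (default: the
  first in file order). PDB files do not say which model is "the"
  structure; first-model selection is our convention.
* **Alternate locations** — the highest-occupancy conformer is kept; ties
  prefer altloc `A`, then first occurrence.
* **Modified residues** — a packaged name→parent table (PSU→U, 1MA→A,
  5MC→C, OMG→G, …, extensible via `register_modified_residue`) keeps
  modified nucleotides with `is_modified=True`; unmapped HETATM residues
  are dropped with a logged warning. Sequences render modified residues as
  lowercase parent bases, so downstream filters can exclude them.
* **Atom names** — PDB v2 primed names (`O2*`) are normalized to v3
  (`O2'`). Waters, ions and protein residues are skipped silently.
* **Indexing** — author numbers are preserved for display; all internal
  pair indices are 1-based positions in the concatenation of chains in
  file order, with chain breaks recorded separately. Inter-chain pairs are
  allowed (two-strand motifs need them).

## Base-pair detection

A candidate pair must pass three geometric tests, each with a tunable
cutoff (`AnnotationParams`):

| parameter | default | meaning |
|---|---|---|
| `hbond_min`, `hbond_max` | 2.4, 3.4 Å | closed window for donor–acceptor heavy-atom distance |
| `max_plane_angle` | 65° | acute angle between least-squares base planes |
| `max_stagger` | 2.5 Å | centroid separation along the mean plane normal |
| `neighbor_cutoff` | 15 Å | glycosidic-N distance for candidate enumeration |

H-bonds are heavy-atom only: crystallographic and predicted models rarely
carry hydrogens, so no hydrogen positions or angle terms are used. Only
base-edge atoms participate (the 2′-hydroxyl counts as a sugar-edge atom;
phosphate and other sugar atoms never pair), and a contact requires a
donor on one side and an acceptor on the other according to a fixed
per-base role table. Base planes are least-squares fits (SVD) through the
ring atoms; the stagger test is what rejects stacked neighbours, whose
planes are parallel but offset by one helical rise (~2.8 Å > 2.5 Å).
Published annotators disagree in exactly these thresholds (some are
stricter than others), which is why all of them are config-exposed; the
defaults are not claimed to reproduce any particular external tool.

## Leontis–Westhof classification

Each residue contributes one edge — Watson–Crick, Hoogsteen or Sugar — and
the pair is labelled *orientation edge/edge* (12 distinct families: 2
orientations × 6 unordered edge combinations). The edge-atom table is
packaged data (`data/edge_atoms.csv`). Atoms shared between the W-C set
and another edge (e.g. G O6, A N6, pyrimidine O2) resolve by partner
context: they count as W-C when the partner atom can itself be W-C,
otherwise as the other edge. A residue's edge is the majority over its
H-bonded atoms; ties go to the edge of the atom in the shortest H-bond.

Orientation is cis iff the |C1′(a)–N(a)–N(b)–C1′(b)| pseudo-dihedral is
≤ 90° (closed on cis), with N the glycosidic nitrogen (N9 purines, N1
pyrimidines). This is a deliberate simplification of the field's
bond-axis-based definition; it is well-behaved whenever neither glycosidic
bond is nearly collinear with the N–N axis. The one classic geometry where
that degeneracy bites is discussed under *Synthetic fixtures* below.

A pair is **canonical** iff it is cis W-C/W-C with base combination AU,
GC or GU. Saenger classes are looked up in packaged data
(`data/saenger.csv`: base combination, orientation, edges, required H-bond
atom pairs); a row matches when its required bonds are a subset of the
observed bonds, the most specific row wins, and `UNASSIGNED` is a normal
outcome (many LW families have no Saenger class). The canonical rows
(XIX = G·C W-C, XX = A·U W-C, XXVIII = G·U wobble) and the common
non-canonical ones (XXI, XXII, XXIII, XXIV, XI, VIII, X) follow the
standard literature; the remaining rows are best-effort reconstructions
and are shipped as editable data, not code.

Multiplets are connected components (≥ 2 pairs) of the
pairs-share-a-residue graph.

## From annotation to bracket notation

Dot-bracket needs one partner per residue. Canonical pairs are always
eligible; non-canonical pairs only in *extended* mode and only when they
have ≥ 2 H-bonds (one-H-bond interactions are reported but never
bracketed). Conflicts resolve by canonical flag, then H-bond count, then
smaller span, then lexicographic (i, j); losers and all non-encodable
interactions go to a side list so nothing is lost.

Pseudoknot orders: order 0 is a maximum-cardinality crossing-free subset
(interval DP, ties toward the lexicographically smallest set), recursing
on the remainder. This greedy peel is usually level-minimal but its
tie-break can pin a bad maximum subset (a six-pair counterexample exists
where it needs 4 levels instead of 3), so when the peel uses more than two
levels and the instance is small (≤ 60 pairs) a bounded exact search
(branch-and-bound coloring of the crossing graph) replaces it with a true
minimum layering, with levels relabelled by descending size. Everything is
deterministic.

Formats: dot-bracket uses `()`, `[]`, `{}`, `<>`, then `Aa`–`Zz` for
orders 4–29 (beyond that the writer refuses); the header is FASTA-style
with chain breaks in a `#` comment. BPSEQ is the standard `i base j`
triple. CT is the standard 6 columns; with `annotated=True` a seventh
column carries `LW:<family>;Saenger:<class>` on non-canonical bracketed
pairs — this column is this package's dialect, and plain 6-column CT is
emitted by default so downstream tools stay compatible.

## Evaluation

Pairs match by identical (i, j) indices only; base identity is not
re-checked. Multiplet members are excluded before matching because
bracket notation cannot represent them. Variants: I all pairs, II
canonical only, III non-canonical ignoring classification, IV
non-canonical requiring LW equality on matched pairs (a matched but
misclassified pair is a false positive; false negatives are the reference
non-canonical pairs left unpredicted — note that published tables are not
always internally consistent about this denominator, and this package
follows the stated rule). MCC is reported as sqrt(PPV×TPR), the TN-free
approximation standard for base-pair comparison; an exact TN-based MCC is
deliberately not offered. Zero denominators give 0.0 with an
`undefined` flag (the analogue of an n/a table cell). Reported numbers
round half-up to 2 decimals; full precision is kept internally.

## Synthetic fixtures

The generators produce ground-truth structures for testing and for the
acceptance script. They model exactly the atoms the pipeline uses — base
ring and exocyclic atoms, C1′, and a rigid 2′-OH placed off C1′ — with
standard planar base geometries; there is no backbone, sugar pucker, or
thermal model. Helices use canonical A-RNA parameters (twist 32.7°/bp,
rise 2.81 Å/bp); G·U steps are sheared into wobble geometry so the
O6···N3/N1···O2 bonds form. Hairpin loops are stacked above the stem
unpaired; extended strands space bases 10 Å apart so no contacts exist.

Non-canonical **pair templates** are built at first use by a deterministic
in-plane rigid-body fit of the partner base to declared H-bond targets,
penalizing spurious polar contacts (< 3.7 Å), steric overlap (< 3.0 Å),
wrong cis/trans side, and dihedral ill-conditioning; every template is
then verified by running the annotator on its own rendering (declared LW
family and exact H-bond set must come back). Eight templates ship: the
three canonical cis W-C/W-C geometries (G–C, A–U, G·U wobble), reverse
Hoogsteen U·A (trans W-C/Hoogsteen, Saenger XXIV), reverse W-C G·C (trans
W-C/W-C, XXII), cis W-C/Sugar A·G, and two Sugar/Hoogsteen realizations
(trans G·G via N2–N7/O2′–O6 and cis G·A via O2′–N7/N3–N6). The classic
sheared G·A bond set (N2–N7, N3–N6) is deliberately not shipped as a
template: its clash-free planar placement leaves the adenine glycosidic
bond collinear with the N9–N9 axis, exactly where the dihedral-based
cis/trans measure is degenerate, so small coordinate noise flips its
orientation label — an instructive limitation of the simplified
orientation convention rather than of the geometry.

`perturb` adds isotropic Gaussian coordinate noise (seeded NumPy
generator). At σ = 0.1 Å every shipped template's LW family is recovered
in ≥ 95 of 100 replicates; the loss mechanism at this noise level is
almost entirely a designated H-bond drifting past the 3.4 Å cutoff, which
usually leaves the family vote unchanged.

**What passing these tests shows — and what it does not.** The fixtures
demonstrate that the geometric classifier is self-consistent, stable under
small coordinate noise, and exact on idealized helices. Real
crystallographic structures have propeller twist, buckle, non-ideal
H-bond geometry, modified residues and genuine ambiguity between
annotation tools; performance there depends on the cutoffs above and is
not certified by the synthetic suite.

## Problem sizes in the test and acceptance runs

Chosen as comfortable working points for the properties being checked:
duplexes span 2–20 bp (all four bases, random sequences); template
recovery uses 100 seeded replicates per template at σ = 0.1 Å; dot-bracket
round trips run on 1000 random structures of 8–40 nt with ≤ 4 pseudoknot
orders; layering minimality is checked on 500 random sets of ≤ 8 pairs
against an exhaustive coloring oracle; self-evaluation uses 25–30 random
labelled structures. The benchmark-arithmetic checks (subset percentages,
the 1088-structure bookkeeping, the MCC identity) take published counts as
inputs and verify the package's arithmetic against the published outputs.

## Known limitations

* No stacking, base–phosphate or base–ribose annotation; no protonated,
  bifurcated or "near-LW" fuzzy classes; no water-mediated pairs.
* mmCIF is not read; assemblies are not expanded; no structure repair.
* The cis/trans dihedral convention degenerates for pairs whose glycosidic
  bond lies along the inter-glycosidic-nitrogen axis (see above).
* The Saenger table beyond the commonly cited classes is reference data of
  best-effort provenance; lookups there should be treated as indicative.
* Minimum-layer search falls back to the greedy peel above 60 pairs or
  when its node budget is exhausted, so very large pseudoknotted systems
  may receive one extra level.
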