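# extpair

**Extended RNA secondary structure from atom coordinates.**

Classical secondary-structure formats record only canonical base pairs
(Watson–Crick A–U and G–C, and the G·U wobble). Real RNA folds are held
together just as much by *non-canonical* pairs — interactions through the
Hoogsteen and sugar edges, in cis or trans glycosidic orientation — which
standard dot-bracket output silently drops. `extpair` derives the
**extended** secondary structure directly from 3D atom coordinates: it
detects hydrogen-bonded base pairs geometrically, classifies each one into
the 12 Leontis–Westhof (LW) geometric families and, where applicable, one of
the 28 Saenger classes, finds base triples and higher-order multiplets,
assigns pseudoknot orders, and serializes the result in dot-bracket, BPSEQ
and CT form. A companion evaluation module scores predicted against
reference structures the way structural-bioinformatics benchmarks do.

It is aimed at people who predict or solve RNA 3D structures and want the
full base-pairing content of a model as text, plus a reproducible way of
scoring it.

## What it computes

**Annotation.** A base pair is an H-bonded, roughly coplanar arrangement of
two bases. With no hydrogens present, an H-bond is a donor/acceptor
heavy-atom contact with distance in [2.4, 3.4] Å between base-edge atoms
(the 2′-OH counts as a sugar-edge atom). Candidate pairs must further have
inter-plane angle ≤ 65° and centroid stagger ≤ 2.5 Å along the mean normal
(this rejects stacked bases). The LW family is *orientation × edge₁/edge₂*:
orientation is cis iff the |C1′–N–N–C1′| pseudo-dihedral is ≤ 90°, and each
residue's edge (W-C, Hoogsteen or Sugar) is the majority edge over its
H-bonded atoms. Saenger classes come from a packaged taxonomy keyed by base
combination, LW family and H-bond atom set. Pairs sharing a residue form
multiplets, which dot-bracket cannot represent.

**Layering.** Bracket-encodable pairs get pseudoknot orders such that pairs
within one order never cross; order 0 is a maximum crossing-free subset
(interval dynamic program) and the remainder recurses, with an exact
minimum-coloring fallback so the number of levels is minimal.

**Evaluation.** Predicted vs reference pair sets are compared by index
under four variants — I: all pairs; II: canonical only; III: non-canonical
only, classification ignored; IV: non-canonical with the LW family required
to match. Scores are

    PPV = TP/(TP+FP),   TPR = TP/(TP+FN),   MCC = sqrt(PPV × TPR)

the TN-free MCC form standard for base-pair prediction. Dataset summaries
aggregate per-structure variant-III counts into per-subset percentages.

## Worked example

```python
from extpair import annotate, build_secondary_structure, write_dotbracket
from extpair import hairpin, plant_pair, get_template, write_pair_list

# a GCG-stem hairpin with a GUGA loop, a 4-nt tail, and one planted
# non-canonical reverse-Hoogsteen U.A pair bridging loop and tail
model = hairpin("GCG", "GUGA", tail_seq="CCAC")
model = plant_pair(model, 5, 13, get_template("trans-WC-Hoogsteen-UA"))

result = annotate(model)
print(write_pair_list(result))
ss = build_secondary_structure(model, result, extended=True)
print(write_dotbracket(ss))
```

prints

```
A.1 G - A.10 C  cis W-C/W-C  Saenger:XIX  hbonds:3  multiplet:-
A.2 C - A.9 G  cis W-C/W-C  Saenger:XIX  hbonds:3  multiplet:-
A.3 G - A.8 C  cis W-C/W-C  Saenger:XIX  hbonds:3  multiplet:-
A.5 U - A.13 A  trans W-C/Hoogsteen  Saenger:XXIV  hbonds:2  multiplet:-

>hairpin
GCGGUGACGCCCAC
(((.[..)))..].
```

The three stem pairs are canonical G–C (Saenger XIX, three H-bonds each);
the planted U5·A13 pair is recovered as trans W-C/Hoogsteen (reverse
Hoogsteen, Saenger XXIV, two H-bonds). Because it crosses the stem it is a
pseudoknot and gets the second bracket alphabet `[ ]`.

The same pipeline is available from the shell:

```bash
extpair fixtures --kind duplex --seq GGCC --out duplex.pdb
extpair annotate duplex.pdb --formats dbn,ct,list --out-dir out/
extpair evaluate out/duplex.dbn reference.dbn --variant III
```

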