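"""Readers and writers for dot-bracket, BPSEQ, CT and the annotated pair list.

Dot-bracket uses one symbol pair per pseudoknot order: ``()``, ``[]``,
``{}``, ``<>``, then ``Aa`` .. ``Zz`` for orders 4-29.  The CT writer can
emit a seventh column carrying LW/Saenger classification for non-canonical
bracketed pairs; with ``annotated=False`` it emits the plain 6-column CT
that downstream tools expect.
"""

from __future__ import annotations

import re

from .basepair_annotation import (
    AnnotationResult,
    Edge,
    LWFamily,
    Orientation,
    UNASSIGNED,
)
from .errors import FormatError
from .secondary_structure import (
    PairedPosition,
    SecondaryStructure,
    assign_orders,
)

#: Opening/closing symbol pairs by pseudoknot order.
BRACKET_PAIRS: tuple[tuple[str, str], ...] = (
    ("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"),
) + tuple((chr(ord("A") + k), chr(ord("a") + k)) for k in range(26))

_OPEN = {o: k for k, (o, _) in enumerate(BRACKET_PAIRS)}
_CLOSE = {c: k for k, (_, c) in enumerate(BRACKET_PAIRS)}

CANONICAL_COMBOS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def _infer_canonical(sequence: str, i: int, j: int) -> bool:
    combo = (sequence[i - 1] + sequence[j - 1]).upper()
    return combo in CANONICAL_COMBOS


def lw_to_string(lw: LWFamily | None) -> str:
    return str(lw) if lw is not None else "UNCLASSIFIED"


_LW_RE = re.compile(r"^(cis|trans) (W-C|Hoogsteen|Sugar)/(W-C|Hoogsteen|Sugar)$")


def lw_from_string(text: str) -> LWFamily | None:
    m = _LW_RE.match(text.strip())
    if not m:
        return None
    return LWFamily(Orientation(m.group(1)), Edge(m.group(2)), Edge(m.group(3)))


# ---------------------------------------------------------------------------
# dot-bracket

def write_dotbracket(ss: SecondaryStructure) -> str:
    """Three lines: ``>`` header, sequence, structure string."""
    if ss.n_orders() > len(BRACKET_PAIRS):
        raise FormatError(
            f"bracket alphabet exhausted: {ss.n_orders()} orders, "
            f"{len(BRACKET_PAIRS)} available"
        )
    header = ">" + (ss.source_id or "structure")
    if ss.chain_breaks:
        header += " # chain_breaks=" + ",".join(map(str, ss.chain_breaks))
    struct = ["."] * ss.length
    for p in ss.paired:
        opener, closer = BRACKET_PAIRS[p.order]
        struct[p.i - 1] = opener
        struct[p.j - 1] = closer
    return "\n".join((header, ss.sequence, "".join(struct))) + "\n"


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Decode a dot-bracket record (pairs and orders, no classification).

    Canonical flags are inferred from the sequence (AU/GC/GU combos).
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    source_id = ""
    breaks: list[int] = []
    if lines and lines[0].startswith(">"):
        header = lines.pop(0)[1:].strip()
        if "# chain_breaks=" in header:
            header, _, brk = header.partition("# chain_breaks=")
            breaks = [int(x) for x in brk.split(",") if x.strip()]
        source_id = header.strip()
    if len(lines) < 2:
        raise FormatError("expected a sequence line and a structure line")
    sequence, structure = lines[0].strip(), lines[1].strip()
    if len(sequence) != len(structure):
        raise FormatError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    stacks: dict[int, list[int]] = {}
    pairs: list[tuple[int, int, int]] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            order = _CLOSE[ch]
            if not stacks.get(order):
                raise FormatError(f"unbalanced {ch!r}", position=pos)
            i = stacks[order].pop()
            pairs.append((i, pos, order))
        else:
            raise FormatError(f"unknown structure symbol {ch!r}", position=pos)
    for order, stack in stacks.items():
        if stack:
            raise FormatError(
                f"unbalanced {BRACKET_PAIRS[order][0]!r}", position=stack[-1]
            )
    paired = [
        PairedPosition(i=i, j=j, order=order,
                       canonical=_infer_canonical(sequence, i, j),
                       lw=None, saenger=UNASSIGNED)
        for i, j, order in sorted(pairs)
    ]
    return SecondaryStructure(sequence=sequence, paired=paired,
                              chain_breaks=breaks, source_id=source_id)


# ---------------------------------------------------------------------------
# BPSEQ

def write_bpseq(ss: SecondaryStructure) -> str:
    """One line per position: ``i base j`` with j=0 when unpaired."""
    partner = ss.pair_map()
    lines = [
        f"{i} {ss.sequence[i - 1]} {partner.get(i, 0)}"
        for i in range(1, ss.length + 1)
    ]
    return "\n".join(lines) + "\n"


def parse_bpseq(text: str) -> SecondaryStructure:
    entries: list[tuple[int, str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise FormatError(f"expected 'i base j', got {line!r}", position=lineno)
        try:
            entries.append((int(fields[0]), fields[1], int(fields[2])))
        except ValueError:
            raise FormatError(f"non-integer index in {line!r}", position=lineno) from None
    entries.sort()
    sequence = "".join(base for _, base, _ in entries)
    index_ok = all(i == k for k, (i, _, _) in enumerate(entries, start=1))
    if not index_ok:
        raise FormatError("BPSEQ indices are not 1..N")
    pair_set: set[tuple[int, int]] = set()
    for i, _, j in entries:
        if j:
            pair_set.add((min(i, j), max(i, j)))
    orders = assign_orders(sorted(pair_set))
    paired = [
        PairedPosition(i=i, j=j, order=orders[(i, j)],
                       canonical=_infer_canonical(sequence, i, j),
                       lw=None, saenger=UNASSIGNED)
        for i, j in sorted(pair_set)
    ]
    return SecondaryStructure(sequence=sequence, paired=paired)


# ---------------------------------------------------------------------------
# CT

def write_ct(ss: SecondaryStructure, annotated: bool = False) -> str:
    """Connectivity table; optional 7th classification column.

    Columns: index, base, previous, next, partner, author index.  The
    previous/next links are 0 across chain breaks and at the termini.
    When ``annotated`` is set, non-canonical bracketed pairs carry
    ``LW:<family>;Saenger:<class>`` in a 7th column, others ``-``.
    """
    partner = ss.pair_map()
    notes: dict[int, str] = {}
    if annotated:
        for p in ss.paired:
            if not p.canonical:
                note = f"LW:{lw_to_string(p.lw)};Saenger:{p.saenger}"
                notes[p.i] = notes[p.j] = note
    break_after = set(ss.chain_breaks)
    lines = [f"{ss.length} {ss.source_id or 'structure'}"]
    for i in range(1, ss.length + 1):
        prev = 0 if (i == 1 or (i - 1) in break_after) else i - 1
        nxt = 0 if (i == ss.length or i in break_after) else i + 1
        row = (f"{i:>5} {ss.sequence[i - 1]} {prev:>5} {nxt:>5} "
               f"{partner.get(i, 0):>5} {i:>5}")
        if annotated:
            row += f" {notes.get(i, '-')}"
        lines.append(row)
    return "\n".join(lines) + "\n"


def parse_ct(text: str) -> SecondaryStructure:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT input")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise FormatError("CT header must start with the position count") from None
    if len(lines) - 1 < n:
        raise FormatError(f"CT header declares {n} positions, found {len(lines) - 1}")
    sequence: list[str] = []
    pair_set: set[tuple[int, int]] = set()
    lw_notes: dict[tuple[int, int], tuple[LWFamily | None, str]] = {}
    breaks: list[int] = []
    for k, line in enumerate(lines[1:n + 1], start=1):
        fields = line.split(maxsplit=6)
        if len(fields) < 6:
            raise FormatError(f"CT row needs 6 columns, got {line!r}", position=k)
        i, base, _prev, nxt, j = (int(fields[0]), fields[1], int(fields[2]),
                                  int(fields[3]), int(fields[4]))
        if i != k:
            raise FormatError("CT indices are not sequential", position=k)
        sequence.append(base)
        if nxt == 0 and k != n:
            breaks.append(k)
        if j:
            key = (min(i, j), max(i, j))
            pair_set.add(key)
            if len(fields) == 7 and fields[6] != "-" and i == key[0]:
                lw_txt, _, sae = fields[6].partition(";Saenger:")
                lw = lw_from_string(lw_txt.removeprefix("LW:"))
                lw_notes[key] = (lw, sae or UNASSIGNED)
    seq = "".join(sequence)
    orders = assign_orders(sorted(pair_set))
    paired = []
    for i, j in sorted(pair_set):
        lw, sae = lw_notes.get((i, j), (None, UNASSIGNED))
        paired.append(PairedPosition(
            i=i, j=j, order=orders[(i, j)],
            canonical=_infer_canonical(seq, i, j) and (i, j) not in lw_notes,
            lw=lw, saenger=sae,
        ))
    return SecondaryStructure(sequence=seq, paired=paired, chain_breaks=breaks)


# ---------------------------------------------------------------------------
# annotated pair list

def write_pair_list(annotation: AnnotationResult) -> str:
    """One line per annotated pair, canonical and non-canonical alike."""
    lines = []
    for pair in annotation.pairs:
        lw = pair.lw
        lw_txt = (f"{lw.orientation.value} {lw.edge_5p.value}/{lw.edge_3p.value}"
                  if lw else "UNCLASSIFIED")
        mult = str(pair.multiplet_id) if pair.multiplet_id is not None else "-"
        lines.append(
            f"{pair.res_i.label} {pair.res_i.base_type} - "
            f"{pair.res_j.label} {pair.res_j.base_type}  {lw_txt}  "
            f"Saenger:{pair.saenger}  hbonds:{pair.n_hbonds}  multiplet:{mult}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
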