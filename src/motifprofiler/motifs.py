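"""Core motif data model and input plumbing.

An RNA structural motif here is a loop region of a 3D structure: one
(hairpin), two (internal loop) or three-plus (multi-loop) strand segments
held together by flanking Watson-Crick stems and structured internally by
non-canonical base pairs (Leontis-Westhof classes) and base stackings.

This module holds the Leontis-Westhof base-pair type, stacking categories,
the ``Motif`` container, the line-oriented loop-file dialect, motif-location
string parsing, merging of base-interaction annotation lists from two
annotation sources, and loop extraction from an annotated chain.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "BasePairType",
    "StackingType",
    "Interaction",
    "Motif",
    "MotifLocation",
    "AnnotationRecord",
    "ALL_BP_TYPES",
    "ALL_STK_TYPES",
    "CANONICAL_PAIRS",
    "WOBBLE_PAIRS",
    "parse_location",
    "merge_annotations",
    "extract_loops",
    "read_loop_file",
    "write_loop_file",
    "loop_file_text",
]

_EDGES = ("W", "H", "S")
_ORIENTATIONS = ("cis", "trans")

_BP_RE = re.compile(r"^(cis|trans)-([WHS])/([WHS])$")


@dataclass(frozen=True, order=True)
class BasePairType:
    """A Leontis-Westhof base-pair class.

    ``orientation`` is the glycosidic-bond orientation (cis or trans) and
    ``edge5``/``edge3`` are the interacting edges of the 5' and 3' partner:
    Watson-Crick (W), Hoogsteen (H) or sugar (S).  There are 18 classes
    (2 orientations x 3 x 3 ordered edge combinations).
    """

    orientation: str
    edge5: str
    edge3: str

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS or self.edge5 not in _EDGES or self.edge3 not in _EDGES:
            raise ValueError(f"invalid base-pair type: {self.orientation}-{self.edge5}/{self.edge3}")

    @classmethod
    def from_string(cls, s: str) -> "BasePairType":
        m = _BP_RE.match(s.strip())
        if m is None:
            raise ValueError(f"unrecognized base-pair type token: {s!r}")
        return cls(m.group(1), m.group(2), m.group(3))

    def __str__(self) -> str:
        return f"{self.orientation}-{self.edge5}/{self.edge3}"

    def reverse(self) -> "BasePairType":
        """The same pair read from the other partner: edges swap, e.g.
        trans-H/S becomes trans-S/H."""
        return BasePairType(self.orientation, self.edge3, self.edge5)


ALL_BP_TYPES: tuple[BasePairType, ...] = tuple(
    BasePairType(o, e5, e3) for o in _ORIENTATIONS for e5 in _EDGES for e3 in _EDGES
)

_STK_CATEGORIES = ("upward", "downward", "inward", "outward")
_STK_REVERSE = {"upward": "downward", "downward": "upward", "inward": "inward", "outward": "outward"}


@dataclass(frozen=True, order=True)
class StackingType:
    """Base-stacking category relative to the 5'->3' direction.

    Upward/downward stacks exchange under strand-order reversal; inward and
    outward are symmetric.
    """

    category: str

    def __post_init__(self) -> None:
        if self.category not in _STK_CATEGORIES:
            raise ValueError(f"unrecognized stacking category: {self.category!r}")

    @classmethod
    def from_string(cls, s: str) -> "StackingType":
        return cls(s.strip())

    def __str__(self) -> str:
        return self.category

    def reverse(self) -> "StackingType":
        return StackingType(_STK_REVERSE[self.category])


ALL_STK_TYPES: tuple[StackingType, ...] = tuple(StackingType(c) for c in _STK_CATEGORIES)

# Stems qualifying as loop boundaries: canonical WC pairs and the G-U wobble,
# all cis-W/W.
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
_CIS_WW = BasePairType("cis", "W", "W")


@dataclass(frozen=True)
class Interaction:
    """One base interaction between motif positions ``i < j`` (1-based,
    5'->3', contiguous across segments)."""

    i: int
    j: int
    kind: str  # 'basepair' | 'stacking'
    bp_type: BasePairType | None = None
    stk_type: StackingType | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("basepair", "stacking"):
            raise ValueError(f"unknown interaction kind: {self.kind!r}")
        if not (1 <= self.i < self.j):
            raise ValueError(f"interaction endpoints must satisfy 1 <= i < j, got ({self.i}, {self.j})")
        if self.kind == "basepair" and self.bp_type is None:
            raise ValueError("basepair interaction requires bp_type")
        if self.kind == "stacking" and self.stk_type is None:
            raise ValueError("stacking interaction requires stk_type")

    @property
    def type_str(self) -> str:
        return str(self.bp_type if self.kind == "basepair" else self.stk_type)


@dataclass
class Motif:
    """A single loop instance.

    ``segments`` are residue-label ranges in the source chain (metadata);
    positions used by ``interactions`` are 1-based and contiguous across
    segments.  ``break_points`` mark the last position of each segment, so a
    hairpin has one break point, an internal loop two, a multi-loop three or
    more.
    """

    id: str
    segments: list[tuple[int, int]]
    sequence: str
    interactions: list[Interaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("motif requires at least one segment")
        for a, b in self.segments:
            if a > b:
                raise ValueError(f"segment range {a}-{b} is reversed")
        if sum(b - a + 1 for a, b in self.segments) != len(self.sequence):
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match segment lengths in {self.id}"
            )
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"non-ACGU letters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for it in self.interactions:
            if it.j > n:
                raise ValueError(f"interaction ({it.i},{it.j}) outside motif of length {n}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def segment_lengths(self) -> list[int]:
        return [b - a + 1 for a, b in self.segments]

    @property
    def break_points(self) -> list[int]:
        out, acc = [], 0
        for ln in self.segment_lengths:
            acc += ln
            out.append(acc)
        return out

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def loop_type(self) -> str:
        k = self.n_segments
        return "hairpin" if k == 1 else ("internal" if k == 2 else "multi")


@dataclass(frozen=True)
class MotifLocation:
    """Parsed motif-location string ``PDBID_CHAIN:a-b[_c-d...]``."""

    pdb_id: str
    chain: str
    segments: tuple[tuple[int, int], ...]

    @property
    def id(self) -> str:
        ranges = "_".join(f"{a}-{b}" for a, b in self.segments)
        return f"{self.pdb_id}_{self.chain}:{ranges}"


_LOC_RE = re.compile(r"^([A-Za-z0-9]{4})_([A-Za-z0-9]+):(.+)$")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def parse_location(s: str) -> MotifLocation:
    """Parse a motif-location string such as ``1S72_0:77-81_93-100``."""
    m = _LOC_RE.match(s.strip())
    if m is None:
        raise ValueError(f"malformed motif location {s!r}: expected PDBID_CHAIN:a-b[_c-d...]")
    pdb_id, chain, rest = m.groups()
    segments = []
    for tok in rest.split("_"):
        rm = _RANGE_RE.match(tok)
        if rm is None:
            raise ValueError(f"malformed segment range {tok!r} in location {s!r}")
        a, b = int(rm.group(1)), int(rm.group(2))
        if a > b:
            raise ValueError(f"reversed segment range {tok!r} in location {s!r}")
        segments.append((a, b))
    return MotifLocation(pdb_id, chain, tuple(segments))


# ---------------------------------------------------------------------------
# Annotation records and merging


@dataclass(frozen=True)
class AnnotationRecord:
    """One chain-level base-interaction annotation from FR3D or DSSR.

    ``res5``/``res3`` are residue labels resolvable against the chain
    sequence (here: 1-based positions, as ints or digit strings);
    ``nt5``/``nt3`` are the corresponding nucleotides.
    """

    res5: int | str
    res3: int | str
    kind: str  # 'basepair' | 'stacking'
    type_str: str
    source: str  # 'FR3D' | 'DSSR'
    nt5: str = "N"
    nt3: str = "N"

    def key(self) -> tuple:
        return (str(self.res5), str(self.res3), self.kind)


def merge_annotations(
    a: list[AnnotationRecord],
    b: list[AnnotationRecord],
    freq: dict[tuple[str, str, str], float],
) -> list[AnnotationRecord]:
    """Merge two annotation lists, resolving per-residue-pair conflicts.

    The union of both lists is kept.  When the two sources annotate the same
    residue pair with different interaction types, the type whose
    (nucleotide-pair, type) combination is observed more often across known
    RNA structures -- as given by ``freq`` -- survives.  If neither
    combination is in the table (or the counts tie) the record from the
    first-listed source is kept and a warning is emitted.
    """

    def lookup(r: AnnotationRecord) -> float | None:
        v = freq.get((r.nt5, r.nt3, r.type_str))
        if v is not None:
            return v
        # same physical interaction written from the other partner
        try:
            rev = str(BasePairType.from_string(r.type_str).reverse())
        except ValueError:
            rev = r.type_str
        return freq.get((r.nt3, r.nt5, rev))

    merged: dict[tuple, AnnotationRecord] = {}
    for rec in a:
        merged[rec.key()] = rec
    out_of_table_conflicts = []
    for rec in b:
        k = rec.key()
        prev = merged.get(k)
        if prev is None:
            merged[k] = rec
        elif prev.type_str != rec.type_str:
            fp, fr = lookup(prev), lookup(rec)
            if fp is None or fr is None or fp == fr:
                out_of_table_conflicts.append(k)
                # keep the first-listed source's record
            elif fr > fp:
                merged[k] = rec
        # identical annotations collapse silently
    if out_of_table_conflicts:
        warnings.warn(
            f"{len(out_of_table_conflicts)} annotation conflict(s) could not be resolved "
            f"by the frequency table; kept the first-listed source",
            stacklevel=2,
        )
    return list(merged.values())


# ---------------------------------------------------------------------------
# Loop extraction


def _resolve(label: int | str, n: int) -> int:
    try:
        idx = int(label)
    except (TypeError, ValueError):
        raise ValueError(f"unresolvable residue label {label!r}") from None
    if not 1 <= idx <= n:
        raise ValueError(f"residue label {label!r} outside chain of length {n}")
    return idx


def _qualifying_helices(
    sequence: str, annotations: list[AnnotationRecord]
) -> list[list[tuple[int, int]]]:
    """Find stacked runs of cis-W/W pairs that qualify as loop-bounding stems:
    a run with at least one canonical (A-U / G-C) pair, or at least two
    (necessarily consecutive) G-U wobbles."""
    n = len(sequence)
    ww_pairs = set()
    for rec in annotations:
        if rec.kind != "basepair" or rec.type_str != str(_CIS_WW):
            continue
        i, j = _resolve(rec.res5, n), _resolve(rec.res3, n)
        if i > j:
            i, j = j, i
        nts = (sequence[i - 1], sequence[j - 1])
        if nts in CANONICAL_PAIRS or nts in WOBBLE_PAIRS:
            ww_pairs.add((i, j))

    helices = []
    seen = set()
    for i, j in sorted(ww_pairs):
        if (i, j) in seen:
            continue
        run = [(i, j)]
        seen.add((i, j))
        while (run[-1][0] + 1, run[-1][1] - 1) in ww_pairs:
            nxt = (run[-1][0] + 1, run[-1][1] - 1)
            run.append(nxt)
            seen.add(nxt)
        helices.append(run)

    def qualifies(run: list[tuple[int, int]]) -> bool:
        n_canon = sum(1 for i, j in run if (sequence[i - 1], sequence[j - 1]) in CANONICAL_PAIRS)
        n_wob = sum(1 for i, j in run if (sequence[i - 1], sequence[j - 1]) in WOBBLE_PAIRS)
        return n_canon >= 1 or n_wob >= 2

    helices = [h for h in helices if qualifies(h)]

    # drop pseudoknotted helices (crossing an earlier-starting kept helix)
    kept: list[list[tuple[int, int]]] = []
    for h in helices:
        io, jo = h[0]
        crossing = any(
            (ko < io < lo < jo) or (io < ko < jo < lo) for k in kept for (ko, lo) in [k[0]]
        )
        if not crossing:
            kept.append(h)
    return kept


def extract_loops(
    chain_sequence: str,
    chain_annotations: list[AnnotationRecord],
    chain_id: str = "XXXX_A",
) -> list[Motif]:
    """Cut loop regions out of an annotated chain.

    Loops are delimited by stems satisfying the boundary criterion (one
    canonical pair or two wobble pairs); each extracted motif includes the
    closing pair positions of its bounding stems, its subsequence, and every
    annotated interaction whose two endpoints both fall inside the motif.
    """
    n = len(chain_sequence)
    helices = _qualifying_helices(chain_sequence, chain_annotations)
    if not helices:
        return []
    outer = {h[0]: h for h in helices}

    motifs: list[Motif] = []
    for h in helices:
        ii, ji = h[-1]  # innermost pair closes the loop inside this helix
        # children: qualifying helices whose outer pair is directly nested
        inside = [g for g in helices if ii < g[0][0] < g[0][1] < ji]
        children = []
        for g in inside:
            a, b = g[0]
            if not any(o[0][0] < a < b < o[0][1] for o in inside if o is not g):
                children.append(g)
        children.sort(key=lambda g: g[0][0])

        if not children:
            segments = [(ii, ji)]
        else:
            bounds = [ii] + [p for g in children for p in g[0]] + [ji]
            segments = [(bounds[k], bounds[k + 1]) for k in range(0, len(bounds), 2)]

        motifs.append(_cut_motif(chain_sequence, chain_annotations, segments, chain_id))
    motifs.sort(key=lambda m: m.segments[0][0])
    return motifs


def _cut_motif(
    sequence: str,
    annotations: list[AnnotationRecord],
    segments: list[tuple[int, int]],
    chain_id: str,
) -> Motif:
    n = len(sequence)
    chain_to_local: dict[int, int] = {}
    seq_parts = []
    pos = 0
    for a, b in segments:
        for c in range(a, b + 1):
            pos += 1
            chain_to_local[c] = pos
        seq_parts.append(sequence[a - 1 : b])
    interactions = []
    seen = set()
    for rec in annotations:
        i, j = _resolve(rec.res5, n), _resolve(rec.res3, n)
        if i not in chain_to_local or j not in chain_to_local:
            continue
        li, lj = chain_to_local[i], chain_to_local[j]
        if rec.kind == "basepair":
            t = BasePairType.from_string(rec.type_str)
            if li > lj:
                li, lj, t = lj, li, t.reverse()
            it = Interaction(li, lj, "basepair", bp_type=t)
        else:
            t = StackingType.from_string(rec.type_str)
            if li > lj:
                li, lj, t = lj, li, t.reverse()
            it = Interaction(li, lj, "stacking", stk_type=t)
        if (it.i, it.j, it.kind, it.type_str) not in seen:
            seen.add((it.i, it.j, it.kind, it.type_str))
            interactions.append(it)
    ranges = "_".join(f"{a}-{b}" for a, b in segments)
    return Motif(
        id=f"{chain_id}:{ranges}",
        segments=list(segments),
        sequence="".join(seq_parts),
        interactions=interactions,
    )


# ---------------------------------------------------------------------------
# Loop-file dialect
#
#   >id
#   SEQ <string>
#   SEG <a>-<b>          (one line per segment)
#   BP <i> <j> <cis|trans>-<W|H|S>/<W|H|S>
#   STK <i> <j> <upward|downward|inward|outward>
#
# Indices are 1-based motif positions.  Canonical form orders SEG lines by
# appearance and BP/STK lines by (i, j, type).


def loop_file_text(m: Motif) -> str:
    lines = [f">{m.id}", f"SEQ {m.sequence}"]
    for a, b in m.segments:
        lines.append(f"SEG {a}-{b}")
    bps = sorted(
        (it for it in m.interactions if it.kind == "basepair"),
        key=lambda it: (it.i, it.j, it.type_str),
    )
    stks = sorted(
        (it for it in m.interactions if it.kind == "stacking"),
        key=lambda it: (it.i, it.j, it.type_str),
    )
    for it in bps:
        lines.append(f"BP {it.i} {it.j} {it.type_str}")
    for it in stks:
        lines.append(f"STK {it.i} {it.j} {it.type_str}")
    return "\n".join(lines) + "\n"


def write_loop_file(m: Motif, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(loop_file_text(m))


def read_loop_file(path) -> Motif:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return _parse_loop_text(text, str(path))


def _parse_loop_text(text: str, origin: str) -> Motif:
    motif_id = None
    sequence = None
    segments: list[tuple[int, int]] = []
    interactions: list[Interaction] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].strip()
            continue
        tok = line.split()
        tag = tok[0]
        try:
            if tag == "SEQ":
                sequence = tok[1]
            elif tag == "SEG":
                rm = _RANGE_RE.match(tok[1])
                if rm is None:
                    raise ValueError(f"bad segment range {tok[1]!r}")
                segments.append((int(rm.group(1)), int(rm.group(2))))
            elif tag == "BP":
                interactions.append(
                    Interaction(int(tok[1]), int(tok[2]), "basepair", bp_type=BasePairType.from_string(tok[3]))
                )
            elif tag == "STK":
                interactions.append(
                    Interaction(int(tok[1]), int(tok[2]), "stacking", stk_type=StackingType.from_string(tok[3]))
                )
            else:
                raise ValueError(f"unknown record tag {tag!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{origin}:{ln}: {exc}") from None
    if motif_id is None or sequence is None or not segments:
        raise ValueError(f"{origin}: incomplete loop file (need header, SEQ and SEG lines)")
    return Motif(id=motif_id, segments=segments, sequence=sequence, interactions=interactions)
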