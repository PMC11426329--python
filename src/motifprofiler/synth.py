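"""Deterministic synthetic motif families, chains and profiles.

Every pipeline stage is testable without structure downloads: a
``FamilyTemplate`` holds a consensus loop (segment lengths, sequence, base
pairs, stackings) plus mutation rates, ``sample_family`` draws noisy
instances from it, and ``plant_in_chain`` embeds family members among decoy
loops to exercise the search.  Templates patterned on the kink-turn and
sarcin-ricin internal loops and a GNRA-like hairpin are packaged; they are
test fixtures echoing the families' characteristic interaction sets, not
claims of biological fidelity.

All sampling uses a caller-supplied seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import (
    ALL_BP_TYPES,
    AnnotationRecord,
    BasePairType,
    Interaction,
    Motif,
    StackingType,
)
from .profile import Profile

__all__ = [
    "FamilyTemplate",
    "PlantedChain",
    "KINK_TURN_LIKE",
    "SARCIN_RICIN_LIKE",
    "GNRA_LIKE",
    "TEMPLATES",
    "sample_family",
    "plant_in_chain",
    "chain_from_dotbracket",
    "random_profile",
]

_NTS = "ACGU"


@dataclass(frozen=True)
class FamilyTemplate:
    """Consensus description of a synthetic motif family.

    ``consensus_bps``/``consensus_stks`` use 1-based motif positions over
    the concatenated segments.  Rates are per-position (substitution), per
    base pair (dropout) and per motif (indel) probabilities in [0, 1].
    """

    name: str
    segment_lengths: tuple[int, ...]
    consensus_sequence: str
    consensus_bps: tuple[tuple[int, int, str], ...]
    consensus_stks: tuple[tuple[int, int, str], ...] = ()
    sub_rate: float = 0.0
    bp_dropout: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        L = sum(self.segment_lengths)
        if len(self.consensus_sequence) != L:
            raise ValueError("consensus sequence length must match segment lengths")
        for i, j, _ in self.consensus_bps + self.consensus_stks:
            if not (1 <= i < j <= L):
                raise ValueError(f"consensus interaction ({i},{j}) outside template length {L}")
        for r in (self.sub_rate, self.bp_dropout, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def segments(self) -> list[tuple[int, int]]:
        out, start = [], 1
        for ln in self.segment_lengths:
            out.append((start, start + ln - 1))
            start += ln
        return out


KINK_TURN_LIKE = FamilyTemplate(
    name="kink_turn_like",
    segment_lengths=(7, 5),
    consensus_sequence="GCGAUGC" + "GGAGC",
    consensus_bps=(
        (1, 12, "cis-W/W"),  # flanking C-stem pair
        (7, 8, "cis-W/W"),  # flanking NC-stem pair
        (3, 10, "trans-H/S"),  # tandem sheared G-A
        (4, 9, "trans-S/H"),  # ... and A-G
        (2, 11, "trans-S/S"),  # crossing pair
        (5, 12, "trans-S/S"),  # crossing pair
    ),
    consensus_stks=(
        (2, 3, "upward"),
        (3, 4, "upward"),
        (5, 6, "upward"),
        (8, 9, "upward"),
        (9, 10, "upward"),
        (10, 11, "upward"),
    ),
    sub_rate=0.08,
    bp_dropout=0.15,
    indel_rate=0.15,
)

SARCIN_RICIN_LIKE = FamilyTemplate(
    name="sarcin_ricin_like",
    segment_lengths=(7, 6),
    consensus_sequence="GCUGAGU" + "AUCGGC",
    consensus_bps=(
        (1, 13, "cis-W/W"),
        (7, 8, "cis-W/W"),
        (2, 12, "trans-H/S"),
        (3, 11, "trans-W/H"),
        (4, 10, "cis-H/S"),
        (5, 9, "trans-H/H"),
        (6, 9, "trans-S/H"),
    ),
    consensus_stks=(
        (2, 3, "upward"),
        (3, 4, "upward"),
        (9, 10, "upward"),
        (10, 11, "upward"),
    ),
    sub_rate=0.08,
    bp_dropout=0.15,
    indel_rate=0.15,
)

GNRA_LIKE = FamilyTemplate(
    name="gnra_like",
    segment_lengths=(6,),
    consensus_sequence="GGAAAC",
    consensus_bps=((1, 6, "cis-W/W"), (2, 5, "trans-H/S")),
    consensus_stks=((3, 4, "upward"), (4, 5, "upward")),
    sub_rate=0.10,
    bp_dropout=0.10,
    indel_rate=0.10,
)

TEMPLATES: dict[str, FamilyTemplate] = {
    t.name: t for t in (KINK_TURN_LIKE, SARCIN_RICIN_LIKE, GNRA_LIKE)
}


def _interactions(bps, stks) -> list[Interaction]:
    out = [Interaction(i, j, "basepair", bp_type=BasePairType.from_string(t)) for i, j, t in bps]
    out += [Interaction(i, j, "stacking", stk_type=StackingType.from_string(t)) for i, j, t in stks]
    return out


def sample_family(t: FamilyTemplate, n: int, seed: int = 0) -> list[Motif]:
    """Draw ``n`` independent noisy instances of the template family.

    With all rates zero every instance equals the consensus.  Substitutions
    replace a nucleotide by a uniformly chosen other one; dropout removes a
    consensus base pair; an indel inserts a random nucleotide at, or deletes
    an interaction-free position from, one strand (interaction indices and
    break points are re-mapped accordingly).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        out.append(_sample_one(t, rng, f"{t.name}#{k + 1}"))
    return out


def _sample_one(t: FamilyTemplate, rng: np.random.Generator, motif_id: str) -> Motif:
    seq = list(t.consensus_sequence)
    for p in range(len(seq)):
        if rng.random() < t.sub_rate:
            seq[p] = rng.choice([c for c in _NTS if c != seq[p]])
    bps = [bp for bp in t.consensus_bps if rng.random() >= t.bp_dropout]
    stks = list(t.consensus_stks)
    seg_lengths = list(t.segment_lengths)

    if rng.random() < t.indel_rate:
        used = {p for i, j, _ in bps + stks for p in (i, j)}
        if rng.random() < 0.5:
            free = [p for p in range(1, len(seq) + 1) if p not in used]
            # deletion must leave its segment non-empty
            free = [p for p in free if seg_lengths[_segment_index(seg_lengths, p)] > 1]
            if free:
                d = int(rng.choice(free))
                seg_lengths[_segment_index(seg_lengths, d)] -= 1
                del seq[d - 1]
                bps = [(_shift(i, d), _shift(j, d), y) for i, j, y in bps]
                stks = [(_shift(i, d), _shift(j, d), y) for i, j, y in stks]
        else:
            s = int(rng.integers(1, len(seq) + 1))  # insert after position s-1
            seg_lengths[_segment_index(seg_lengths, s)] += 1
            seq.insert(s - 1, str(rng.choice(list(_NTS))))
            bps = [(i if i < s else i + 1, j if j < s else j + 1, y) for i, j, y in bps]
            stks = [(i if i < s else i + 1, j if j < s else j + 1, y) for i, j, y in stks]

    segments, start = [], 1
    for ln in seg_lengths:
        segments.append((start, start + ln - 1))
        start += ln
    return Motif(
        id=motif_id,
        segments=segments,
        sequence="".join(seq),
        interactions=_interactions(bps, stks),
    )


def _segment_index(seg_lengths: list[int], pos: int) -> int:
    acc = 0
    for k, ln in enumerate(seg_lengths):
        acc += ln
        if pos <= acc:
            return k
    raise IndexError(pos)


def _shift(p: int, deleted: int) -> int:
    return p - 1 if p > deleted else p


@dataclass
class PlantedChain:
    """A chain loop-set with known ground truth: the planted family members'
    ids are logged for recovery checks."""

    loops: list[Motif]
    planted_ids: list[str]


def plant_in_chain(motifs: list[Motif], decoy_count: int, seed: int = 0) -> PlantedChain:
    """Mix the given motifs with random-sequence decoy loops of the same
    junction type (random segment lengths, sparse random base pairs and
    stackings), in a seeded random order."""
    if not motifs:
        raise ValueError("need at least one motif to plant")
    n_seg = motifs[0].n_segments
    if any(m.n_segments != n_seg for m in motifs):
        raise ValueError("planted motifs must share one junction type")
    rng = np.random.default_rng(seed)
    mean_lens = [
        int(round(np.mean([m.segment_lengths[s] for m in motifs]))) for s in range(n_seg)
    ]
    loops = list(motifs)
    for k in range(decoy_count):
        seg_lengths = [max(2, ln + int(rng.integers(-1, 2))) for ln in mean_lens]
        L = sum(seg_lengths)
        seq = "".join(rng.choice(list(_NTS), size=L))
        n_bp = int(rng.integers(1, 4))
        cells = set()
        bps = []
        for _ in range(n_bp):
            i = int(rng.integers(1, L))
            j = int(rng.integers(i + 1, L + 1))
            if (i, j) in cells:
                continue
            cells.add((i, j))
            bps.append((i, j, str(ALL_BP_TYPES[int(rng.integers(len(ALL_BP_TYPES)))])))
        stks = []
        if L > 2:
            i = int(rng.integers(1, L - 1))
            stks.append((i, i + 1, "upward"))
        segments, start = [], 1
        for ln in seg_lengths:
            segments.append((start, start + ln - 1))
            start += ln
        loops.append(
            Motif(
                id=f"DECOY#{k + 1}",
                segments=segments,
                sequence=seq,
                interactions=_interactions(bps, stks),
            )
        )
    order = rng.permutation(len(loops))
    loops = [loops[i] for i in order]
    return PlantedChain(loops=loops, planted_ids=[m.id for m in motifs])


def chain_from_dotbracket(
    db: str, loop_fill: str = "A", source: str = "FR3D"
) -> tuple[str, list[AnnotationRecord]]:
    """Build a chain sequence and its annotation list from a dot-bracket
    string: every bracket pair becomes a canonical G-C cis-W/W annotation,
    unpaired positions are filled with ``loop_fill``."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    seq = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
            seq.append("G")
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {pos}")
            pairs.append((stack.pop(), pos))
            seq.append("C")
        elif ch == ".":
            seq.append(loop_fill)
        else:
            raise ValueError(f"unexpected dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unmatched '('")
    annotations = [
        AnnotationRecord(i, j, "basepair", "cis-W/W", source, nt5=seq[i - 1], nt3=seq[j - 1])
        for i, j in sorted(pairs)
    ]
    return "".join(seq), annotations


def random_profile(rng: np.random.Generator, max_segments: int = 3) -> Profile:
    """A random structurally valid profile (used by round-trip and
    orientation property tests)."""
    n_seg = int(rng.integers(1, max_segments + 1))
    seg_lengths = [int(rng.integers(2, 6)) for _ in range(n_seg)]
    L = sum(seg_lengths)
    mc = int(rng.integers(1, 7))
    symbols = ["A", "C", "G", "U", "-"]
    columns = []
    for _ in range(L):
        k = int(rng.integers(1, min(3, mc) + 1))
        chosen = rng.choice(symbols, size=k, replace=False)
        counts = rng.multinomial(mc - k, np.ones(k) / k) + 1
        columns.append({str(s): int(c) for s, c in zip(chosen, counts)})
    bp: dict[tuple[int, int], dict] = {}
    stk: dict[tuple[int, int], dict] = {}
    for _ in range(int(rng.integers(0, 4))):
        i = int(rng.integers(1, L))
        j = int(rng.integers(i + 1, L + 1))
        t = str(ALL_BP_TYPES[int(rng.integers(len(ALL_BP_TYPES)))])
        pair = f"{rng.choice(list(_NTS))}-{rng.choice(list(_NTS))}"
        bp.setdefault((i, j), {})[(t, pair)] = int(rng.integers(1, mc + 1))
    for _ in range(int(rng.integers(0, 3))):
        i = int(rng.integers(1, L))
        j = int(rng.integers(i + 1, L + 1))
        cat = str(rng.choice(["upward", "downward", "inward", "outward"]))
        stk.setdefault((i, j), {})[cat] = int(rng.integers(1, mc + 1))
    break_points, acc = [], 0
    for ln in seg_lengths:
        acc += ln
        break_points.append(acc)
    return Profile(columns=columns, bp=bp, stk=stk, break_points=break_points, mc=mc)
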