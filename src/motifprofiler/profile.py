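"""The structural profile container and its text (.pfl) representation.

A profile summarizes a group of aligned motif instances position by
position: for every column a count map over nucleotides (plus the gap
symbol ``-``), for every position pair count maps of the observed base
pairs (keyed by LW type and nucleotide pair, counted separately per
nucleotide pair) and of the observed stackings, the break points marking
segment ends, and the motif count MC.  Column counts including gaps always
sum to MC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .motifs import BasePairType, Motif, StackingType

__all__ = ["Profile", "motif_to_profile", "read_pfl", "write_pfl", "pfl_text"]

GAP = "-"

BpCell = dict[tuple[str, str], int]  # (lw-type, "N-N") -> count
StkCell = dict[str, int]  # category -> count
NtColumn = dict[str, int]  # nucleotide or '-' -> count


@dataclass
class Profile:
    columns: list[NtColumn]
    bp: dict[tuple[int, int], BpCell]
    stk: dict[tuple[int, int], StkCell]
    break_points: list[int]
    mc: int
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.columns)

    @property
    def n_segments(self) -> int:
        return len(self.break_points)

    @property
    def segment_bounds(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each segment."""
        out, start = [], 1
        for bp in self.break_points:
            out.append((start, bp))
            start = bp + 1
        return out

    def segment_of(self, pos: int) -> int:
        for k, (a, b) in enumerate(self.segment_bounds):
            if a <= pos <= b:
                return k
        raise IndexError(f"position {pos} outside profile of length {self.length}")

    @property
    def loop_type(self) -> str:
        k = self.n_segments
        return "hairpin" if k == 1 else ("internal" if k == 2 else "multi")

    def validate(self) -> None:
        if self.mc < 1:
            raise ValueError("motif count must be >= 1")
        n = self.length
        if not self.break_points or self.break_points[-1] != n:
            raise ValueError("last break point must equal profile length")
        if any(b <= a for a, b in zip(self.break_points, self.break_points[1:])):
            raise ValueError("break points must be strictly increasing")
        for idx, col in enumerate(self.columns, start=1):
            if sum(col.values()) != self.mc:
                raise ValueError(
                    f"column {idx} counts sum to {sum(col.values())}, expected MC={self.mc}"
                )
            if any(c < 1 for c in col.values()):
                raise ValueError(f"column {idx} has a non-positive count")
        for cells in (self.bp, self.stk):
            for (i, j), cell in cells.items():
                if not (1 <= i < j <= n):
                    raise ValueError(f"interaction cell ({i},{j}) outside profile of length {n}")
                for key, c in cell.items():
                    if not (1 <= c <= self.mc):
                        raise ValueError(f"cell ({i},{j}) entry {key} count {c} outside [1, MC]")

    def structurally_equal(self, other: "Profile") -> bool:
        return (
            self.columns == other.columns
            and self.bp == other.bp
            and self.stk == other.stk
            and self.break_points == other.break_points
            and self.mc == other.mc
        )


def motif_to_profile(m: Motif) -> Profile:
    """Wrap a single motif as a profile: MC = 1, every count 1, one
    nucleotide per column.  Duplicate interaction annotations collapse to a
    single unit count (a warning is emitted)."""
    columns: list[NtColumn] = [{nt: 1} for nt in m.sequence]
    bp: dict[tuple[int, int], BpCell] = {}
    stk: dict[tuple[int, int], StkCell] = {}
    dupes = 0
    for it in m.interactions:
        if it.kind == "basepair":
            pair = f"{m.sequence[it.i - 1]}-{m.sequence[it.j - 1]}"
            cell = bp.setdefault((it.i, it.j), {})
            key = (str(it.bp_type), pair)
        else:
            cell = stk.setdefault((it.i, it.j), {})
            key = str(it.stk_type)
        if key in cell:
            dupes += 1
        else:
            cell[key] = 1
    if dupes:
        warnings.warn(f"{dupes} duplicate interaction(s) in motif {m.id} collapsed", stacklevel=2)
    return Profile(
        columns=columns,
        bp=bp,
        stk=stk,
        break_points=m.break_points,
        mc=1,
        source_ids=[m.id],
    )


# ---------------------------------------------------------------------------
# .pfl text format
#
# Sections in fixed order; entries inside each cell sorted by descending
# frequency, ties broken lexicographically on the entry token.
#
#   #SEQUENCE
#   col 1 G:3,A:2
#   #BASEPAIRS
#   2 10 trans-H/S(G-A):4,cis-W/W(G-C):1
#   #STACKINGS
#   1 2 upward:5
#   #BREAKPOINTS
#   5 12
#   #MOTIFCOUNT
#   5


def _sorted_entries(cell: dict, fmt) -> str:
    items = sorted(cell.items(), key=lambda kv: (-kv[1], fmt(kv[0])))
    return ",".join(f"{fmt(k)}:{v}" for k, v in items)


def pfl_text(p: Profile) -> str:
    lines = ["#SEQUENCE"]
    for idx, col in enumerate(p.columns, start=1):
        lines.append(f"col {idx} " + _sorted_entries(col, str))
    lines.append("#BASEPAIRS")
    for (i, j) in sorted(p.bp):
        lines.append(f"{i} {j} " + _sorted_entries(p.bp[(i, j)], lambda k: f"{k[0]}({k[1]})"))
    lines.append("#STACKINGS")
    for (i, j) in sorted(p.stk):
        lines.append(f"{i} {j} " + _sorted_entries(p.stk[(i, j)], str))
    lines.append("#BREAKPOINTS")
    lines.append(" ".join(str(b) for b in p.break_points))
    lines.append("#MOTIFCOUNT")
    lines.append(str(p.mc))
    return "\n".join(lines) + "\n"


def write_pfl(p: Profile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(pfl_text(p))


_SECTIONS = ("#SEQUENCE", "#BASEPAIRS", "#STACKINGS", "#BREAKPOINTS", "#MOTIFCOUNT")


def read_pfl(path) -> Profile:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return parse_pfl_text(text, origin=str(path))


def parse_pfl_text(text: str, origin: str = "<pfl>") -> Profile:
    section = None
    expected = list(_SECTIONS)
    columns: list[NtColumn] = []
    bp: dict[tuple[int, int], BpCell] = {}
    stk: dict[tuple[int, int], StkCell] = {}
    break_points: list[int] = []
    mc = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if not expected or line != expected[0]:
                raise ValueError(f"{origin}:{ln}: unexpected section header {line!r}")
            section = expected.pop(0)
            continue
        if section == "#SEQUENCE":
            tok = line.split()
            if len(tok) != 3 or tok[0] != "col":
                raise ValueError(f"{origin}:{ln}: malformed sequence-profile line")
            col: NtColumn = {}
            for entry in tok[2].split(","):
                sym, cnt = entry.rsplit(":", 1)
                col[sym] = int(cnt)
            if int(tok[1]) != len(columns) + 1:
                raise ValueError(f"{origin}:{ln}: column index {tok[1]} out of order")
            columns.append(col)
        elif section == "#BASEPAIRS":
            i, j, entries = _parse_cell_line(line, origin, ln)
            cell: BpCell = {}
            for token, cnt in entries:
                if not (token.endswith(")") and "(" in token):
                    raise ValueError(f"{origin}:{ln}: malformed base-pair entry {token!r}")
                lw, pair = token[:-1].split("(", 1)
                BasePairType.from_string(lw)  # validates
                cell[(lw, pair)] = cnt
            bp[(i, j)] = cell
        elif section == "#STACKINGS":
            i, j, entries = _parse_cell_line(line, origin, ln)
            scell: StkCell = {}
            for token, cnt in entries:
                StackingType.from_string(token)  # validates
                scell[token] = cnt
            stk[(i, j)] = scell
        elif section == "#BREAKPOINTS":
            break_points = [int(t) for t in line.split()]
        elif section == "#MOTIFCOUNT":
            mc = int(line)
        else:
            raise ValueError(f"{origin}:{ln}: data before any section header")
    if mc is None:
        raise ValueError(f"{origin}: missing #MOTIFCOUNT section")
    return Profile(columns=columns, bp=bp, stk=stk, break_points=break_points, mc=mc)


def _parse_cell_line(line: str, origin: str, ln: int):
    tok = line.split(None, 2)
    if len(tok) != 3:
        raise ValueError(f"{origin}:{ln}: malformed interaction-profile line")
    entries = []
    for entry in tok[2].split(","):
        token, cnt = entry.rsplit(":", 1)
        entries.append((token, int(cnt)))
    return int(tok[0]), int(tok[1]), entries
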