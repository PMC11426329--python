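"""Scoring model: substitution matrices and weighted profile-cell scores.

Three matrices drive the alignment score: an 18x18 base-pair matrix over
Leontis-Westhof classes (isostericity-derived: geometrically interchangeable
pairs score high), a 4x4 stacking-category matrix, and a 5x5 nucleotide
matrix (A, C, G, U and the gap symbol ``-``).

A profile cell holds several entries with frequencies (counts).  Matching a
cell of profile X against the corresponding cell of profile Y uses the
weighted average

    S = (1/m) * sum_a (1/n) * sum_b  Count(e_b^Y) * M(e_b^Y, e_a^X)

with m distinct entries on the X side and n on the Y side.  By default the
count is normalized by Y's motif count (relative frequency), so profiles of
different sizes compare on the same scale; raw counts are available via a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .motifs import ALL_BP_TYPES, ALL_STK_TYPES, BasePairType, StackingType

__all__ = [
    "ScoringMatrices",
    "load_matrices",
    "load_pair_frequencies",
    "score_bp_cell",
    "score_stk_cell",
    "score_nt_column",
]

NT_LABELS = ("A", "C", "G", "U", "-")


@dataclass
class ScoringMatrices:
    """Lookup tables M(.,.) plus gap penalties.

    ``bp`` is keyed by LW-type string pairs; the optional ``bp_nt``
    refinement, keyed by ((type, nt-pair), (type, nt-pair)), overrides the
    type-level score when present.  All lookups take the Y-side entry first,
    matching the weighted-score formula.
    """

    bp: dict[tuple[str, str], float]
    stk: dict[tuple[str, str], float]
    nt: dict[tuple[str, str], float]
    bp_nt: dict[tuple[tuple[str, str], tuple[str, str]], float] = field(default_factory=dict)
    gap_penalty: float = -2.0

    def bp_score(self, y: tuple[str, str], x: tuple[str, str]) -> float:
        """Score of matching Y-side entry against X-side entry; entries are
        (LW-type string, nt-pair string like 'G-A')."""
        v = self.bp_nt.get((y, x))
        if v is not None:
            return v
        return self.bp[(y[0], x[0])]

    def stk_score(self, y: str, x: str) -> float:
        return self.stk[(y, x)]

    def nt_score(self, y: str, x: str) -> float:
        return self.nt[(y, x)]


def _parse_matrix_tsv(text: str, origin: str) -> dict[tuple[str, str], float]:
    """Parse a labelled TSV grid.  Empty cells are mirrored from the
    transposed cell; a cell empty in both places is an error."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    raw: dict[tuple[str, str], str] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        row = parts[0]
        cells = parts[1:]
        if len(cells) != len(header):
            raise ValueError(f"{origin}: row {row!r} has {len(cells)} cells, expected {len(header)}")
        for col, cell in zip(header, cells):
            raw[(row, col)] = cell.strip()
    out: dict[tuple[str, str], float] = {}
    for (r, c), cell in raw.items():
        if cell != "":
            out[(r, c)] = float(cell)
    for (r, c) in raw:
        if (r, c) not in out:
            mirror = out.get((c, r))
            if mirror is None:
                raise ValueError(f"{origin}: cell ({r}, {c}) missing and no symmetric mirror")
            out[(r, c)] = mirror
    return out


def _read_packaged(name: str) -> str:
    return resources.files("motifprofiler.data").joinpath(name).read_text(encoding="utf-8")


def load_matrices(
    bp_path=None,
    stk_path=None,
    nt_path=None,
    gap_penalty: float = -2.0,
) -> ScoringMatrices:
    """Load scoring matrices from TSV files; ``None`` selects the packaged
    defaults.  Validates completeness against the 18 LW classes, the 4
    stacking categories and the 5 nucleotide symbols."""

    def read(path, default_name):
        if path is None:
            return _parse_matrix_tsv(_read_packaged(default_name), default_name)
        with open(path, encoding="utf-8") as fh:
            return _parse_matrix_tsv(fh.read(), str(path))

    bp = read(bp_path, "bp_matrix.tsv")
    stk = read(stk_path, "stk_matrix.tsv")
    nt = read(nt_path, "nt_matrix.tsv")

    bp_labels = [str(t) for t in ALL_BP_TYPES]
    for a in bp_labels:
        for b in bp_labels:
            if (a, b) not in bp:
                raise ValueError(f"base-pair matrix missing cell ({a}, {b})")
    stk_labels = [str(t) for t in ALL_STK_TYPES]
    for a in stk_labels:
        for b in stk_labels:
            if (a, b) not in stk:
                raise ValueError(f"stacking matrix missing cell ({a}, {b})")
    for a in NT_LABELS:
        for b in NT_LABELS:
            if (a, b) not in nt:
                raise ValueError(f"nucleotide matrix missing cell ({a}, {b})")
    if nt[("-", "-")] != 0.0:
        raise ValueError("nucleotide matrix gap-gap score must be 0")
    return ScoringMatrices(bp=bp, stk=stk, nt=nt, gap_penalty=gap_penalty)


def load_pair_frequencies(path=None) -> dict[tuple[str, str, str], float]:
    """Load the (nt5, nt3, LW-type) -> count table used to arbitrate
    annotation conflicts.  The packaged default is a synthetic table with
    plausible relative magnitudes, not survey-derived counts."""
    text = _read_packaged("pair_frequencies.synthetic.tsv") if path is None else open(path, encoding="utf-8").read()
    out: dict[tuple[str, str, str], float] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("nt5\t"):
            continue
        nt5, nt3, lw, count = ln.split("\t")
        out[(nt5, nt3, lw)] = float(count)
    return out


def _weighted(x_cell: dict, y_cell: dict, lookup, normalize: bool, mc_y: int | None) -> float:
    if not x_cell or not y_cell:
        raise ValueError("weighted cell score requires both cells non-empty")
    if normalize and not mc_y:
        raise ValueError("normalized scoring requires the Y-side motif count")
    m, n = len(x_cell), len(y_cell)
    total = 0.0
    for ex in x_cell:
        inner = 0.0
        for ey, count in y_cell.items():
            c = count / mc_y if normalize else count
            inner += c * lookup(ey, ex)
        total += inner / n
    return total / m


def score_bp_cell(
    x_cell: dict[tuple[str, str], int],
    y_cell: dict[tuple[str, str], int],
    matrices: ScoringMatrices,
    normalize: bool = False,
    mc_y: int | None = None,
) -> float:
    """Weighted score of matching two base-pair profile cells; entries are
    keyed by (LW-type, nt-pair)."""
    return _weighted(x_cell, y_cell, matrices.bp_score, normalize, mc_y)


def score_stk_cell(
    x_cell: dict[str, int],
    y_cell: dict[str, int],
    matrices: ScoringMatrices,
    normalize: bool = False,
    mc_y: int | None = None,
) -> float:
    return _weighted(x_cell, y_cell, matrices.stk_score, normalize, mc_y)


def score_nt_column(
    x_col: dict[str, int],
    y_col: dict[str, int],
    matrices: ScoringMatrices,
    normalize: bool = False,
    mc_y: int | None = None,
) -> float:
    return _weighted(x_col, y_col, matrices.nt_score, normalize, mc_y)
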