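"""Clique-anchored profile-to-profile alignment.

Two structural profiles are aligned by first matching their base-interaction
cells.  Every candidate cell matching (an X cell paired with a Y cell of the
same kind and segment) becomes a vertex of a compatibility graph, weighted by
the weighted cell score; two vertices are joined iff the relation group of
the X cells equals that of the Y cells, where the six relation groups
(juxtaposing, juxtaposing with shared nucleotide, crossing, enclosing, and
enclosing with shared nucleotide left/right) classify how two ordered
interactions sit relative to each other.  Any clique of this graph is a
mutually consistent set of interaction matchings; its endpoint pairs anchor
the alignment, and the unanchored stretches between anchors are aligned by
dynamic programming over the sequence profiles, never bridging break points.

The total score of a candidate alignment sums the matched base-pair cell
scores, the stacking cell scores recoverable between anchored endpoints, the
nucleotide-column scores of all aligned columns, and a linear gap penalty.
Cliques are enumerated with a branch-and-bound search (for k outstanding
vertices a clique needs at least k(k-1)/2 edges among them; optimistic score
bounds prune hopeless branches), and the search is exhaustive up to those
sound bounds, so the reported alignment maximizes the total score over every
orientation of the second profile.

Internal loops have two strand orientations and s-way multi-loops have s
cyclic ones; re-orienting rotates the strand order, re-indexes every cell,
and reverses interaction types whose endpoint order flips (trans-H/S becomes
trans-S/H, upward stacking becomes downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import BasePairType, StackingType
from .profile import GAP, Profile
from .scoring import ScoringMatrices, score_bp_cell, score_nt_column, score_stk_cell

__all__ = [
    "AlignConfig",
    "Vertex",
    "CompatibilityGraph",
    "AlignmentResult",
    "order_interactions",
    "relation_group",
    "rotate_profile",
    "enumerate_orientations",
    "build_compatibility_graph",
    "find_best_clique",
    "extend_alignment",
    "align_profiles",
    "merge_profiles",
]

RELATION_GROUPS = (
    "juxtaposing",
    "juxtaposing_shared",
    "crossing",
    "enclosing",
    "enclosing_shared_left",
    "enclosing_shared_right",
)


@dataclass(frozen=True)
class AlignConfig:
    """Knobs of the alignment engine.

    include_stackings: add stacking cells to the compatibility graph (off by
        default; stackings then contribute to the score only between
        base-pair-anchored endpoints, which keeps the graph small).
    gap_penalty: linear per-gap-column cost of the flank extension.
    normalize_counts: divide cell counts by the Y-side motif count in the
        weighted scores, so different-sized profiles compare on one scale.
    chunk_size: guide-tree chunking threshold.
    """

    include_stackings: bool = False
    gap_penalty: float = -2.0
    normalize_counts: bool = True
    chunk_size: int = 5


def order_interactions(p: Profile, kind: str = "basepair") -> list[tuple[int, int]]:
    """Interaction cells of a profile ordered 5'->3': (i, j) precedes (k, l)
    iff i < k, or i = k and j < l."""
    cells = p.bp if kind == "basepair" else p.stk
    return sorted(cells)


def relation_group(a: tuple[int, int], b: tuple[int, int]) -> str:
    """Classify the relative configuration of two ordered interaction cells.

    ``a`` = (i, j) must precede ``b`` = (k, l) in the interaction ordering.
    """
    (i, j), (k, l) = a, b
    if a == b:
        raise ValueError("relation group undefined for identical cells")
    if not (i < k or (i == k and j < l)):
        raise ValueError(f"cell {a} does not precede cell {b}")
    if i == k:
        return "enclosing_shared_left"
    if j == l:
        return "enclosing_shared_right"
    if j == k:
        return "juxtaposing_shared"
    if j < k:
        return "juxtaposing"
    if l < j:
        return "enclosing"
    return "crossing"


def _rel_signed(c1: tuple[int, int], c2: tuple[int, int]) -> tuple[str, int]:
    if c1 == c2:
        return ("identical", 0)
    if c1 < c2:
        return (relation_group(c1, c2), 1)
    return (relation_group(c2, c1), -1)


# ---------------------------------------------------------------------------
# Orientations


def rotate_profile(p: Profile, r: int) -> Profile:
    """Cyclically rotate the strand order of a profile by ``r`` segments,
    re-indexing all columns and interaction cells.  When re-keying swaps a
    cell's endpoint order, the interaction types are reversed."""
    s = p.n_segments
    r %= s
    if r == 0:
        return p
    bounds = p.segment_bounds
    new_order = bounds[r:] + bounds[:r]
    old_to_new: dict[int, int] = {}
    pos = 0
    for a, b in new_order:
        for old in range(a, b + 1):
            pos += 1
            old_to_new[old] = pos
    columns = [None] * p.length
    for old, new in old_to_new.items():
        columns[new - 1] = dict(p.columns[old - 1])

    def rekey_bp(cells):
        out = {}
        for (i, j), cell in cells.items():
            ni, nj = old_to_new[i], old_to_new[j]
            if ni < nj:
                out[(ni, nj)] = dict(cell)
            else:
                out[(nj, ni)] = {
                    (str(BasePairType.from_string(lw).reverse()), f"{pair.split('-')[1]}-{pair.split('-')[0]}"): c
                    for (lw, pair), c in cell.items()
                }
        return out

    def rekey_stk(cells):
        out = {}
        for (i, j), cell in cells.items():
            ni, nj = old_to_new[i], old_to_new[j]
            if ni < nj:
                out[(ni, nj)] = dict(cell)
            else:
                out[(nj, ni)] = {
                    str(StackingType.from_string(cat).reverse()): c for cat, c in cell.items()
                }
        return out

    break_points = []
    acc = 0
    for a, b in new_order:
        acc += b - a + 1
        break_points.append(acc)
    return Profile(
        columns=columns,
        bp=rekey_bp(p.bp),
        stk=rekey_stk(p.stk),
        break_points=break_points,
        mc=p.mc,
        source_ids=list(p.source_ids),
    )


def enumerate_orientations(p: Profile) -> list[Profile]:
    """All cyclic strand rotations of a profile: 1 for hairpins, 2 for
    internal loops, s for s-way multi-loops.  Index 0 is the identity."""
    return [rotate_profile(p, r) for r in range(p.n_segments)]


# ---------------------------------------------------------------------------
# Compatibility graph


@dataclass(frozen=True)
class Vertex:
    kind: str  # 'basepair' | 'stacking'
    x_cell: tuple[int, int]
    y_cell: tuple[int, int]
    score: float


@dataclass
class CompatibilityGraph:
    vertices: list[Vertex]
    adj: list[set[int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.vertices)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.adj[u]


def build_compatibility_graph(
    x: Profile,
    y: Profile,
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
) -> CompatibilityGraph:
    """Vertices pair same-kind, segment-consistent interaction cells of X and
    Y, weighted by the weighted cell score; edges join matchings whose cells
    stand in the same relation group on both sides."""
    nz, ny = cfg.normalize_counts, y.mc
    vertices: list[Vertex] = []
    for kind in ("basepair", "stacking"):
        if kind == "stacking" and not cfg.include_stackings:
            continue
        x_cells = order_interactions(x, kind)
        y_cells = order_interactions(y, kind)
        scorer = score_bp_cell if kind == "basepair" else score_stk_cell
        cell_map_x = x.bp if kind == "basepair" else x.stk
        cell_map_y = y.bp if kind == "basepair" else y.stk
        for xc in x_cells:
            for yc in y_cells:
                if x.segment_of(xc[0]) != y.segment_of(yc[0]):
                    continue
                if x.segment_of(xc[1]) != y.segment_of(yc[1]):
                    continue
                vertices.append(
                    Vertex(kind, xc, yc, scorer(cell_map_x[xc], cell_map_y[yc], matrices, nz, ny))
                )
    adj: list[set[int]] = [set() for _ in vertices]
    for u in range(len(vertices)):
        for v in range(u + 1, len(vertices)):
            if _consistent(vertices[u], vertices[v]):
                adj[u].add(v)
                adj[v].add(u)
    return CompatibilityGraph(vertices=vertices, adj=adj)


def _consistent(u: Vertex, v: Vertex) -> bool:
    if u.kind == v.kind and (u.x_cell == v.x_cell or u.y_cell == v.y_cell):
        return False  # one cell cannot be matched twice
    return _rel_signed(u.x_cell, v.x_cell) == _rel_signed(u.y_cell, v.y_cell)


# ---------------------------------------------------------------------------
# Maximum-weight clique (branch and bound)


def _cap_by_edges(cand: list[int], adj: list[set[int]]) -> int:
    """A clique of t extra vertices needs t(t-1)/2 edges among the
    candidates; return the largest feasible t."""
    k = len(cand)
    e = sum(1 for i, u in enumerate(cand) for v in cand[i + 1 :] if v in adj[u])
    t = k
    while t > 0 and t * (t - 1) // 2 > e:
        t -= 1
    return t


def _potential(cand: list[int], weights: list[float], adj: list[set[int]]) -> float:
    pos = sorted((weights[v] for v in cand if weights[v] > 0), reverse=True)
    t = _cap_by_edges(cand, adj)
    return sum(pos[:t])


def _better(score, size, idxs, best_score, best_size, best_idxs) -> bool:
    if score != best_score:
        return score > best_score
    if size != best_size:
        return size > best_size
    return idxs < best_idxs


def find_best_clique(g: CompatibilityGraph) -> tuple[list[int], float]:
    """The clique with the maximum total vertex score (the empty clique, at
    score 0, competes).  Branch-and-bound with the edge-count upper bound;
    equal scores prefer the larger clique, then the lexicographically
    smallest vertex-index list."""
    weights = [v.score for v in g.vertices]
    best = {"idxs": [], "score": 0.0, "size": 0}

    def expand(clique: list[int], score: float, cand: list[int]) -> None:
        if _better(score, len(clique), clique, best["score"], best["size"], best["idxs"]):
            best.update(idxs=list(clique), score=score, size=len(clique))
        for k, v in enumerate(cand):
            rest = cand[k:]
            if score + _potential(rest, weights, g.adj) < best["score"]:
                continue
            clique.append(v)
            expand(clique, score + weights[v], [u for u in cand[k + 1 :] if u in g.adj[v]])
            clique.pop()

    expand([], 0.0, list(range(g.n)))
    return best["idxs"], best["score"]


# ---------------------------------------------------------------------------
# Anchored extension


@dataclass
class AlignmentResult:
    """A complete profile-to-profile alignment: the monotone column mapping
    (pairs of 1-based positions, ``None`` marking a gap), the chosen
    orientation of Y (rotation index), the matched interaction cells, and
    the total alignment score."""

    mapping: list[tuple[int | None, int | None]]
    orientation: int
    clique: list[Vertex]
    score: float

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.mapping if a is not None and b is not None]


def _anchor_map(clique: list[Vertex]) -> dict[int, int]:
    anchors: dict[int, int] = {}
    rev: dict[int, int] = {}
    for v in clique:
        for xp, yp in ((v.x_cell[0], v.y_cell[0]), (v.x_cell[1], v.y_cell[1])):
            if anchors.get(xp, yp) != yp or rev.get(yp, xp) != xp:
                raise ValueError("inconsistent anchor set: clique endpoints collide")
            anchors[xp] = yp
            rev[yp] = xp
    return anchors


def _region_dp(
    xs: int, xe: int, ys: int, ye: int, colscore, gap: float
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Global alignment of x columns [xs..xe] with y columns [ys..ye]
    (1-based, inclusive; empty ranges allowed).  Ties prefer the diagonal,
    then consuming x."""
    nx, ny = xe - xs + 1, ye - ys + 1
    if nx < 0 or ny < 0:
        raise ValueError("negative region")
    dp = [[0.0] * (ny + 1) for _ in range(nx + 1)]
    for i in range(1, nx + 1):
        dp[i][0] = i * gap
    for j in range(1, ny + 1):
        dp[0][j] = j * gap
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            dp[i][j] = max(
                dp[i - 1][j - 1] + colscore(xs + i - 1, ys + j - 1),
                dp[i - 1][j] + gap,
                dp[i][j - 1] + gap,
            )
    # traceback (diag > up > left on ties)
    path: list[tuple[int | None, int | None]] = []
    i, j = nx, ny
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i][j] == dp[i - 1][j - 1] + colscore(xs + i - 1, ys + j - 1):
            path.append((xs + i - 1, ys + j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and dp[i][j] == dp[i - 1][j] + gap:
            path.append((xs + i - 1, None))
            i -= 1
        else:
            path.append((None, ys + j - 1))
            j -= 1
    path.reverse()
    return dp[nx][ny], path


def extend_alignment(
    x: Profile,
    y: Profile,
    clique: list[Vertex],
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
    orientation: int = 0,
    _colscore=None,
) -> AlignmentResult:
    """Fix the clique's endpoint matchings as anchors and align every
    unanchored stretch by sequence-profile dynamic programming, segment by
    segment (gaps never bridge break points).  Returns the full monotone
    mapping and the total alignment score."""
    if x.n_segments != y.n_segments:
        raise ValueError(
            f"segment-count mismatch: {x.n_segments} vs {y.n_segments} (junction types differ)"
        )
    nz = cfg.normalize_counts
    if _colscore is None:
        cache: dict[tuple[int, int], float] = {}

        def _colscore(i: int, j: int) -> float:
            v = cache.get((i, j))
            if v is None:
                v = score_nt_column(x.columns[i - 1], y.columns[j - 1], matrices, nz, y.mc)
                cache[(i, j)] = v
            return v

    anchors = _anchor_map(clique)
    for xp, yp in anchors.items():
        if x.segment_of(xp) != y.segment_of(yp):
            raise ValueError(f"anchor ({xp},{yp}) crosses segments")

    mapping: list[tuple[int | None, int | None]] = []
    seq_score = 0.0
    for (xa, xb), (ya, yb) in zip(x.segment_bounds, y.segment_bounds):
        seg_anchors = sorted((p, anchors[p]) for p in anchors if xa <= p <= xb)
        for (p1, q1), (p2, q2) in zip(seg_anchors, seg_anchors[1:]):
            if q2 <= q1:
                raise ValueError("anchors not monotone within segment")
        prev_x, prev_y = xa - 1, ya - 1
        for p, q in seg_anchors + [(xb + 1, yb + 1)]:
            s, path = _region_dp(prev_x + 1, p - 1, prev_y + 1, q - 1, _colscore, cfg.gap_penalty)
            seq_score += s
            mapping.extend(path)
            if p <= xb:
                mapping.append((p, q))
                seq_score += _colscore(p, q)
            prev_x, prev_y = p, q

    clique_score = sum(v.score for v in clique)
    in_clique = {(v.x_cell, v.y_cell) for v in clique if v.kind == "stacking"}
    stk_bonus = 0.0
    for (i, j), cell in x.stk.items():
        if i in anchors and j in anchors:
            ycell_key = (anchors[i], anchors[j])
            if ycell_key in y.stk and ((i, j), ycell_key) not in in_clique:
                stk_bonus += score_stk_cell(cell, y.stk[ycell_key], matrices, nz, y.mc)

    return AlignmentResult(
        mapping=mapping,
        orientation=orientation,
        clique=list(clique),
        score=clique_score + stk_bonus + seq_score,
    )


# ---------------------------------------------------------------------------
# Full alignment over orientations


def align_profiles(
    x: Profile,
    y: Profile,
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
) -> AlignmentResult:
    """Best-scoring complete alignment of two profiles over all orientations
    of Y.

    Every clique of the compatibility graph is a candidate anchor set; the
    search enumerates them best-first with branch-and-bound pruning (the
    bound combines the remaining positive vertex weights, the edge-count
    clique bound, the unconstrained sequence-alignment optimum and the
    maximum stacking bonus) and scores each candidate by its full anchored
    extension, so the result is optimal for the total alignment score, not
    merely for the anchored part.  Ties prefer, in order: higher score, the
    earlier orientation, the larger clique, the lexicographically smallest
    vertex-index list.
    """
    if x.n_segments != y.n_segments:
        raise ValueError(
            f"cannot align a {x.loop_type} loop with a {y.loop_type} loop: "
            f"{x.n_segments} vs {y.n_segments} segments in every orientation"
        )
    best: AlignmentResult | None = None
    best_key: tuple[float, int, list] | None = None  # (score, size, idx list) within orientation

    for ori, y_or in enumerate(enumerate_orientations(y)):
        g = build_compatibility_graph(x, y_or, matrices, cfg)
        nz = cfg.normalize_counts
        cache: dict[tuple[int, int], float] = {}

        def colscore(i: int, j: int, y_or=y_or, cache=cache) -> float:
            v = cache.get((i, j))
            if v is None:
                v = score_nt_column(x.columns[i - 1], y_or.columns[j - 1], matrices, nz, y_or.mc)
                cache[(i, j)] = v
            return v

        def evaluate(idxs: list[int], y_or=y_or, g=g, colscore=colscore, ori=ori) -> AlignmentResult:
            return extend_alignment(
                x, y_or, [g.vertices[k] for k in idxs], matrices, cfg, ori, _colscore=colscore
            )

        empty = evaluate([])
        u_seq = empty.score  # unconstrained sequence optimum bounds any anchored mapping
        u_stk = _stk_potential(x, y_or, matrices, cfg)
        weights = [v.score for v in g.vertices]

        local_best: dict = {"res": empty, "score": empty.score, "size": 0, "idxs": []}

        def expand(idxs: list[int], bp_score: float, cand: list[int], local_best=local_best, g=g, weights=weights, u_stk=u_stk, u_seq=u_seq, evaluate=evaluate) -> None:
            for k, v in enumerate(cand):
                rest = cand[k:]
                if bp_score + _potential(rest, weights, g.adj) + u_stk + u_seq < local_best["score"]:
                    continue
                idxs.append(v)
                res = evaluate(idxs)
                if _better(
                    res.score, len(idxs), idxs, local_best["score"], local_best["size"], local_best["idxs"]
                ):
                    local_best.update(res=res, score=res.score, size=len(idxs), idxs=list(idxs))
                expand(idxs, bp_score + weights[v], [u for u in cand[k + 1 :] if u in g.adj[v]])
                idxs.pop()

        expand([], 0.0, list(range(g.n)))

        res = local_best["res"]
        if best is None or res.score > best.score:
            best = res
            best_key = (res.score, local_best["size"], local_best["idxs"])
    assert best is not None
    return best


def _stk_potential(x: Profile, y: Profile, matrices: ScoringMatrices, cfg: AlignConfig) -> float:
    """Upper bound on the stacking contribution of any alignment."""
    total = 0.0
    for xc, cell in x.stk.items():
        cand = [
            score_stk_cell(cell, ycell, matrices, cfg.normalize_counts, y.mc)
            for yc, ycell in y.stk.items()
            if x.segment_of(xc[0]) == y.segment_of(yc[0]) and x.segment_of(xc[1]) == y.segment_of(yc[1])
        ]
        best = max(cand, default=0.0)
        if best > 0:
            total += best
    return total


# ---------------------------------------------------------------------------
# Merging


def merge_profiles(x: Profile, y: Profile, a: AlignmentResult) -> Profile:
    """Merge two aligned profiles into one.

    Aligned columns sum their count maps; a column matched to a gap gains a
    gap count equal to the other profile's motif count, so column sums stay
    equal to the merged motif count MC^X + MC^Y.  Interaction cells are
    re-keyed through the alignment mapping and summed entry-wise; unaligned
    interactions are carried over so no structural information is lost.
    """
    y_or = rotate_profile(y, a.orientation)
    pos_x: dict[int, int] = {}
    pos_y: dict[int, int] = {}
    columns: list[dict[str, int]] = []
    seg_of_col: list[int] = []
    for xi, yj in a.mapping:
        col: dict[str, int] = {}
        if xi is not None and yj is not None:
            col = dict(x.columns[xi - 1])
            for k, c in y_or.columns[yj - 1].items():
                col[k] = col.get(k, 0) + c
        elif xi is not None:
            col = dict(x.columns[xi - 1])
            col[GAP] = col.get(GAP, 0) + y_or.mc
        elif yj is not None:
            col = dict(y_or.columns[yj - 1])
            col[GAP] = col.get(GAP, 0) + x.mc
        else:
            raise ValueError("mapping entry with neither side set")
        columns.append(col)
        idx = len(columns)
        if xi is not None:
            pos_x[xi] = idx
        if yj is not None:
            pos_y[yj] = idx
        seg_of_col.append(x.segment_of(xi) if xi is not None else y_or.segment_of(yj))

    if len(pos_x) != x.length or len(pos_y) != y_or.length:
        raise ValueError("alignment mapping does not cover both profiles")

    def fold(cells_x: dict, cells_y: dict) -> dict:
        out: dict[tuple[int, int], dict] = {}
        for cells, pos in ((cells_x, pos_x), (cells_y, pos_y)):
            for (i, j), cell in cells.items():
                key = (pos[i], pos[j])
                tgt = out.setdefault(key, {})
                for k, c in cell.items():
                    tgt[k] = tgt.get(k, 0) + c
        return out

    break_points = [idx + 1 for idx in range(len(columns)) if idx + 1 == len(columns) or seg_of_col[idx + 1] != seg_of_col[idx]]
    return Profile(
        columns=columns,
        bp=fold(x.bp, y_or.bp),
        stk=fold(x.stk, y_or.stk),
        break_points=break_points,
        mc=x.mc + y_or.mc,
        source_ids=list(x.source_ids) + list(y_or.source_ids),
    )
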