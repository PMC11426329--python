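"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's search machinery: cliques come from
subset enumeration, alignments from exhaustive enumeration of monotone
matchings, and weighted cell scores from plain double loops.
"""

from itertools import combinations, product

from motifprofiler.align import build_compatibility_graph, enumerate_orientations
from motifprofiler.scoring import score_nt_column, score_stk_cell


def brute_weighted(x_cell, y_cell, lookup, normalize=False, mc_y=None):
    """Literal double-sum of the weighted matching score."""
    m, n = len(x_cell), len(y_cell)
    total = 0.0
    for ex in x_cell:
        for ey, count in y_cell.items():
            c = count / mc_y if normalize else count
            total += (1.0 / m) * (1.0 / n) * c * lookup(ey, ex)
    return total


def all_cliques(g):
    """Every clique of the compatibility graph (including the empty one),
    by subset enumeration."""
    n = g.n
    for size in range(n + 1):
        for subset in combinations(range(n), size):
            if all(v in g.adj[u] for u, v in combinations(subset, 2)):
                yield subset


def best_clique_exhaustive(g):
    """Maximum-weight clique by subset enumeration, with the tie rule:
    larger clique first, then lexicographically smallest index list."""
    best = ((), 0.0)
    for clique in all_cliques(g):
        score = sum(g.vertices[v].score for v in clique)
        bs = best[1]
        if score > bs or (
            score == bs
            and (len(clique) > len(best[0]) or (len(clique) == len(best[0]) and list(clique) < list(best[0])))
        ):
            best = (clique, score)
    return list(best[0]), best[1]


def _segment_matchings(xa, xb, ya, yb):
    """All monotone partial matchings of x columns [xa..xb] with y columns
    [ya..yb] (unmatched columns become gaps)."""
    xs, ys = list(range(xa, xb + 1)), list(range(ya, yb + 1))
    for k in range(min(len(xs), len(ys)) + 1):
        for xsub in combinations(xs, k):
            for ysub in combinations(ys, k):
                yield list(zip(xsub, ysub))


def best_alignment_exhaustive(x, y, matrices, cfg):
    """Best total alignment score over all orientations of y, all consistent
    interaction matchings (cliques) and all anchored monotone gapped
    mappings."""
    best = None
    for y_or in enumerate_orientations(y):
        g = build_compatibility_graph(x, y_or, matrices, cfg)
        per_segment = [
            list(_segment_matchings(xa, xb, ya, yb))
            for (xa, xb), (ya, yb) in zip(x.segment_bounds, y_or.segment_bounds)
        ]
        mappings = [
            [pair for seg in combo for pair in seg] for combo in product(*per_segment)
        ]
        for clique in all_cliques(g):
            verts = [g.vertices[v] for v in clique]
            anchors = {}
            ok = True
            for v in verts:
                for xp, yp in ((v.x_cell[0], v.y_cell[0]), (v.x_cell[1], v.y_cell[1])):
                    if anchors.setdefault(xp, yp) != yp:
                        ok = False
            if not ok:
                continue
            anchor_pairs = set(anchors.items())
            clique_score = sum(v.score for v in verts)
            in_clique_stk = {(v.x_cell, v.y_cell) for v in verts if v.kind == "stacking"}
            stk_bonus = 0.0
            for (i, j), cell in x.stk.items():
                if i in anchors and j in anchors:
                    key = (anchors[i], anchors[j])
                    if key in y_or.stk and ((i, j), key) not in in_clique_stk:
                        stk_bonus += score_stk_cell(
                            cell, y_or.stk[key], matrices, cfg.normalize_counts, y_or.mc
                        )
            for mapping in mappings:
                if not anchor_pairs <= set(mapping):
                    continue
                cols = sum(
                    score_nt_column(
                        x.columns[i - 1], y_or.columns[j - 1], matrices, cfg.normalize_counts, y_or.mc
                    )
                    for i, j in mapping
                )
                gaps = (x.length - len(mapping)) + (y_or.length - len(mapping))
                total = clique_score + stk_bonus + cols + gaps * cfg.gap_penalty
                if best is None or total > best:
                    best = total
    return best


def random_graph(rng, n_max=12):
    """A random weighted graph in compatibility-graph form (vertices carry
    scores; cells are dummies)."""
    from motifprofiler.align import CompatibilityGraph, Vertex

    n = int(rng.integers(0, n_max + 1))
    vertices = [
        Vertex("basepair", (1, 2), (1, 2), float(round(rng.normal(1.0, 3.0), 2)))
        for _ in range(n)
    ]
    adj = [set() for _ in range(n)]
    p = rng.uniform(0.2, 0.8)
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p:
                adj[u].add(v)
                adj[v].add(u)
    return CompatibilityGraph(vertices=vertices, adj=adj)


def random_small_profile(rng, n_segments, max_seg_len=3, max_bp=2, max_stk=1):
    """Small random profile for exhaustive alignment checks."""
    from motifprofiler.synth import random_profile

    while True:
        p = random_profile(rng, max_segments=3)
        if (
            p.n_segments == n_segments
            and p.length <= n_segments * max_seg_len
            and len(p.bp) <= max_bp
            and len(p.stk) <= max_stk
        ):
            return p
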