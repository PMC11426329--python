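"""Progressive profile construction under a greedy guide tree.

All input motifs become single-motif profiles; the best-scoring pair is
aligned and merged, the result re-enters the pool, and the loop repeats
until one profile remains.  Large inputs are first split into chunks
(default five) that are reduced independently and then merged by the same
loop, recursively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignConfig, AlignmentResult, align_profiles, merge_profiles
from .motifs import Motif
from .profile import Profile, motif_to_profile
from .scoring import ScoringMatrices

__all__ = ["ProfilePool", "best_pair", "build_profile", "build_profile_with_tree"]


@dataclass
class ProfilePool:
    """Live profiles with provenance (which motif ids each covers) and a
    parenthesized merge-history label per entry."""

    profiles: list[Profile] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def provenance(self) -> list[frozenset[str]]:
        return [frozenset(p.source_ids) for p in self.profiles]


def best_pair(
    pool: ProfilePool, matrices: ScoringMatrices, cfg: AlignConfig = AlignConfig()
) -> tuple[int, int, AlignmentResult]:
    """Exhaustive scan for the highest-scoring profile pair; ties keep the
    lowest (i, j) index pair."""
    if len(pool) < 2:
        raise ValueError("best_pair requires at least two profiles")
    best = None
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            res = align_profiles(pool.profiles[i], pool.profiles[j], matrices, cfg)
            if best is None or res.score > best[2].score:
                best = (i, j, res)
    return best


def _reduce(pool: ProfilePool, matrices: ScoringMatrices, cfg: AlignConfig) -> tuple[Profile, str]:
    while len(pool) > 1:
        i, j, res = best_pair(pool, matrices, cfg)
        merged = merge_profiles(pool.profiles[i], pool.profiles[j], res)
        label = f"({pool.labels[i]},{pool.labels[j]})"
        keep = [k for k in range(len(pool)) if k not in (i, j)]
        pool.profiles = [pool.profiles[k] for k in keep] + [merged]
        pool.labels = [pool.labels[k] for k in keep] + [label]
    return pool.profiles[0], pool.labels[0]


def build_profile_with_tree(
    motifs: list[Motif],
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
) -> tuple[Profile, str]:
    """Build the family profile of a motif group; also return the merge tree
    as a newick-like string (the merge order is part of the result, so it is
    logged for reproducibility)."""
    if not motifs:
        raise ValueError("need at least one motif")
    n_seg = motifs[0].n_segments
    offending = [m.id for m in motifs if m.n_segments != n_seg]
    if offending:
        raise ValueError(
            "all motifs must share one junction type; "
            f"expected {n_seg} segment(s) but these differ: {offending}"
        )
    profiles = [motif_to_profile(m) for m in motifs]
    labels = [m.id for m in motifs]
    chunk = max(2, cfg.chunk_size)
    while len(profiles) > 1:
        if len(profiles) > chunk:
            new_profiles, new_labels = [], []
            for k in range(0, len(profiles), chunk):
                pool = ProfilePool(profiles[k : k + chunk], labels[k : k + chunk])
                p, lab = _reduce(pool, matrices, cfg)
                new_profiles.append(p)
                new_labels.append(lab)
            profiles, labels = new_profiles, new_labels
        else:
            p, lab = _reduce(ProfilePool(profiles, labels), matrices, cfg)
            profiles, labels = [p], [lab]
    return profiles[0], labels[0] + ";"


def build_profile(
    motifs: list[Motif],
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
) -> Profile:
    """Single profile summarizing all input motifs (MC = number of inputs)."""
    return build_profile_with_tree(motifs, matrices, cfg)[0]
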