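"""Profile-based motif search over RNA chains.

Candidate loops (extracted with the stem criterion) are each wrapped as a
single-motif profile and aligned against the target family profile; hits
are ranked by alignment score.  A z-score locates each hit relative to the
family itself: the target profile is aligned against every participating
member instance, and a hit's z-score is (score - mu) / sigma of those
member scores.  Positive z means the candidate sits inside the family's own
score range, i.e. it is structurally close to the family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .align import AlignConfig, align_profiles
from .motifs import Motif
from .profile import Profile, motif_to_profile
from .scoring import ScoringMatrices

__all__ = ["SearchStats", "SearchHit", "calibrate", "zscore", "search_chains"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchStats:
    """Alignment-score statistics of a profile against its own members:
    mean ``mu``, population standard deviation ``sigma``, member count
    ``n``."""

    mu: float
    sigma: float
    n: int


@dataclass(frozen=True)
class SearchHit:
    motif_id: str
    score: float
    z: float
    rank: int


def calibrate(
    profile: Profile,
    members: list[Motif],
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
) -> SearchStats:
    """Align the target profile against each participating member's
    single-motif profile and summarize the scores (population sd)."""
    if not members:
        raise ValueError("calibration requires at least one member motif")
    scores = [
        align_profiles(profile, motif_to_profile(m), matrices, cfg).score for m in members
    ]
    arr = np.asarray(scores, dtype=float)
    return SearchStats(mu=float(arr.mean()), sigma=float(arr.std()), n=len(members))


def zscore(s: float, stats: SearchStats) -> float:
    """(s - mu) / sigma.  A degenerate family (sigma = 0) maps its own mean
    to 0 and anything else to +/-inf."""
    if stats.sigma > 0:
        return (s - stats.mu) / stats.sigma
    if s == stats.mu:
        return 0.0
    return math.inf if s > stats.mu else -math.inf


def search_chains(
    profile: Profile,
    stats: SearchStats,
    chains: list[list[Motif]],
    matrices: ScoringMatrices,
    cfg: AlignConfig = AlignConfig(),
    min_z: float | None = None,
) -> list[SearchHit]:
    """Scan chain loop-sets for instances of the profiled family.

    Loops whose segment count differs from the profile's cannot align in any
    orientation and are skipped (logged).  Hits are sorted by score in
    decreasing order (ties by id) and ranked from 1.
    """
    scored: list[tuple[str, float]] = []
    for loops in chains:
        for loop in loops:
            if loop.n_segments != profile.n_segments:
                logger.info(
                    "skipping %s: %d segment(s), profile has %d",
                    loop.id,
                    loop.n_segments,
                    profile.n_segments,
                )
                continue
            res = align_profiles(profile, motif_to_profile(loop), matrices, cfg)
            scored.append((loop.id, res.score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    hits = [
        SearchHit(motif_id=mid, score=s, z=zscore(s, stats), rank=r)
        for r, (mid, s) in enumerate(scored, start=1)
    ]
    if min_z is not None:
        hits = [h for h in hits if h.z >= min_z]
    return hits
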