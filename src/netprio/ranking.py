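"""Per-index top-k candidate ranking against a disease seed set.

Every non-seed network gene is scored against the seeds; a gene's score
is the MAX over seeds of S(seed, gene) — a candidate qualifies through
its single strongest seed link.  Candidates are then sorted (score
descending, symbol ascending for determinism) and cut at k.

Scores are computed with a common-neighbor walk (seed → common neighbor
→ candidate) rather than per-pair set intersections, so a full ranking
over an interactome-scale graph is linear in the seeds' two-hop
neighborhoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .indices import INDEX_NAMES, normalize_index, resolve_log_base
from .network import PPINetwork, SeedSet

logger = logging.getLogger(__name__)

__all__ = ["ScoredCandidate", "RankedGeneList", "score_candidates", "top_k",
           "rank_candidates", "build_all_lists"]


@dataclass(frozen=True)
class ScoredCandidate:
    """A non-seed network gene with its best score against the seed set."""

    candidate: str
    index: str
    score: float
    best_seed: str

    @property
    def is_zero(self) -> bool:
        return self.score == 0.0


@dataclass(frozen=True)
class RankedGeneList:
    """Ordered top-k candidates for one (disease, index, k).

    ``genes`` holds (symbol, score) pairs with non-increasing scores,
    no duplicates, and no seed genes; ``len(genes) <= k``.
    """

    disease_name: str
    index: str
    k: int
    genes: tuple[tuple[str, float], ...]

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return any(g == gene for g, _ in self.genes)


def _in_network_seeds(net: PPINetwork, seeds: SeedSet) -> list[str]:
    present = [s for s in seeds if s in net]
    missing = [s for s in seeds if s not in net]
    if missing:
        logger.warning(
            "disease %s: %d seed(s) absent from network and dropped: %s",
            seeds.disease_name, len(missing), ", ".join(missing),
        )
    if not present:
        raise ValueError(
            f"seed set disjoint from network for disease {seeds.disease_name!r}"
        )
    return present


def _seed_scores(
    net: PPINetwork, seed: str, index: str, base: float
) -> dict[str, float]:
    """S(seed, c) for every node c reachable by the given index (others 0)."""
    if index == "PAC":
        ks = net.degree(seed)
        return {c: float(ks * net.degree(c)) for c in net.nodes if c != seed}
    # common-neighbor indices: two-hop walk seed -> z -> c
    acc: dict[str, float] = {}
    common: dict[str, int] = {}
    for z in net.neighbors(seed):
        kz = net.degree(z)
        if kz < 2:  # z's only neighbor is the seed itself
            continue
        w = 1.0 if index == "JC" else 1.0 / math.log(kz, base) if index == "AA" else 1.0 / kz
        for c in net.neighbors(z):
            if c == seed:
                continue
            acc[c] = acc.get(c, 0.0) + w
            common[c] = common.get(c, 0) + 1
    if index == "JC":
        ks = net.degree(seed)
        return {
            c: common[c] / (ks + net.degree(c) - common[c]) for c in acc
        }
    return acc


def score_candidates(
    net: PPINetwork,
    seeds: SeedSet,
    index: str,
    log_base: str | float = "e",
) -> list[ScoredCandidate]:
    """Score every non-seed network gene: max over seeds of S(seed, gene).

    ``best_seed`` is the seed attaining the max (lexicographic tie-break).
    Seeds absent from the network are dropped with a warning; an entirely
    absent seed set is an error.  Zero-score candidates are retained.
    """
    name = normalize_index(index)
    base = resolve_log_base(log_base)
    present = sorted(_in_network_seeds(net, seeds))
    seed_set = set(seeds.genes)

    best: dict[str, tuple[float, str]] = {}
    for seed in present:  # sorted => lexicographic seed tie-break by first-wins
        for c, s in _seed_scores(net, seed, name, base).items():
            if c in seed_set:
                continue
            cur = best.get(c)
            if cur is None or s > cur[0]:
                best[c] = (s, seed)

    out = []
    for c in net.nodes:
        if c in seed_set:
            continue
        s, bs = best.get(c, (0.0, present[0]))
        out.append(ScoredCandidate(candidate=c, index=name, score=s, best_seed=bs))
    return out


def top_k(
    cands: list[ScoredCandidate],
    k: int,
    disease_name: str = "",
    zero_policy: str = "exclude",
) -> RankedGeneList:
    """Cut a scored candidate list to the k best.

    Sort order is (score descending, symbol ascending).  With the default
    ``zero_policy="exclude"`` zero-score candidates are removed before
    cutting, so the list may hold fewer than k genes.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if zero_policy not in ("exclude", "include"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    pool = [c for c in cands if c.score > 0.0] if zero_policy == "exclude" else list(cands)
    pool.sort(key=lambda c: (-c.score, c.candidate))
    index = cands[0].index if cands else "?"
    return RankedGeneList(
        disease_name=disease_name,
        index=index,
        k=k,
        genes=tuple((c.candidate, c.score) for c in pool[:k]),
    )


def rank_candidates(
    net: PPINetwork,
    seeds: SeedSet,
    index: str,
    k: int,
    zero_policy: str = "exclude",
    log_base: str | float = "e",
) -> RankedGeneList:
    """Convenience: score_candidates followed by top_k."""
    cands = score_candidates(net, seeds, index, log_base=log_base)
    return top_k(cands, k, disease_name=seeds.disease_name, zero_policy=zero_policy)


def build_all_lists(
    net: PPINetwork,
    seed_sets: list[SeedSet],
    indices: list[str] = list(INDEX_NAMES),
    ks: list[int] = [10, 50, 100],
    zero_policy: str = "exclude",
    log_base: str | float = "e",
) -> list[RankedGeneList]:
    """One RankedGeneList per (disease, index, k), in that deterministic order.

    |seed_sets| × |indices| × |ks| lists in total — e.g. five diseases,
    four indices and cutoffs {10, 50, 100} yield 60 lists.
    """
    if not seed_sets or not indices or not ks:
        raise ValueError("seed_sets, indices and ks must all be non-empty")
    out: list[RankedGeneList] = []
    for seeds in seed_sets:
        for index in indices:
            try:
                cands = score_candidates(net, seeds, index, log_base=log_base)
            except ValueError as exc:
                raise ValueError(
                    f"scoring failed for disease {seeds.disease_name!r}, "
                    f"index {index}: {exc}"
                ) from exc
            for k in ks:
                out.append(
                    top_k(cands, k, disease_name=seeds.disease_name,
                          zero_policy=zero_policy)
                )
    return out
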