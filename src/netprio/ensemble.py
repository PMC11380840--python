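"""Simple-majority-voting (SMV) ensemble over per-index ranked gene lists.

Each index contributes one top-k list for a disease; a gene's vote count
is the number of lists containing it.  Genes with at least ⌈n_lists/2⌉
votes form the ensemble list — with the four default indices the
threshold is 2.  Membership is defined purely by votes, so the ensemble
list is not truncated to k and its length varies.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from .ranking import RankedGeneList

__all__ = ["SMVGeneList", "smv_vote", "build_all_smv"]


@dataclass(frozen=True)
class SMVGeneList:
    """Majority-voted gene list for one (disease, k).

    ``members`` is ordered by vote count descending then symbol
    ascending; every vote count is >= ``threshold``.
    ``supporters`` maps each member to the sorted indices that voted
    for it.
    """

    disease_name: str
    k: int
    members: tuple[tuple[str, int], ...]
    threshold: int
    supporters: dict[str, tuple[str, ...]]

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


def smv_vote(lists: list[RankedGeneList]) -> SMVGeneList:
    """Aggregate >=2 per-index lists sharing one (disease, k) by majority vote.

    The vote threshold is ⌈n_lists/2⌉ (2 for the four default indices).
    """
    if len(lists) < 2:
        raise ValueError("SMV needs at least 2 per-index lists")
    disease = lists[0].disease_name
    k = lists[0].k
    if any(l.disease_name != disease for l in lists):
        raise ValueError("mixed disease names across input lists")
    if any(l.k != k for l in lists):
        raise ValueError("mixed k cutoffs across input lists")
    indices = [l.index for l in lists]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate index among input lists: {sorted(indices)}")

    votes: dict[str, list[str]] = defaultdict(list)
    for l in lists:
        for gene in l.symbols:
            votes[gene].append(l.index)

    threshold = math.ceil(len(lists) / 2)
    members = sorted(
        ((g, len(v)) for g, v in votes.items() if len(v) >= threshold),
        key=lambda gv: (-gv[1], gv[0]),
    )
    supporters = {g: tuple(sorted(votes[g])) for g, _ in members}
    return SMVGeneList(
        disease_name=disease, k=k, members=tuple(members),
        threshold=threshold, supporters=supporters,
    )


def build_all_smv(lists: list[RankedGeneList]) -> list[SMVGeneList]:
    """One SMVGeneList per (disease, k) group, ordered (disease, k).

    Five diseases × three cutoffs yield 15 ensemble lists.  A group
    backed by a single index is an error.
    """
    groups: dict[tuple[str, int], list[RankedGeneList]] = defaultdict(list)
    order: list[tuple[str, int]] = []
    for l in lists:
        key = (l.disease_name, l.k)
        if key not in groups:
            order.append(key)
        groups[key].append(l)
    out = []
    for key in order:
        group = groups[key]
        if len({l.index for l in group}) < 2:
            raise ValueError(
                f"group (disease={key[0]!r}, k={key[1]}) has fewer than 2 indices"
            )
        out.append(smv_vote(group))
    return out
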