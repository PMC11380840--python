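"""Local similarity indices for link prediction on an undirected graph.

Each index scores a node pair (x, y) from the pair's immediate
neighborhood only — the common-neighbor set Γ(x) ∩ Γ(y) and node
degrees — which keeps them tractable on interactome-scale graphs:

* ``PAC`` (preferential attachment): k_x · k_y.  Rests on the scale-free
  premise that high-degree nodes keep attracting links.
* ``AA`` (Adamic-Adar): Σ_z 1/log(k_z) over common neighbors z; hub
  intermediaries are down-weighted logarithmically.
* ``JC`` (Jaccard): |Γ(x)∩Γ(y)| / |Γ(x)∪Γ(y)| ∈ [0, 1].
* ``RAI`` (resource allocation): Σ_z 1/k_z; penalizes hubs harder
  than AA.

The Adamic-Adar logarithm base is configurable (natural log default;
rankings are invariant to the base, absolute scores are not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import PPINetwork

__all__ = [
    "INDEX_NAMES",
    "PairScore",
    "pac_score",
    "aa_score",
    "jc_score",
    "rai_score",
    "score_pair",
]

#: The closed set of supported index names.
INDEX_NAMES: tuple[str, ...] = ("PAC", "AA", "JC", "RAI")

_LOG_BASES = {"e": math.e, "10": 10.0, "2": 2.0}


def normalize_index(index: str) -> str:
    name = str(index).upper()
    if name not in INDEX_NAMES:
        raise ValueError(
            f"unknown index {index!r}; valid names: {', '.join(INDEX_NAMES)}"
        )
    return name


def resolve_log_base(log_base: str | float) -> float:
    """Map a config value (``'e'``, ``'10'``, ``'2'`` or a float) to a base."""
    if isinstance(log_base, str):
        try:
            return _LOG_BASES[log_base]
        except KeyError:
            raise ValueError(
                f"unknown log base {log_base!r}; expected 'e', '10' or '2'"
            ) from None
    base = float(log_base)
    if base <= 1.0:
        raise ValueError("log base must be > 1")
    return base


@dataclass(frozen=True)
class PairScore:
    """A single similarity score S(x, y) under one index (symmetric in x, y)."""

    x: str
    y: str
    index: str
    score: float


def _check_pair(net: PPINetwork, x: str, y: str) -> None:
    if x == y:
        raise ValueError(f"self-pair: {x!r}")
    net.neighbors(x)  # raises KeyError on unknown nodes
    net.neighbors(y)


def pac_score(net: PPINetwork, x: str, y: str) -> float:
    """Preferential attachment: k_x · k_y."""
    _check_pair(net, x, y)
    return float(net.degree(x) * net.degree(y))


def aa_score(net: PPINetwork, x: str, y: str, log_base: str | float = "e") -> float:
    """Adamic-Adar: Σ over common neighbors z of 1/log(k_z).

    Every common neighbor has degree ≥ 2 (it touches both x and y), so
    the logarithm never vanishes.
    """
    _check_pair(net, x, y)
    base = resolve_log_base(log_base)
    common = net.neighbors(x) & net.neighbors(y)
    return sum(1.0 / math.log(net.degree(z), base) for z in common)


def jc_score(net: PPINetwork, x: str, y: str) -> float:
    """Jaccard: |Γ(x)∩Γ(y)| / |Γ(x)∪Γ(y)|; 0 when the union is empty."""
    _check_pair(net, x, y)
    gx, gy = net.neighbors(x), net.neighbors(y)
    union = gx | gy
    if not union:
        return 0.0
    return len(gx & gy) / len(union)


def rai_score(net: PPINetwork, x: str, y: str) -> float:
    """Resource allocation: Σ over common neighbors z of 1/k_z."""
    _check_pair(net, x, y)
    common = net.neighbors(x) & net.neighbors(y)
    return sum(1.0 / net.degree(z) for z in common)


def score_pair(
    net: PPINetwork, x: str, y: str, index: str, log_base: str | float = "e"
) -> PairScore:
    """Dispatch to the named index; symmetric in (x, y)."""
    name = normalize_index(index)
    if name == "PAC":
        s = pac_score(net, x, y)
    elif name == "AA":
        s = aa_score(net, x, y, log_base=log_base)
    elif name == "JC":
        s = jc_score(net, x, y)
    else:
        s = rai_score(net, x, y)
    return PairScore(x=x, y=y, index=name, score=s)
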