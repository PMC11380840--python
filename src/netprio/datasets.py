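"""Packaged seed-gene lists for the five cancers.

The curated OMIM-derived seed lists (gastric, colorectal, breast,
prostate and lung cancer) ship with the package as plain-text fixtures
so a run can be anchored without any database access.
"""

from __future__ import annotations

from importlib import resources

from .network import SeedSet

__all__ = ["DISEASES", "load_seed_set", "load_all_seed_sets"]

DISEASES = (
    "gastric_cancer",
    "colorectal_cancer",
    "breast_cancer",
    "prostate_cancer",
    "lung_cancer",
)


def load_seed_set(disease: str) -> SeedSet:
    """Load one packaged seed list by disease name (see ``DISEASES``)."""
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}; known: {DISEASES}")
    text = (
        resources.files("netprio.data")
        .joinpath(f"omim_{disease}.txt")
        .read_text()
    )
    genes = tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    return SeedSet(disease_name=disease, genes=genes)


def load_all_seed_sets() -> dict[str, SeedSet]:
    return {d: load_seed_set(d) for d in DISEASES}
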