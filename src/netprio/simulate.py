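"""Synthetic inputs: scale-free PPI graphs with planted disease modules.

The generator emulates the study conditions the pipeline targets:

* a preferential-attachment (Barabási–Albert) growth graph, matching the
  scale-free premise behind degree-based indices;
* disjoint "disease modules" densified by adding each absent
  within-module edge with probability ``p_in`` — the clustered disease
  neighborhood that common-neighbor indices exploit;
* seed/held-out splits of module members (OMIM-style seeds vs a larger
  external validation list);
* validation lists = held-out members plus noise genes (GeneCard-style);
* a GMT annotation collection whose "module terms" are biased toward
  module members, so seed lists are genuinely enriched.

Everything is bit-reproducible from ``rng_seed`` and written in exactly
the text formats the pipeline reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .enrichment import TermAnnotation, enrich, significant_terms, write_gmt
from .network import PPINetwork, SeedSet, write_edge_list

__all__ = ["SyntheticScenario", "ScenarioBundle", "generate_network",
           "split_seeds", "make_validation", "make_gmt",
           "generate_scenario", "write_scenario"]

#: Default module layout: five diseases, sizes 30–50, densities 0.5–0.7.
DEFAULT_MODULES: tuple[tuple[int, float], ...] = (
    (30, 0.50), (35, 0.55), (40, 0.60), (45, 0.65), (50, 0.70),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults mirror a five-disease, small-seed-set regime at desk scale:
    a 1,000-node m=3 preferential-attachment graph, five disjoint
    modules of 30–50 genes with within-module edge probability 0.5–0.7,
    30% of each module used as seeds, validation lists with 30% noise,
    and 200 annotation terms of which a few per module are
    module-biased.
    """

    n_nodes: int = 1000
    attach_m: int = 3
    modules: tuple[tuple[int, float], ...] = DEFAULT_MODULES
    seed_fraction: float = 0.3
    validation_noise: float = 0.3
    n_terms: int = 200
    term_enrichment_bias: float = 25.0
    module_terms_per_module: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.attach_m < 1:
            raise ValueError("need n_nodes >= 2 and attach_m >= 1")
        if sum(s for s, _ in self.modules) > self.n_nodes:
            raise ValueError("module sizes exceed n_nodes")
        for size, p_in in self.modules:
            if not (0.0 < p_in <= 1.0):
                raise ValueError(f"p_in out of (0, 1]: {p_in}")
            if size < 2:
                raise ValueError("modules need at least 2 genes")
        if not (0.0 < self.seed_fraction < 1.0):
            raise ValueError("seed_fraction must be in (0, 1)")
        if not (0.0 <= self.validation_noise < 1.0):
            raise ValueError("validation_noise must be in [0, 1)")
        if self.term_enrichment_bias < 1.0:
            raise ValueError("term_enrichment_bias must be >= 1")


def _gene_name(i: int) -> str:
    return f"G{i + 1:06d}"


def generate_network(
    scn: SyntheticScenario,
) -> tuple[PPINetwork, dict[str, tuple[str, ...]]]:
    """Grow the scale-free base graph and densify the planted modules.

    The base graph is Barabási–Albert growth (m isolated seed nodes,
    every later node attaches ``attach_m`` edges preferentially), giving
    ``attach_m · (n_nodes − attach_m)`` base edges.  Module members are
    drawn disjointly at random; each absent within-module edge is then
    added independently with that module's ``p_in``.  Deterministic
    under ``rng_seed``.
    """
    rng = np.random.default_rng(scn.rng_seed)
    g = nx.barabasi_albert_graph(
        scn.n_nodes, scn.attach_m, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})

    all_nodes = sorted(g.nodes)
    total = sum(s for s, _ in scn.modules)
    chosen = rng.choice(len(all_nodes), size=total, replace=False)
    modules: dict[str, tuple[str, ...]] = {}
    pos = 0
    for mi, (size, p_in) in enumerate(scn.modules):
        members = sorted(all_nodes[j] for j in chosen[pos:pos + size])
        pos += size
        modules[f"disease_{mi + 1}"] = tuple(members)
        for a in range(size):
            for b in range(a + 1, size):
                u, v = members[a], members[b]
                if not g.has_edge(u, v) and rng.random() < p_in:
                    g.add_edge(u, v)
    return PPINetwork(g), modules


def split_seeds(
    module_genes: Sequence[str],
    seed_fraction: float,
    rng_seed: int,
    disease_name: str = "disease",
) -> tuple[SeedSet, set[str]]:
    """Split a module into seed genes and held-out genes.

    ``|seeds| = max(1, round(seed_fraction · |module|))``, clamped so at
    least one gene stays held out.
    """
    if not (0.0 < seed_fraction < 1.0):
        raise ValueError("seed_fraction must be in (0, 1)")
    genes = sorted(module_genes)
    if len(genes) < 2:
        raise ValueError("module must contain at least 2 genes to split")
    n_seed = max(1, min(len(genes) - 1, round(seed_fraction * len(genes))))
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(genes), size=n_seed, replace=False)
    seeds = tuple(genes[i] for i in sorted(idx))
    held = set(genes) - set(seeds)
    return SeedSet(disease_name=disease_name, genes=seeds), held


def make_validation(
    held_out: Iterable[str],
    universe: Iterable[str],
    noise: float,
    rng_seed: int,
) -> set[str]:
    """Held-out module genes plus ``round(noise·|held_out|)`` decoys.

    Decoys are drawn uniformly from ``universe`` minus the held-out set;
    pass a universe excluding module members to keep decoys module-free.
    """
    if not (0.0 <= noise < 1.0):
        raise ValueError("noise must be in [0, 1)")
    held = set(held_out)
    pool = sorted(set(universe) - held)
    n_extra = min(len(pool), round(noise * len(held)))
    rng = np.random.default_rng(rng_seed)
    extra = {pool[i] for i in rng.choice(len(pool), size=n_extra, replace=False)}
    return held | extra


def make_gmt(
    modules: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    n_terms: int,
    bias: float,
    rng_seed: int,
    module_terms_per_module: int = 3,
    alpha: float = 0.05,
    max_retries: int = 20,
    guarantee_queries: Mapping[str, Sequence[str]] | None = None,
) -> list[TermAnnotation]:
    """Generate an annotation collection enriched in the planted modules.

    ``module_terms_per_module`` terms per module draw their genes with
    sampling weight ``bias`` for that module's members (weight 1
    elsewhere); the remaining terms are uniform.  The collection is
    resampled (bounded retries) until every guarantee query — by default
    each module's full gene list, in a scenario run each disease's seed
    list — shows at least one Bonferroni-significant term at ``alpha``.
    """
    if bias < 1.0:
        raise ValueError("bias must be >= 1")
    uni = sorted(universe)
    n_module_terms = module_terms_per_module * len(modules)
    if n_terms < n_module_terms:
        raise ValueError("n_terms smaller than the number of module terms")
    rng = np.random.default_rng(rng_seed)

    def draw() -> list[TermAnnotation]:
        terms: list[TermAnnotation] = []
        tid = 0
        for name, members in modules.items():
            member_set = set(members)
            w = np.array([bias if g in member_set else 1.0 for g in uni])
            w = w / w.sum()
            for _ in range(module_terms_per_module):
                size = int(rng.integers(15, 31))
                picks = rng.choice(len(uni), size=size, replace=False, p=w)
                tid += 1
                terms.append(TermAnnotation(
                    term_id=f"T{tid:04d}",
                    term_name=f"module term ({name})",
                    genes=frozenset(uni[i] for i in picks),
                ))
        while tid < n_terms:
            size = int(rng.integers(5, 41))
            picks = rng.choice(len(uni), size=size, replace=False)
            tid += 1
            terms.append(TermAnnotation(
                term_id=f"T{tid:04d}", term_name="background term",
                genes=frozenset(uni[i] for i in picks),
            ))
        return terms

    queries = guarantee_queries if guarantee_queries is not None else modules
    for _ in range(max_retries):
        terms = draw()
        ok = all(
            significant_terms(enrich(list(q), terms, alpha=alpha))
            for q in queries.values()
        )
        if ok:
            return terms
    raise RuntimeError(
        f"no module-enriched collection after {max_retries} retries; "
        f"increase term_enrichment_bias (currently {bias})"
    )


@dataclass
class ScenarioBundle:
    """Everything one synthetic study produces, in memory."""

    scenario: SyntheticScenario
    network: PPINetwork
    modules: dict[str, tuple[str, ...]]
    seed_sets: dict[str, SeedSet]
    held_out: dict[str, set[str]]
    validations: dict[str, set[str]]
    terms: list[TermAnnotation] = field(default_factory=list)


def generate_scenario(scn: SyntheticScenario) -> ScenarioBundle:
    """Run every generator stage with seeds derived from ``scn.rng_seed``."""
    rng = np.random.default_rng(scn.rng_seed)
    child = lambda: int(rng.integers(2**31))  # noqa: E731
    net, modules = generate_network(scn)
    seed_sets: dict[str, SeedSet] = {}
    held_out: dict[str, set[str]] = {}
    validations: dict[str, set[str]] = {}
    for name, members in modules.items():
        seeds, held = split_seeds(members, scn.seed_fraction, child(),
                                  disease_name=name)
        seed_sets[name] = seeds
        held_out[name] = held
        validations[name] = make_validation(
            held, net.nodes - set(members), scn.validation_noise, child()
        )
    terms = make_gmt(
        modules, sorted(net.nodes), scn.n_terms, scn.term_enrichment_bias,
        child(), module_terms_per_module=scn.module_terms_per_module,
        guarantee_queries={d: s.genes for d, s in seed_sets.items()},
    )
    return ScenarioBundle(
        scenario=scn, network=net, modules=modules, seed_sets=seed_sets,
        held_out=held_out, validations=validations, terms=terms,
    )


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's external formats.

    Emits ``network.tsv``, per-disease ``<name>_seeds.txt`` and
    ``<name>_validation.txt``, ``terms.gmt`` and ``truth.json`` (module
    assignments, for tests).  Returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["network"] = outdir / "network.tsv"
    write_edge_list(bundle.network, paths["network"])

    for name, seeds in bundle.seed_sets.items():
        p = outdir / f"{name}_seeds.txt"
        p.write_text("".join(f"{g}\n" for g in seeds.genes))
        paths[f"{name}_seeds"] = p
        v = outdir / f"{name}_validation.txt"
        v.write_text("".join(f"{g}\n" for g in sorted(bundle.validations[name])))
        paths[f"{name}_validation"] = v

    paths["gmt"] = outdir / "terms.gmt"
    write_gmt(bundle.terms, paths["gmt"])

    truth = {
        "rng_seed": bundle.scenario.rng_seed,
        "modules": {n: sorted(m) for n, m in bundle.modules.items()},
        "held_out": {n: sorted(h) for n, h in bundle.held_out.items()},
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
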