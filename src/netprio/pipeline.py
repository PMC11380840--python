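"""End-to-end pipeline: network + seeds -> ranked lists, ensemble, metrics.

All randomness lives in the synthetic generator; given fixed input files
the pipeline is fully deterministic, and a rerun with the same config
produces byte-identical outputs (the manifest records a config hash and
per-file checksums, no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .enrichment import go_assessment, read_gmt
from .ensemble import SMVGeneList, build_all_smv
from .evaluation import evaluate_run
from .indices import INDEX_NAMES
from .network import read_edge_list, read_gene_list
from .ranking import RankedGeneList, build_all_lists

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "write_ranked_list", "write_smv_list"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one prioritization run."""

    network: Path
    seeds: dict[str, Path]                  # disease name -> seed list file
    outdir: Path
    indices: tuple[str, ...] = INDEX_NAMES
    ks: tuple[int, ...] = (10, 50, 100)
    zero_policy: str = "exclude"
    log_base: str = "e"
    validations: dict[str, Path] = field(default_factory=dict)
    gmt: Path | None = None
    alpha: float = 0.05
    universe_policy: str = "network_minus_seeds"
    strict_fn: bool = False
    network_dialect: str = "tsv"

    def __post_init__(self) -> None:
        self.network = Path(self.network)
        self.outdir = Path(self.outdir)
        self.seeds = {d: Path(p) for d, p in self.seeds.items()}
        self.validations = {d: Path(p) for d, p in self.validations.items()}
        self.gmt = Path(self.gmt) if self.gmt else None
        self.ks = tuple(sorted(int(k) for k in self.ks))
        if not self.seeds:
            raise ValueError("config lists no seed files")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for p in [self.network, *self.seeds.values(),
                  *self.validations.values(),
                  *( [self.gmt] if self.gmt else [] )]:
            if not p.exists():
                raise FileNotFoundError(f"config references missing file: {p}")

    @classmethod
    def from_mapping(cls, cfg: dict, base: Path | None = None) -> "RunConfig":
        """Build from a parsed YAML/JSON mapping; paths relative to ``base``."""
        base = Path(base) if base else Path.cwd()
        rel = lambda p: base / p  # noqa: E731
        return cls(
            network=rel(cfg["network"]),
            seeds={d: rel(p) for d, p in cfg["seeds"].items()},
            outdir=rel(cfg["outdir"]),
            indices=tuple(cfg.get("indices", INDEX_NAMES)),
            ks=tuple(cfg.get("ks", (10, 50, 100))),
            zero_policy=cfg.get("zero_policy", "exclude"),
            log_base=str(cfg.get("log_base", "e")),
            validations={d: rel(p) for d, p in cfg.get("validations", {}).items()},
            gmt=rel(cfg["gmt"]) if cfg.get("gmt") else None,
            alpha=float(cfg.get("alpha", 0.05)),
            universe_policy=cfg.get("universe_policy", "network_minus_seeds"),
            strict_fn=bool(cfg.get("strict_fn", False)),
            network_dialect=cfg.get("network_dialect", "tsv"),
        )

    def config_hash(self) -> str:
        payload = json.dumps({
            "network": str(self.network), "seeds": {d: str(p) for d, p in self.seeds.items()},
            "indices": list(self.indices), "ks": list(self.ks),
            "zero_policy": self.zero_policy, "log_base": self.log_base,
            "validations": {d: str(p) for d, p in self.validations.items()},
            "gmt": str(self.gmt) if self.gmt else None, "alpha": self.alpha,
            "universe_policy": self.universe_policy, "strict_fn": self.strict_fn,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def write_ranked_list(rl: RankedGeneList, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("rank\tgene\tscore\n")
        for i, (gene, score) in enumerate(rl.genes, start=1):
            fh.write(f"{i}\t{gene}\t{score:.6g}\n")


def write_smv_list(sl: SMVGeneList, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("gene\tvotes\tcontributing_indices\n")
        for gene, votes in sl.members:
            fh.write(f"{gene}\t{votes}\t{','.join(sl.supporters[gene])}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full flow and return the run directory.

    Writes per-index ranked lists, SMV lists, ``metrics.tsv`` /
    ``roc.tsv`` / ``auc.tsv`` when validations are given,
    ``go_metrics.tsv`` / ``go_auc.tsv`` when a GMT is given, and a
    ``manifest.json`` with the config hash and file checksums.  On any
    stage failure a ``.partial`` marker is left in the run directory and
    a :class:`PipelineError` naming the stage is raised.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".partial"
    marker.write_text("run in progress or aborted\n")
    written: list[Path] = []
    stage = "load"
    try:
        net = read_edge_list(cfg.network, dialect=cfg.network_dialect)
        seed_sets = {d: read_gene_list(p, d) for d, p in sorted(cfg.seeds.items())}

        stage = "rank"
        ranked = build_all_lists(
            net, list(seed_sets.values()), list(cfg.indices), list(cfg.ks),
            zero_policy=cfg.zero_policy, log_base=cfg.log_base,
        )
        for rl in ranked:
            p = outdir / f"{rl.disease_name}_{rl.index.lower()}_{rl.k}.tsv"
            write_ranked_list(rl, p)
            written.append(p)

        stage = "smv"
        smv = build_all_smv(ranked)
        for sl in smv:
            p = outdir / f"{sl.disease_name}_smv_{sl.k}.tsv"
            write_smv_list(sl, p)
            written.append(p)

        if cfg.validations:
            stage = "evaluate"
            validations = {
                d: set(read_gene_list(p, d).genes)
                for d, p in cfg.validations.items()
            }
            ev = evaluate_run(
                ranked, smv, validations, net, seed_sets,
                universe_policy=cfg.universe_policy, strict=cfg.strict_fn,
            )
            for name, frame in [("metrics.tsv", ev.metrics),
                                ("roc.tsv", ev.roc_points),
                                ("auc.tsv", ev.auc)]:
                p = outdir / name
                frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
                written.append(p)

        if cfg.gmt:
            stage = "go-eval"
            terms = read_gmt(cfg.gmt)
            gv = go_assessment(seed_sets, ranked, smv, terms, alpha=cfg.alpha)
            for name, frame in [("go_metrics.tsv", gv.metrics),
                                ("go_roc.tsv", gv.roc_points),
                                ("go_auc.tsv", gv.auc)]:
                p = outdir / name
                frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
                written.append(p)

        stage = "manifest"
        manifest = {
            "tool": "netprio",
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "n_ranked_lists": len(ranked),
            "n_smv_lists": len(smv),
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    marker.unlink(missing_ok=True)
    return outdir
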