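"""Over-representation analysis (ORA) and term-overlap assessment.

A gene list is tested for over-representation in each annotation term
with the one-sided hypergeometric tail P(X >= overlap), Bonferroni-
corrected over the number of tested terms; a term is significant when
the adjusted p-value is strictly below alpha (default 0.05).

The term-overlap assessment mirrors the gene-level evaluation one level
up: the significant terms of the seed list act as the validation set and
the significant terms of each predicted gene list are scored against it
with the same precision/recall/F-measure and ROC machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .ensemble import SMVGeneList
from .evaluation import EvaluationResult, OverlapResult, roc_from_cutoffs
from .network import SeedSet
from .ranking import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["TermAnnotation", "EnrichmentResult", "read_gmt", "write_gmt",
           "hypergeom_p", "enrich", "term_overlap_eval", "go_assessment"]


@dataclass(frozen=True)
class TermAnnotation:
    """One gene set (e.g. a GO term) from a GMT collection."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric ORA outcome for one term."""

    term_id: str
    overlap_count: int
    query_size: int
    term_size: int
    background_size: int
    p_raw: float
    p_adjusted: float
    significant: bool


def read_gmt(path: str | Path) -> list[TermAnnotation]:
    """Read a GMT file: ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Genes are deduplicated within a line; zero-gene lines are dropped
    with a warning; a repeated term_id is an error.
    """
    path = Path(path)
    terms: list[TermAnnotation] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed GMT row at line {lineno}")
            term_id, name = fields[0].strip(), fields[1].strip()
            if term_id in seen:
                raise ValueError(f"{path}: duplicate term_id {term_id!r}")
            seen.add(term_id)
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("%s: line %d (%s) has no genes; dropped",
                               path, lineno, term_id)
                continue
            terms.append(TermAnnotation(term_id=term_id, term_name=name, genes=genes))
    if not terms:
        raise ValueError(f"{path}: empty GMT file")
    return terms


def write_gmt(terms: Sequence[TermAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")


def hypergeom_p(overlap: int, query_size: int, term_size: int,
                background_size: int) -> float:
    """Exact upper-tail hypergeometric p-value P(X >= overlap).

    X counts term members in a query of ``query_size`` genes drawn
    without replacement from ``background_size`` genes of which
    ``term_size`` carry the annotation.
    """
    if not (0 <= overlap <= min(query_size, term_size) <= background_size):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, query={query_size}, "
            f"term={term_size}, background={background_size}"
        )
    if query_size > background_size:
        raise ValueError("query_size exceeds background_size")
    # sf(k-1) = P(X >= k), exact for these sizes
    return float(min(1.0, hypergeom.sf(overlap - 1, background_size,
                                       term_size, query_size)))


def enrich(
    query: Iterable[str],
    terms: Sequence[TermAnnotation],
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Bonferroni-corrected hypergeometric ORA of a gene list.

    The background defaults to the union of all annotated genes; the
    query is intersected with the background before testing, so genes
    without any annotation never affect the result.  Only terms with at
    least one in-background gene are tested; significance requires
    ``p_adjusted < alpha`` (strict).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    bg = set(background) if background is not None else set().union(
        *(t.genes for t in terms)
    )
    q = set(query) & bg
    if not q:
        raise ValueError("query not annotated: no query gene in background")

    tested = [(t, t.genes & bg) for t in terms]
    tested = [(t, tg) for t, tg in tested if tg]
    n_tests = len(tested)
    out = []
    for t, tg in tested:
        ov = len(q & tg)
        p = hypergeom_p(ov, len(q), len(tg), len(bg))
        p_adj = min(1.0, p * n_tests)
        out.append(EnrichmentResult(
            term_id=t.term_id, overlap_count=ov, query_size=len(q),
            term_size=len(tg), background_size=len(bg),
            p_raw=p, p_adjusted=p_adj, significant=p_adj < alpha,
        ))
    return out


def significant_terms(results: Sequence[EnrichmentResult]) -> set[str]:
    return {r.term_id for r in results if r.significant}


def term_overlap_eval(
    predicted_terms: Iterable[str],
    validation_terms: Iterable[str],
    collection_size: int,
) -> OverlapResult:
    """Confusion counts of predicted vs validation term sets.

    ``collection_size`` (the number of terms in the annotation
    collection) fixes the TN count.
    """
    val = set(validation_terms)
    if not val:
        raise ValueError("no disease-related terms: empty validation set")
    pred = set(predicted_terms)
    tp = len(pred & val)
    fp = len(pred - val)
    fn = len(val - pred)
    tn = collection_size - tp - fp - fn
    if tn < 0:
        raise ValueError("collection_size smaller than the union of term sets")
    return OverlapResult(tp=tp, fp=fp, fn=fn, tn=tn)


def go_assessment(
    seed_sets: Mapping[str, SeedSet],
    ranked_lists: Sequence[RankedGeneList],
    smv_lists: Sequence[SMVGeneList],
    terms: Sequence[TermAnnotation],
    alpha: float = 0.05,
) -> EvaluationResult:
    """Term-level assessment of every gene list against seed-derived terms.

    For each disease the significant terms of its seed list form the
    validation term set; the significant terms of each per-index and
    ensemble list are then scored with precision/recall/F-measure, and
    ROC/AUC is computed over the k cutoffs.  SB/SW flags mirror the
    gene-level evaluation.
    """
    validation_terms: dict[str, set[str]] = {}
    for disease, seeds in seed_sets.items():
        sig = significant_terms(enrich(seeds.genes, terms, alpha=alpha))
        if not sig:
            raise ValueError(
                f"seed list for {disease!r} yields zero significant terms at "
                f"alpha={alpha}; in synthetic settings increase the term bias "
                f"or raise alpha"
            )
        validation_terms[disease] = sig

    n_terms = len(terms)
    per_dm: dict[tuple[str, str], list[tuple[int, OverlapResult]]] = {}
    rows = []

    def eval_one(disease: str, method: str, k: int, symbols: Sequence[str]):
        try:
            pred = significant_terms(enrich(symbols, terms, alpha=alpha))
        except ValueError:  # list entirely unannotated -> no terms inferred
            pred = set()
        res = term_overlap_eval(pred, validation_terms[disease], n_terms)
        rows.append({
            "disease": disease, "method": method, "k": k,
            "n_predicted_terms": len(pred),
            "n_validation_terms": len(validation_terms[disease]),
            "tp": res.tp, "fp": res.fp, "fn": res.fn, "tn": res.tn,
            "precision": res.precision, "recall": res.recall,
            "f_measure": res.f_measure,
        })
        per_dm.setdefault((disease, method), []).append((k, res))

    for l in ranked_lists:
        eval_one(l.disease_name, l.index, l.k, list(l.symbols))
    for l in smv_lists:
        eval_one(l.disease_name, "SMV", l.k, list(l.symbols))

    metrics = pd.DataFrame(rows)
    metrics["single_best"] = False
    metrics["single_worst"] = False
    lsi = metrics["method"] != "SMV"
    for (_, _), grp in metrics[lsi].groupby(["disease", "k"]):
        metrics.loc[grp.index[grp["f_measure"] == grp["f_measure"].max()],
                    "single_best"] = True
        metrics.loc[grp.index[grp["f_measure"] == grp["f_measure"].min()],
                    "single_worst"] = True

    roc_rows, auc_rows = [], []
    for (disease, method), krs in sorted(per_dm.items()):
        krs.sort(key=lambda kr: kr[0])
        try:
            curve = roc_from_cutoffs([r for _, r in krs], [k for k, _ in krs])
        except ValueError:
            continue
        for fpr, tpr in curve.points:
            roc_rows.append({"disease": disease, "method": method,
                             "fpr": fpr, "tpr": tpr})
        auc_rows.append({"disease": disease, "method": method, "auc": curve.auc})

    metrics = metrics.sort_values(["disease", "method", "k"]).reset_index(drop=True)
    return EvaluationResult(
        metrics=metrics,
        roc_points=pd.DataFrame(roc_rows),
        auc=pd.DataFrame(auc_rows),
    )
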