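"""Overlap evaluation of predicted gene (or term) lists.

A predicted list is scored against a validation list over an explicit
universe: TP = predicted ∩ validation, FP = predicted \\ validation,
FN = validation \\ predicted, TN = the rest of the universe.  Precision,
recall and F-measure follow the usual definitions

    P = TP/(TP+FP),  R = TP/(TP+FN),  F = 2·P·R/(P+R)

with zero substituted for any 0/0 (the conservative convention).  ROC
curves are built from the overlap counts at the successive rank cutoffs,
with the trivial endpoints (0,0) and (1,1) appended and AUC by the
trapezoidal rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import SMVGeneList
from .network import PPINetwork, SeedSet
from .ranking import RankedGeneList

__all__ = ["OverlapResult", "ROCCurve", "overlap", "roc_from_cutoffs",
           "build_universe", "evaluate_run", "EvaluationResult"]

UNIVERSE_POLICIES = ("network_minus_seeds", "network", "predicted_union_validation")


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


@dataclass(frozen=True)
class OverlapResult:
    """Confusion counts and derived metrics for one predicted list."""

    tp: int
    fp: int
    fn: int
    tn: int
    #: validation genes outside the universe (a ranking over the universe
    #: can never recover them); counted as FN only in strict mode.
    unreachable: int = 0

    @property
    def precision(self) -> float:
        return _safe_div(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return _safe_div(2.0 * p * r, p + r)

    @property
    def tpr(self) -> float:
        return self.recall

    @property
    def fpr(self) -> float:
        return _safe_div(self.fp, self.fp + self.tn)


def overlap(
    predicted: Sequence[str],
    validation: Iterable[str],
    universe: Iterable[str],
    strict: bool = False,
) -> OverlapResult:
    """Confusion counts of a predicted list against a validation list.

    ``predicted`` must lie inside ``universe``.  Validation genes outside
    the universe are reported as ``unreachable`` and excluded from FN
    unless ``strict`` is set.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    pred = set(predicted)
    stray = pred - uni
    if stray:
        raise ValueError(f"predicted genes outside universe: {sorted(stray)[:5]}")
    val_all = set(validation)
    val = val_all & uni
    unreachable = len(val_all - uni)
    tp = len(pred & val)
    fp = len(pred - val)
    fn = len(val - pred) + (unreachable if strict else 0)
    tn = len(uni) - tp - fp - len(val - pred)
    return OverlapResult(tp=tp, fp=fp, fn=fn, tn=tn, unreachable=unreachable)


@dataclass(frozen=True)
class ROCCurve:
    """Piecewise-linear ROC through the rank-cutoff operating points."""

    points: tuple[tuple[float, float], ...]  # (FPR, TPR), endpoints included
    auc: float
    cutoffs: tuple[int, ...] = field(default_factory=tuple)


def roc_from_cutoffs(
    results: Sequence[OverlapResult], cutoffs: Sequence[int] = ()
) -> ROCCurve:
    """ROC/AUC from overlap results at ascending rank cutoffs.

    Each result contributes an interior point (FPR_k, TPR_k); (0,0) and
    (1,1) are appended and AUC is the trapezoidal area over the
    FPR-sorted polyline.
    """
    if not results:
        raise ValueError("need at least one interior overlap result")
    pts = []
    for r in results:
        if r.tp + r.fn == 0 or r.fp + r.tn == 0:
            raise ValueError("degenerate validation/universe: empty class")
        pts.append((r.fpr, r.tpr))
    pts = sorted(set(pts + [(0.0, 0.0), (1.0, 1.0)]))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=tuple(pts), auc=auc, cutoffs=tuple(cutoffs))


def build_universe(
    net: PPINetwork,
    seeds: SeedSet,
    validation: Iterable[str],
    policy: str = "network_minus_seeds",
    predicted: Iterable[str] = (),
) -> set[str]:
    """The negative-class universe for one disease.

    Default policy: all network nodes minus the in-network seed genes,
    plus validation genes present in the network (so a seed that is also
    a validation gene stays countable).
    """
    if policy not in UNIVERSE_POLICIES:
        raise ValueError(f"unknown universe policy {policy!r}")
    nodes = net.nodes
    val_in = set(validation) & nodes
    if policy == "network":
        return nodes
    if policy == "predicted_union_validation":
        return set(predicted) | val_in
    return (nodes - set(seeds.genes)) | val_in


@dataclass
class EvaluationResult:
    """Tables produced by a full evaluation run."""

    metrics: pd.DataFrame     # disease, method, k, tp..f_measure, SB/SW flags
    roc_points: pd.DataFrame  # disease, method, fpr, tpr
    auc: pd.DataFrame         # disease, method, auc


def evaluate_run(
    ranked_lists: Sequence[RankedGeneList],
    smv_lists: Sequence[SMVGeneList],
    validations: Mapping[str, Iterable[str]],
    net: PPINetwork,
    seed_sets: Mapping[str, SeedSet],
    universe_policy: str = "network_minus_seeds",
    strict: bool = False,
) -> EvaluationResult:
    """Evaluate every per-index and ensemble list against its validation set.

    Produces one metrics row per (disease, method, k) — methods are the
    four indices plus ``SMV`` — and ROC/AUC rows per (disease, method)
    across the k cutoffs.  The single best (SB) and single worst (SW)
    index per (disease, k) are flagged by F-measure.
    """
    diseases = {l.disease_name for l in ranked_lists} | {
        l.disease_name for l in smv_lists
    }
    missing = sorted(d for d in diseases if d not in validations)
    if missing:
        raise ValueError(f"missing validation set for disease(s): {missing}")

    per_dm: dict[tuple[str, str], list[tuple[int, OverlapResult]]] = {}
    rows = []

    def eval_one(disease: str, method: str, k: int, symbols: Sequence[str]):
        val = set(validations[disease])
        uni = build_universe(
            net, seed_sets[disease], val, policy=universe_policy,
            predicted=symbols,
        )
        res = overlap(symbols, val, uni, strict=strict)
        rows.append({
            "disease": disease, "method": method, "k": k,
            "n_predicted": len(symbols),
            "tp": res.tp, "fp": res.fp, "fn": res.fn, "tn": res.tn,
            "unreachable_validation": res.unreachable,
            "precision": res.precision, "recall": res.recall,
            "f_measure": res.f_measure,
        })
        per_dm.setdefault((disease, method), []).append((k, res))

    for l in ranked_lists:
        eval_one(l.disease_name, l.index, l.k, l.symbols)
    for l in smv_lists:
        eval_one(l.disease_name, "SMV", l.k, l.symbols)

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
            continue  # degenerate (empty positive/negative class)
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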