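"""Filter accuracy against truth labels and crude-vs-refined concordance.

When call sets carry truth labels (simulation, or validated data), the
germline-exclusion filter can be scored exactly: true somatic calls
kept (TP), germline/artifact calls kept (FP), somatic removed (FN) and
germline removed (TN).  Enrichment screens run on the crude
(panel-filtered) and refined (matched-normal subtracted) call sets are
compared by counting units significant in each and in both, and cohort
mutation proportions are compared with the two-sample test for
equality of proportions (pooled-variance chi-square, Yates continuity
correction on by default).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult
from .variants import CallSet

__all__ = [
    "ConfusionSummary",
    "confusion_vs_truth",
    "sum_confusions",
    "compare_enrichment_results",
    "proportion_equality_test",
]

_SOMATIC = "somatic"
_NEGATIVE = {"germline", "artifact"}


@dataclasses.dataclass(frozen=True)
class ConfusionSummary:
    """Set-partition counts of a filter's output against truth labels."""

    sample_id: str
    tp: int  # somatic kept
    fp: int  # germline/artifact kept
    fn: int  # somatic removed
    tn: int  # germline/artifact removed

    @property
    def n_kept(self) -> int:
        return self.tp + self.fp

    @property
    def n_input(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def fp_fraction_kept(self) -> float:
        return self.fp / self.n_kept if self.n_kept else float("nan")


def confusion_vs_truth(kept: CallSet, candidates: CallSet) -> ConfusionSummary:
    """Score a filtered call set against the labeled candidate list.

    ``candidates`` is the pre-filter list with a truth label on every
    call; ``kept`` is the filter's output (must be a subset).  Counts
    are conserved: kept + removed = input size.
    """
    if not kept.variants <= candidates.variants:
        extra = next(iter(kept.variants - candidates.variants))
        raise ValueError(f"kept call {extra} absent from the candidate list")
    tp = fp = fn = tn = 0
    for v in candidates.variants:
        label = candidates.attrs.get(v, {}).get("label")
        if label == _SOMATIC:
            positive = True
        elif label in _NEGATIVE:
            positive = False
        else:
            raise ValueError(f"candidate call {v} has no truth label")
        if v in kept.variants:
            tp += positive
            fp += not positive
        else:
            fn += positive
            tn += not positive
    return ConfusionSummary(sample_id=candidates.sample_id, tp=tp, fp=fp, fn=fn, tn=tn)


def sum_confusions(confusions: Iterable[ConfusionSummary]) -> ConfusionSummary:
    cs = list(confusions)
    return ConfusionSummary(
        sample_id="cohort",
        tp=sum(c.tp for c in cs),
        fp=sum(c.fp for c in cs),
        fn=sum(c.fn for c in cs),
        tn=sum(c.tn for c in cs),
    )


def _alpha_for(kind: str, alpha_gene: float, alpha_pathway: float) -> float:
    return alpha_pathway if kind == "pathway" else alpha_gene


def compare_enrichment_results(
    crude: Sequence[EnrichmentResult],
    refined: Sequence[EnrichmentResult],
    alpha_gene: float = 0.02,
    alpha_pathway: float = 0.05,
) -> pd.DataFrame:
    """Crude / refined / overlap counts of significant units, by kind.

    Genes and domains are thresholded at ``alpha_gene`` and pathways at
    ``alpha_pathway``.  A Spearman rank correlation between crude and
    refined p-values over the shared unit universe is reported as a
    concordance diagnostic (an addition beyond the headline counts).
    """
    rows = []
    kinds = sorted({r.kind for r in list(crude) + list(refined)})
    for kind in kinds:
        a = _alpha_for(kind, alpha_gene, alpha_pathway)
        pc = {r.unit_id: r.p_value for r in crude if r.kind == kind}
        pr = {r.unit_id: r.p_value for r in refined if r.kind == kind}
        sig_c = {u for u, p in pc.items() if p < a}
        sig_r = {u for u, p in pr.items() if p < a}
        both = sig_c & sig_r
        common = sorted(set(pc) & set(pr))
        if len(common) >= 3:
            rho = float(
                stats.spearmanr([pc[u] for u in common], [pr[u] for u in common]).statistic
            )
        else:
            rho = float("nan")
        rows.append(
            (
                kind,
                len(sig_c),
                len(sig_r),
                len(both),
                len(sig_c - sig_r),
                len(sig_r - sig_c),
                rho,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "n_crude",
            "n_refined",
            "n_overlap",
            "n_crude_only",
            "n_refined_only",
            "spearman_rho",
        ],
    )


def proportion_equality_test(
    x1: int, n1: int, x2: int, n2: int, continuity_correction: bool = True
) -> tuple[float, float]:
    """Two-sample test for equality of proportions (pooled chi-square).

    Returns (chi-square statistic, two-sided p).  The Yates continuity
    correction is on by default, matching the usual R convention; with
    identical proportions and the correction off the statistic is 0 and
    p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= x <= n):
            raise ValueError("successes must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)
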