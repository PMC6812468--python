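"""Best-match scoring of predicted orthologous groups against a reference.

Each reference group is matched to the predicted group sharing the most genes
with it; precision is shared/|predicted| and recall shared/|reference| for
that match.  Macro averages (unweighted means over reference groups) are the
headline numbers; micro averages (pooled counts) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .clustering import OrthoGroup

__all__ = ["GroupComparison", "EvaluationSummary", "best_match_scores"]


@dataclass(frozen=True)
class GroupComparison:
    """One reference group scored against its best-matching prediction."""

    reference_id: str
    best_predicted_id: Optional[str]
    shared: int
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


@dataclass(frozen=True)
class EvaluationSummary:
    comparisons: Tuple[GroupComparison, ...]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float


def best_match_scores(
    reference: Sequence[OrthoGroup], predicted: Sequence[OrthoGroup]
) -> EvaluationSummary:
    """Score predictions by best-match overlap with every reference group.

    The best match maximizes the shared-gene count; ties prefer the higher
    precision (smaller predicted group), then the smaller group, then the id.
    Genes absent from any prediction simply reduce recall.
    """
    if not reference:
        raise ValueError("reference group set must be non-empty")

    gene_to_pred: Dict[str, List[OrthoGroup]] = {}
    for pg in predicted:
        for gene in pg.members:
            gene_to_pred.setdefault(gene, []).append(pg)

    comparisons: List[GroupComparison] = []
    total_shared = 0
    total_pred_size = 0
    total_ref_size = 0
    for rg in reference:
        overlap: Dict[str, int] = {}
        pred_by_id: Dict[str, OrthoGroup] = {}
        for gene in rg.members:
            for pg in gene_to_pred.get(gene, ()):
                overlap[pg.group_id] = overlap.get(pg.group_id, 0) + 1
                pred_by_id[pg.group_id] = pg
        if overlap:
            best_id = min(
                overlap,
                key=lambda gid: (
                    -overlap[gid],
                    -overlap[gid] / len(pred_by_id[gid].members),
                    len(pred_by_id[gid].members),
                    gid,
                ),
            )
            shared = overlap[best_id]
            pred_size = len(pred_by_id[best_id].members)
            comparisons.append(
                GroupComparison(
                    reference_id=rg.group_id,
                    best_predicted_id=best_id,
                    shared=shared,
                    precision=shared / pred_size,
                    recall=shared / len(rg.members),
                )
            )
            total_shared += shared
            total_pred_size += pred_size
        else:
            comparisons.append(
                GroupComparison(
                    reference_id=rg.group_id,
                    best_predicted_id=None,
                    shared=0,
                    precision=0.0,
                    recall=0.0,
                )
            )
        total_ref_size += len(rg.members)

    n = len(comparisons)
    return EvaluationSummary(
        comparisons=tuple(comparisons),
        macro_precision=sum(c.precision for c in comparisons) / n,
        macro_recall=sum(c.recall for c in comparisons) / n,
        macro_f1=sum(c.f1 for c in comparisons) / n,
        micro_precision=(total_shared / total_pred_size) if total_pred_size else 0.0,
        micro_recall=(total_shared / total_ref_size) if total_ref_size else 0.0,
    )
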