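"""Six-way read categorization and micro-averaged rank-level metrics.

Every evaluated read falls into exactly one category at a given rank:

- TP: classified to the true taxon (after lifting both truth and
  prediction to the rank under consideration);
- VP (vague positive): classified to a strict ancestor of the truth above
  that rank — informative but not rank-correct;
- FP: the read is from the index but lands on a wrong node at or above the
  rank (ancestors of the truth excluded);
- FP* (strict false positive): the read is not from the index at all but
  was assigned some taxon;
- FN: from the index but reported unclassified;
- TN: not from the index and correctly unclassified.

PPV = TP/(TP+FP+FP*) and sensitivity = TP/(TP+FP+FN+VP); VPs reduce
sensitivity but never PPV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .taxonomy import Taxonomy

CATEGORIES = ("TP", "VP", "FP", "FP_STRICT", "FN", "TN")


@dataclass
class CategoryCounts:
    rank: str
    TP: int = 0
    VP: int = 0
    FP: int = 0
    FP_STRICT: int = 0
    FN: int = 0
    TN: int = 0

    def add(self, category: str) -> None:
        setattr(self, category, getattr(self, category) + 1)

    @property
    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self) if f.name != "rank")


def categorize_read(
    true_taxon: int | None,
    predicted_taxon: int | None,
    rank: str,
    taxonomy: Taxonomy,
) -> str | None:
    """Category of one read at one rank; None if the read is excluded.

    A read whose true taxon has no ancestor at the evaluated rank is
    excluded so that the same read set is evaluated at every rank.
    """
    if true_taxon is None:
        if predicted_taxon is None:
            return "TN"
        return "FP_STRICT"
    if true_taxon not in taxonomy:
        raise KeyError(f"unknown true taxon {true_taxon}")
    truth_at_rank = taxonomy.ancestor_at_rank(true_taxon, rank)
    if truth_at_rank is None:
        return None  # no true label at this rank
    if predicted_taxon is None:
        return "FN"
    if predicted_taxon not in taxonomy:
        raise KeyError(f"unknown predicted taxon {predicted_taxon}")
    pred_at_rank = taxonomy.ancestor_at_rank(predicted_taxon, rank)
    if pred_at_rank is not None:
        # prediction is at or below the rank: lift and compare
        return "TP" if pred_at_rank == truth_at_rank else "FP"
    # prediction sits above the rank
    if taxonomy.is_ancestor(predicted_taxon, true_taxon, strict=True):
        return "VP"
    return "FP"


def categorize_reads(
    truths: dict[str, int | None],
    predictions: dict[str, int | None],
    rank: str,
    taxonomy: Taxonomy,
) -> CategoryCounts:
    """Tally categories over a read set (prediction defaults to unclassified)."""
    counts = CategoryCounts(rank=rank)
    for read_id, truth in truths.items():
        cat = categorize_read(truth, predictions.get(read_id), rank, taxonomy)
        if cat is not None:
            counts.add(cat)
    return counts


@dataclass
class RankMetrics:
    rank: str
    ppv: float
    sensitivity: float
    f1: float
    counts: CategoryCounts


def compute_metrics(counts: CategoryCounts) -> RankMetrics:
    """Micro-averaged PPV, sensitivity and their harmonic mean (F1).

    Undefined metrics (zero denominator) come back as NaN.
    """
    ppv_den = counts.TP + counts.FP + counts.FP_STRICT
    sens_den = counts.TP + counts.FP + counts.FN + counts.VP
    ppv = counts.TP / ppv_den if ppv_den else math.nan
    sens = counts.TP / sens_den if sens_den else math.nan
    f1 = f1_score(ppv, sens)
    return RankMetrics(counts.rank, ppv, sens, f1, counts)


def f1_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity."""
    if math.isnan(ppv) or math.isnan(sensitivity):
        return math.nan
    if ppv + sensitivity == 0:
        return 0.0
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def evaluate(
    truths: dict[str, int | None],
    predictions: dict[str, int | None],
    ranks: list[str],
    taxonomy: Taxonomy,
) -> list[RankMetrics]:
    """Per-rank metrics over a truth/prediction table."""
    return [
        compute_metrics(categorize_reads(truths, predictions, rank, taxonomy))
        for rank in ranks
    ]
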