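"""Classification of bivalency dynamics between stages and expression summaries.

Between two stages A and B the bivalent gene sets partition into
"A specific" (lost), "Shared" (maintained) and "B specific" (gained).
Counts along a stage series and descriptive expression quartiles of the
groups are the paper-style summaries; no inferential statistics are
attached here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UniverseMismatchError
from .formats_io import ExpressionTable
from .bivalency_calling import StageCallSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionPartition:
    """Disjoint partition of bivalent(A) U bivalent(B) for a stage pair."""

    stage_a: str
    stage_b: str
    a_specific: frozenset[str]
    shared: frozenset[str]
    b_specific: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"{self.stage_a}_specific": len(self.a_specific),
            "shared": len(self.shared),
            f"{self.stage_b}_specific": len(self.b_specific),
        }

    @property
    def fractions(self) -> dict[str, float]:
        """Shared fraction under both denominators (each stage's bivalent count)."""
        n_a = len(self.a_specific) + len(self.shared)
        n_b = len(self.b_specific) + len(self.shared)
        return {
            f"shared_of_{self.stage_a}": len(self.shared) / n_a if n_a else math.nan,
            f"shared_of_{self.stage_b}": len(self.shared) / n_b if n_b else math.nan,
        }

    def groups(self) -> dict[str, frozenset[str]]:
        return {
            f"{self.stage_a}_specific": self.a_specific,
            "shared": self.shared,
            f"{self.stage_b}_specific": self.b_specific,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, group) for group, genes in self.groups().items() for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "group"])


def classify_transition(calls_a: StageCallSet, calls_b: StageCallSet) -> TransitionPartition:
    """Set-algebra partition of bivalent genes between two stages."""
    if calls_a.gene_universe != calls_b.gene_universe:
        offenders = sorted(calls_a.gene_universe ^ calls_b.gene_universe)
        raise UniverseMismatchError(
            f"stages '{calls_a.stage}' and '{calls_b.stage}' have different gene universes "
            f"(first offenders: {offenders[:10]})"
        )
    biv_a, biv_b = calls_a.bivalent_genes, calls_b.bivalent_genes
    return TransitionPartition(
        stage_a=calls_a.stage,
        stage_b=calls_b.stage,
        a_specific=frozenset(biv_a - biv_b),
        shared=frozenset(biv_a & biv_b),
        b_specific=frozenset(biv_b - biv_a),
    )


def count_timeline(
    calls: Sequence[StageCallSet | tuple[str, int]],
) -> pd.DataFrame:
    """Ordered table of per-stage bivalent counts with consecutive fold changes.

    Accepts StageCallSets or plain ``(stage, count)`` pairs.  The fold change
    of the first stage, and of any stage following a zero count, is NaN
    (undefined, not infinity).
    """
    if len(calls) == 0:
        raise ValueError("count_timeline requires at least one stage")
    rows = []
    for item in calls:
        if isinstance(item, StageCallSet):
            rows.append((item.stage, item.n_bivalent))
        else:
            stage, count = item
            rows.append((str(stage), int(count)))
    df = pd.DataFrame(rows, columns=["stage", "n_bivalent"])
    folds = [math.nan]
    for prev, cur in zip(df["n_bivalent"], df["n_bivalent"][1:]):
        folds.append(cur / prev if prev > 0 else math.nan)
    df["fold_change_vs_prev"] = folds
    return df


@dataclass(frozen=True)
class GroupExpressionSummary:
    """Descriptive quartiles of per-gene expression for gene groups.

    ``kind`` is "fpkm" for single-stage summaries or "log2fc" for a
    contrast between two stages.
    """

    table: pd.DataFrame  # index group; columns n, q1, median, q3
    kind: str

    def median(self, group: str) -> float:
        return float(self.table.loc[group, "median"])


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def summarize_group_expression(
    groups: Mapping[str, Iterable[str]],
    expression: ExpressionTable,
    stage: str | None = None,
    contrast: tuple[str, str] | None = None,
    pseudocount: float = 1.0,
    min_coverage: float = 0.9,
) -> GroupExpressionSummary:
    """Quartile summary of expression (or log2 fold change) per gene group.

    Exactly one of ``stage`` or ``contrast=(A, B)`` must be given; a contrast
    summarizes per-gene log2((FPKM_B + c) / (FPKM_A + c)).  Genes absent from
    the expression table are dropped with a logged count; a group covered
    below ``min_coverage`` raises ValueError.
    """
    if (stage is None) == (contrast is None):
        raise ValueError("provide exactly one of stage or contrast")
    if stage is not None:
        per_gene = expression.values[stage].astype(float)
        kind = "fpkm"
    else:
        a, b = contrast
        per_gene = np.log2(
            (expression.values[b].astype(float) + pseudocount)
            / (expression.values[a].astype(float) + pseudocount)
        )
        kind = "log2fc"

    rows = {}
    for name, genes in groups.items():
        genes = list(dict.fromkeys(genes))
        if not genes:
            rows[name] = (0, math.nan, math.nan, math.nan)
            continue
        present = [g for g in genes if g in per_gene.index]
        n_missing = len(genes) - len(present)
        if n_missing:
            logger.info("group %s: dropped %d genes without expression", name, n_missing)
        if len(present) < min_coverage * len(genes):
            raise ValueError(
                f"group '{name}': expression covers only {len(present)}/{len(genes)} genes "
                f"(< {min_coverage:.0%})"
            )
        vals = per_gene.loc[present].to_numpy(dtype=float)
        q1, med, q3 = _quartiles(vals)
        rows[name] = (len(present), q1, med, q3)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["n", "q1", "median", "q3"])
    table["n"] = table["n"].astype(int)
    table.index.name = "group"
    return GroupExpressionSummary(table=table, kind=kind)


@dataclass(frozen=True)
class ListIntersection:
    """Raw-count intersection of a bivalent call set with an external gene list."""

    in_both: frozenset[str]
    bivalent_only: frozenset[str]
    list_only: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "in_both": len(self.in_both),
            "bivalent_only": len(self.bivalent_only),
            "list_only": len(self.list_only),
        }


def intersect_with_list(calls: StageCallSet, gene_list: Iterable[str]) -> ListIntersection:
    """Overlap counts between the stage's bivalent set and an external list."""
    listed = frozenset(gene_list)
    if not listed:
        logger.warning("external gene list is empty; all overlap counts are 0")
    biv = calls.bivalent_genes
    return ListIntersection(
        in_both=biv & listed,
        bivalent_only=biv - listed,
        list_only=listed - biv,
    )
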