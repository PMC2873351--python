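"""Gene-expression validation of thermodynamic reaction classes.

Genes behind regulatory-candidate reactions are expected to show wider
log2 fold-change ranges across perturbation experiments than genes
behind thermodynamic bottlenecks (which are concentration-controlled and
need no transcriptional regulation). Per (gene, reaction) pair the
pipeline keeps only experiments whose coefficient of variation is
strictly below ``cv_max`` (default 0.2), takes the [min, max] of the
retained fold changes, and compares range widths between the two classes
with a two-sided Wilcoxon rank-sum test and a Welch two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_io import ExpressionDataset
from .tva import ReactionClass

logger = logging.getLogger("thermoflux")

__all__ = [
    "GeneRangeRecord",
    "ClassComparison",
    "fold_change_ranges",
    "rank_sum_test",
    "welch_t_test",
    "compare_classes",
    "annotate_with_exchange_coefficients",
]


@dataclass
class GeneRangeRecord:
    gene: str
    reaction_id: str
    class_label: str
    fc_range: tuple[float, float] | None  # None when no experiment survives
    n_experiments_retained: int

    @property
    def width(self) -> float | None:
        if self.fc_range is None:
            return None
        return self.fc_range[1] - self.fc_range[0]


@dataclass
class ClassComparison:
    statistic_name: str
    statistic: float
    p_value: float
    n_regulatory: int
    n_bottleneck: int
    method: str = ""


def filter_by_cv(expr: ExpressionDataset, cv_max: float) -> ExpressionDataset:
    """Keep only entries with cv strictly below cv_max (idempotent)."""
    kept = {k: v for k, v in expr.fold_changes.items() if v[1] < cv_max}
    return ExpressionDataset(experiments=list(expr.experiments), fold_changes=kept)


def fold_change_ranges(
    expr: ExpressionDataset,
    classes: list[ReactionClass],
    gpr: dict[str, set[str]],
    cv_max: float = 0.2,
) -> list[GeneRangeRecord]:
    """Per (gene, reaction) fold-change range over CV-passing experiments.

    ``gpr`` maps reaction id to its gene set. Genes absent from every
    experiment, or with every experiment failing the CV filter, yield a
    null-range record (excluded from downstream tests) plus a warning.
    """
    if cv_max <= 0:
        raise ValueError("cv_max must be > 0")
    filtered = filter_by_cv(expr, cv_max)
    records: list[GeneRangeRecord] = []
    for cls in classes:
        for gene in sorted(gpr.get(cls.reaction_id, set())):
            fcs = [fc for _, fc, _ in filtered.entries_for_gene(gene)]
            if not fcs:
                logger.warning(
                    "gene %s (reaction %s): no CV-passing expression entries "
                    "(gene absent from all experiments or all entries filtered)",
                    gene, cls.reaction_id,
                )
                records.append(GeneRangeRecord(gene, cls.reaction_id, cls.label, None, 0))
            else:
                records.append(
                    GeneRangeRecord(
                        gene, cls.reaction_id, cls.label, (min(fcs), max(fcs)), len(fcs)
                    )
                )
    return records


def rank_sum_test(widths_a: list[float], widths_b: list[float]) -> ClassComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p for two width samples.

    Exact null distribution when min(n) <= 8 with no ties; normal
    approximation with tie correction otherwise. Identical constant
    samples give p = 1.
    """
    a, b = np.asarray(widths_a, float), np.asarray(widths_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ClassComparison("wilcoxon_rank_sum_two_sided", math.nan, 1.0,
                               len(a), len(b), method="degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ClassComparison(
        "wilcoxon_rank_sum_two_sided", float(res.statistic), float(res.pvalue),
        len(a), len(b), method=method,
    )


def welch_t_test(widths_a: list[float], widths_b: list[float]) -> ClassComparison:
    """Welch two-sample t-test (unequal variance), two-sided."""
    a, b = np.asarray(widths_a, float), np.asarray(widths_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t-test needs n >= 2 per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return ClassComparison("welch_t_two_sample", 0.0, 1.0, len(a), len(b),
                               method="degenerate")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ClassComparison(
        "welch_t_two_sample", float(res.statistic), float(res.pvalue),
        len(a), len(b), method="welch-satterthwaite",
    )


def compare_classes(
    records: list[GeneRangeRecord],
    label_a: str = "regulatory_candidate",
    label_b: str = "bottleneck",
) -> list[ClassComparison]:
    """Run both global tests on width samples from two class labels."""
    widths_a = [r.width for r in records if r.class_label == label_a and r.width is not None]
    widths_b = [r.width for r in records if r.class_label == label_b and r.width is not None]
    if not widths_a or not widths_b:
        raise ValueError(
            "no usable fold-change widths for one of the classes "
            f"({label_a}: {len(widths_a)}, {label_b}: {len(widths_b)})"
        )
    out = [rank_sum_test(widths_a, widths_b)]
    if len(widths_a) >= 2 and len(widths_b) >= 2:
        out.append(welch_t_test(widths_a, widths_b))
    return out


def annotate_with_exchange_coefficients(
    classes: list[ReactionClass],
    exchange_table: dict[str, float],
    threshold: float = 0.0,
) -> list[dict]:
    """Join literature exchange coefficients onto bottleneck reactions.

    Exchange coefficients (C13 isotopomer reversibility measures) are
    consumed as opaque literature annotations; missing entries are left
    blank, and coefficients above *threshold* are flagged.
    """
    rows = []
    for c in classes:
        if c.label != "bottleneck":
            continue
        coef = exchange_table.get(c.reaction_id)
        rows.append(
            {
                "reaction_id": c.reaction_id,
                "exchange_coefficient": coef,
                "flagged": coef is not None and coef > threshold,
            }
        )
    return rows


def write_ranges_report(records: list[GeneRangeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\treaction_id\tclass_label\tfc_min\tfc_max\twidth\tn_retained\n")
        for r in records:
            if r.fc_range is None:
                fh.write(f"{r.gene}\t{r.reaction_id}\t{r.class_label}\t\t\t\t0\n")
            else:
                fh.write(
                    f"{r.gene}\t{r.reaction_id}\t{r.class_label}\t{r.fc_range[0]:.6g}\t"
                    f"{r.fc_range[1]:.6g}\t{r.width:.6g}\t{r.n_experiments_retained}\n"
                )


def write_comparison_report(comparisons: list[ClassComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic_name\tstatistic\tp_value\tn_regulatory\tn_bottleneck\tmethod\n")
        for c in comparisons:
            fh.write(
                f"{c.statistic_name}\t{c.statistic:.6g}\t{c.p_value:.6g}\t"
                f"{c.n_regulatory}\t{c.n_bottleneck}\t{c.method}\n"
            )
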