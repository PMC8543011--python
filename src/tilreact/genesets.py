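"""Derivation and validation of tumor-specific activation gene sets.

Paired bulk expression of TILs co-cultured with autologous vs
allogeneic tumor cells yields one log2 fold-change (LFC) per gene per
patient.  Genes are filtered on the paired t-test p-value (< 0.01) and
the mean LFC (> 2 for CD8+ TILs, > 1.4 for CD4+), excluding the three
assay markers *TNFRSF9*, *TNF* and *IFNG* themselves; the resulting
sets are validated against antigen-specific reference samples by a
top-K rank statistic (default K = 300).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flow import ConfigurationError
from .synthetic import BulkExpressionPair

EXCLUDED_MARKER_GENES: tuple[str, ...] = ("TNFRSF9", "TNF", "IFNG")

#: Default mean-LFC cutoffs per TIL subset.
LFC_CUTOFFS: Mapping[str, float] = {"CD8": 2.0, "CD4": 1.4}


@dataclass
class DEGResult:
    """Per-gene paired differential-expression records.

    ``lfc`` is the genes × patients matrix of per-patient log2
    fold-changes (autologous − allogeneic, both already on log2 scale);
    ``table`` holds the per-gene mean LFC and two-sided paired t-test
    p-value.
    """

    lfc: pd.DataFrame
    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index


@dataclass(frozen=True)
class ActivationGeneSet:
    """A filtered tumor-specific activation gene set."""

    subset: str
    genes: tuple[str, ...]
    p_cutoff: float
    lfc_cutoff: float
    excluded: tuple[str, ...] = EXCLUDED_MARKER_GENES


@dataclass(frozen=True)
class ValidationReport:
    """Rank-based validation of a gene set against a reference sample."""

    reference_id: str
    k: int
    fraction_top_k: float
    fraction_lfc_gt1: float


def compute_paired_lfc(pairs: BulkExpressionPair) -> DEGResult:
    """Per-patient LFCs and paired t-test per gene.

    The matrix must already be log2-normalized, so the per-patient LFC
    is the difference of the autologous and allogeneic columns.  The
    p-value is the two-sided paired t-test across patients; genes with
    identical values in both conditions (zero difference everywhere)
    get p = 1 by convention, and zero-variance nonzero shifts get p = 0.
    """
    samples = pairs.samples
    patients = sorted(samples["patient"].unique())
    auto_cols, allo_cols = [], []
    missing = []
    for pid in patients:
        rows = samples[samples["patient"] == pid]
        by_cond = rows.set_index("condition")["sample"]
        if "autologous" not in by_cond.index or "allogeneic" not in by_cond.index:
            missing.append(pid)
            continue
        auto_cols.append(by_cond["autologous"])
        allo_cols.append(by_cond["allogeneic"])
    if missing:
        raise ConfigurationError(f"patients without a matched pair: {missing}")

    auto = pairs.matrix[auto_cols].to_numpy()
    allo = pairs.matrix[allo_cols].to_numpy()
    lfc = auto - allo
    n = lfc.shape[1]

    # zero-variance genes warn inside scipy and yield nan; both are
    # resolved by the conventions below
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_rel(auto, allo, axis=1)
    pvals = np.asarray(t_res.pvalue, dtype=float)
    mean_lfc = lfc.mean(axis=1)
    sd = lfc.std(axis=1, ddof=1)
    degenerate = sd == 0
    pvals[degenerate & (mean_lfc == 0)] = 1.0
    pvals[degenerate & (mean_lfc != 0)] = 0.0

    genes = pairs.matrix.index
    lfc_df = pd.DataFrame(lfc, index=genes, columns=patients)
    table = pd.DataFrame({"mean_lfc": mean_lfc, "p_value": pvals}, index=genes)
    return DEGResult(lfc=lfc_df, table=table)


def derive_gene_set(
    degs: DEGResult,
    subset: str,
    p_cutoff: float = 0.01,
    lfc_cutoff: float | None = None,
    excluded: Sequence[str] = EXCLUDED_MARKER_GENES,
) -> ActivationGeneSet:
    """Filter DEGs into an activation gene set.

    Keeps genes with p < ``p_cutoff`` and mean LFC > ``lfc_cutoff``
    (subset default: 2.0 for CD8, 1.4 for CD4), then removes the
    excluded assay-marker genes.
    """
    if lfc_cutoff is None:
        try:
            lfc_cutoff = LFC_CUTOFFS[subset]
        except KeyError:
            raise ConfigurationError(
                f"no default LFC cutoff for subset {subset!r}; pass lfc_cutoff"
            ) from None
    table = degs.table
    keep = (table["p_value"] < p_cutoff) & (table["mean_lfc"] > lfc_cutoff)
    genes = tuple(g for g in table.index[keep] if g not in set(excluded))
    return ActivationGeneSet(
        subset=subset,
        genes=genes,
        p_cutoff=p_cutoff,
        lfc_cutoff=lfc_cutoff,
        excluded=tuple(excluded),
    )


def intersect_sets(cd8: ActivationGeneSet, cd4: ActivationGeneSet) -> list[str]:
    """Genes shared between two activation gene sets, sorted lexicographically."""
    return sorted(set(cd8.genes) & set(cd4.genes))


def validate_top_k(
    gene_set: ActivationGeneSet,
    reference: DEGResult,
    k: int = 300,
    reference_id: str = "",
) -> ValidationReport:
    """Validate a gene set against a reference DEG ranking.

    Ranks the reference genes by decreasing mean LFC (ties broken by
    stable gene-name order) and reports the fraction of set members
    within the top ``k`` and the fraction with mean LFC > 1 in the
    reference.
    """
    table = reference.table
    if k > len(table):
        raise ConfigurationError(
            f"K = {k} exceeds the reference gene universe ({len(table)})"
        )
    missing = [g for g in gene_set.genes if g not in table.index]
    if missing:
        raise ConfigurationError(f"gene set members absent from reference: {missing}")
    ranked = table.sort_index().sort_values("mean_lfc", ascending=False, kind="stable")
    top_k = set(ranked.index[:k])
    genes = gene_set.genes
    if not genes:
        raise ConfigurationError("cannot validate an empty gene set")
    frac_top = sum(g in top_k for g in genes) / len(genes)
    frac_lfc = sum(table.loc[g, "mean_lfc"] > 1.0 for g in genes) / len(genes)
    return ValidationReport(
        reference_id=reference_id,
        k=k,
        fraction_top_k=frac_top,
        fraction_lfc_gt1=frac_lfc,
    )
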