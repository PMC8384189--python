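"""Concordantly regulated gene sets, overlap statistics, and composition fractions.

Two differential-expression contrasts (e.g. a deletion strain and an acute
depletion strain, each against its own control) are combined as: take the
union of genes significant in either contrast, then retain only genes whose
fold change points the same way in both. The retained set splits into a
down-regulated and an up-regulated cluster; composition is then summarized
by coactivator class and by fold-change magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; NaN for an empty denominator."""
    if denominator == 0:
        return float("nan")
    return float(Decimal(100.0 * numerator / denominator).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def significant_sets(de: pd.DataFrame, alpha: float = 0.05) -> tuple[set, set]:
    """(up, down) gene-id sets at adjusted p < alpha, split by log2fc sign."""
    tested = de[de["status"] == "tested"] if "status" in de else de
    sig = tested[tested["padj"] < alpha]
    up = set(sig.index[sig["log2fc"] > 0])
    down = set(sig.index[sig["log2fc"] < 0])
    return up, down


@dataclass
class RegulatedSets:
    """Bookkeeping of the union-and-concordance filter across two contrasts."""

    union_significant: set
    concordant_down: set
    concordant_up: set
    discordant: set  # in the union, but lfc signs disagree (or a zero lfc)
    single_result: set  # in the union, but absent from one DE table
    table: pd.DataFrame = field(repr=False)  # per-gene lfc/padj from both contrasts

    @property
    def retained(self) -> set:
        return self.concordant_down | self.concordant_up

    def summary(self) -> pd.DataFrame:
        rows = [
            ("union_significant", len(self.union_significant)),
            ("concordant_down", len(self.concordant_down)),
            ("concordant_up", len(self.concordant_up)),
            ("retained", len(self.retained)),
            ("discordant_dropped", len(self.discordant)),
            ("single_result_dropped", len(self.single_result)),
        ]
        return pd.DataFrame(rows, columns=["category", "n_genes"])


def concordant_union(de1: pd.DataFrame, de2: pd.DataFrame, alpha: float = 0.05) -> RegulatedSets:
    """Union of significant genes across two contrasts, filtered for shared direction.

    A gene enters the union if significant (padj < alpha) in either contrast;
    it is retained iff sign(lfc1) == sign(lfc2) != 0 — direction, not dual
    significance, is the filter. Genes present in only one table, or with a
    zero/undefined lfc, are dropped and reported in their own categories so
    the bookkeeping always sums to the union size.
    """
    up1, down1 = significant_sets(de1, alpha)
    up2, down2 = significant_sets(de2, alpha)
    union = up1 | down1 | up2 | down2

    both = union & set(de1.index) & set(de2.index)
    single = union - both

    lfc1 = de1["log2fc"].reindex(sorted(both))
    lfc2 = de2["log2fc"].reindex(sorted(both))
    s1 = np.sign(lfc1.to_numpy())
    s2 = np.sign(lfc2.to_numpy())
    ok = np.isfinite(s1) & np.isfinite(s2) & (s1 == s2) & (s1 != 0)
    genes = np.array(sorted(both), dtype=object)
    concordant_down = set(genes[ok & (s1 < 0)])
    concordant_up = set(genes[ok & (s1 > 0)])
    discordant = set(genes[~ok])

    table = pd.DataFrame(
        {
            "log2fc_1": de1["log2fc"].reindex(sorted(union)),
            "padj_1": de1["padj"].reindex(sorted(union)),
            "log2fc_2": de2["log2fc"].reindex(sorted(union)),
            "padj_2": de2["padj"].reindex(sorted(union)),
        }
    )
    return RegulatedSets(
        union_significant=union,
        concordant_down=concordant_down,
        concordant_up=concordant_up,
        discordant=discordant,
        single_result=single,
        table=table,
    )


def venn_overlap(set_a: set, set_b: set) -> dict:
    """Pairwise overlap counts and shared fractions (percent, one decimal)."""
    inter = len(set_a & set_b)
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_intersection": inter,
        "pct_of_a": pct(inter, len(set_a)),
        "pct_of_b": pct(inter, len(set_b)),
    }


def class_fractions(gene_set: set, labels: pd.Series) -> pd.DataFrame:
    """Counts and percentages per coactivator class over annotated genes only.

    ``labels`` maps gene id -> class in {CR, TFIID, unannotated}; genes
    labelled ``unannotated`` (or missing) are excluded from the percentage
    denominator, which is how composition is reported against a partially
    annotated genome.
    """
    lab = labels.reindex(sorted(gene_set)).fillna("unannotated")
    n_annotated = int((lab != "unannotated").sum())
    rows = []
    for cls in ["CR", "TFIID", "unannotated"]:
        n = int((lab == cls).sum())
        rows.append(
            {
                "gene_class": cls,
                "n_genes": n,
                "pct_of_annotated": pct(n, n_annotated) if cls != "unannotated" else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_annotated"] = n_annotated
    return out


def magnitude_fraction(gene_set: set, lfc: pd.Series, fold_threshold: float = 2.0) -> dict:
    """Fraction of a gene set changed by less than ``fold_threshold``-fold.

    Uses the strict inequality 2^|lfc| < threshold. Raises ``ValueError`` if
    any member lacks an lfc value.
    """
    values = lfc.reindex(sorted(gene_set))
    if values.isna().any():
        raise ValueError(f"missing log2fc for genes: {list(values.index[values.isna()])}")
    n = len(values)
    below = int((np.exp2(np.abs(values.to_numpy())) < fold_threshold).sum())
    return {"n_below": below, "n_total": n, "pct_below": pct(below, n)}
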