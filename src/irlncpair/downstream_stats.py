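"""Downstream statistics: riskscore vs clinical features, immune-gene
differential expression, over-representation analysis, and 2^-ddCT
relative quantification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression_io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .immune_screen import classify_de, moderated_t_test


@dataclass(frozen=True)
class GroupComparison:
    """Rank-based comparison of riskscores across the levels of one
    clinical feature (rank-sum W for two levels, Kruskal-Wallis H for
    more)."""

    feature: str
    groups: tuple
    statistic: float
    p: float
    effect_direction: str

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValidationError(f"{self.feature}: p out of range")


ENRICHMENT_COLUMNS = (
    "set_name",
    "overlap",
    "set_size",
    "universe_size",
    "draws",
    "p",
    "adj_p",
    "q",
    "members_hit",
)

#: TSV header names used when enrichment results are written out.
ENRICHMENT_TSV_COLUMNS = {
    "set_name": "Description",
    "p": "p",
    "adj_p": "p adjust",
    "q": "Q value",
    "overlap": "Count",
    "members_hit": "gene ID",
}


def riskscore_by_clinical(
    assign: pd.DataFrame,
    clin: ClinicalTable,
    features: list[str],
) -> list[GroupComparison]:
    """Compare riskscores across clinical-feature levels.

    Two levels: Wilcoxon rank-sum (normal approximation with continuity
    correction; exact when both sides have n <= 10). More levels:
    Kruskal-Wallis.
    """
    scores = assign["riskscore"]
    out = []
    for feature in features:
        if feature not in clin.data.columns:
            raise ValidationError(f"unknown clinical feature {feature!r}")
        col = clin.data.loc[assign.index, feature]
        mask = col.notna()
        levels = sorted(col[mask].unique())
        if len(levels) < 2:
            raise ValidationError(f"feature {feature!r} has a single level")
        by_level = [scores[mask][col[mask] == lv].to_numpy(float) for lv in levels]
        if len(levels) == 2:
            a, b = by_level
            method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            stat, p = stats.kruskal(*by_level)
            stat, p = float(stat), float(p)
        medians = [np.median(v) for v in by_level]
        direction = f"higher in {levels[int(np.argmax(medians))]}"
        out.append(GroupComparison(feature, tuple(levels), stat, min(p, 1.0), direction))
    return out


def immune_gene_dea(
    expr: ExpressionMatrix,
    labels: pd.Series | dict,
    gene_subset: set,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential expression restricted to ``gene_subset``
    (moderation hyperparameters estimated within the subset, so results do
    not depend on genes outside it).

    Unlike the lncRNA screen, immune genes are called Up/Down on p <= p_max
    and the sign of logFC alone — the fold-change gate applies only to the
    lncRNA differential-expression step.
    """
    genes = [g for g in expr.genes if g in set(gene_subset)]
    if not genes:
        raise ValidationError("gene_subset is empty or absent from matrix")
    de = moderated_t_test(expr.subset_genes(genes), labels)
    return classify_de(de, (0.0, 0.0), p_max=p_max)


def ora_hypergeometric(
    hits: set,
    universe: set,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hits`` (drawn
    from ``universe``) in each gene set; BH-adjusted p and BH q-values,
    sorted ascending by p."""
    universe = {g.upper() for g in universe}
    hits = {g.upper() for g in hits}
    if not universe:
        raise ValidationError("empty universe")
    if not hits <= universe:
        raise ValidationError(f"hits outside universe: {sorted(hits - universe)}")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in sets.sets.items():
        in_universe = [m for m in members if m in universe]
        k_set = len(in_universe)
        hit_members = [m for m in in_universe if m in hits]
        k = len(hit_members)
        if k_set == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, k_set, N))
        rows.append((name, k, k_set, M, N, min(p, 1.0), "/".join(hit_members)))
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "universe_size",
            "draws",
            "p",
            "members_hit",
        ],
    )
    adj = multipletests(df["p"], method="fdr_bh")[1]
    df["adj_p"] = adj
    df["q"] = adj
    df = df[list(ENRICHMENT_COLUMNS)]
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative quantification 2^-ddCT.

    ddCT = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    the returned fold change is 2 ** -ddCT.
    """
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def write_enrichment_tsv(df: pd.DataFrame, path) -> None:
    df.rename(columns=ENRICHMENT_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
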