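"""Immune-related lncRNA screening and differential expression.

Screening: a lncRNA is called immune-related (ir-lncRNA) when its
expression correlates with at least one immune gene beyond |rho| >= 0.4 at
p <= 1e-4 (Spearman by default; Pearson selectable).

Differential expression between two groups uses an empirical-Bayes
moderated t: per-gene sample variances are shrunk toward a pooled prior
s0^2 with prior degrees of freedom d0, both estimated by the method of
moments on the log sample variances. The posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

with residual df d = n1 + n2 - 2, and the moderated t is referred to a
t-distribution with d0 + d df. d0 = 0 degrades to the ordinary
pooled-variance t; d0 = inf uses s0^2 for every gene.

Genes are called Up/Down only when the raw p <= 0.05 *and* the log2 fold
change falls outside a data-driven gate: mean(logFC) +/- 2 sd(logFC) over
all tested genes. Benjamini-Hochberg adjusted p-values are reported but
not filtered on (with small two-group cohorts they rarely clear 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression_io import ExpressionMatrix

DE_COLUMNS = ("gene", "logFC", "AveExpr", "t", "p", "adj_p", "change")

#: Column names used when a DEResult frame is written to TSV.
DE_TSV_COLUMNS = {
    "gene": "Genes",
    "logFC": "log FC",
    "AveExpr": "Ave Expr",
    "t": "t",
    "p": "p value",
    "adj_p": "adj p value",
    "change": "Change",
}


@dataclass(frozen=True)
class CorrelationRecord:
    immune_gene: str
    lncRNA: str
    rho: float
    p: float

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"rho out of range: {self.rho}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p out of range: {self.p}")


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    d0: prior degrees of freedom (>= 0; math.inf allowed), s0_sq: prior
    variance (> 0). ``estimate`` fits both by the method of moments on the
    log sample variances (Smyth-style).
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValidationError("s0_sq must be > 0")

    @staticmethod
    def estimate(variances: np.ndarray, df: int) -> "ModerationParams":
        s2 = np.asarray(variances, dtype=float)
        s2 = s2[s2 > 0]
        if len(s2) < 2:
            return ModerationParams(0.0, float(np.mean(variances)) or 1.0)
        z = np.log(s2)
        e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
        emean = float(np.mean(e))
        evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
        if evar <= 0:
            return ModerationParams(math.inf, math.exp(emean))
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
        )
        return ModerationParams(d0, s0_sq)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _corr_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between two gene blocks."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    return r


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation on n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def correlate_genes(
    expr: ExpressionMatrix,
    rows: list[str],
    cols: list[str],
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation (rho) and p-value matrices between two gene lists.

    Zero-variance genes yield NaN rho/p (reported with a warning by the
    screening callers and excluded from threshold decisions).
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    x = expr.values.loc[rows].to_numpy(dtype=float)
    y = expr.values.loc[cols].to_numpy(dtype=float)
    if method == "spearman":
        x, y = _rank_rows(x), _rank_rows(y)
    n = x.shape[1]
    r = _corr_matrix(x, y)
    p = _corr_p(r, n)
    rho = pd.DataFrame(r, index=rows, columns=cols)
    pval = pd.DataFrame(p, index=rows, columns=cols)
    return rho, pval


def screen_ir_lncRNAs(
    expr: ExpressionMatrix,
    immune_genes: set,
    lnc_genes: set,
    rho_min: float = 0.4,
    p_max: float = 1e-4,
    method: str = "spearman",
) -> tuple[set[str], list[CorrelationRecord]]:
    """Immune-related lncRNAs: correlated with >= 1 immune gene at
    |rho| >= rho_min and p <= p_max."""
    immune = [g for g in expr.genes if g in immune_genes]
    lnc = [g for g in expr.genes if g in lnc_genes]
    overlap = set(immune) & set(lnc)
    if overlap:
        raise ValidationError(f"immune and lncRNA sets overlap: {sorted(overlap)}")
    if not immune or not lnc:
        raise ValidationError("immune gene or lncRNA set absent from matrix")
    rho, pval = correlate_genes(expr, immune, lnc, method=method)
    if rho.isna().any().any():
        bad = sorted(
            set(rho.index[rho.isna().all(axis=1)]) | set(rho.columns[rho.isna().all(axis=0)])
        )
        warnings.warn(
            f"zero-variance genes excluded from correlation screen: {bad}",
            stacklevel=2,
        )
    hit = (rho.abs() >= rho_min) & (pval <= p_max)
    hit = hit.fillna(False)
    records = []
    for i, j in zip(*np.nonzero(hit.to_numpy())):
        ig, lg = hit.index[i], hit.columns[j]
        records.append(
            CorrelationRecord(ig, lg, float(rho.iat[i, j]), float(pval.iat[i, j]))
        )
    retained = {rec.lncRNA for rec in records}
    return retained, records


def moderated_t_test(
    expr: ExpressionMatrix,
    group_labels: pd.Series | dict,
    moderation: ModerationParams | str = "auto",
) -> pd.DataFrame:
    """Two-group moderated t-test on log2 expression.

    ``group_labels`` maps sample ID -> group; exactly two groups, each with
    >= 2 samples. logFC = mean(group1) - mean(group2), where group1 is the
    first label in the order of appearance across the matrix's samples.
    Returns a DEResult frame (gene, logFC, AveExpr, t, p, adj_p, change)
    with ``change`` initialized to NotSig (see :func:`classify_de`).
    """
    labels = pd.Series(group_labels)
    labels = labels.loc[[s for s in expr.samples if s in labels.index]]
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValidationError(f"need exactly two groups, got {groups}")
    idx1 = [s for s in expr.samples if labels.get(s) == groups[0]]
    idx2 = [s for s in expr.samples if labels.get(s) == groups[1]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples")
    x1 = expr.values[idx1].to_numpy(dtype=float)
    x2 = expr.values[idx2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    logfc = m1 - m2
    ave = expr.values[idx1 + idx2].to_numpy(dtype=float).mean(axis=1)
    d = n1 + n2 - 2
    s2 = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = s2 / d
    if moderation == "auto":
        moderation = ModerationParams.estimate(s2, d)
    elif not isinstance(moderation, ModerationParams):
        raise ValidationError("moderation must be 'auto' or ModerationParams")
    d0, s0 = moderation.d0, moderation.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = math.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": expr.genes,
            "logFC": logfc,
            "AveExpr": ave,
            "t": t,
            "p": p,
            "adj_p": adj_p,
            "change": "NotSig",
        }
    )


def fc_gate(de: pd.DataFrame) -> tuple[float, float]:
    """Fold-change gate: mean(logFC) +/- 2 sd(logFC) over tested genes."""
    if len(de) < 2:
        raise ValidationError("fc_gate needs >= 2 genes")
    logfc = de["logFC"].to_numpy(dtype=float)
    mu, sd = float(np.mean(logfc)), float(np.std(logfc, ddof=1))
    return mu - 2.0 * sd, mu + 2.0 * sd


def classify_de(
    de: pd.DataFrame, gate: tuple[float, float], p_max: float = 0.05
) -> pd.DataFrame:
    """Assign Up/Down/NotSig per gene from (logFC, p) and the fc gate."""
    lo, hi = gate
    out = de.copy()
    up = (out["logFC"] > hi) & (out["p"] <= p_max)
    down = (out["logFC"] < lo) & (out["p"] <= p_max)
    out["change"] = np.select([up, down], ["Up", "Down"], default="NotSig")
    return out


def reverse_immune_genes(
    expr: ExpressionMatrix,
    model_lncRNAs: set,
    immune_genes: set,
    rho_min: float = 0.4,
    p_max: float = 0.05,
    method: str = "spearman",
) -> set[str]:
    """Reverse extraction: immune genes correlated with >= 1 model lncRNA."""
    if not model_lncRNAs:
        raise ValidationError("model_lncRNAs must be nonempty")
    retained, _ = screen_ir_lncRNAs(
        expr,
        immune_genes=model_lncRNAs,
        lnc_genes=immune_genes,
        rho_min=rho_min,
        p_max=p_max,
        method=method,
    )
    return retained


def write_de_tsv(de: pd.DataFrame, path) -> None:
    de.rename(columns=DE_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
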