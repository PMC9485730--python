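"""Relative-expression 0/1 pair encoding.

For an ordered gene pair A|B and a sample, the pair indicator is 1 when
expression(A) > expression(B) in that sample and 0 otherwise (ties count as
0). Because the encoding only compares two genes *within* one sample it is
rank-based per sample and needs no cross-platform normalization — that is
the point of the construction.

Pairs whose indicator is nearly constant across a cohort (pairRatio close
to 0 or 1) carry no discriminative information and are removed by
:func:`pair_ratio_filter`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import ExpressionMatrix


@dataclass(frozen=True)
class PairDefinition:
    """An ordered gene pair in canonical orientation (gene_a < gene_b
    lexicographically). ``display_label`` preserves an original, possibly
    flipped, orientation for reporting; the stored indicators always follow
    the canonical orientation."""

    gene_a: str
    gene_b: str
    display_label: str | None = None

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValidationError(f"pair with identical genes: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValidationError(
                f"pair {self.gene_a}|{self.gene_b} not in canonical orientation"
            )

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"


def canonicalize_label(label: str) -> tuple[str, bool]:
    """Return the canonical 'A|B' form of a pair label and whether the
    input was flipped relative to canonical."""
    a, b = split_label(label)
    if a > b:
        return f"{b}|{a}", True
    return f"{a}|{b}", False


def split_label(label: str) -> tuple[str, str]:
    parts = label.split("|")
    if len(parts) != 2 or not all(parts):
        raise ValidationError(f"malformed pair label {label!r}")
    return parts[0], parts[1]


@dataclass
class PairMatrix:
    """0/1 indicator matrix, pairs x samples, plus per-pair ratio.

    ``indicators`` is indexed by canonical pair labels; ``pair_ratio`` is
    the row mean of the indicators (fraction of samples where the first,
    canonically ordered, gene is the higher-expressed one).
    """

    pairs: list[PairDefinition]
    indicators: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [p.label for p in self.pairs]
        if list(self.indicators.index) != labels:
            raise ValidationError("indicator index does not match pair labels")

    @property
    def samples(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.pairs]

    @property
    def pair_ratio(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def __len__(self) -> int:
        return len(self.pairs)

    def indicator_for(self, label: str) -> pd.Series:
        """Indicator row for a pair label in *the orientation of the label*.

        A label flipped relative to canonical returns 1 - canonical row
        (exact when expression values are untied; ties were encoded as 0).
        """
        canonical, flipped = canonicalize_label(label)
        if canonical not in self.indicators.index:
            raise KeyError(f"pair {label!r} not present in pair matrix")
        row = self.indicators.loc[canonical]
        if flipped:
            row = 1 - row
        return row.rename(label)


def encode_pairs(expr: ExpressionMatrix, genes: list[str]) -> PairMatrix:
    """Encode all C(n,2) ordered pairs of ``genes`` as 0/1 indicators.

    Pairs are enumerated in the order of the input gene list and stored in
    canonical orientation (indicator = 1 iff the lexicographically smaller
    gene is the higher expressed; ties give 0).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("need at least two genes to build pairs")
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"duplicate genes in pair list: {dups}")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    sub = expr.values.loc[genes]
    pairs: list[PairDefinition] = []
    rows = []
    for ga, gb in combinations(genes, 2):
        if ga > gb:
            ga, gb = gb, ga
        pairs.append(PairDefinition(ga, gb))
        rows.append((sub.loc[ga].to_numpy() > sub.loc[gb].to_numpy()).astype(np.int8))
    indicators = pd.DataFrame(
        np.vstack(rows), index=[p.label for p in pairs], columns=expr.samples
    )
    return PairMatrix(pairs, indicators)


def pair_ratio_filter(pm: PairMatrix, lo: float = 0.2, hi: float = 0.8) -> PairMatrix:
    """Keep pairs with lo < pairRatio < hi (strict open interval)."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError(f"invalid pairRatio bounds ({lo}, {hi})")
    ratio = pm.pair_ratio
    keep = [(lo < ratio[p.label] < hi) for p in pm.pairs]
    pairs = [p for p, k in zip(pm.pairs, keep) if k]
    indicators = pm.indicators.loc[[p.label for p in pairs]]
    return PairMatrix(pairs, indicators, dict(pm.metadata))


def intersect_pairs(
    a: PairMatrix, b: PairMatrix
) -> tuple[list[PairDefinition], tuple[PairMatrix, PairMatrix]]:
    """Pairs whose canonical labels occur in both matrices, plus aligned
    pair-subset views sharing the common order (a's order)."""
    in_b = set(b.indicators.index)
    common = [p for p in a.pairs if p.label in in_b]
    labels = [p.label for p in common]
    view_a = PairMatrix(common, a.indicators.loc[labels], dict(a.metadata))
    view_b = PairMatrix(common, b.indicators.loc[labels], dict(b.metadata))
    return common, (view_a, view_b)


def write_pair_matrix(pm: PairMatrix, path) -> None:
    out = pm.indicators.copy()
    out["pair_ratio"] = pm.pair_ratio.round(6)
    out.to_csv(path, sep="\t", index_label="pair")


def read_pair_matrix(path) -> PairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "pair_ratio" in df.columns:
        df = df.drop(columns=["pair_ratio"])
    pairs = [PairDefinition(*split_label(lbl)) for lbl in df.index]
    return PairMatrix(pairs, df.astype(np.int8))
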