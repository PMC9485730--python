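"""Synthetic cohorts with the statistical structure the analysis assumes.

Two cohorts are emulated:

* a *discovery* cohort — 28 tumours split 17 non-responder / 11 responder
  (pathologic response to neoadjuvant chemoradiotherapy; non-response is
  taken as radioresistance) — used for ir-lncRNA screening and
  differential expression; and
* a *survival* cohort — 179 tumours with overall-survival follow-up and
  clinical covariates — used for Cox modelling and risk stratification.

The generator plants three kinds of structure:

* **immune linkage** — ``n_linked_lnc`` lncRNAs are linear transforms of an
  immune gene plus Gaussian noise, with population correlation
  ``rho_true``;
* **group effects** — ``n_de_lnc`` lncRNAs (a subset of the linked ones)
  get a mean shift of ±``de_effect`` log2 units in the non-responder
  group. The immune partner of a shifted lncRNA is co-shifted
  (co-regulation); without this the group shift would wash out the planted
  correlation at n = 28;
* **pair hazards** — ``pair_betas`` maps pair labels (e.g. ``"A|B"``) to
  true Cox log-hazard ratios. Survival times are exponential with rate
  ``baseline_hazard * exp(sum(beta_i * indicator_i))`` and independent
  exponential censoring at ``censor_rate``. Genes appearing in
  ``pair_betas`` are given equal baseline means so their 0/1 indicator is
  informative (pairRatio near 0.5).

Expression is Gaussian on the log2 scale with gene means drawn uniformly
from 4-8 (the AveExpr range typical of array data). One global seed is
split (``numpy.random.SeedSequence.spawn``) into independent streams for
gene means, discovery noise, survival noise and clinical covariates, so
enlarging one block never perturbs another.

The module also ships verbatim fixtures of the study tables this pipeline
is organized around (differential ir-lncRNAs; clinical margins; Cox fits
of the prognostic pairs), used as worked examples throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression_io import ClinicalTable, ExpressionMatrix
from .pair_encoding import split_label

NON_RESPONDER = "non_responder"
RESPONDER = "responder"

#: Table-2-style categorical margins used to draw clinical covariates.
CLINICAL_MARGINS = {
    "sex": (("Female", 33), ("Male", 146)),
    "tobacco": (("Yes", 114), ("No", 65)),
    "alcohol": (("Yes", 106), ("No", 73)),
    "t_stage": (("T1", 12), ("T2", 27), ("T3", 110), ("T4", 30)),
    "n_stage": (("N0", 83), ("N1", 62), ("N2", 22), ("N3", 12)),
    "tnm_stage": (("Stage I", 10), ("Stage II", 77), ("Stage III", 92)),
    "grade": (("Poorly", 49), ("Moderately", 98), ("Well", 32)),
}
AGE_MEAN, AGE_SD, AGE_RANGE = 58.0, 9.03, (36.0, 82.0)


def _default_pair_betas() -> dict[str, float]:
    return {
        "LNC0001|LNC0002": 0.687,
        "LNC0003|LNC0004": 0.863,
        "LNC0005|LNC0006": 0.419,
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts (defaults mirror the two
    cohorts the analysis is designed for)."""

    n_samples_discovery: int = 28
    n_nonresponder: int = 17
    n_responder: int = 11
    n_samples_survival: int = 179
    n_immune_genes: int = 120
    n_lncRNAs: int = 700
    n_linked_lnc: int = 250
    rho_true: float = 0.8
    n_de_lnc: int = 26
    de_effect: float = 1.5
    pair_betas: dict[str, float] = field(default_factory=_default_pair_betas)
    baseline_hazard: float = 0.008  # events per month
    censor_rate: float = 0.015  # censorings per month
    noise_sd: float = 1.0
    confounding: float = 0.0  # age <-> pair-indicator/hazard confounding knob
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_samples_discovery,
            self.n_nonresponder,
            self.n_responder,
            self.n_samples_survival,
            self.n_immune_genes,
            self.n_lncRNAs,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all sample/gene counts must be positive")
        if self.n_nonresponder + self.n_responder != self.n_samples_discovery:
            raise ConfigurationError(
                "n_nonresponder + n_responder must equal n_samples_discovery"
            )
        if not (0 <= self.n_linked_lnc <= self.n_lncRNAs):
            raise ConfigurationError("n_linked_lnc must be <= n_lncRNAs")
        if not (0 <= self.n_de_lnc <= self.n_lncRNAs):
            raise ConfigurationError("n_de_lnc must be <= n_lncRNAs")
        if not (-1.0 < self.rho_true < 1.0):
            raise ConfigurationError("rho_true must lie in (-1, 1)")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ConfigurationError("noise_sd, hazard and censor rates must be > 0")

    # -- gene naming ----------------------------------------------------
    @property
    def immune_gene_names(self) -> list[str]:
        return [f"IMM{i + 1:04d}" for i in range(self.n_immune_genes)]

    @property
    def lncrna_names(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lncRNAs)]

    @property
    def de_lncrna_names(self) -> list[str]:
        return self.lncrna_names[: self.n_de_lnc]

    def _streams(self):
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(5)
        return {
            "means": np.random.default_rng(kids[0]),
            "discovery": np.random.default_rng(kids[1]),
            "survival_expr": np.random.default_rng(kids[2]),
            "survival_times": np.random.default_rng(kids[3]),
            "clinical": np.random.default_rng(kids[4]),
        }


def _gene_means(cfg: SimConfig, rng) -> pd.Series:
    names = cfg.immune_gene_names + cfg.lncrna_names
    means = pd.Series(rng.uniform(4.0, 8.0, size=len(names)), index=names)
    for label in cfg.pair_betas:
        a, b = split_label(label)
        for g in (a, b):
            if g not in means.index:
                raise KeyError(f"pair_betas references unknown gene {g!r}")
        means[b] = means[a]
    return means


def _expression_block(cfg: SimConfig, means: pd.Series, rng, n: int) -> pd.DataFrame:
    """Immune + lncRNA expression for n samples (no group effects)."""
    n_imm, n_lnc = cfg.n_immune_genes, cfg.n_lncRNAs
    z_imm = rng.standard_normal((n_imm, n))
    eps = rng.standard_normal((n_lnc, n))
    imm_names, lnc_names = cfg.immune_gene_names, cfg.lncrna_names
    imm = means[imm_names].to_numpy()[:, None] + z_imm
    rho = cfg.rho_true
    lnc = np.empty((n_lnc, n))
    for j in range(n_lnc):
        if j < cfg.n_linked_lnc:
            partner = j % n_imm
            signal = rho * z_imm[partner] + np.sqrt(1 - rho**2) * eps[j]
        else:
            signal = eps[j]
        lnc[j] = means[lnc_names[j]] + cfg.noise_sd * signal
    values = np.vstack([imm, lnc])
    return pd.DataFrame(values, index=imm_names + lnc_names)


def _de_sign(j: int) -> int:
    return -1 if j % 2 == 0 else 1


def generate_discovery_cohort(cfg: SimConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """Two-group discovery cohort; returns (expression, sample labels)."""
    streams = cfg._streams()
    means = _gene_means(cfg, streams["means"])
    n = cfg.n_samples_discovery
    df = _expression_block(cfg, means, streams["discovery"], n)
    samples = [f"D{i + 1:03d}" for i in range(n)]
    df.columns = samples
    labels = pd.Series(
        [NON_RESPONDER] * cfg.n_nonresponder + [RESPONDER] * cfg.n_responder,
        index=samples,
        name="group",
    )
    nr = labels == NON_RESPONDER
    n_imm = cfg.n_immune_genes
    for j in range(cfg.n_de_lnc):
        shift = _de_sign(j) * cfg.de_effect
        lnc_name = cfg.lncrna_names[j]
        df.loc[lnc_name, nr.values] += shift
        if j < cfg.n_linked_lnc:  # co-shift the immune partner
            partner = cfg.immune_gene_names[j % n_imm]
            df.loc[partner, nr.values] += shift
    em = ExpressionMatrix(df, {"cohort": "discovery", "seed": cfg.seed})
    return em, labels


def generate_survival_cohort(cfg: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Survival cohort with exponential proportional-hazards event times
    driven by the planted pair indicators."""
    streams = cfg._streams()
    means = _gene_means(cfg, streams["means"])
    n = cfg.n_samples_survival
    df = _expression_block(cfg, means, streams["survival_expr"], n)
    samples = [f"S{i + 1:03d}" for i in range(n)]
    df.columns = samples

    rng_clin = streams["clinical"]
    age = np.clip(
        rng_clin.normal(AGE_MEAN, AGE_SD, size=n), AGE_RANGE[0], AGE_RANGE[1]
    ).round(1)
    covariates = {"age": age}
    for col, margins in CLINICAL_MARGINS.items():
        levels = [lv for lv, _ in margins]
        p = np.array([c for _, c in margins], dtype=float)
        p /= p.sum()
        covariates[col] = rng_clin.choice(levels, size=n, p=p)

    if cfg.confounding:
        age_z = (age - 60.0) / 10.0
        for label in cfg.pair_betas:
            a, _ = split_label(label)
            df.loc[a] += cfg.confounding * age_z

    eta = np.zeros(n)
    for label, beta in cfg.pair_betas.items():
        a, b = split_label(label)
        for g in (a, b):
            if g not in df.index:
                raise KeyError(f"pair_betas references unknown gene {g!r}")
        indicator = (df.loc[a].to_numpy() > df.loc[b].to_numpy()).astype(float)
        eta += beta * indicator
    if cfg.confounding:
        eta += cfg.confounding * (age - 60.0) / 10.0

    rng_surv = streams["survival_times"]
    event_time = rng_surv.exponential(1.0 / (cfg.baseline_hazard * np.exp(eta)))
    censor_time = rng_surv.exponential(1.0 / cfg.censor_rate, size=n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    clin = pd.DataFrame(
        {
            "os_time": np.maximum(os_time, 1e-6),
            "os_event": os_event,
            "sex": covariates["sex"],
            "age": covariates["age"],
            "tobacco": covariates["tobacco"],
            "alcohol": covariates["alcohol"],
            "t_stage": covariates["t_stage"],
            "n_stage": covariates["n_stage"],
            "tnm_stage": covariates["tnm_stage"],
            "grade": covariates["grade"],
        },
        index=pd.Index(samples, name="sample"),
    )
    em = ExpressionMatrix(df, {"cohort": "survival", "seed": cfg.seed})
    return em, ClinicalTable(clin)


# -- packaged table fixtures -------------------------------------------


def _data_path(name: str):
    return resources.files("irlncpair.data").joinpath(name)


def table1_fixture() -> pd.DataFrame:
    """Differential-expression table of the 26 ir-lncRNAs (verbatim rows:
    gene, logFC, AveExpr, t, p, adj_p, change)."""
    with resources.as_file(_data_path("table1_de_ir_lncrnas.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def table3_fixture() -> pd.DataFrame:
    """Univariate + multivariate Cox fits of the prognostic ir-lncRNA pairs
    (verbatim rows: pair, model, beta, se, hr, hr_lo, hr_hi, p)."""
    with resources.as_file(_data_path("table3_cox_pairs.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def table2_margins_fixture() -> pd.DataFrame:
    """Printed clinical margins (item, level, count, percent; n = 179)."""
    with resources.as_file(_data_path("table2_clinical_margins.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def immune_de_genes_fixture() -> list[str]:
    """The 11 immune genes reported differentially expressed."""
    with resources.as_file(_data_path("immune_de_genes.txt")) as p:
        return [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
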