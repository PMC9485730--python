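"""End-to-end orchestration: screen -> DE -> pair encode -> filter ->
intersect -> univariate Cox -> LASSO -> multivariate Cox -> riskscore ->
stratify -> KM/log-rank -> time-ROC -> clinical Cox -> Wilcoxon ->
reverse immune genes -> immune DE -> over-representation.

Every stage writes its table to the output directory and records its
counts; output files contain no timestamps, so a rerun at the same seed is
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import downstream_stats, immune_screen, pair_encoding, survival_risk
from .errors import IrLncPairError, ValidationError
from .expression_io import (
    read_clinical_tsv,
    read_expression_tsv,
    read_gmt,
    read_symbol_list,
    write_clinical_tsv,
    write_expression_tsv,
)
from .synthetic_data import (
    SimConfig,
    generate_discovery_cohort,
    generate_survival_cohort,
)

log = logging.getLogger("irlncpair")

CLINICAL_FEATURES = (
    "sex",
    "tobacco",
    "alcohol",
    "t_stage",
    "n_stage",
    "tnm_stage",
    "grade",
)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run. Threshold defaults are the
    screening/model-building values the pipeline is designed around."""

    discovery_expression: str = ""
    discovery_labels: str = ""
    survival_expression: str = ""
    clinical: str = ""
    immune_list: str = ""
    gmt: str = ""
    rho_min: float = 0.4
    rho_p_max: float = 1e-4
    corr_method: str = "spearman"
    de_p_max: float = 0.05
    pair_ratio_lo: float = 0.2
    pair_ratio_hi: float = 0.8
    uni_p_max: float = 0.05
    multi_p_max: float = 0.05
    reverse_rho_min: float = 0.4
    reverse_p_max: float = 0.05
    lasso_folds: int = 10
    cutoff_rule: str = "median"
    horizons: tuple = (12.0, 24.0, 36.0)  # months
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.pair_ratio_lo < self.pair_ratio_hi <= 1):
            raise ValidationError("invalid pairRatio bounds")
        hs = tuple(float(h) for h in self.horizons)
        if any(h <= 0 for h in hs) or list(hs) != sorted(hs):
            raise ValidationError("horizons must be positive ascending")
        self.horizons = hs

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return PipelineConfig(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class PipelineStageError(IrLncPairError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage, self.cause = stage, cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full analysis; returns a report dict with counts and
    headline statistics, all of which are also persisted under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, float] = {}
    report: dict = {"counts": counts}

    def stage(name):
        log.info("stage: %s", name)
        return _StageGuard(name)

    with stage("load_inputs"):
        disc = read_expression_tsv(cfg.discovery_expression)
        labels = pd.read_csv(
            cfg.discovery_labels, sep="\t", index_col=0
        ).iloc[:, 0]
        surv_expr = read_expression_tsv(cfg.survival_expression)
        clin = read_clinical_tsv(cfg.clinical)
        immune = read_symbol_list(cfg.immune_list)
        gene_sets = read_gmt(cfg.gmt) if cfg.gmt else None
        lnc_genes = {g for g in disc.genes if g not in immune}

    with stage("screen_ir_lncRNAs"):
        ir_set, corr_records = immune_screen.screen_ir_lncRNAs(
            disc, immune, lnc_genes, cfg.rho_min, cfg.rho_p_max, cfg.corr_method
        )
        counts["ir_lncRNAs_screened"] = len(ir_set)
        pd.DataFrame(
            [(r.immune_gene, r.lncRNA, r.rho, r.p) for r in corr_records],
            columns=["immune_gene", "lncRNA", "rho", "p"],
        ).to_csv(out / "ir_lncrna_correlations.tsv", sep="\t", index=False,
                 float_format="%.6g")

    with stage("differential_expression"):
        ir_expr = disc.subset_genes(sorted(ir_set))
        de = immune_screen.moderated_t_test(ir_expr, labels)
        gate = immune_screen.fc_gate(de)
        de = immune_screen.classify_de(de, gate, p_max=cfg.de_p_max)
        immune_screen.write_de_tsv(de, out / "de_ir_lncrnas.tsv")
        de_genes = de.loc[de["change"] != "NotSig", "gene"].tolist()
        counts["de_ir_lncRNAs"] = len(de_genes)
        counts["de_up"] = int((de["change"] == "Up").sum())
        counts["de_down"] = int((de["change"] == "Down").sum())
        report["fc_gate"] = gate

    with stage("pair_encoding"):
        if len(de_genes) < 2:
            raise ValidationError("fewer than two DE ir-lncRNAs; cannot pair")
        pm_disc = pair_encoding.encode_pairs(disc, de_genes)
        counts["pairs_built"] = len(pm_disc)
        pm_disc_f = pair_encoding.pair_ratio_filter(
            pm_disc, cfg.pair_ratio_lo, cfg.pair_ratio_hi
        )
        counts["pairs_filtered_discovery"] = len(pm_disc_f)
        surv_genes = [g for g in de_genes if g in surv_expr.values.index]
        pm_surv = pair_encoding.encode_pairs(surv_expr, surv_genes)
        pm_surv_f = pair_encoding.pair_ratio_filter(
            pm_surv, cfg.pair_ratio_lo, cfg.pair_ratio_hi
        )
        counts["pairs_filtered_survival"] = len(pm_surv_f)
        common, (view_d, view_s) = pair_encoding.intersect_pairs(pm_disc_f, pm_surv_f)
        counts["pairs_intersected"] = len(common)
        pair_encoding.write_pair_matrix(pm_disc_f, out / "pairs_discovery.tsv")
        pair_encoding.write_pair_matrix(view_s, out / "pairs_survival.tsv")

    with stage("cox_univariate"):
        uni_fits = []
        for p in view_s.pairs:
            row = view_s.indicators.loc[p.label]
            if row.nunique() <= 1:
                continue
            uni_fits.append(
                survival_risk.cox_univariate(row.astype(float), clin, name=p.label)
            )
        uni_df = survival_risk.coxfits_to_frame(uni_fits)
        uni_df.insert(1, "model", "Univariate")
        uni_df.to_csv(out / "cox_univariate.tsv", sep="\t", index=False,
                      float_format="%.6g")
        uni_sig = [f.variable for f in uni_fits if f.p < cfg.uni_p_max]
        counts["pairs_univariate_significant"] = len(uni_sig)

    with stage("lasso_selection"):
        if len(uni_sig) == 0:
            raise ValidationError("no univariately significant pairs")
        if len(uni_sig) == 1:
            lasso_selected = list(uni_sig)
            counts["pairs_lasso_selected"] = 1
        else:
            sub = pair_encoding.PairMatrix(
                [p for p in view_s.pairs if p.label in set(uni_sig)],
                view_s.indicators.loc[uni_sig],
            )
            lasso = survival_risk.lasso_cox_select(
                sub, clin, n_folds=cfg.lasso_folds, seed=cfg.seed
            )
            lasso.coef_path.to_csv(out / "lasso_path.tsv", sep="\t",
                                   float_format="%.6g")
            lasso_selected = lasso.selected or list(uni_sig)
            counts["pairs_lasso_selected"] = len(lasso_selected)

    with stage("cox_multivariate"):
        X = view_s.indicators.loc[lasso_selected].T.astype(float)
        multi_fits = survival_risk.cox_multivariate(X, clin)
        multi_df = survival_risk.coxfits_to_frame(multi_fits)
        multi_df.insert(1, "model", "Multivariate")
        multi_df.to_csv(out / "cox_multivariate.tsv", sep="\t", index=False,
                        float_format="%.6g")
        final_fits = [f for f in multi_fits if f.p < cfg.multi_p_max]
        if not final_fits:
            final_fits = multi_fits
        model = survival_risk.RiskModel(
            [f.variable for f in final_fits], [round(f.beta, 3) for f in final_fits]
        )
        counts["pairs_in_model"] = len(model.pairs)
        report["model"] = dict(zip(model.pairs, model.coefs))

    with stage("risk_stratification"):
        scores = survival_risk.risk_score(model, pm_surv)
        horizon_mid = cfg.horizons[min(1, len(cfg.horizons) - 1)]
        assign = survival_risk.stratify(
            scores, rule=cfg.cutoff_rule, horizon=horizon_mid, surv=clin
        )
        model.to_json(
            out / "risk_model.json",
            cutoff=float(assign["cutoff"].iloc[0]),
            cutoff_rule=cfg.cutoff_rule,
        )
        assign.to_csv(out / "risk_groups.tsv", sep="\t", index_label="sample",
                      float_format="%.6g")
        counts["n_high_risk"] = int((assign["group"] == survival_risk.HIGH).sum())
        counts["n_low_risk"] = int((assign["group"] == survival_risk.LOW).sum())
        report["median_riskscore"] = float(np.median(scores))

    with stage("km_logrank"):
        curves, chi_sq, p = survival_risk.km_logrank(assign, clin)
        km_rows = []
        for grp, cur in curves.items():
            cur = cur.assign(group=grp)
            km_rows.append(cur)
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False,
                                  float_format="%.6g")
        report["logrank_chi_sq"] = chi_sq
        report["logrank_p"] = p

    with stage("time_roc"):
        roc_rows = []
        aucs = {}
        for h in cfg.horizons:
            roc = survival_risk.time_roc(scores, clin, h)
            aucs[h] = roc.auc
            roc_rows.append(
                pd.DataFrame(
                    {"horizon": h, "cutoff": roc.cutoffs, "fpr": roc.fpr,
                     "tpr": roc.tpr}
                )
            )
        pd.concat(roc_rows).to_csv(out / "time_roc.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        report["auc"] = aucs

    with stage("cox_clinical"):
        clin_fits = survival_risk.cox_clinical(clin, scores)
        for key in ("univariate", "multivariate"):
            survival_risk.coxfits_to_frame(clin_fits[key]).to_csv(
                out / f"cox_clinical_{key}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )

    with stage("riskscore_by_clinical"):
        features = [f for f in CLINICAL_FEATURES if f in clin.data.columns]
        comparisons = downstream_stats.riskscore_by_clinical(assign, clin, features)
        pd.DataFrame(
            [
                (c.feature, "/".join(map(str, c.groups)), c.statistic, c.p,
                 c.effect_direction)
                for c in comparisons
            ],
            columns=["feature", "levels", "statistic", "p", "effect_direction"],
        ).to_csv(out / "riskscore_by_clinical.tsv", sep="\t", index=False,
                 float_format="%.6g")

    with stage("reverse_immune_genes"):
        model_genes = sorted(
            {g for lbl in model.pairs for g in pair_encoding.split_label(lbl)}
        )
        reversed_immune = immune_screen.reverse_immune_genes(
            disc, set(model_genes), immune,
            rho_min=cfg.reverse_rho_min, p_max=cfg.reverse_p_max,
            method=cfg.corr_method,
        )
        counts["reverse_immune_genes"] = len(reversed_immune)
        (out / "reverse_immune_genes.txt").write_text(
            "\n".join(sorted(reversed_immune)) + "\n"
        )

    with stage("immune_gene_dea"):
        if reversed_immune:
            imm_de = downstream_stats.immune_gene_dea(disc, labels, reversed_immune)
            immune_screen.write_de_tsv(imm_de, out / "de_immune_genes.tsv")
            de_immune = imm_de.loc[imm_de["change"] != "NotSig", "gene"].tolist()
        else:
            de_immune = []
        counts["de_immune_genes"] = len(de_immune)

    with stage("enrichment"):
        if gene_sets is not None and de_immune and reversed_immune:
            enrich = downstream_stats.ora_hypergeometric(
                set(de_immune), set(reversed_immune), gene_sets
            )
            downstream_stats.write_enrichment_tsv(enrich, out / "enrichment.tsv")
            counts["enriched_sets_p05"] = int((enrich["p"] < 0.05).sum())

    with stage("report"):
        with open(out / "counts.json", "w", encoding="utf-8") as fh:
            json.dump(counts, fh, indent=2, sort_keys=True)
        _write_summary(out / "summary.txt", cfg, counts, report)
    return report


class _StageGuard:
    def __init__(self, name):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineStageError):
            raise PipelineStageError(self.name, exc) from exc
        return False


def _write_summary(path, cfg, counts, report):
    lines = ["ir-lncRNA pair prognostic pipeline summary",
             f"seed: {cfg.seed}", ""]
    order = [
        "ir_lncRNAs_screened", "de_ir_lncRNAs", "de_up", "de_down",
        "pairs_built", "pairs_filtered_discovery", "pairs_filtered_survival",
        "pairs_intersected", "pairs_univariate_significant",
        "pairs_lasso_selected", "pairs_in_model", "n_high_risk", "n_low_risk",
        "reverse_immune_genes", "de_immune_genes",
    ]
    for key in order:
        if key in counts:
            lines.append(f"{key}: {counts[key]}")
    if "model" in report:
        lines.append("")
        lines.append("riskscore = " + " + ".join(
            f"{c:g} x {p}" for p, c in report["model"].items()
        ))
        lines.append(f"median riskscore: {report['median_riskscore']:.6g}")
        lines.append(
            f"log-rank chi-sq: {report['logrank_chi_sq']:.6g} "
            f"(p = {report['logrank_p']:.3g})"
        )
        for h, a in report.get("auc", {}).items():
            lines.append(f"AUC at {h:g} months: {a:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_command(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write both synthetic cohorts plus the immune list and an example GMT."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    disc, labels = generate_discovery_cohort(cfg)
    surv, clin = generate_survival_cohort(cfg)
    paths = {
        "discovery_expression": out / "discovery_expression.tsv",
        "discovery_labels": out / "discovery_labels.tsv",
        "survival_expression": out / "survival_expression.tsv",
        "clinical": out / "clinical.tsv",
        "immune_list": out / "immune_genes.txt",
        "gmt": out / "example_sets.gmt",
    }
    write_expression_tsv(disc, paths["discovery_expression"])
    labels.to_frame().to_csv(paths["discovery_labels"], sep="\t",
                             index_label="sample")
    write_expression_tsv(surv, paths["survival_expression"])
    write_clinical_tsv(clin, paths["clinical"])
    paths["immune_list"].write_text("\n".join(cfg.immune_gene_names) + "\n")
    _write_example_gmt(cfg, paths["gmt"])
    return paths


def _write_example_gmt(cfg: SimConfig, path) -> None:
    """Gene sets over the simulated immune genes: the co-shifted partners
    of the group-effect lncRNAs (a truly enriched set) plus seeded random
    sets."""
    imm = cfg.immune_gene_names
    partners = [imm[j % len(imm)] for j in range(min(cfg.n_de_lnc, cfg.n_linked_lnc))]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 91]))
    lines = ["\t".join(["PLANTED_PARTNERS", "immune partners of group-effect lncRNAs",
                        *dict.fromkeys(partners)])]
    for k in range(3):
        members = rng.choice(imm, size=min(20, len(imm)), replace=False)
        lines.append("\t".join([f"RANDOM_SET_{k + 1}", "seeded random immune set",
                                *members]))
    Path(path).write_text("\n".join(lines) + "\n")
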