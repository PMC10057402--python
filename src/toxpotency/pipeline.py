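"""End-to-end orchestration with a config file, manifest and seeds.

Stage order per exposure: (optional two-channel normalization) ->
differential expression -> Williams-trend prefilter -> BMD modelling ->
potency estimators; in parallel, DEG ranks -> GSEA/ORA, signature fold
changes -> classifier, and the bioassay statistics. Every run writes a
manifest (parameters, seeds, per-stage row counts) sufficient to
reproduce it bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmd as bmd_mod
from . import io as tio
from .biostats import bioassay_tests
from .datatypes import ExpressionMatrix, GeneSetCollection
from .enrichment import gsea_nes, ora_fisher, rank_genes, surface_area_correlation
from .fibrosis import classify_conditions
from .potency import gene25_potency, lcrd, ntp_pathway_potency, rank_exposures
from .preprocess import differential_expression
from .simulate import SimConfig, make_compendium, make_gene_sets, simulate_bioassay, simulate_experiment
from .trend import prefilter, williams_scan

# the printed analysis settings of the study being emulated
PAPER_MODE = {
    "nperm_de": 30000,
    "fc_thresh": 1.5,
    "fdr_thresh": 0.05,
    "trend_p_cutoff": 0.5,
    "trend_fc_cutoff": 1.5,
    "bmr_factor": 1.349,
    "ntp_min_genes": 3,
    "ntp_min_fraction": 0.05,
    "lcrd_ratio": 1.66,
    "prob_hi": 0.8,
    "prob_lo": 0.2,
}


@dataclass
class PipelineConfig:
    """Paths plus per-stage parameters; defaults run a self-contained
    synthetic experiment."""

    outdir: str = "toxpotency_run"
    seed: int = 0
    matrix: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    compendium: str | None = None
    bet_table: str | None = None
    bioassay: str | None = None
    sim: dict = field(default_factory=dict)
    nperm_de: int = 2000
    nperm_trend: int = 1000
    nperm_gsea: int = 1000
    statistic: str = "Fs"
    fc_thresh: float = 1.5
    fdr_thresh: float = 0.05
    trend_p_cutoff: float = 0.05
    trend_fc_cutoff: float = 1.5
    bmr_factor: float = 1.349
    compute_bounds: bool = True
    ntp_min_genes: int = 3
    ntp_min_fraction: float = 0.05
    lcrd_ratio: float = 1.66
    prob_hi: float = 0.8
    prob_lo: float = 0.2
    paper_mode: bool = False

    def __post_init__(self) -> None:
        if self.paper_mode:
            for key, value in PAPER_MODE.items():
                if hasattr(self, key):
                    setattr(self, key, value)
        for name in ("fdr_thresh", "trend_p_cutoff", "prob_hi", "prob_lo"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"PipelineConfig.{name} outside [0, 1]")
        if self.fc_thresh < 1 or self.trend_fc_cutoff < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.bmr_factor <= 0 or self.lcrd_ratio <= 1:
            raise ValueError("bmr_factor must be > 0 and lcrd_ratio > 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Stage failures halt the run with the stage named; outputs written
    before the failure are preserved in the output directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "load_inputs"
    try:
        if config.matrix and config.metadata:
            em = tio.read_matrix(config.matrix, config.metadata)
            truth = None
            sim_cfg = None
        else:
            sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
            em, truth = simulate_experiment(sim_cfg)
            tio.write_matrix(em, out / "matrix.tsv", out / "metadata.tsv")
            tio.write_truth(truth, out / "truth.json")
        if config.gmt:
            sets = tio.read_gmt(config.gmt)
        elif sim_cfg is not None:
            sets = make_gene_sets(sim_cfg)
            tio.write_gmt(sets, out / "modules.gmt")
        else:
            sets = None
        manifest["stages"]["load_inputs"] = {
            "n_genes": len(em.gene_ids),
            "n_samples": len(em.sample_ids),
            "n_sets": len(sets) if sets else 0,
        }

        exposures = [e for e in pd.unique(em.samples["exposure"])]
        potency_estimates = []
        nes_records: list[pd.DataFrame] = []
        deg_counts, prefilter_counts, bmd_counts = {}, {}, {}
        for exposure in exposures:
            stage = f"differential_expression[{exposure}]"
            degs = differential_expression(
                em,
                exposure,
                statistic=config.statistic,
                nperm=config.nperm_de,
                seed=config.seed,
                fc_thresh=config.fc_thresh,
                fdr_thresh=config.fdr_thresh,
            )
            for dose, table in degs.items():
                tio.write_table(table.reset_index(names="gene_id"), out / f"deg_{exposure}_{dose:g}.tsv")
                deg_counts[f"{exposure}@{dose:g}"] = int(table["is_deg"].sum())

            stage = f"trend_prefilter[{exposure}]"
            sub = em.subset_exposure(exposure)
            trend = prefilter(
                williams_scan(sub, nperm=config.nperm_trend, seed=config.seed),
                p_cutoff=config.trend_p_cutoff,
                fc_cutoff=config.trend_fc_cutoff,
            )
            tio.write_table(trend.reset_index(names="gene_id"), out / f"trend_{exposure}.tsv")
            genes = trend.index[trend["pass"]].tolist()
            prefilter_counts[exposure] = len(genes)

            stage = f"bmd[{exposure}]"
            bmd_table = bmd_mod.run_bmd(
                sub, genes, bmr_factor=config.bmr_factor, compute_bounds=config.compute_bounds
            )
            tio.write_table(bmd_table.reset_index(), out / f"bmd_{exposure}.tsv")
            bmds = bmd_mod.passing_bmds(bmd_table)
            bmd_counts[exposure] = len(bmds)

            stage = f"potency[{exposure}]"
            if sets is not None:
                potency_estimates.append(
                    ntp_pathway_potency(
                        bmds, sets, exposure, config.ntp_min_genes, config.ntp_min_fraction
                    )
                )
            potency_estimates.append(gene25_potency(bmds, exposure))
            if bmds:
                potency_estimates.append(lcrd(bmds, exposure, ratio_thresh=config.lcrd_ratio))
            else:
                from .potency import PotencyEstimate

                potency_estimates.append(PotencyEstimate(exposure, "lcrd", None, False))

            stage = f"gsea[{exposure}]"
            if sets is not None:
                frames = []
                for dose, table in degs.items():
                    ranks = rank_genes(table)
                    nes = gsea_nes(ranks, sets, nperm=config.nperm_gsea, seed=config.seed)
                    frames.append(nes.reset_index().assign(exposure=exposure, dose=dose))
                gsea_all = pd.concat(frames, ignore_index=True)
                tio.write_table(gsea_all, out / f"gsea_{exposure}.tsv")
                nes_records.append(gsea_all)
                top_dose = max(degs)
                universe = list(em.gene_ids)
                deg_list = degs[top_dose].index[degs[top_dose]["is_deg"]].tolist()
                ora_rows = [
                    {"set": name, **ora_fisher(deg_list, universe, gs)}
                    for name, gs in sets.items()
                ]
                tio.write_table(pd.DataFrame(ora_rows), out / f"ora_{exposure}.tsv")

        stage = "potency_ranking"
        ranking = rank_exposures(potency_estimates)
        tio.write_table(ranking, out / "potency_ranking.tsv")

        stage = "surface_area_correlation"
        if config.bet_table and nes_records:
            bet_df = tio.read_table(config.bet_table)
            bet = dict(zip(bet_df["exposure"], bet_df["bet"].astype(float)))
            nes_all = pd.concat(nes_records, ignore_index=True)
            corr_rows = []
            for name, sub_nes in nes_all.groupby("set"):
                frame = sub_nes.rename(columns={"nes": "value"})[["exposure", "dose", "value"]]
                if len(frame) < 3:
                    continue
                rho, p = surface_area_correlation(frame, bet)
                corr_rows.append({"set": name, "rho": rho, "p": p, "n": len(frame)})
            tio.write_table(pd.DataFrame(corr_rows), out / "surface_correlation.tsv")

        stage = "classifier"
        calls = None
        panel_sets = sets.sets.get("signature") if sets is not None else None
        comp_labels = None
        if config.compendium:
            comp, comp_labels = tio.read_compendium(config.compendium)
        elif sim_cfg is not None:
            comp, comp_labels = make_compendium(sim_cfg)
            tio.write_compendium(comp, comp_labels, out / "compendium.tsv")
        if comp_labels is not None and panel_sets is not None:
            query = _signature_fold_changes(em, panel_sets)
            calls = classify_conditions(
                comp, comp_labels, query, hi=config.prob_hi, lo=config.prob_lo
            )
            tio.write_table(calls.reset_index(names="condition"), out / "fibrosis_calls.tsv")

        stage = "bioassay_stats"
        bio = None
        if config.bioassay:
            bio = tio.read_table(config.bioassay)
        elif sim_cfg is not None:
            bio = simulate_bioassay(sim_cfg)
            tio.write_table(bio, out / "bioassay.tsv")
        if bio is not None:
            results = pd.concat(
                [
                    bioassay_tests(bio, "neutrophils", method="kruskal_dunn"),
                    bioassay_tests(bio, "tail_dna", method="auto", seed=config.seed),
                ]
            )
            tio.write_table(results, out / "bioassay_stats.tsv")

        manifest["stages"].update(
            {
                "deg_counts": deg_counts,
                "prefilter_counts": prefilter_counts,
                "bmd_pass_counts": bmd_counts,
                "potency": {
                    f"{e.exposure_id}:{e.method}": (e.potency if e.defined else None)
                    for e in potency_estimates
                },
                "fibrosis_calls": (
                    {str(i): c for i, c in calls["call"].items()} if calls is not None else {}
                ),
            }
        )
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _signature_fold_changes(em: ExpressionMatrix, panel: list[str]) -> pd.DataFrame:
    """Per exposure-dose condition, mean log2 fold change vs the
    exposure's vehicle control over the signature panel."""
    rows = {}
    meta = em.samples.loc[em.values.columns]
    for exposure, sub in meta.groupby("exposure", sort=False):
        ctrl_cols = sub.index[sub["dose"] == 0]
        if len(ctrl_cols) == 0:
            continue
        ctrl = em.values.loc[panel, ctrl_cols].mean(axis=1)
        for dose in sorted(sub.loc[sub["dose"] > 0, "dose"].unique()):
            cols = sub.index[sub["dose"] == dose]
            fc = em.values.loc[panel, cols].mean(axis=1) - ctrl
            rows[f"{exposure}@{dose:g}"] = fc
    return pd.DataFrame(rows).T
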