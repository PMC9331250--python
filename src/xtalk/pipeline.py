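"""End-to-end pipeline: simulate -> DEG -> enrichment -> GRN -> network -> validate.

Stages communicate through tab-separated artifact files under the configured
output directory, so each stage can also be run individually from the CLI
against previously written artifacts. Any stage failure aborts the run with a
stage-labelled error. The run log records every threshold and the seed (and
no timestamps, so identically-configured runs are byte-identical).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import deg as deg_mod
from . import enrichment as enr_mod
from . import grn as grn_mod
from . import network as net_mod
from . import phenotype as phe_mod
from .config import PipelineConfig
from .errors import StageError, XtalkError
from .io import (
    CountMatrix,
    GeneSetCollection,
    PhenotypeTable,
    SampleSheet,
    read_count_matrix,
    read_gmt,
)
from .simulate import simulate_study

ANALYSES = {
    "lipid_fibrosis": ("lipid", "fibrosis"),
    "inflammation": ("inflammation",),
}

STAGES = ("simulate", "phenotype", "deg", "enrich", "grn", "network", "validate")


class Pipeline:
    """Stage runner bound to one configuration."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._log_lines: list[str] = []

    # -- plumbing ----------------------------------------------------------

    def path(self, name: str) -> Path:
        return self.outdir / name

    def log(self, message: str) -> None:
        self._log_lines.append(message)

    def write_log(self) -> None:
        lines = ["# xtalk run log"] + self.config.describe() + self._log_lines
        self.path("run_log.txt").write_text("\n".join(lines) + "\n")

    def _inputs(self) -> tuple[SampleSheet, CountMatrix, CountMatrix, GeneSetCollection]:
        cfg = self.config
        for name in ("liver_counts", "aorta_counts", "sample_sheet", "gene_sets"):
            if getattr(cfg, name) is None:
                raise StageError(
                    f"[inputs] {name} not configured (set it or add a simulate block)"
                )
        sheet = SampleSheet.read(cfg.sample_sheet)
        liver = read_count_matrix(cfg.liver_counts, sheet)
        aorta = read_count_matrix(cfg.aorta_counts, sheet)
        sets = read_gmt(cfg.gene_sets)
        return sheet, liver, aorta, sets

    def _run_stage(self, label: str, fn):
        try:
            return fn()
        except XtalkError as exc:
            raise StageError(f"[{label}] {exc}") from exc
        except Exception as exc:  # noqa: BLE001 - label unexpected failures too
            raise StageError(f"[{label}] {type(exc).__name__}: {exc}") from exc

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        if cfg.simulate is None:
            self.log("simulate\tskipped (inputs provided)")
            return
        params = dict(cfg.simulate)
        if "timepoints" in params:
            params["timepoints"] = tuple(params["timepoints"])
        study = simulate_study(seed=cfg.stage_seed("simulate"), **params)
        indir = self.path("inputs")
        study.write(indir)
        cfg.liver_counts = str(indir / "liver_counts.tsv")
        cfg.aorta_counts = str(indir / "aorta_counts.tsv")
        cfg.sample_sheet = str(indir / "sample_sheet.tsv")
        cfg.gene_sets = str(indir / "gene_sets.gmt")
        cfg.phenotype = str(indir / "phenotype.tsv")
        # independent follow-up study of the same planted biology, used for
        # cross-study validation of the inferred regulators
        study2 = simulate_study(
            seed=cfg.stage_seed("simulate_study2"), truth=study.truth, **params
        )
        deg2 = deg_mod.deg_all(
            study2.liver, study2.sheet, deg_p=cfg.deg_p, tissue="liver"
        )
        last = deg2["time_weeks"].max()
        deg2_last = deg2[deg2["time_weeks"] == last].reset_index(drop=True)
        deg2_path = self.path("study2_deg.tsv")
        deg2_last.to_csv(deg2_path, sep="\t", index=False)
        cfg.study2_deg = str(deg2_path)
        self.log(f"simulate\twrote inputs for {study.liver.shape[0]}+{study.aorta.shape[0]} genes")

    def stage_phenotype(self) -> None:
        cfg = self.config
        if cfg.phenotype is None:
            self.log("phenotype\tskipped (no phenotype table)")
            return
        table = PhenotypeTable.read(cfg.phenotype)
        report = phe_mod.phenotype_report(table)
        report.to_csv(self.path("phenotype_comparisons.tsv"), sep="\t", index=False)
        df = table.frame
        last = df["time_weeks"].max()
        end = df[df["time_weeks"] == last]
        fit = phe_mod.quadratic_r2(end["steatosis"], end["lesion_area"])
        pd.DataFrame(
            [
                {
                    "x": "steatosis",
                    "y": "lesion_area",
                    "time_weeks": last,
                    "b0": fit.b0,
                    "b1": fit.b1,
                    "b2": fit.b2,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value,
                }
            ]
        ).to_csv(self.path("quadratic_fit.tsv"), sep="\t", index=False)
        self.log(f"phenotype\tlesion~steatosis quadratic R2={fit.r_squared:.3f}")

    def stage_deg(self) -> None:
        cfg = self.config
        sheet, liver, aorta, _ = self._inputs()
        for tissue, cm in (("liver", liver), ("aorta", aorta)):
            table = deg_mod.deg_all(cm, sheet, deg_p=cfg.deg_p, tissue=tissue)
            table.to_csv(self.path(f"deg_{tissue}.tsv"), sep="\t", index=False)
            n_sig = int(table["significant"].sum())
            self.log(f"deg\t{tissue}: {n_sig} significant (gene,timepoint) records")

    def stage_enrich(self) -> None:
        cfg = self.config
        _, liver, aorta, sets = self._inputs()
        records = {}
        for tissue, cm in (("liver", liver), ("aorta", aorta)):
            table = pd.read_csv(self.path(f"deg_{tissue}.tsv"), sep="\t")
            universe = set(cm.frame.index[cm.frame.sum(axis=1) > 0])
            rec = enr_mod.enrich_all(table, sets, universe, enrich_p=cfg.enrich_p)
            rec.to_csv(self.path(f"enrichment_{tissue}.tsv"), sep="\t", index=False)
            records[tissue] = rec
        combined = pd.concat(records.values(), ignore_index=True)
        dynamics = enr_mod.process_dynamics(combined, top_cutoff=cfg.top_cutoff)
        dynamics.to_csv(self.path("process_dynamics.tsv"), sep="\t", index=False)
        overlap_rows = []
        for t in sorted(combined["time_weeks"].unique()):
            ov = enr_mod.dep_overlap(records["liver"], records["aorta"], t)
            overlap_rows.append(
                {
                    "time_weeks": t,
                    "n_liver": ov.n_liver,
                    "n_aorta": ov.n_aorta,
                    "n_shared": ov.n_shared,
                    "aorta_shared_fraction": ov.aorta_shared_fraction,
                }
            )
        pd.DataFrame(overlap_rows).to_csv(
            self.path("dep_overlap.tsv"), sep="\t", index=False
        )
        self.log(f"enrich\t{int(combined['dep'].sum())} DEP records")
        if cfg.make_plots:
            from .plots import plot_process_dynamics

            plot_process_dynamics(dynamics, self.path("process_dynamics.png"))

    def _analysis_genes(
        self, sets: GeneSetCollection, categories: tuple[str, ...]
    ) -> tuple[list[str], list[str]]:
        deg_liver = pd.read_csv(self.path("deg_liver.tsv"), sep="\t")
        deg_aorta = pd.read_csv(self.path("deg_aorta.tsv"), sep="\t")
        liver_degs = set(deg_liver.loc[deg_liver["significant"], "gene_id"])
        aorta_degs = set(deg_aorta.loc[deg_aorta["significant"], "gene_id"])
        source_pool = set()
        for s in sets.by_category(*categories):
            source_pool |= set(s.genes)
        target_pool = set()
        for s in sets.by_category("lipid", "inflammation", "fibrosis"):
            target_pool |= set(s.genes)
        sources = sorted(liver_degs & source_pool)
        targets = sorted(aorta_degs & target_pool)
        if not targets:
            targets = sorted(aorta_degs)
        return sources, targets

    def stage_grn(self) -> None:
        cfg = self.config
        sheet, liver, aorta, sets = self._inputs()
        for label, categories in ANALYSES.items():
            sources, targets = self._analysis_genes(sets, categories)
            if len(sources) < 2 or len(targets) < 2:
                raise StageError(
                    f"[grn] analysis {label}: need >=2 source and target genes "
                    f"(got {len(sources)}/{len(targets)})"
                )
            src_trajs = grn_mod.build_trajectories(liver, sheet, genes=sources)
            tgt_trajs = grn_mod.build_trajectories(aorta, sheet, genes=targets)
            est = grn_mod.TimeSeriesGRN(
                n_trees=cfg.n_trees,
                alpha_mode=cfg.alpha_mode,
                ensemble=cfg.ensemble,
                random_state=cfg.stage_seed(f"grn_{label}"),
            )
            est.fit(src_trajs, tgt_trajs)
            est.vim_matrix_.write(
                self.path(f"vim_{label}.tsv"), sidecar=self.path(f"vim_{label}.meta.tsv")
            )
            self.log(
                f"grn\t{label}: {len(sources)} sources x {len(targets)} targets"
            )

    def stage_network(self) -> None:
        cfg = self.config
        _, liver, aorta, sets = self._inputs()
        liver_genes = set(liver.frame.index)
        aorta_genes = set(aorta.frame.index)
        for label in ANALYSES:
            vim = grn_mod.VimMatrix.read(self.path(f"vim_{label}.tsv"))
            edges = net_mod.select_edges(vim, percentile=cfg.vim_percentile)
            # direction filter re-asserted: every retained edge must run
            # liver -> aorta
            bad = [
                r.source
                for r in edges.itertuples()
                if r.source not in liver_genes or r.target not in aorta_genes
            ]
            if bad:
                raise StageError(
                    f"[network] {label}: edges not directed liver->aorta: {bad}"
                )
            edges.to_csv(self.path(f"edges_{label}.tsv"), sep="\t", index=False)
            graph = net_mod.assemble_network(edges, sets, label=label)
            nodes_df, edges_df = net_mod.network_tables(graph)
            nodes_df.to_csv(self.path(f"network_nodes_{label}.tsv"), sep="\t", index=False)
            edges_df.to_csv(self.path(f"network_edges_{label}.tsv"), sep="\t", index=False)
            self.log(f"network\t{label}: {len(edges)} edges retained")

    def stage_validate(self) -> None:
        cfg = self.config
        deg_liver = pd.read_csv(self.path("deg_liver.tsv"), sep="\t")
        last = deg_liver["time_weeks"].max()
        lfc = deg_liver[deg_liver["time_weeks"] == last].set_index("gene_id")["log2fc"]
        regulators: list[tuple[str, str]] = []
        seen = set()
        for label in ANALYSES:
            edges = pd.read_csv(self.path(f"edges_{label}.tsv"), sep="\t")
            for gene in edges["source"]:
                if gene in seen or gene not in lfc.index:
                    continue
                seen.add(gene)
                regulators.append((gene, "up" if lfc[gene] > 0 else "down"))
        regulators.sort()
        if cfg.study2_deg is None:
            report = net_mod.ConcordanceReport(
                table=pd.DataFrame(columns=net_mod.CONCORDANCE_COLUMNS),
                n_concordant=0,
                n_discordant=0,
                n_not_de=0,
            )
            self.log("validate\tskipped concordance (no second-study DEG table)")
        else:
            deg2 = pd.read_csv(cfg.study2_deg, sep="\t")
            report = net_mod.concordance(regulators, deg2, fc_cutoff=cfg.fc_cutoff)
            self.log(
                f"validate\tconcordant={report.n_concordant} "
                f"discordant={report.n_discordant} not_de={report.n_not_de}"
            )
        report.write(self.path("concordance.tsv"))
        if cfg.make_plots and len(report.table):
            from .plots import plot_concordance_heatmap

            plot_concordance_heatmap(report.table, self.path("concordance.png"))

    # -- driver ------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> dict[str, Path]:
        for stage in stages:
            if stage not in STAGES:
                raise StageError(f"[pipeline] unknown stage {stage!r}")
            self._run_stage(stage, getattr(self, f"stage_{stage}"))
        self.write_log()
        return {p.name: p for p in sorted(self.outdir.glob("*.tsv"))}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage under ``config``; returns the artifact paths."""
    return Pipeline(config).run()
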