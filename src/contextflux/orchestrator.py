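"""End-to-end pipeline: expression preprocessing -> tiers -> context
extraction -> condition submodels -> FVA status calls -> enrichment and
reporter metabolites.

Two entry modes share one code path: *user-data* mode reads a model
(SBML/JSON), an expression matrix + metadata, and optional biomass / medium /
marker / gene-set files from the paths in :class:`PipelineConfig`;
*synthetic demo* mode (any of those paths left unset) generates the toy
network and a batch-structured expression matrix with the kynurenine-like
branch planted down in naive cells, the scenario every stage is expected to
recover.

Every stage writes its table under ``out_dir``; the resolved configuration
is written next to the outputs and all randomness flows from a single root
seed split per stage, so identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (context_extraction, enrichment, expression, flux_compare,
               model_io, reaction_scoring, reporter, synthetic_data)
from .context_extraction import ExtractionParams
from .expression import ExpressionMatrix
from .flux_compare import LOGFC_THRESHOLDS

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "demo_config",
           "DEMO_MARKERS", "demo_expression_spec"]

log = logging.getLogger("contextflux")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# Planted marker panel of the synthetic demo: four genes with real condition
# effects plus one null "candidate marker" that must come out non-significant.
DEMO_MARKERS = {
    "gene_1001": "naive",
    "gene_1002": "naive",
    "gene_1003": "primed",
    "gene_1004": "primed",
    "gene_1005": "naive",   # planted null
}
_DEMO_MARKER_LOGFC = {"gene_1001": 2.0, "gene_1002": 2.0,
                      "gene_1003": -2.0, "gene_1004": -2.0}
DEMO_TRP_LOGFC = -1.5


@dataclass
class PipelineConfig:
    # input paths; None switches the synthetic demo on for that input
    model_path: str | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    biomass_path: str | None = None
    medium_path: str | None = None
    gene_sets_path: str | None = None
    markers_path: str | None = None
    out_dir: str = "contextflux_out"

    # stage parameters
    high_frac: float = 0.10
    neg_frac: float = 0.10
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    objective_fraction: float = 0.9
    logfc_thresholds: tuple[float, ...] = LOGFC_THRESHOLDS
    padj_threshold: float = 0.05
    reporter_n_background: int = 10000
    reporter_alpha: float = 0.05
    kmeans_k: int = 2
    seed: int = 0

    # synthetic demo parameters
    demo_trp_logfc: float = DEMO_TRP_LOGFC

    def validate(self) -> None:
        if not (0 < self.high_frac and 0 < self.neg_frac
                and self.high_frac + self.neg_frac < 1):
            raise ValueError("tier fractions must be positive and sum below 1")
        if not 0 <= self.objective_fraction <= 1:
            raise ValueError("objective_fraction must lie in [0, 1]")
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must lie in (0, 1)")
        if self.reporter_n_background < 100:
            raise ValueError("reporter_n_background must be >= 100")
        if any(t <= 0 for t in self.logfc_thresholds):
            raise ValueError("logFC thresholds must be positive")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["logfc_thresholds"] = list(self.logfc_thresholds)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "extraction" in doc and isinstance(doc["extraction"], dict):
            doc["extraction"] = ExtractionParams(**doc["extraction"])
        if "logfc_thresholds" in doc:
            doc["logfc_thresholds"] = tuple(doc["logfc_thresholds"])
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config(out_dir: str, seed: int = 0, **overrides) -> PipelineConfig:
    """Configuration of the bundled synthetic demo."""
    return PipelineConfig(out_dir=str(out_dir), seed=seed, **overrides)


def demo_expression_spec(seed: int,
                         trp_logfc: float = DEMO_TRP_LOGFC
                         ) -> synthetic_data.ExpressionSimSpec:
    """The demo's expression scenario: batch structure, planted markers, and
    the tryptophan/kynurenine-like branch down-regulated in naive cells."""
    spec = synthetic_data.ExpressionSimSpec(
        de_genes=dict(_DEMO_MARKER_LOGFC), seed=seed)
    spec = synthetic_data.plant_pathway_downregulation(
        spec, synthetic_data.TRP_BRANCH_GENES, trp_logfc)
    return spec


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return inner
    return wrap


def _read_two_column_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {str(k): float(v) for k, v in zip(df[0], df[1])}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the in-memory stage results.

    Outputs written under ``config.out_dir``: the resolved config, the
    (possibly simulated) inputs, per-stage TSV tables, the extracted model
    (JSON), and ``run.log``.  Any stage failure raises
    :class:`PipelineError` naming the stage; earlier outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        config.to_yaml(out / "config.resolved.yaml")
        root = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(4)]
        sim_seed, kmeans_seed, reporter_seed, _ = seeds
        log.info("root seed %d; stage seeds sim=%d kmeans=%d reporter=%d",
                 config.seed, sim_seed, kmeans_seed, reporter_seed)

        # ---------------- inputs ----------------
        synthetic = config.model_path is None or config.expression_path is None

        @_stage("load_inputs")
        def load_inputs():
            if config.model_path is not None:
                model = model_io.read_model(config.model_path)
            else:
                model = synthetic_data.make_toy_network(
                    synthetic_data.ToyNetworkSpec(seed=sim_seed))
                model_io.write_model(model, out / "generic_model.json")
            if config.expression_path is not None:
                x = ExpressionMatrix.from_tsv(config.expression_path,
                                              config.metadata_path)
            else:
                spec = demo_expression_spec(sim_seed, config.demo_trp_logfc)
                x = synthetic_data.simulate_expression(model.genes, spec)
                x.to_tsv(out / "expression_raw.tsv", out / "sample_metadata.tsv")
            if config.markers_path is not None:
                mk = pd.read_csv(config.markers_path, sep="\t", header=None)
                markers = {str(g): str(d) for g, d in zip(mk[0], mk[1])}
            else:
                markers = dict(DEMO_MARKERS) if synthetic else {}
            return model, x, markers

        model, x_raw, markers = load_inputs()
        log.info("model %s: %d metabolites, %d reactions, %d genes", model.id,
                 *context_extraction.model_stats(model))
        log.info("expression: %d genes x %d samples", *x_raw.values.shape)

        # ---------------- expression stages ----------------
        @_stage("normalize")
        def do_normalize():
            return expression.normalize(x_raw)

        x_norm = do_normalize()

        @_stage("combat")
        def do_combat():
            xc = expression.combat_correct(x_norm)
            xc.to_tsv(out / "expression_corrected.tsv",
                      out / "sample_metadata_corrected.tsv")
            return xc

        x_corr = do_combat()

        @_stage("pca_kmeans")
        def do_pca_kmeans():
            n_comp = min(10, len(x_corr.samples) - 1, len(x_corr.genes))
            scores, explained = expression.pca(x_corr, n_comp)
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            _, sil_cond, ari_cond = expression.kmeans_heterogeneity(
                scores, config.kmeans_k, x_corr.condition, seed=kmeans_seed)
            naive = x_corr.subset_samples(
                x_corr.samples[(x_corr.condition == "naive").to_numpy()])
            n_comp_n = min(10, len(naive.samples) - 1, len(naive.genes))
            scores_n, _ = expression.pca(naive, n_comp_n)
            _, sil_naive, ari_naive_batch = expression.kmeans_heterogeneity(
                scores_n, 2, naive.batch, seed=kmeans_seed)
            report = pd.DataFrame([
                {"analysis": "all_samples_k%d" % config.kmeans_k,
                 "mean_silhouette": sil_cond, "ari_vs_condition": ari_cond},
                {"analysis": "naive_only_k2",
                 "mean_silhouette": sil_naive, "ari_vs_batch": ari_naive_batch},
            ])
            report.to_csv(out / "clustering_report.tsv", sep="\t", index=False)
            log.info("clustering: ARI vs condition %.3f; naive-only silhouette %.3f",
                     ari_cond, sil_naive)
            return scores, explained, report

        results["pca"] = do_pca_kmeans()

        @_stage("differential_expression")
        def do_de():
            de = expression.differential_expression(x_corr)
            de.to_csv(out / "differential_expression.tsv", sep="\t",
                      index_label="gene")
            n_sig = int((de["adj_p"] < config.padj_threshold).sum())
            log.info("DE: %d/%d genes significant at BH %.2f", n_sig, len(de),
                     config.padj_threshold)
            return de

        de = do_de()
        results["de"] = de

        @_stage("marker_panel")
        def do_markers():
            table, missing = expression.marker_panel(de, markers)
            table.to_csv(out / "marker_panel.tsv", sep="\t")
            if missing:
                log.warning("markers missing from DE universe: %s", missing)
            return table, missing

        results["markers"] = do_markers()

        # ---------------- scoring, tiers, extraction ----------------
        @_stage("reaction_scoring")
        def do_scoring():
            gene_expr = reaction_scoring.summarize_gene_expression(
                x_corr, model_genes=model.genes)
            scores = reaction_scoring.score_reactions(model, gene_expr)
            tiers = reaction_scoring.assign_tiers(model, scores,
                                                  config.high_frac, config.neg_frac)
            if model.objective_id is not None:
                # growth is the context's defining demand: keep it in the core
                tiers[model.objective_id] = "high"
            table = reaction_scoring.tier_table(model, scores, tiers)
            table.to_csv(out / "reaction_tiers.tsv", sep="\t")
            counts = table["tier"].value_counts().to_dict()
            log.info("tiers: %s", counts)
            return scores, tiers

        scores, tiers = do_scoring()

        @_stage("context_extraction")
        def do_extract():
            res = context_extraction.corda_extract(model, tiers, config.extraction)
            model_io.write_model(res.submodel, out / "context_model.json")
            report = pd.DataFrame(
                {
                    "origin_tier": [tiers[r] for r in model.reaction_ids()],
                    "included": [r in res.included_ids() for r in model.reaction_ids()],
                    "tally": [res.dependency_tally.get(r, 0)
                              for r in model.reaction_ids()],
                },
                index=pd.Index(model.reaction_ids(), name="reaction"),
            )
            report.to_csv(out / "extraction_report.tsv", sep="\t")
            log.info("extraction: %d of %d reactions kept",
                     len(res.submodel.reactions), len(model.reactions))
            return res

        extraction = do_extract()
        results["extraction"] = extraction
        context = extraction.submodel

        # ---------------- biomass, medium, condition models, FVA ----------
        @_stage("prepare_flux_model")
        def do_prepare():
            m = context
            if config.biomass_path is not None:
                m = flux_compare.add_biomass(m, _read_two_column_tsv(config.biomass_path))
            if m.objective_id is None:
                raise ValueError("model has no growth objective; provide a biomass table")
            if config.medium_path is not None:
                m = flux_compare.apply_medium(m, _read_two_column_tsv(config.medium_path))
            return m

        flux_model = do_prepare()

        @_stage("fva_compare")
        def do_fva():
            calls = {}
            fva_tables = {}
            for thr in config.logfc_thresholds:
                naive_m = flux_compare.derive_condition_model(
                    flux_model, de, "naive", thr, config.padj_threshold)
                primed_m = flux_compare.derive_condition_model(
                    flux_model, de, "primed", thr, config.padj_threshold)
                fva_n = flux_compare.fva(naive_m, config.objective_fraction)
                fva_p = flux_compare.fva(primed_m, config.objective_fraction)
                fva_n.to_csv(out / f"fva_naive_thr{thr:.2f}.tsv", sep="\t",
                             index_label="reaction")
                fva_p.to_csv(out / f"fva_primed_thr{thr:.2f}.tsv", sep="\t",
                             index_label="reaction")
                calls[thr] = flux_compare.classify_status(fva_n, fva_p)
                fva_tables[thr] = (fva_n, fva_p)
                log.info("threshold %.2f: status counts %s", thr,
                         calls[thr]["status"].value_counts().to_dict())
            up_naive, up_primed = flux_compare.consensus_status(calls)
            status = pd.DataFrame(
                {f"status_at_{thr:.2f}": calls[thr]["status"]
                 for thr in config.logfc_thresholds})
            status["robust_call"] = [
                "up_naive" if r in set(up_naive)
                else "up_primed" if r in set(up_primed) else ""
                for r in status.index
            ]
            status.to_csv(out / "reaction_status.tsv", sep="\t",
                          index_label="reaction")
            log.info("robust sets: %d up-naive, %d up-primed",
                     len(up_naive), len(up_primed))
            return calls, fva_tables, up_naive, up_primed

        calls, fva_tables, up_naive, up_primed = do_fva()
        results["status"] = calls
        results["up_naive"], results["up_primed"] = up_naive, up_primed

        # ---------------- enrichment ----------------
        @_stage("enrichment")
        def do_enrich():
            if config.gene_sets_path is not None:
                collection = enrichment.read_gmt(config.gene_sets_path)
            else:
                sets = synthetic_data.toy_gene_sets(model)
                collection = enrichment.GeneSetCollection(sets=sets)
                enrichment.write_gmt(collection, out / "gene_sets.gmt")
            universe = set(model.genes)
            tables = {}
            for label, rxns in (("up_naive", up_naive), ("up_primed", up_primed)):
                genes = flux_compare.genes_from_reactions(flux_model, rxns)
                table = enrichment.enrich(genes, collection, universe)
                table.to_csv(out / f"enrichment_{label}.tsv", sep="\t")
                tables[label] = table
                if len(table):
                    log.info("%s: top set %s (adj_p %.3g)", label,
                             table.index[0], table["adj_p"].iloc[0])
            return tables

        results["enrichment"] = do_enrich()

        # ---------------- reporter metabolites ----------------
        @_stage("reporter")
        def do_reporter():
            nb = reporter.metabolite_gene_neighborhood(context)
            scores_r = reporter.reporter_scores(
                nb, de, n_background=config.reporter_n_background,
                seed=reporter_seed)
            scores_r.to_csv(out / "reporter_scores.tsv", sep="\t")
            sig = reporter.significant_reporters(scores_r, config.reporter_alpha)
            sig.to_csv(out / "reporter_significant.tsv", sep="\t")
            log.info("reporter: %d/%d metabolites significant at BH %.2f",
                     len(sig), len(scores_r), config.reporter_alpha)
            return scores_r, sig

        results["reporter"] = do_reporter()
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
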