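"""End-to-end orchestration: screen → targets → disease genes → candidates
→ network → enrichment, from a single validated config.

Each stage writes its intermediate table into the output directory and the
run finishes with ``report.json`` holding every headline count, recomputed
from the in-memory objects that were just serialized (so the report and the
files cannot drift).  A failed stage leaves a ``FAILED`` marker naming the
stage; reruns on unchanged inputs are bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io
from .candidates import expand_interactors, map_candidates
from .datatypes import ValidationError
from .degs import call_degs, deg_gene_set, merge_disease_genes, volcano_table
from .enrich import (
    enrichment_table,
    hypergeom_enrich,
    kappa_group,
    significant_rows,
    summarize_categories,
)
from .network import (
    NetworkStats,
    build_network,
    network_stats,
    pooled_key_targets,
    select_key_nodes,
)
from .screen import ScreenConfig, herb_overlap_table, merge_sources, screen_adme
from .targets import (
    build_compendium,
    common_targets_by_herb_count,
    coverage_stats,
    filter_predicted,
)

logger = logging.getLogger("herbnet")


@dataclass
class PipelineConfig:
    """Validated paths and thresholds for one pipeline run."""

    tcmsp_ingredients: Path
    hit_ingredients: Path
    validated_targets: Path
    predicted_targets: Path
    expression: Path
    groups: Path
    curated: dict[str, Path]
    edges: Path
    gene_sets: list[Path]
    output_dir: Path

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True
    sim_min: float = 1.0
    pred_score_min: float = 0.0
    p_max: float = 0.05
    fc_min: float = 1.5
    fc_scale: str = "log"
    score_min: float = 0.9
    edge_scores_0_999: bool = False
    include_interactor_interactor: bool = True
    q_max: float = 0.05
    kappa_min: float = 0.4
    min_herbs: int = 7

    def validate(self) -> None:
        for name in (
            "tcmsp_ingredients",
            "hit_ingredients",
            "validated_targets",
            "predicted_targets",
            "expression",
            "groups",
            "edges",
        ):
            path = Path(getattr(self, name))
            if not path.exists():
                raise ValidationError(f"config path {name} does not exist: {path}")
        for source, path in self.curated.items():
            if not Path(path).exists():
                raise ValidationError(
                    f"curated list for {source!r} does not exist: {path}"
                )
        for path in self.gene_sets:
            if not Path(path).exists():
                raise ValidationError(f"gene-set file does not exist: {path}")
        for bound, lo, hi in (
            ("p_max", 0.0, 1.0),
            ("score_min", 0.0, 1.0),
            ("q_max", 0.0, 1.0),
            ("dl_min", 0.0, 1.0),
        ):
            v = getattr(self, bound)
            if not (lo <= v <= hi):
                raise ValidationError(f"{bound}={v} outside [{lo}, {hi}]")
        if self.fc_min < 1.0:
            raise ValidationError(f"fc_min must be >= 1, got {self.fc_min}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        cfg = cls(
            tcmsp_ingredients=resolve(inputs["tcmsp_ingredients"]),
            hit_ingredients=resolve(inputs["hit_ingredients"]),
            validated_targets=resolve(inputs["validated_targets"]),
            predicted_targets=resolve(inputs["predicted_targets"]),
            expression=resolve(inputs["expression"]),
            groups=resolve(inputs["groups"]),
            curated={k: resolve(v) for k, v in inputs.get("curated", {}).items()},
            edges=resolve(inputs["edges"]),
            gene_sets=[resolve(p) for p in inputs.get("gene_sets", [])],
            output_dir=resolve(raw["output_dir"]),
            **params,
        )
        cfg.validate()
        return cfg


def run_stages(
    merged_ingredients,
    validated,
    predicted,
    matrix,
    curated,
    edges,
    gene_sets=None,
    *,
    sim_min: float = 1.0,
    pred_score_min: float = 0.0,
    p_max: float = 0.05,
    fc_min: float = 1.5,
    score_min: float = 0.9,
    q_max: float = 0.05,
    kappa_min: float = 0.4,
) -> dict:
    """Run every analysis stage on in-memory objects, no file IO.

    Takes the merged active-ingredient list, raw validated/predicted
    associations, an :class:`~herbnet.datatypes.ExpressionMatrix`, the
    curated source→genes map, canonicalized scored edges and (optionally) a
    gene-set collection; returns a dict with every intermediate object
    (``compendium``, ``degs``, ``disease``, ``candidates``, ``network``,
    ``stats``, ``key_ingredients``, ``key_targets``, ``enrichment``).
    """
    predicted_kept = filter_predicted(predicted, sim_min, pred_score_min)
    compendium = build_compendium(validated, predicted_kept, merged_ingredients)
    degs = call_degs(matrix, p_max, fc_min)
    disease = merge_disease_genes(deg_gene_set(degs), curated)
    cands = map_candidates(compendium, disease)
    cands = expand_interactors(cands, edges, score_min)
    net = build_network(cands, compendium)
    if net.n_nodes:
        stats = network_stats(net)
        key_ing, key_cand, key_prot = select_key_nodes(net, stats)
    else:
        stats = NetworkStats(0, 0, 0.0, 0.0, {})
        key_ing, key_cand, key_prot = [], [], []
    pooled = pooled_key_targets(key_cand, key_prot, stats)
    enrichment = []
    if gene_sets is not None and pooled:
        background = compendium.target_universe | cands.interactors
        query = set(pooled)
        enrichment = hypergeom_enrich(query, gene_sets, background)
        sig = significant_rows(enrichment, q_max)
        if sig:
            kappa_group(sig, gene_sets, query, kappa_min)
    return {
        "compendium": compendium,
        "degs": degs,
        "disease": disease,
        "candidates": cands,
        "network": net,
        "stats": stats,
        "key_ingredients": key_ing,
        "key_candidate_targets": key_cand,
        "key_proteins": key_prot,
        "key_targets": pooled,
        "enrichment": enrichment,
    }


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(
        isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
        for h in logger.handlers
    ):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write all outputs, return the run report."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    handler = _setup_logging(out)
    stage = "setup"
    try:
        # ---- ingredient screen ------------------------------------------
        stage = "screen"
        tcmsp = io.read_ingredient_table(cfg.tcmsp_ingredients, "tcmsp")
        hit = io.read_ingredient_table(cfg.hit_ingredients, "hit")
        screen_cfg = ScreenConfig(cfg.ob_min, cfg.dl_min, cfg.inclusive)
        kept = screen_adme(tcmsp, screen_cfg)
        merged = merge_sources(kept, hit)
        logger.info(
            "screen: %d ADME-scored -> %d kept; %d curated; %d merged",
            len(tcmsp), len(kept), len(hit), len(merged),
        )
        io.write_ingredient_table(merged, out / "merged_ingredients.tsv")
        overlap = herb_overlap_table(merged)
        overlap.to_csv(out / "herb_overlap.tsv", sep="\t", index=False)

        # ---- target compendium ------------------------------------------
        stage = "targets"
        validated = io.read_association_table(cfg.validated_targets, "validated")
        predicted = io.read_association_table(cfg.predicted_targets, "predicted")
        predicted_kept = filter_predicted(predicted, cfg.sim_min, cfg.pred_score_min)
        merged_ids = {r.ingredient_id for r in merged}
        validated = [a for a in validated if a.ingredient_id in merged_ids]
        predicted_kept = [a for a in predicted_kept if a.ingredient_id in merged_ids]
        compendium = build_compendium(validated, predicted_kept, merged)
        logger.info(
            "targets: %d associations over %d genes",
            len(compendium.associations), len(compendium.target_universe),
        )
        rows = sorted(compendium.associations)
        with open(out / "compendium.tsv", "w") as fh:
            fh.write("ingredient\tgene\tevidence\n")
            for ing, gene, ev in rows:
                fh.write(f"{ing}\t{gene}\t{ev}\n")
        coverage = coverage_stats(compendium)
        coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
        buckets = common_targets_by_herb_count(compendium, cfg.min_herbs)
        with open(out / "common_targets.tsv", "w") as fh:
            fh.write("herb_count\tn_genes\tgenes\n")
            for count in sorted(buckets, reverse=True):
                fh.write(
                    f"{count}\t{len(buckets[count])}\t{','.join(sorted(buckets[count]))}\n"
                )

        # ---- disease genes ----------------------------------------------
        stage = "disease_genes"
        matrix = io.read_expression(cfg.expression, cfg.groups)
        degs = call_degs(matrix, cfg.p_max, cfg.fc_min, fc_scale=cfg.fc_scale)
        volcano = volcano_table(degs)
        volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
        deg_df = volcano.assign(
            fc=[d.fc for d in degs], p=[d.p for d in degs], q=[d.q for d in degs]
        )
        deg_df.to_csv(out / "degs.tsv", sep="\t", index=False)
        curated = {s: io.read_gene_list(p) for s, p in cfg.curated.items()}
        disease = merge_disease_genes(deg_gene_set(degs), curated)
        logger.info(
            "disease genes: %d DEGs (%d up, %d down) + curated -> %d merged",
            volcano.attrs["n_deg"], volcano.attrs["n_up"], volcano.attrs["n_down"],
            len(disease.genes),
        )
        with open(out / "disease_genes.tsv", "w") as fh:
            fh.write("gene\tsources\n")
            for gene in sorted(disease.genes):
                fh.write(f"{gene}\t{','.join(sorted(disease.provenance[gene]))}\n")

        # ---- candidate mapping ------------------------------------------
        stage = "candidates"
        cands = map_candidates(compendium, disease)
        edges = io.read_edge_table(cfg.edges, scores_0_999=cfg.edge_scores_0_999)
        cands = expand_interactors(
            cands, edges, cfg.score_min, cfg.include_interactor_interactor
        )
        logger.info(
            "candidates: %d candidates, %d interactors, %d kept edges",
            len(cands.candidates), len(cands.interactors), len(cands.kept_edges),
        )
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("gene\tevidence\n")
            for gene in sorted(cands.candidates):
                fh.write(f"{gene}\t{cands.evidence_of[gene]}\n")
        (out / "interactors.tsv").write_text(
            "gene\n" + "".join(f"{g}\n" for g in sorted(cands.interactors))
        )
        io.write_edge_table(cands.kept_edges, out / "kept_edges.tsv")

        # ---- network -----------------------------------------------------
        stage = "network"
        net = build_network(cands, compendium)
        if net.n_nodes == 0:
            logger.warning("empty candidate set: network and enrichment are empty")
            stats = NetworkStats(0, 0, 0.0, 0.0, {})
            key_ing, key_cand, key_prot = [], [], []
        else:
            stats = network_stats(net)
            key_ing, key_cand, key_prot = select_key_nodes(net, stats)
        key_all = key_ing + key_cand + key_prot
        pooled = pooled_key_targets(key_cand, key_prot, stats)
        logger.info(
            "network: %d nodes, %d edges, mean degree %.3f; %d key ingredients, "
            "%d key targets",
            stats.n_nodes, stats.n_edges, stats.mean_degree, len(key_ing), len(pooled),
        )
        io.write_network(net, stats.degrees, out / "network.sif", "sif")
        io.write_network(
            net, stats.degrees, out / "network.graphml", "graphml", key_nodes=key_all
        )
        io.write_network(
            net, stats.degrees, out / "node_table.tsv", "node_table", key_nodes=key_all
        )
        nx_graph = net.to_networkx()
        mean_neighbors = (
            sum(len(list(nx_graph.neighbors(n))) for n in nx_graph) / stats.n_nodes
            if stats.n_nodes
            else 0.0
        )
        stats_payload = {
            "n_nodes": stats.n_nodes,
            "n_edges": stats.n_edges,
            "mean_degree": stats.mean_degree,
            "mean_neighbors": mean_neighbors,
            "key_threshold": stats.key_threshold,
            "key_ingredients": key_ing,
            "key_candidate_targets": key_cand,
            "key_proteins": key_prot,
            "key_targets_pooled": pooled,
        }
        (out / "network_stats.json").write_text(
            json.dumps(stats_payload, indent=2, sort_keys=True) + "\n"
        )

        # ---- enrichment --------------------------------------------------
        stage = "enrichment"
        sets = io.read_gmt(cfg.gene_sets[0]) if cfg.gene_sets else None
        for extra in cfg.gene_sets[1:]:
            more = io.read_gmt(extra)
            for tid, term in more.terms.items():
                sets.add(tid, term)
        summary: dict = {}
        enr_rows = []
        if sets is not None and pooled:
            background = compendium.target_universe | cands.interactors
            query = set(pooled)
            enr_rows = hypergeom_enrich(query, sets, background)
            sig = significant_rows(enr_rows, cfg.q_max)
            if sig:
                kappa_group(sig, sets, query, cfg.kappa_min)
                summary = summarize_categories(sig)
            enrichment_table(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            for category, df in summary.items():
                df.to_csv(out / f"enrichment_groups_{category}.tsv", sep="\t", index=False)
        n_sig = len(significant_rows(enr_rows, cfg.q_max)) if enr_rows else 0
        logger.info("enrichment: %d terms tested, %d significant", len(enr_rows), n_sig)

        # ---- report ------------------------------------------------------
        stage = "report"
        top_groups = {
            category: {
                "group_name": df.iloc[0]["group_name"],
                "group_share_pct": float(df.iloc[0]["group_share_pct"]),
                "n_terms": int(df.iloc[0]["n_terms"]),
            }
            for category, df in summary.items()
            if len(df)
        }
        validated_genes = {
            g for g in cands.candidates if cands.evidence_of[g] == "validated"
        }
        report = {
            "n_ingredients_screened_in": len(kept),
            "n_ingredients_curated": len(hit),
            "n_active_ingredients": len(merged),
            "n_targets": len(compendium.target_universe),
            "n_validated_targets": len(
                {g for (_, g, ev) in compendium.associations if ev == "validated"}
            ),
            "n_predicted_targets": len(
                {g for (_, g, ev) in compendium.associations if ev == "predicted"}
            ),
            "n_degs": volcano.attrs["n_deg"],
            "n_degs_up": volcano.attrs["n_up"],
            "n_degs_down": volcano.attrs["n_down"],
            "n_disease_genes": len(disease.genes),
            "n_candidates": len(cands.candidates),
            "n_candidates_validated": len(validated_genes),
            "n_candidates_predicted": len(cands.candidates) - len(validated_genes),
            "n_interactors": len(cands.interactors),
            "n_kept_edges": len(cands.kept_edges),
            "n_nodes": stats.n_nodes,
            "n_edges": stats.n_edges,
            "mean_degree": stats.mean_degree,
            "key_threshold": stats.key_threshold,
            "key_ingredients": key_ing,
            "n_key_targets": len(pooled),
            "key_targets": pooled,
            "n_enriched_terms": len(enr_rows),
            "top_groups": top_groups,
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        return report
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
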