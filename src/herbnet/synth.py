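"""Synthetic pipeline inputs with planted ground truth.

Every external data source the pipeline consumes — ADME-scored and curated
herb→ingredient tables, validated/predicted target associations, a
two-group expression matrix, curated disease-gene lists, a scored PPI edge
table and GMT annotation sets — is emulated here with known ground truth:

* a configurable number of **hub ingredients** wired to a target fan-out
  far above the median and covering most planted disease genes, so the
  degree-centrality rule downstream must recover them;
* **planted differentially expressed genes** with stated log2 fold
  changes on top of i.i.d. Gaussian noise;
* a **planted enriched pathway** whose genes are over-sampled from the
  disease-reachable part of the target universe.

All sampling is driven by named substreams spawned from one seed, so each
generator writes byte-identical files for the same (params, seed) pair and
adding a new stream never shifts an existing one.  Default sizes follow a
realistic multi-herb formula study: 12 herbs, ~170 active ingredients,
~900 targets, ~110 disease genes and a few-hundred-node network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .datatypes import IngredientRecord, TargetAssociation, ValidationError
from .screen import ScreenConfig, merge_sources, screen_adme

_STREAMS = ("kb", "targets", "expr", "curated", "ppi", "genesets")


@dataclass
class SynthParams:
    """Generation parameters; defaults give the paper-scale preset."""

    # knowledgebase
    n_herbs: int = 12
    n_tcmsp: int = 480          # ADME-scored compounds before screening
    n_hit: int = 39             # curated bioactive compounds
    n_shared_names: int = 0     # compound names present in both sources
    herb_overlap_prob: float = 0.05
    ob_range: tuple[float, float] = (0.0, 60.0)   # straddles the 30% cut
    dl_range: tuple[float, float] = (0.0, 0.4)    # straddles the 0.18 cut
    # targets
    n_genes: int = 900          # target gene universe
    mean_targets: float = 8.0   # Poisson fan-out per non-hub active ingredient
    validated_frac: float = 0.25
    n_hubs: int = 3
    hub_fanout: int = 300
    hub_disease_coverage: float = 0.9
    hub_validated_frac: float = 0.3
    # expression
    n_expr_genes: int = 2000
    n_per_group: int = 6
    n_up: int = 23
    n_down: int = 28
    deg_in_universe_frac: float = 0.35
    log2fc_range: tuple[float, float] = (1.0, 2.5)
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # curated disease genes
    n_curated_pool: int = 59
    curated_in_universe_frac: float = 0.35
    curated_per_source: int = 25
    # PPI
    n_proteins: int = 100
    n_edges: int = 1200
    high_score_frac: float = 0.35
    # gene sets
    n_terms_per_category: int = 15
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_size: int = 30
    planted_term_disease_frac: float = 0.65

    def validate(self) -> None:
        if self.n_herbs < 2:
            raise ValidationError("need at least 2 herbs")
        if self.n_tcmsp < 1 or self.n_hit < 0:
            raise ValidationError("need at least one ADME-scored compound")
        if self.n_per_group < 2:
            raise ValidationError("need >= 2 samples per group")
        if self.n_up + self.n_down > self.n_expr_genes:
            raise ValidationError("more planted DEGs than expression genes")
        if self.n_hubs > self.n_tcmsp:
            raise ValidationError("more hubs than ADME-scored compounds")
        if self.hub_fanout > self.n_genes:
            raise ValidationError("hub fan-out exceeds the gene universe")
        if self.n_shared_names > min(self.n_tcmsp, self.n_hit):
            raise ValidationError("shared names exceed a source's size")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    seed: int
    planted_degs: dict[str, float]
    planted_hub_ingredients: list[str]
    planted_enriched_terms: list[str]
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


class SynthPlan:
    """All random choices for one (params, seed), drawn in a fixed order.

    Each public generator rebuilds the same plan from (params, seed) and
    writes its own slice of the files, so calls are independent yet
    mutually consistent.
    """

    def __init__(self, params: SynthParams, seed: int) -> None:
        params.validate()
        self.params = params
        self.seed = seed
        children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
        rngs = {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}
        p = params

        self.herbs = [f"H{i + 1:02d}" for i in range(p.n_herbs)]
        self.universe = [f"TG{i + 1:04d}" for i in range(p.n_genes)]
        protein_pool = [f"PR{i + 1:04d}" for i in range(p.n_proteins)]
        self.protein_pool = protein_pool

        # ---- knowledgebase -------------------------------------------------
        rng = rngs["kb"]
        n_unique = p.n_tcmsp + p.n_hit - p.n_shared_names
        names = [f"cmpd-{i + 1:04d}" for i in range(n_unique)]
        self.tcmsp_names = names[: p.n_tcmsp]
        self.hit_names = names[p.n_tcmsp - p.n_shared_names :]

        def sample_herbs() -> set[str]:
            primary = self.herbs[rng.integers(p.n_herbs)]
            extra = {
                h
                for h in self.herbs
                if h != primary and rng.random() < p.herb_overlap_prob
            }
            return {primary} | extra

        ob = rng.uniform(*p.ob_range, size=p.n_tcmsp)
        dl = rng.uniform(*p.dl_range, size=p.n_tcmsp)
        self.tcmsp_records = [
            IngredientRecord(
                ingredient_id=name,
                herbs=sample_herbs(),
                ob=round(float(ob[i]), 2),
                dl=round(float(dl[i]), 3),
                source="tcmsp",
            )
            for i, name in enumerate(self.tcmsp_names)
        ]
        self.hit_records = [
            IngredientRecord(
                ingredient_id=name, herbs=sample_herbs(), source="hit"
            )
            for name in self.hit_names
        ]

        # hubs: ADME-scored compounds forced through the screen
        hub_idx = rng.choice(p.n_tcmsp, size=p.n_hubs, replace=False)
        self.hub_ingredients = sorted(self.tcmsp_names[i] for i in hub_idx)
        cfg = ScreenConfig()
        for i in hub_idx:
            rec = self.tcmsp_records[i]
            rec.ob = round(float(rng.uniform(cfg.ob_min + 5, p.ob_range[1])), 2)
            rec.dl = round(float(rng.uniform(cfg.dl_min + 0.05, p.dl_range[1])), 3)

        self.active = merge_sources(screen_adme(self.tcmsp_records, cfg), self.hit_records)

        # ---- disease-gene plan (drawn before targets so hubs can cover it) -
        rng = rngs["expr"]
        n_planted = p.n_up + p.n_down
        n_deg_universe = int(round(n_planted * p.deg_in_universe_frac))
        deg_universe_genes = list(
            rng.choice(self.universe, size=n_deg_universe, replace=False)
        )
        extra_pool = [f"EX{i + 1:04d}" for i in range(p.n_expr_genes - p.n_genes)]
        deg_extra = list(
            rng.choice(extra_pool, size=n_planted - n_deg_universe, replace=False)
        )
        deg_genes = deg_universe_genes + deg_extra
        perm = rng.permutation(n_planted)
        magnitudes = rng.uniform(*p.log2fc_range, size=n_planted)
        self.planted_degs: dict[str, float] = {}
        for rank, idx in enumerate(perm):
            sign = 1.0 if rank < p.n_up else -1.0
            self.planted_degs[deg_genes[idx]] = round(sign * float(magnitudes[idx]), 3)
        self.expr_genes = self.universe + extra_pool
        self.deg_universe_genes = deg_universe_genes

        rng = rngs["curated"]
        n_cur_universe = int(round(p.n_curated_pool * p.curated_in_universe_frac))
        non_deg_universe = [g for g in self.universe if g not in self.planted_degs]
        cur_universe = list(
            rng.choice(non_deg_universe, size=n_cur_universe, replace=False)
        )
        cur_extra = [f"CU{i + 1:04d}" for i in range(p.n_curated_pool - n_cur_universe)]
        self.curated_pool = cur_universe + cur_extra
        self.curated_lists: dict[str, set[str]] = {}
        for source in ("ttd", "drugbank", "kegg", "disgenet", "omim"):
            picked = rng.choice(
                self.curated_pool,
                size=min(p.curated_per_source, len(self.curated_pool)),
                replace=False,
            )
            self.curated_lists[source] = set(picked)
        self.curated_in_universe = cur_universe

        #: genes the screen should surface as candidates
        self.disease_plan = sorted(set(deg_universe_genes) | set(cur_universe))

        # ---- target associations ------------------------------------------
        rng = rngs["targets"]
        hub_set = set(self.hub_ingredients)
        self.validated: list[TargetAssociation] = []
        self.predicted: list[TargetAssociation] = []
        universe_arr = np.array(self.universe)
        for rec in self.active:
            if rec.ingredient_id in hub_set:
                covered = [
                    g
                    for g in self.disease_plan
                    if rng.random() < p.hub_disease_coverage
                ]
                n_fill = max(p.hub_fanout - len(covered), 0)
                fill = rng.choice(universe_arr, size=n_fill, replace=False)
                genes = sorted(set(covered) | set(fill))
                # hub associations mix evidence classes, but predicted ones
                # always pass the similarity/score filter so downstream
                # filtering cannot erode the planted fan-out
                for g in genes:
                    if rng.random() < p.hub_validated_frac:
                        self.validated.append(
                            TargetAssociation(rec.ingredient_id, g, "validated")
                        )
                    else:
                        self.predicted.append(
                            TargetAssociation(
                                rec.ingredient_id,
                                g,
                                "predicted",
                                similarity=round(float(rng.uniform(1.05, 2.0)), 3),
                                prediction_score=round(float(rng.uniform(0.05, 1.0)), 3),
                            )
                        )
                continue
            fanout = int(rng.poisson(p.mean_targets)) + 1
            genes = sorted(
                set(rng.choice(universe_arr, size=min(fanout, p.n_genes), replace=False))
            )
            for g in genes:
                if rng.random() < p.validated_frac:
                    self.validated.append(
                        TargetAssociation(rec.ingredient_id, g, "validated")
                    )
                else:
                    self.predicted.append(
                        TargetAssociation(
                            rec.ingredient_id,
                            g,
                            "predicted",
                            similarity=round(float(rng.uniform(0.5, 2.0)), 3),
                            prediction_score=round(float(rng.uniform(-0.2, 1.0)), 3),
                        )
                    )

        # ---- expression matrix --------------------------------------------
        rng = rngs["expr"]  # continues the expr stream after DEG placement
        n_genes = len(self.expr_genes)
        n = p.n_per_group
        baseline = rng.normal(p.baseline_mean, p.baseline_sd, size=n_genes)
        noise = rng.normal(0.0, p.noise_sd, size=(n_genes, 2 * n))
        values = baseline[:, None] + noise
        shift = np.array(
            [self.planted_degs.get(g, 0.0) for g in self.expr_genes]
        )
        values[:, :n] += shift[:, None]  # case columns first
        self.expr_values = np.round(values, 6)
        self.expr_samples = [f"case_{i + 1}" for i in range(n)] + [
            f"ctrl_{i + 1}" for i in range(n)
        ]
        self.expr_groups = {
            s: ("case" if s.startswith("case") else "control")
            for s in self.expr_samples
        }

        # ---- PPI edges -----------------------------------------------------
        rng = rngs["ppi"]
        disease_arr = np.array(self.disease_plan)
        pool_arr = np.array(protein_pool)
        edges: dict[tuple[str, str], float] = {}
        kind = rng.random(p.n_edges)
        for i in range(p.n_edges):
            if kind[i] < 0.55:  # candidate-to-protein
                a = str(rng.choice(disease_arr))
                b = str(rng.choice(pool_arr))
            elif kind[i] < 0.75:  # protein-to-protein
                a, b = (str(x) for x in rng.choice(pool_arr, size=2, replace=False))
            else:  # background noise among targets/proteins
                a = str(rng.choice(universe_arr))
                b = str(rng.choice(np.concatenate([universe_arr, pool_arr])))
            if a == b:
                continue
            if rng.random() < p.high_score_frac:
                score = float(rng.beta(50, 2))
            else:
                score = float(rng.beta(2, 8))
            key = (a, b) if a < b else (b, a)
            score = round(score, 4)
            if key not in edges or score > edges[key]:
                edges[key] = score
        self.edges = [(a, b, s) for (a, b), s in sorted(edges.items())]

        # ---- annotation gene sets -----------------------------------------
        rng = rngs["genesets"]
        annotatable = np.array(self.universe + protein_pool)
        self.genesets: dict[str, tuple[str, str, set[str]]] = {}
        n_disease = int(round(p.planted_term_size * p.planted_term_disease_frac))
        planted_genes = set(
            rng.choice(disease_arr, size=min(n_disease, len(disease_arr)), replace=False)
        ) | set(rng.choice(annotatable, size=p.planted_term_size - n_disease, replace=False))
        self.planted_term = "KEGG0001"
        self.genesets[self.planted_term] = (
            "planted disease pathway",
            "kegg",
            {str(g) for g in planted_genes},
        )
        for cat, prefix in (("kegg", "KEGG"), ("molecular_function", "MF")):
            start = 2 if cat == "kegg" else 1
            for j in range(start, p.n_terms_per_category + 1):
                size = int(rng.integers(*p.term_size_range))
                genes = {str(g) for g in rng.choice(annotatable, size=size, replace=False)}
                self.genesets[f"{prefix}{j:04d}"] = (f"synthetic term {prefix}{j}", cat, genes)

    def ground_truth(self) -> GroundTruth:
        # tuples become lists so the manifest equals its JSON round-trip
        params = json.loads(json.dumps(asdict(self.params)))
        return GroundTruth(
            seed=self.seed,
            planted_degs=dict(sorted(self.planted_degs.items())),
            planted_hub_ingredients=list(self.hub_ingredients),
            planted_enriched_terms=[self.planted_term],
            params=params,
        )


def _write_ingredient_rows(records, path) -> None:
    """Write per-(herb, ingredient) rows in the raw export layout."""
    with open(path, "w") as fh:
        fh.write("herb\tingredient\tob\tdl\n")
        for rec in sorted(records, key=lambda r: r.ingredient_id):
            ob = "" if rec.ob is None else f"{rec.ob:g}"
            dl = "" if rec.dl is None else f"{rec.dl:g}"
            for herb in sorted(rec.herbs):
                fh.write(f"{herb}\t{rec.ingredient_id}\t{ob}\t{dl}\n")


def gen_knowledgebase(
    params: SynthParams, seed: int, outdir
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the herb→ingredient and ingredient→target tables.

    Produces ``tcmsp_ingredients.tsv``, ``hit_ingredients.tsv``,
    ``validated_targets.tsv``, ``predicted_targets.tsv`` and
    ``ground_truth.json``; returns the path map and the ground truth.
    """
    plan = SynthPlan(params, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tcmsp": outdir / "tcmsp_ingredients.tsv",
        "hit": outdir / "hit_ingredients.tsv",
        "validated": outdir / "validated_targets.tsv",
        "predicted": outdir / "predicted_targets.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    _write_ingredient_rows(plan.tcmsp_records, paths["tcmsp"])
    _write_ingredient_rows(plan.hit_records, paths["hit"])
    io.write_association_table(plan.validated, paths["validated"])
    io.write_association_table(plan.predicted, paths["predicted"])
    gt = plan.ground_truth()
    gt.to_json(paths["ground_truth"])
    return paths, gt


def gen_expression(
    params: SynthParams, seed: int, outdir
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the expression matrix, sample groups and curated gene lists.

    The model is log2 intensity = gene baseline ~ N(mu, tau^2) + planted
    group shift (cases only) + N(0, sigma^2) noise.
    """
    plan = SynthPlan(params, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .datatypes import ExpressionMatrix

    m = ExpressionMatrix(
        genes=plan.expr_genes,
        samples=plan.expr_samples,
        group=plan.expr_groups,
        values=plan.expr_values,
    )
    paths = {
        "matrix": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    io.write_expression(m, paths["matrix"], paths["groups"])
    for source, genes in plan.curated_lists.items():
        p = outdir / f"curated_{source}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(genes)))
        paths[f"curated_{source}"] = p
    gt = plan.ground_truth()
    gt.to_json(paths["ground_truth"])
    return paths, gt


def gen_ppi_and_genesets(
    params: SynthParams, seed: int, outdir
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the scored PPI edge table and the GMT annotation files.

    Edge scores follow a two-component Beta mixture with a high-confidence
    mode above 0.9; one pathway term is planted with genes over-sampled
    from the disease-reachable universe.
    """
    plan = SynthPlan(params, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .datatypes import GeneSet, GeneSetCollection, ScoredEdge

    edges = [ScoredEdge(a, b, s) for a, b, s in plan.edges]
    paths = {
        "edges": outdir / "ppi_edges.tsv",
        "kegg_gmt": outdir / "pathways.gmt",
        "mf_gmt": outdir / "functions.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    io.write_edge_table(edges, paths["edges"])
    for cat, key in (("kegg", "kegg_gmt"), ("molecular_function", "mf_gmt")):
        coll = GeneSetCollection(
            {
                tid: GeneSet(name=name, category=c, genes=genes)
                for tid, (name, c, genes) in plan.genesets.items()
                if c == cat
            }
        )
        io.write_gmt(coll, paths[key])
    gt = plan.ground_truth()
    gt.to_json(paths["ground_truth"])
    return paths, gt


def generate_all(
    params: SynthParams, seed: int, outdir
) -> tuple[dict[str, Path], GroundTruth]:
    """Write every pipeline input into ``outdir``; one consistent plan."""
    paths, gt = gen_knowledgebase(params, seed, outdir)
    p2, _ = gen_expression(params, seed, outdir)
    p3, _ = gen_ppi_and_genesets(params, seed, outdir)
    paths.update(p2)
    paths.update(p3)
    return paths, gt
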