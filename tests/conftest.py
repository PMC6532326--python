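"""Shared fixtures: a published herb-overlap table, small synthetic presets
and an end-to-end pipeline run cached per session."""

from __future__ import annotations

import pathlib

import pytest

from herbnet.datatypes import IngredientRecord
from herbnet.pipeline import PipelineConfig, run_pipeline
from herbnet.synth import SynthParams, generate_all

# Published overlap table of a 12-herb formula: ingredient -> contributing
# herbs (herb codes as printed).  Used to check herb-overlap counting
# against the published per-ingredient totals.
FORMULA_OVERLAP_TABLE: dict[str, list[str]] = {
    "beta-sitosterol": ["CT", "CL", "OF", "PGS", "RC", "RP", "RS"],
    "sitosterol": ["CT", "OF", "PGS", "RP", "RS", "RCX"],
    "quercetin": ["SM", "AgR", "OF", "RC", "SP"],
    "stigmasterol": ["SM", "CL", "RP"],
    "acetic acid": ["AgR", "CT", "RP"],
    "kaempferol": ["AgR", "OF", "RM"],
    "(-)-taxifolin": ["SM", "CT"],
    "clr": ["SM", "CL"],
    "hederagenin": ["AgR", "CL"],
    "fa": ["AgR", "RCX"],
    "(+)-catechin": ["CT", "RP"],
    "baicalein": ["PGS", "RP"],
    "ecdysterone": ["RC", "RM"],
    "mandanol": ["RS", "RCX"],
}


@pytest.fixture
def formula_overlap_records() -> list[IngredientRecord]:
    return [
        IngredientRecord(ingredient_id=name, herbs=set(herbs), source="both")
        for name, herbs in FORMULA_OVERLAP_TABLE.items()
    ]


def small_params() -> SynthParams:
    """A fast preset preserving every structural feature of the default."""
    return SynthParams(
        n_tcmsp=60,
        n_hit=10,
        n_genes=150,
        n_expr_genes=300,
        n_up=5,
        n_down=5,
        n_curated_pool=15,
        n_proteins=30,
        n_edges=200,
        hub_fanout=60,
        n_hubs=1,
        n_terms_per_category=6,
        term_size_range=(5, 15),
        planted_term_size=12,
    )


@pytest.fixture
def small_synth_params() -> SynthParams:
    return small_params()


def pipeline_config_for(paths: dict, outdir: pathlib.Path) -> PipelineConfig:
    return PipelineConfig(
        tcmsp_ingredients=paths["tcmsp"],
        hit_ingredients=paths["hit"],
        validated_targets=paths["validated"],
        predicted_targets=paths["predicted"],
        expression=paths["matrix"],
        groups=paths["groups"],
        curated={
            s: paths[f"curated_{s}"]
            for s in ("ttd", "drugbank", "kegg", "disgenet", "omim")
        },
        edges=paths["edges"],
        gene_sets=[paths["kegg_gmt"], paths["mf_gmt"]],
        output_dir=outdir,
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One small synthetic dataset generated and piped end to end."""
    root = tmp_path_factory.mktemp("small_run")
    paths, gt = generate_all(small_params(), seed=11, outdir=root / "data")
    cfg = pipeline_config_for(paths, root / "out")
    report = run_pipeline(cfg)
    return {"paths": paths, "gt": gt, "cfg": cfg, "report": report}
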