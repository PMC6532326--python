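"""Differential-expression calling and disease-gene merging.

A two-group (case vs control) comparison on log2 intensities, as in a
reanalysed two-condition microarray: per-gene two-sided t-test (Welch by
default) with a raw p-value cut-off and a linear fold-change cut-off
``max(fc, 1/fc) >= fc_min``.  No multiple-testing correction enters the
call — Benjamini–Hochberg q-values are reported alongside for reference
only, matching the common raw-p workflow for small two-group designs.
The resulting gene list is then unioned with curated disease-gene lists
into a single provenance-tagged disease-gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CURATED_SOURCES,
    DiseaseGeneSet,
    ExpressionMatrix,
    ValidationError,
    canonical_symbol,
)


@dataclass
class DegResult:
    """Per-gene differential-expression call.

    ``log2fc`` is case minus control on the log2 scale; ``fc`` the linear
    fold change; ``direction`` is ``up``/``down`` for significant genes
    passing the fold-change criterion and ``ns`` otherwise.
    """

    gene: str
    log2fc: float
    fc: float
    p: float
    q: float
    direction: str


def call_degs(
    m: ExpressionMatrix,
    p_max: float = 0.05,
    fc_min: float = 1.5,
    equal_var: bool = False,
    fc_scale: str = "log",
) -> list[DegResult]:
    """Call differentially expressed genes between case and control.

    Parameters
    ----------
    m
        Expression matrix of log2 intensities, >= 2 samples per group.
    p_max
        Raw two-sided p-value cut-off (strict ``p < p_max``).
    fc_min
        Linear fold-change cut-off; a gene passes when
        ``max(fc, 1/fc) >= fc_min``.
    equal_var
        False (default) for Welch's t-test, True for Student's t.
    fc_scale
        ``"log"``: fold change from the difference of log2-scale group
        means (``fc = 2**(mean_case - mean_control)``).  ``"linear"``:
        ratio of linear-scale group means.

    Zero-variance genes get ``p = 1`` (never a crash, never significant).
    The output is one :class:`DegResult` per gene in input order and is
    invariant to sample-column and gene-row permutations.
    """
    if fc_scale not in ("log", "linear"):
        raise ValidationError(f"fc_scale must be 'log' or 'linear', got {fc_scale!r}")
    case = m.values[:, m.group_columns("case")]
    control = m.values[:, m.group_columns("control")]

    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(case, control, axis=1, equal_var=equal_var)
    zero_var = (case.var(axis=1) == 0) & (control.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    if fc_scale == "log":
        log2fc = case.mean(axis=1) - control.mean(axis=1)
        fc = np.exp2(log2fc)
    else:
        fc = np.exp2(case).mean(axis=1) / np.exp2(control).mean(axis=1)
        log2fc = np.log2(fc)

    _, q, _, _ = multipletests(p, method="fdr_bh")

    results = []
    for i, gene in enumerate(m.genes):
        significant = p[i] < p_max
        if significant and fc[i] >= fc_min:
            direction = "up"
        elif significant and fc[i] <= 1.0 / fc_min:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DegResult(
                gene=gene,
                log2fc=float(log2fc[i]),
                fc=float(fc[i]),
                p=float(p[i]),
                q=float(q[i]),
                direction=direction,
            )
        )
    return results


def volcano_table(degs: list[DegResult]) -> pd.DataFrame:
    """Plot-ready volcano table with direction counts attached.

    One row per gene with ``gene``, ``log2fc``, ``neg_log10_p`` and
    ``direction``; ``df.attrs`` carries ``n_up``, ``n_down`` and ``n_deg``
    (their sum).
    """
    rows = [
        {
            "gene": d.gene,
            "log2fc": d.log2fc,
            "neg_log10_p": -np.log10(d.p),
            "direction": d.direction,
        }
        for d in degs
    ]
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "neg_log10_p", "direction"])
    n_up = int((df["direction"] == "up").sum()) if len(df) else 0
    n_down = int((df["direction"] == "down").sum()) if len(df) else 0
    df.attrs["n_up"] = n_up
    df.attrs["n_down"] = n_down
    df.attrs["n_deg"] = n_up + n_down
    return df


def deg_gene_set(degs: list[DegResult]) -> set[str]:
    """Genes called up or down."""
    return {d.gene for d in degs if d.direction != "ns"}


def merge_disease_genes(
    deg_genes: set[str], curated: dict[str, set[str]]
) -> DiseaseGeneSet:
    """Union expression-derived and curated disease genes with provenance.

    ``curated`` maps a source tag (one of ``ttd``, ``drugbank``, ``kegg``,
    ``disgenet``, ``omim``) to its gene list.  Every gene in the merged set
    is tagged with each source that reported it; expression-derived genes
    get the tag ``deg``.
    """
    unknown = set(curated) - set(CURATED_SOURCES)
    if unknown:
        raise ValidationError(
            f"unknown curated source tag(s): {sorted(unknown)}; "
            f"expected {CURATED_SOURCES}"
        )
    provenance: dict[str, set[str]] = {}
    for g in deg_genes:
        provenance.setdefault(canonical_symbol(g), set()).add("deg")
    for source, genes in curated.items():
        for g in genes:
            provenance.setdefault(canonical_symbol(g), set()).add(source)
    return DiseaseGeneSet(genes=set(provenance), provenance=provenance)
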