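"""Collapse gene-level profiles to reaction level via the GPR max-min rule.

The fitness of knocking out a reaction is modelled as the best (max) surviving
isozyme, each isozyme being only as fit as its worst (min) subunit gene:

    score(r, cond) = max over OR-clauses of [ min over clause genes ]

Missing data policy: a clause containing a gene with no measurement is not
evaluable and is dropped; a reaction whose clauses are all dropped gets a
missing score for that condition. The fraction of GPR genes with data is
reported as ``coverage`` so downstream consumers can filter.

After the collapse, reaction scores are Z-normalized per condition over the
set of reactions with any finite value (population std).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import MetabolicModel, Reaction
from .profiles import ProfileMatrix, z_normalize

__all__ = [
    "reaction_score",
    "collapse_gene_matrix",
    "gpr_coverage",
    "build_reaction_matrix",
    "build_expression_reaction_matrix",
]


def reaction_score(reaction: Reaction, gene_scores: Mapping[str, float]) -> float:
    """Max-min collapse of one reaction's GPR for a single condition.

    ``gene_scores`` maps gene id to a real score; genes absent from the map
    (or mapped to NaN) count as missing. Orphan reactions are an error.
    """
    if reaction.gpr is None:
        raise ValueError(f"reaction {reaction.id!r} is orphan; no GPR to collapse")
    best = float("nan")
    for clause in reaction.gpr.clauses:
        vals = []
        evaluable = True
        for g in clause:
            v = gene_scores.get(g)
            if v is None or not math.isfinite(v):
                evaluable = False
                break
            vals.append(v)
        if not evaluable:
            continue
        clause_score = min(vals)
        if math.isnan(best) or clause_score > best:
            best = clause_score
    return best


def gpr_coverage(reaction: Reaction, covered_genes: set[str]) -> float:
    """Fraction of the reaction's GPR genes present in ``covered_genes``."""
    if reaction.gpr is None:
        return 0.0
    genes = reaction.gpr.genes
    return sum(1 for g in genes if g in covered_genes) / len(genes)


def collapse_gene_matrix(model: MetabolicModel, gene_matrix: ProfileMatrix) -> pd.DataFrame:
    conds = gene_matrix.col_ids
    gvals = gene_matrix.values
    rows: dict[str, list[float]] = {}
    for r in model.non_orphans:
        genes = sorted(r.gpr.genes)
        present = [g for g in genes if g in gvals.index]
        if not present:
            rows[r.id] = [float("nan")] * len(conds)
            continue
        sub = gvals.loc[present]
        scores = []
        for c in conds:
            gene_scores = sub[c].to_dict()
            scores.append(reaction_score(r, gene_scores))
        rows[r.id] = scores
    df = pd.DataFrame.from_dict(rows, orient="index", columns=conds)
    return df


def build_reaction_matrix(
    model: MetabolicModel, gene_matrix: ProfileMatrix
) -> ProfileMatrix:
    """Reaction x condition fitness matrix: max-min collapse of the raw gene
    scores, then per-condition Z-normalization over reactions with data.

    The input must be the raw (pre-normalization) gene matrix; only the
    reaction-level matrix is normalized.
    """
    if gene_matrix.normalized:
        raise ValueError("expected the raw (pre-normalization) gene matrix")
    df = collapse_gene_matrix(model, gene_matrix)
    df = df.dropna(how="all")
    if df.empty:
        raise ValueError("no reaction has an evaluable GPR under the given matrix")
    return z_normalize(ProfileMatrix(df))


def build_expression_reaction_matrix(
    model: MetabolicModel,
    expression_matrices: Mapping[str, ProfileMatrix],
    covered_genes: set[str] | None = None,
) -> dict[str, ProfileMatrix]:
    """Per-dataset reaction x sample expression matrices.

    For each dataset: restrict to genes also covered by the fitness screen
    (when ``covered_genes`` is given), Z-normalize gene expression per sample,
    apply the max-min collapse, then Z-normalize the reaction rows per sample.
    Datasets are kept separate (no concatenation); scores from several
    datasets are averaged downstream.
    """
    out: dict[str, ProfileMatrix] = {}
    for name, mat in expression_matrices.items():
        vals = mat.values
        if covered_genes is not None:
            keep = [g for g in vals.index if g in covered_genes]
            if not keep:
                raise ValueError(
                    f"expression dataset {name!r}: no genes overlap the fitness screen"
                )
            vals = vals.loc[keep]
        if vals.shape[1] < 2:
            raise ValueError(
                f"expression dataset {name!r}: need >=2 samples to Z-normalize"
            )
        normed = z_normalize(ProfileMatrix(vals))
        collapsed = collapse_gene_matrix(model, ProfileMatrix(normed.values)).dropna(how="all")
        if collapsed.empty:
            raise ValueError(
                f"expression dataset {name!r}: no reaction has an evaluable GPR"
            )
        out[name] = z_normalize(ProfileMatrix(collapsed))
    return out
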