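"""Association Likelihood Scores: assigning candidate genes to orphan reactions.

The method: a reaction's behaviour should resemble its metabolic
neighborhood, so a candidate gene for an orphan reaction is scored by the
mean Spearman correlation of its fitness vector with the two most-correlated
fitness vectors among the orphan's non-orphan profiled neighbors (the
Association Likelihood Score, ALS). Two neighbors is the minimum that lets a
single gap in a linear pathway be bridged. The fitness ALS can be adjusted
with the candidate's promoter ALS values (weight ``alpha``), averaged with an
expression-based ALS (one score per expression dataset, then averaged), and
calibrated into Bayesian / unbiased confidences against score distributions
of known (true) and spurious gene-reaction pairs obtained by leave-one-out
on the non-orphan reactions.

The user-facing surface follows the model/results idiom::

    model = GeneAssignment(metabolic_model, gene_fitness, expression={...})
    res = model.fit()
    print(res.summary())
    report = model.loo_validate(k_max=20)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._corr import MIN_OVERLAP_DEFAULT, spearman_matrix, spearman_pair
from .model_core import MetabolicModel
from .neighborhood import NeighborhoodGraph, adequate_reactions, greedy_prune
from .profiles import ProfileMatrix, z_normalize
from .reaction_profiles import build_expression_reaction_matrix, build_reaction_matrix

__all__ = [
    "als",
    "als_promoter_adjusted",
    "als_expression",
    "als_combined",
    "rank_candidates",
    "weak_udist",
    "strong_udist",
    "ConfidencePrior",
    "confidence",
    "ValidationReport",
    "GeneAssignment",
    "AssignmentResults",
]


# ---------------------------------------------------------------------------
# Elementary scoring operations
# ---------------------------------------------------------------------------


def als(
    cand_vector: Sequence[float] | pd.Series,
    neighbor_vectors: pd.DataFrame,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> float:
    """Mean Spearman correlation to the two best-correlated neighbor vectors.

    ``neighbor_vectors`` holds one row per non-orphan profiled neighbor of
    the target reaction, aligned to the candidate's condition order.
    Neighbors with fewer than ``min_overlap`` shared finite conditions are
    skipped; fewer than two usable neighbors is an error (the reaction is
    not adequate for this candidate).
    """
    cand = np.asarray(cand_vector, dtype=float)
    rhos = [
        spearman_pair(cand, neighbor_vectors.iloc[i].to_numpy(), min_overlap)
        for i in range(neighbor_vectors.shape[0])
    ]
    usable = sorted((r for r in rhos if np.isfinite(r)), reverse=True)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable neighbors; reaction not scoreable")
    return float((usable[0] + usable[1]) / 2.0)


def als_promoter_adjusted(
    als_value: float,
    promoter_als_values: Sequence[float] = (),
    alpha: float = 0.21,
) -> float:
    """Fitness ALS plus ``alpha`` times the sum of the candidate's promoter
    ALS values; with no linked promoters the score is unchanged."""
    vals = [v for v in promoter_als_values if np.isfinite(v)]
    return float(als_value + alpha * sum(vals))


def als_expression(dataset_scores: Sequence[float]) -> float:
    """Average of the per-dataset expression ALS values (NaN when none)."""
    vals = [v for v in dataset_scores if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def als_combined(fit_score: float, expr_score: float) -> tuple[float, bool]:
    """Equal-weight average of the fitness and expression scores.

    Returns ``(score, fitness_only)``; when the expression score is missing
    the fitness score is passed through and flagged, and vice versa. Both
    missing yields NaN.
    """
    fit_ok = np.isfinite(fit_score)
    expr_ok = np.isfinite(expr_score)
    if fit_ok and expr_ok:
        return float(0.5 * fit_score + 0.5 * expr_score), False
    if fit_ok:
        return float(fit_score), True
    if expr_ok:
        return float(expr_score), False
    return float("nan"), True


def rank_candidates(
    scores: Mapping[str, float], top_k: int = 20
) -> list[tuple[str, float, int]]:
    """Rank candidates by descending score, ties broken by gene id.

    Returns at most ``top_k`` tuples (gene, score, rank). NaN-scored
    candidates are unscoreable and excluded. An empty candidate set is an
    error.
    """
    if not scores:
        raise ValueError("empty candidate set")
    finite = [(g, s) for g, s in scores.items() if np.isfinite(s)]
    finite.sort(key=lambda t: (-t[1], t[0]))
    return [(g, float(s), i + 1) for i, (g, s) in enumerate(finite[:top_k])]


# ---------------------------------------------------------------------------
# Uniform null baselines
# ---------------------------------------------------------------------------


def weak_udist(top_g: int, n_reactions: int, total_genes: int) -> float:
    """Expected correct identifications when the top-G genes are drawn
    uniformly from all candidates: G * R / TotalGenes."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    return top_g * n_reactions / total_genes


def strong_udist(top_g: int, avg_genes_per_reaction: float) -> float:
    """Expected identifications when every drawn gene is a true gene of some
    reaction: G * Avg(genes per reaction)."""
    if avg_genes_per_reaction < 0:
        raise ValueError("average genes per reaction must be >= 0")
    return top_g * avg_genes_per_reaction


# ---------------------------------------------------------------------------
# Confidence calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidencePrior:
    """Prior probability that a random (gene, reaction) pairing is correct."""

    p_true: float

    def __post_init__(self) -> None:
        if not 0 < self.p_true < 1:
            raise ValueError("p_true must lie strictly between 0 and 1")


def confidence(
    score: float,
    true_scores: Sequence[float],
    false_scores: Sequence[float],
    prior: ConfidencePrior,
) -> tuple[float, float]:
    """Bayesian and unbiased confidence of an assignment score.

    Tail probabilities are inclusive empirical survival fractions
    P(ALS >= score) under the true-pair and spurious-pair score
    distributions. The marginal P(ALS >= score) is the prior mixture of the
    two tails. A score above every observation in both distributions has
    undefined confidence (NaN, NaN).
    """
    t = np.asarray(true_scores, dtype=float)
    f = np.asarray(false_scores, dtype=float)
    t = t[np.isfinite(t)]
    f = f[np.isfinite(f)]
    if t.size == 0 or f.size == 0:
        raise ValueError("both empirical score distributions must be non-empty")
    p_t = float(np.mean(t >= score))
    p_f = float(np.mean(f >= score))
    if p_t == 0 and p_f == 0:
        return float("nan"), float("nan")
    marginal = prior.p_true * p_t + (1 - prior.p_true) * p_f
    bayesian = p_t * prior.p_true / marginal if marginal > 0 else float("nan")
    unbiased = p_t / (p_t + p_f)
    return bayesian, unbiased


# ---------------------------------------------------------------------------
# Vectorized scoring context
# ---------------------------------------------------------------------------


def _top2_mean(corr_block: np.ndarray) -> np.ndarray:
    """Per row: mean of the two largest finite entries (NaN if fewer than 2)."""
    finite = np.isfinite(corr_block)
    counts = finite.sum(axis=1)
    tmp = np.where(finite, corr_block, -np.inf)
    tmp = np.sort(tmp, axis=1)
    out = tmp[:, -2:].mean(axis=1)
    out[counts < 2] = np.nan
    return out


@dataclass
class _Context:
    """Everything derived from one condition set: matrices, graph, correlations."""

    zfv_genes: ProfileMatrix
    rxn_raw: pd.DataFrame
    rxn_matrix: ProfileMatrix
    graph: NeighborhoodGraph
    adequate: set[str]
    gene_rxn_corr: pd.DataFrame
    zfv_prom: ProfileMatrix | None
    prom_rxn_corr: pd.DataFrame | None
    expr_gene_z: dict[str, ProfileMatrix] = field(default_factory=dict)
    expr_rxn_raw: dict[str, pd.DataFrame] = field(default_factory=dict)
    expr_corrs: dict[str, pd.DataFrame] = field(default_factory=dict)
    nonorphan_profiled: set[str] = field(default_factory=set)

    def neighbors_of(self, rid: str) -> list[str]:
        return sorted(
            n for n in self.graph.neighbors(rid) if n in self.nonorphan_profiled
        )


@dataclass
class ValidationReport:
    """Leave-one-out validation summary.

    ``ranks`` has one row per evaluated reaction with the best true-gene rank
    (NaN-free; unrecoverable genes get +inf). ``accuracy`` maps k to the
    fraction of reactions whose true gene made the top k.
    """

    ranks: pd.DataFrame
    k_max: int
    mode: str
    n_conditions: int
    baselines: dict[str, float]

    @property
    def accuracy(self) -> pd.Series:
        ks = np.arange(1, self.k_max + 1)
        vals = [float(np.mean(self.ranks["best_true_rank"] <= k)) for k in ks]
        return pd.Series(vals, index=ks, name="accuracy")

    def top_k_hits(self, k: int) -> int:
        return int((self.ranks["best_true_rank"] <= k).sum())

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k_max": self.k_max,
            "n_conditions": self.n_conditions,
            "n_reactions": int(len(self.ranks)),
            "accuracy": {int(k): v for k, v in self.accuracy.items()},
            "baselines": self.baselines,
        }


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------


class GeneAssignment:
    """Gene-to-orphan-reaction assignment model.

    Parameters
    ----------
    model : MetabolicModel
        Stoichiometry, GPR rules and the orphan partition.
    gene_fitness : ProfileMatrix
        Raw (un-normalized) gene x condition fitness matrix; every row is a
        candidate gene.
    expression : mapping of dataset id -> ProfileMatrix, optional
        Gene x sample expression matrices, kept separate per dataset.
    promoters : ProfileMatrix, optional
        Raw promoter x condition fitness matrix (region-averaged insertion
        scores).
    promoter_map : mapping gene id -> sequence of promoter ids, optional
    alpha : float
        Weight of the promoter ALS adjustment (0 disables it).
    cutoff : int
        High-frequency metabolite cutoff for neighborhood pruning.
    top_k : int
        Number of ranked candidates reported per orphan reaction.
    min_overlap : int
        Minimum shared finite conditions for a Spearman correlation.
    """

    def __init__(
        self,
        model: MetabolicModel,
        gene_fitness: ProfileMatrix,
        expression: Mapping[str, ProfileMatrix] | None = None,
        promoters: ProfileMatrix | None = None,
        promoter_map: Mapping[str, Sequence[str]] | None = None,
        alpha: float = 0.21,
        cutoff: int = 11,
        top_k: int = 20,
        min_overlap: int = MIN_OVERLAP_DEFAULT,
    ):
        self.model = model
        self.gene_fitness = gene_fitness
        self.expression = dict(expression) if expression else {}
        self.promoters = promoters
        self.promoter_map = {k: list(v) for k, v in (promoter_map or {}).items()}
        self.alpha = float(alpha)
        self.cutoff = int(cutoff)
        self.top_k = int(top_k)
        self.min_overlap = int(min_overlap)
        self._context: _Context | None = None

    # -- context construction ------------------------------------------------

    def _build_context(self, conditions: Sequence[str] | None = None) -> _Context:
        from .reaction_profiles import collapse_gene_matrix

        gene_raw = self.gene_fitness
        if conditions is not None:
            gene_raw = gene_raw.subset_conditions(conditions)
        zfv_genes = z_normalize(gene_raw)
        rxn_raw = collapse_gene_matrix(self.model, gene_raw).dropna(how="all")
        if rxn_raw.empty:
            raise ValueError("no reaction has an evaluable GPR under the given matrix")
        rxn_matrix = z_normalize(ProfileMatrix(rxn_raw))
        graph = greedy_prune(self.model, rxn_matrix.row_ids, cutoff=self.cutoff)
        adequate = adequate_reactions(self.model, graph, rxn_matrix.row_ids)
        gene_rxn_corr = spearman_matrix(
            zfv_genes.values, rxn_matrix.values, self.min_overlap
        )
        zfv_prom = prom_corr = None
        if self.promoters is not None and self.alpha != 0:
            proms = self.promoters
            if conditions is not None:
                proms = proms.subset_conditions(conditions)
            zfv_prom = z_normalize(proms)
            prom_corr = spearman_matrix(
                zfv_prom.values, rxn_matrix.values, self.min_overlap
            )
        expr_gene_z: dict[str, ProfileMatrix] = {}
        expr_rxn_raw: dict[str, pd.DataFrame] = {}
        expr_corrs: dict[str, pd.DataFrame] = {}
        if self.expression:
            covered = set(gene_raw.row_ids)
            for name, gene_expr in self.expression.items():
                keep = [g for g in gene_expr.row_ids if g in covered]
                if not keep:
                    raise ValueError(
                        f"expression dataset {name!r}: no genes overlap the fitness screen"
                    )
                zge = z_normalize(gene_expr.subset_rows(keep))
                raw_expr = collapse_gene_matrix(self.model, ProfileMatrix(zge.values)).dropna(
                    how="all"
                )
                if raw_expr.empty:
                    raise ValueError(
                        f"expression dataset {name!r}: no reaction has an evaluable GPR"
                    )
                expr_gene_z[name] = zge
                expr_rxn_raw[name] = raw_expr
                rxn_expr = z_normalize(ProfileMatrix(raw_expr))
                expr_corrs[name] = spearman_matrix(
                    zge.values, rxn_expr.values, self.min_overlap
                )
        nonorphan_profiled = {r.id for r in self.model.non_orphans} & set(
            rxn_matrix.row_ids
        )
        return _Context(
            zfv_genes=zfv_genes,
            rxn_raw=rxn_raw,
            rxn_matrix=rxn_matrix,
            graph=graph,
            adequate=adequate,
            gene_rxn_corr=gene_rxn_corr,
            zfv_prom=zfv_prom,
            prom_rxn_corr=prom_corr,
            expr_gene_z=expr_gene_z,
            expr_rxn_raw=expr_rxn_raw,
            expr_corrs=expr_corrs,
            nonorphan_profiled=nonorphan_profiled,
        )

    @property
    def context(self) -> _Context:
        if self._context is None:
            self._context = self._build_context()
        return self._context

    # -- scoring -------------------------------------------------------------

    def _neighbor_rows(
        self, ctx: _Context, neighbors: list[str], hidden: str | None
    ) -> pd.DataFrame:
        """Z-normalized neighbor reaction vectors; when a reaction is hidden
        (cast as orphan in LOO) it has no vector of its own, so the
        per-condition normalization is recomputed over the remaining
        reactions."""
        if hidden is None:
            return ctx.rxn_matrix.values.loc[neighbors]
        reduced = ctx.rxn_raw.drop(index=hidden, errors="ignore")
        return z_normalize(ProfileMatrix(reduced)).values.loc[neighbors]

    def _fitness_scores(
        self, ctx: _Context, neighbors: list[str], hidden: str | None = None
    ) -> pd.Series:
        if hidden is None:
            block = ctx.gene_rxn_corr[neighbors].to_numpy(dtype=float)
            return pd.Series(_top2_mean(block.copy()), index=ctx.gene_rxn_corr.index)
        nb = self._neighbor_rows(ctx, neighbors, hidden)
        corr = spearman_matrix(ctx.zfv_genes.values, nb, self.min_overlap)
        return pd.Series(_top2_mean(corr.to_numpy()), index=corr.index)

    def _promoter_terms(
        self, ctx: _Context, neighbors: list[str], hidden: str | None = None
    ) -> pd.Series:
        genes = ctx.gene_rxn_corr.index
        if ctx.prom_rxn_corr is None or not self.promoter_map:
            return pd.Series(0.0, index=genes)
        if hidden is None:
            block = ctx.prom_rxn_corr[neighbors].to_numpy(dtype=float)
            prom_als = pd.Series(
                _top2_mean(block.copy()), index=ctx.prom_rxn_corr.index
            )
        else:
            nb = self._neighbor_rows(ctx, neighbors, hidden)
            corr = spearman_matrix(ctx.zfv_prom.values, nb, self.min_overlap)
            prom_als = pd.Series(_top2_mean(corr.to_numpy()), index=corr.index)
        terms = []
        for g in genes:
            vals = [
                prom_als[p]
                for p in self.promoter_map.get(g, [])
                if p in prom_als.index and np.isfinite(prom_als[p])
            ]
            terms.append(sum(vals))
        return pd.Series(terms, index=genes, dtype=float)

    def _expression_scores(
        self, ctx: _Context, neighbors: list[str], hidden: str | None = None
    ) -> pd.Series:
        genes = ctx.gene_rxn_corr.index
        if not ctx.expr_corrs:
            return pd.Series(np.nan, index=genes)
        per_dataset = []
        for name, corr_full in ctx.expr_corrs.items():
            raw = ctx.expr_rxn_raw[name]
            nbrs = [n for n in neighbors if n in raw.index and n != hidden]
            if len(nbrs) < 2:
                continue
            if hidden is None:
                block = corr_full[nbrs].to_numpy(dtype=float)
                per_dataset.append(
                    pd.Series(_top2_mean(block.copy()), index=corr_full.index)
                )
            else:
                reduced = raw.drop(index=hidden, errors="ignore")
                nb = z_normalize(ProfileMatrix(reduced)).values.loc[nbrs]
                corr = spearman_matrix(
                    ctx.expr_gene_z[name].values, nb, self.min_overlap
                )
                per_dataset.append(
                    pd.Series(_top2_mean(corr.to_numpy()), index=corr.index)
                )
        if not per_dataset:
            return pd.Series(np.nan, index=genes)
        stacked = pd.concat(per_dataset, axis=1)
        return stacked.mean(axis=1, skipna=True).reindex(genes)

    def _combined_scores(
        self, ctx: _Context, rid: str, neighbors: list[str], hidden: str | None = None
    ) -> pd.DataFrame:
        """Per-candidate score components for one adequate reaction."""
        fit = self._fitness_scores(ctx, neighbors, hidden)
        prom = self._promoter_terms(ctx, neighbors, hidden)
        adj = fit + self.alpha * prom
        expr = self._expression_scores(ctx, neighbors, hidden)
        combined = np.where(
            np.isfinite(expr), 0.5 * adj + 0.5 * expr, adj
        )
        return pd.DataFrame(
            {
                "als_fitness": fit,
                "promoter_term": prom,
                "als_adjusted": adj,
                "als_expression": expr,
                "combined": combined,
                "fitness_only": ~np.isfinite(expr),
            }
        )

    # -- public API ----------------------------------------------------------

    def default_prior(self) -> ConfidencePrior:
        """(# true gene-reaction pairs) / (# genes x # non-orphan reactions)."""
        genes = set(self.gene_fitness.row_ids)
        nonorphans = self.model.non_orphans
        n_pairs = sum(
            1 for r in nonorphans for g in r.gpr.genes if g in genes
        )
        denom = len(genes) * len(nonorphans)
        p = n_pairs / denom if denom else 0.5
        p = min(max(p, 1e-9), 1 - 1e-9)
        return ConfidencePrior(p_true=p)

    def fit(
        self,
        compute_confidence: bool = True,
        prior: ConfidencePrior | None = None,
        max_false_scores: int = 100_000,
        seed: int | None = 0,
    ) -> "AssignmentResults":
        """Score and rank candidate genes for every adequate orphan reaction."""
        ctx = self.context
        orphan_ids = [r.id for r in self.model.orphans if r.id in ctx.adequate]
        rows = []
        for rid in orphan_ids:
            neighbors = ctx.neighbors_of(rid)
            if len(neighbors) < 2:
                continue
            table = self._combined_scores(ctx, rid, neighbors)
            ranked = rank_candidates(table["combined"].to_dict(), self.top_k)
            for gene, score, rank in ranked:
                rec = table.loc[gene]
                rows.append(
                    {
                        "reaction_id": rid,
                        "gene_id": gene,
                        "rank": rank,
                        "als_fitness": rec["als_fitness"],
                        "promoter_term": rec["promoter_term"],
                        "als_expression": rec["als_expression"],
                        "combined": score,
                        "fitness_only": bool(rec["fitness_only"]),
                    }
                )
        assignments = pd.DataFrame(
            rows,
            columns=[
                "reaction_id",
                "gene_id",
                "rank",
                "als_fitness",
                "promoter_term",
                "als_expression",
                "combined",
                "fitness_only",
            ],
        )
        results = AssignmentResults(
            model=self,
            assignments=assignments,
            n_adequate_orphans=len(orphan_ids),
            n_inadequate_orphans=len(self.model.orphans) - len(orphan_ids),
        )
        if compute_confidence and not assignments.empty:
            prior = prior or self.default_prior()
            true_s, false_s = self._loo_score_distributions(
                max_false_scores=max_false_scores, seed=seed
            )
            bayes, unb = [], []
            for s in assignments["combined"]:
                b, u = confidence(float(s), true_s, false_s, prior)
                bayes.append(b)
                unb.append(u)
            results.assignments["bayesian_conf"] = bayes
            results.assignments["unbiased_conf"] = unb
            results.prior = prior
        return results

    def _loo_score_distributions(
        self, max_false_scores: int = 100_000, seed: int | None = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """True-pair and spurious-pair combined-score distributions from
        leave-one-out over adequate non-orphan reactions."""
        ctx = self.context
        rng = np.random.default_rng(seed)
        true_scores: list[float] = []
        false_scores: list[float] = []
        for r in self.model.non_orphans:
            if r.id not in ctx.adequate:
                continue
            neighbors = [n for n in ctx.neighbors_of(r.id) if n != r.id]
            if len(neighbors) < 2:
                continue
            table = self._combined_scores(ctx, r.id, neighbors, hidden=r.id)
            truth = {g for g in r.gpr.genes if g in table.index}
            scores = table["combined"]
            for g, s in scores.items():
                if not np.isfinite(s):
                    continue
                (true_scores if g in truth else false_scores).append(float(s))
        false_arr = np.asarray(false_scores)
        if false_arr.size > max_false_scores:
            false_arr = rng.choice(false_arr, size=max_false_scores, replace=False)
        return np.asarray(true_scores), false_arr

    def loo_validate(
        self,
        k_max: int = 20,
        mode: str = "first_gene",
        conditions: Sequence[str] | None = None,
        n_conditions: int | None = None,
        seed: int | None = None,
        score: str = "combined",
    ) -> ValidationReport:
        """Leave-one-out validation over adequate non-orphan reactions.

        Each adequate non-orphan reaction is cast as an orphan: its own
        vector cannot serve as a neighbor, every gene in the fitness matrix
        is a candidate (its true genes included), and the best true-gene rank
        is recorded. ``mode='second_gene'`` restricts to reactions with >= 2
        measured genes, removes the best-ranked true gene and asks for the
        rank of another. ``n_conditions`` (with ``seed``) subsamples the
        condition set; ``score`` selects 'fitness', 'expression' or
        'combined' scoring.
        """
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        if mode not in ("first_gene", "second_gene"):
            raise ValueError(f"unknown mode {mode!r}")
        if conditions is None and n_conditions is not None:
            all_conds = self.gene_fitness.col_ids
            if n_conditions > len(all_conds):
                raise ValueError("n_conditions exceeds available conditions")
            rng = np.random.default_rng(seed)
            conditions = list(
                rng.choice(all_conds, size=n_conditions, replace=False)
            )
        ctx = self.context if conditions is None else self._build_context(conditions)
        rows = []
        for r in self.model.non_orphans:
            if r.id not in ctx.adequate:
                continue
            neighbors = [n for n in ctx.neighbors_of(r.id) if n != r.id]
            if len(neighbors) < 2:
                continue
            table = self._combined_scores(ctx, r.id, neighbors, hidden=r.id)
            if score == "fitness":
                series = table["als_adjusted"]
            elif score == "expression":
                series = table["als_expression"]
            elif score == "combined":
                series = table["combined"]
            else:
                raise ValueError(f"unknown score source {score!r}")
            truth = {g for g in r.gpr.genes if g in series.index}
            if not truth:
                continue
            if mode == "second_gene" and len(truth) < 2:
                continue
            order = rank_candidates(series.to_dict(), top_k=len(series))
            rank_of = {g: rk for g, _, rk in order}
            true_ranks = sorted(rank_of.get(g, math.inf) for g in truth)
            if mode == "second_gene":
                best = true_ranks[1] if len(true_ranks) > 1 else math.inf
                # removing the best-ranked true gene shifts everyone below up one
                best = best - 1 if math.isfinite(best) else best
            else:
                best = true_ranks[0]
            rows.append(
                {
                    "reaction_id": r.id,
                    "best_true_rank": best,
                    "n_true_genes": len(truth),
                    "n_candidates": len(series),
                }
            )
        ranks = pd.DataFrame(
            rows, columns=["reaction_id", "best_true_rank", "n_true_genes", "n_candidates"]
        )
        total_genes = len(self.gene_fitness.row_ids)
        nonorphans = self.model.non_orphans
        genes_per_rxn = (
            float(np.mean([len(r.gpr.genes) for r in nonorphans])) if nonorphans else 0.0
        )
        baselines = {
            "weak_udist_topk": weak_udist(k_max, len(ranks), total_genes),
            "strong_udist_topk": strong_udist(k_max, genes_per_rxn),
        }
        return ValidationReport(
            ranks=ranks,
            k_max=k_max,
            mode=mode,
            n_conditions=len(ctx.zfv_genes.col_ids),
            baselines=baselines,
        )


@dataclass
class AssignmentResults:
    """Ranked candidate genes per adequate orphan reaction."""

    model: GeneAssignment
    assignments: pd.DataFrame
    n_adequate_orphans: int
    n_inadequate_orphans: int
    prior: ConfidencePrior | None = None

    def top(self, reaction_id: str, k: int | None = None) -> pd.DataFrame:
        sub = self.assignments[self.assignments["reaction_id"] == reaction_id]
        return sub.head(k) if k else sub

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.assignments.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = [
            "Gene-to-orphan-reaction assignment",
            "=" * 50,
            f"orphan reactions (adequate):    {self.n_adequate_orphans}",
            f"orphan reactions (inadequate):  {self.n_inadequate_orphans}",
            f"candidate genes:                {len(self.model.gene_fitness.row_ids)}",
            f"conditions:                     {len(self.model.gene_fitness.col_ids)}",
            f"alpha (promoter weight):        {self.model.alpha}",
            f"metabolite frequency cutoff:    {self.model.cutoff}",
            f"top-k reported:                 {self.model.top_k}",
        ]
        if self.prior is not None:
            lines.append(f"assignment prior p_true:        {self.prior.p_true:.3%}")
        if not self.assignments.empty:
            lines.append("-" * 50)
            lines.append("top candidate per reaction:")
            best = self.assignments[self.assignments["rank"] == 1]
            for _, row in best.iterrows():
                conf = ""
                if "unbiased_conf" in row and np.isfinite(row.get("unbiased_conf", np.nan)):
                    conf = f"  unbiased_conf={row['unbiased_conf']:.3f}"
                lines.append(
                    f"  {row['reaction_id']:<16} {row['gene_id']:<12} "
                    f"combined={row['combined']:+.3f}{conf}"
                )
        return "\n".join(lines)
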