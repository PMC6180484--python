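"""Genome-wide statistics for fitness screens.

Covers four families of analyses:

* region-effect tests — does one class of genomic region (e.g. 3'UTRs, or
  sigma28-dependent promoters) show the strongest negative fitness effect in
  more conditions than a uniform null would predict (exact binomial tail);
* co-fitness / co-expression — Spearman correlation of profile vectors,
  enrichment of functional gene-pair classes against the background
  (one-tailed Wilcoxon rank-sum), survival-ratio curves, and distance/GC
  stratification of gene pairs;
* minimum-hypergeometric (mHG) statistics on ranked binary lists and the
  mutual (mmHG) variant for comparing two rankings, with shuffle-based
  empirical p-values;
* PSSM scanning of promoter sequences with mHG enrichment at the top of a
  fitness ranking.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._corr import MIN_OVERLAP_DEFAULT, spearman_matrix, spearman_pair
from .profiles import ProfileMatrix

__all__ = [
    "GenePairClass",
    "binom_tail",
    "region_effect_test",
    "cofitness_matrix",
    "class_enrichment",
    "relative_ratio_curve",
    "stratify_pairs",
    "mhg",
    "mmhg_pair",
    "pssm_enrichment",
]


@dataclass
class GenePairClass:
    """A named set of unordered gene pairs (operon, paralog, distance bin...)."""

    name: str
    pairs: set[frozenset[str]]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"class {self.name!r}: self-pair or malformed pair {set(p)}")


# ---------------------------------------------------------------------------
# Binomial region-effect tests
# ---------------------------------------------------------------------------


def binom_tail(n: int, p: float, k: int) -> float:
    """Exact inclusive upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p))


_STATISTICS = {
    "mean": lambda v: float(np.mean(v)),
    "pct10": lambda v: float(np.percentile(v, 10)),
    "pct25": lambda v: float(np.percentile(v, 25)),
    "median": lambda v: float(np.median(v)),
}


def region_effect_test(
    kind_matrices: Mapping[str, ProfileMatrix],
    focal_kind: str,
    statistic: str = "mean",
) -> tuple[int, int, float]:
    """Count conditions where the focal region kind is most negatively
    affected, and score the count against a uniform null.

    ``kind_matrices`` maps each region kind to a region x condition matrix
    (all matrices must share the condition set). Per condition the chosen
    statistic (mean, pct10, pct25 or median) is computed per kind over finite
    scores; a *win* is the focal kind attaining the strictly smallest value.
    Conditions where any kind has no finite score are skipped. Returns
    ``(wins, n_conditions_used, p)`` with ``p = binom_tail(n_used, 1/n_kinds,
    wins)`` — the null success probability is the exact rational 1/n_kinds.
    """
    if focal_kind not in kind_matrices:
        raise KeyError(f"focal kind {focal_kind!r} not among matrices")
    if len(kind_matrices) < 2:
        raise ValueError("need at least two region kinds")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]
    kinds = sorted(kind_matrices)
    conditions = kind_matrices[kinds[0]].col_ids
    for k in kinds:
        if kind_matrices[k].col_ids != conditions:
            raise ValueError("all kinds must share an identical condition set")
    wins = 0
    used = 0
    skipped = []
    for cond in conditions:
        per_kind = {}
        ok = True
        for k in kinds:
            col = kind_matrices[k].values[cond].to_numpy(dtype=float)
            col = col[np.isfinite(col)]
            if col.size == 0:
                ok = False
                break
            per_kind[k] = stat(col)
        if not ok:
            skipped.append(cond)
            continue
        used += 1
        focal_val = per_kind[focal_kind]
        if all(focal_val < v for k, v in per_kind.items() if k != focal_kind):
            wins += 1
    if skipped:
        warnings.warn(f"skipped {len(skipped)} condition(s) with a missing kind")
    if used == 0:
        raise ValueError("no condition had scores for every kind")
    p = binom_tail(used, 1.0 / len(kinds), wins)
    return wins, used, p


# ---------------------------------------------------------------------------
# Co-fitness
# ---------------------------------------------------------------------------


def cofitness_matrix(
    matrix: ProfileMatrix, min_overlap: int = MIN_OVERLAP_DEFAULT
) -> pd.DataFrame:
    """Symmetric gene x gene Spearman correlation matrix (unit diagonal).

    Pairs with fewer than ``min_overlap`` shared finite conditions are NaN.
    """
    if len(matrix.row_ids) < 2:
        raise ValueError("need at least two elements")
    corr = spearman_matrix(matrix.values, matrix.values, min_overlap=min_overlap)
    arr = corr.to_numpy()
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)


def pair_values(
    cofit: pd.DataFrame, pairs: Iterable[frozenset[str]]
) -> np.ndarray:
    """Extract co-fitness values for a set of unordered pairs (finite only)."""
    vals = []
    for p in pairs:
        a, b = sorted(p)
        if a in cofit.index and b in cofit.index:
            v = cofit.loc[a, b]
            if np.isfinite(v):
                vals.append(float(v))
    return np.asarray(vals)


def class_enrichment(
    class_values: Sequence[float],
    background_values: Sequence[float],
    exact_max_n: int = 10,
) -> float:
    """One-tailed Wilcoxon rank-sum p-value: is the class shifted high
    relative to the background?

    The caller is expected to have removed the class pairs (and, for
    non-operon classes, same-operon pairs) from the background. Small samples
    (n1 + n2 <= ``exact_max_n``) use the exact permutation distribution,
    larger ones the tie-corrected normal approximation.
    """
    x = np.asarray(class_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size < 3:
        warnings.warn("class has fewer than 3 pairs; p-value computed exactly")
    small = x.size + y.size <= exact_max_n
    method = "exact" if small and not _has_ties(x, y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def relative_ratio_curve(
    class_values: Sequence[float],
    background_values: Sequence[float],
    xs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """log10 ratio of class vs background survival fractions over a grid.

    For each threshold x: rho(x, C) = fraction of class pairs with value >= x,
    same for the background; the curve reports log10[rho(x,C)/rho(x,T)].
    Points where either fraction is 0 are returned NaN with ``defined=False``.
    """
    x_arr = np.asarray(class_values, dtype=float)
    t_arr = np.asarray(background_values, dtype=float)
    if t_arr.size == 0:
        raise ValueError("background must be non-empty")
    if xs is None:
        xs = np.arange(-0.5, 1.0001, 0.05)
    rows = []
    for x in xs:
        rho_c = float(np.mean(x_arr >= x)) if x_arr.size else float("nan")
        rho_t = float(np.mean(t_arr >= x))
        defined = rho_c > 0 and rho_t > 0
        rows.append(
            {
                "x": float(x),
                "rho_class": rho_c,
                "rho_background": rho_t,
                "log10_ratio": math.log10(rho_c / rho_t) if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def stratify_pairs(
    genes: pd.DataFrame,
    bin_sizes: Sequence[int] = (5_000, 10_000, 20_000, 50_000, 100_000),
    gc_deciles: int = 10,
    gc_filter: bool = True,
) -> list[GenePairClass]:
    """Group gene pairs into start-to-start distance classes, optionally
    filtering out pairs whose genes fall in the same GC-content decile.

    ``genes`` needs columns ``start`` and (when filtering) ``gc``, plus an
    optional ``scaffold`` column; cross-scaffold pairs are excluded. Distance
    bins are cumulative: a pair belongs to every bin of size >= its distance.
    GC decile boundaries are empirical quantiles, right-closed.
    """
    if "start" not in genes.columns:
        raise ValueError("genes frame needs a 'start' column")
    ids = list(genes.index.astype(str))
    starts = genes["start"].to_numpy(dtype=float)
    scaff = (
        genes["scaffold"].astype(str).to_numpy()
        if "scaffold" in genes.columns
        else np.array([""] * len(ids))
    )
    if gc_filter:
        if "gc" not in genes.columns:
            raise ValueError("GC filtering requires a 'gc' column")
        gc = genes["gc"].to_numpy(dtype=float)
        # right-closed empirical decile bins
        edges = np.quantile(gc, np.linspace(0, 1, gc_deciles + 1))
        decile = np.clip(np.searchsorted(edges[1:-1], gc, side="left"), 0, gc_deciles - 1)
    classes = {size: set() for size in bin_sizes}
    for i, j in itertools.combinations(range(len(ids)), 2):
        if scaff[i] != scaff[j]:
            continue
        if gc_filter and decile[i] == decile[j]:
            continue
        dist = abs(starts[i] - starts[j])
        for size in bin_sizes:
            if dist <= size:
                classes[size].add(frozenset((ids[i], ids[j])))
    return [
        GenePairClass(name=f"distance_bin:{size}", pairs=classes[size])
        for size in bin_sizes
    ]


# ---------------------------------------------------------------------------
# Minimum hypergeometric statistics
# ---------------------------------------------------------------------------


def mhg(labels: Sequence[int]) -> tuple[float, int, int]:
    """Minimum hypergeometric score of a ranked 0/1 list.

    Scans all prefixes n = 1..N and returns the minimum inclusive
    hypergeometric upper tail P(X >= b(n)) with X ~ Hypergeom(N, B, n),
    together with the minimizing prefix length and its 1-count. An all-zero
    list scores 1 by convention. The score is a statistic, not a p-value.
    """
    lab = np.asarray(labels, dtype=int)
    if lab.ndim != 1 or lab.size < 1:
        raise ValueError("labels must be a non-empty 1-D 0/1 vector")
    if not np.isin(lab, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n_total = lab.size
    b_total = int(lab.sum())
    if b_total == 0:
        return 1.0, 0, 0
    b_running = np.cumsum(lab)
    ns = np.arange(1, n_total + 1)
    tails = stats.hypergeom.sf(b_running - 1, n_total, b_total, ns)
    # first prefix attaining the minimum, robust to float noise on exact ties
    idx = int(np.nonzero(tails <= tails.min() + 1e-12)[0][0])
    return float(tails[idx]), int(ns[idx]), int(b_running[idx])


def mmhg_pair(
    rank_a: Sequence[str],
    rank_b: Sequence[str],
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Mutual mHG between two rankings of the same element set.

    For every threshold B on list a, the top-B elements of a become the
    1-labels, ordered by list b, and the mHG is taken; the mutual score is the
    minimum over B. The empirical p-value is the fraction of ``n_shuffles``
    random shufflings of list a whose mutual score is <= the observed one.
    """
    if sorted(rank_a) != sorted(rank_b):
        raise ValueError("rankings must cover the same element set")
    rng = np.random.default_rng(rng)
    score, n_at, b_at, b_thresh = _mmhg_score(list(rank_a), list(rank_b))
    hits = 0
    shuffled = list(rank_a)
    for _ in range(n_shuffles):
        rng.shuffle(shuffled)
        s, _, _, _ = _mmhg_score(shuffled, list(rank_b))
        if s <= score:
            hits += 1
    return {
        "score": score,
        "N": len(rank_a),
        "B": b_thresh,
        "n": n_at,
        "b": b_at,
        "empirical_p": hits / n_shuffles,
    }


def _mmhg_score(rank_a: list[str], rank_b: list[str]) -> tuple[float, int, int, int]:
    n = len(rank_a)
    best = (1.0, 0, 0, 0)
    pos_in_a = {e: i for i, e in enumerate(rank_a)}
    order_b = np.array([pos_in_a[e] for e in rank_b])
    for b_thresh in range(1, n):
        labels = (order_b < b_thresh).astype(int)
        s, n_at, b_at = mhg(labels)
        if s < best[0]:
            best = (s, n_at, b_at, b_thresh)
    return best


# ---------------------------------------------------------------------------
# PSSM scanning
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pssm_scores(
    sequences: Mapping[str, str],
    pssm: np.ndarray,
    pseudo: float = 1e-9,
) -> dict[str, float]:
    """Best log-odds PSSM score per sequence over positions and both strands.

    ``pssm`` is a 4 x w matrix of base probabilities (rows A, C, G, T);
    scores are log2 odds against a uniform background. Sequences shorter
    than the motif are skipped with a warning.
    """
    pssm = np.asarray(pssm, dtype=float)
    if pssm.shape[0] != 4:
        raise ValueError("pssm must have 4 rows (A, C, G, T)")
    logodds = np.log2((pssm + pseudo) / 0.25)
    w = pssm.shape[1]
    out: dict[str, float] = {}
    skipped = 0
    for name, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < w:
            skipped += 1
            continue
        best = -np.inf
        for strand_seq in (seq, seq.translate(_COMPLEMENT)[::-1]):
            idx = np.array([_BASE_INDEX.get(c, -1) for c in strand_seq])
            for i in range(len(strand_seq) - w + 1):
                window = idx[i : i + w]
                if (window < 0).any():
                    continue
                best = max(best, float(logodds[window, np.arange(w)].sum()))
        out[name] = best
    if skipped:
        warnings.warn(f"{skipped} sequence(s) shorter than the motif were skipped")
    return out


def pssm_enrichment(
    ranked_promoters: Sequence[tuple[str, str]],
    pssm: np.ndarray,
    hit_threshold: float,
) -> tuple[set[str], float]:
    """mHG enrichment of PSSM hits at the top of a fitness-ranked promoter list.

    ``ranked_promoters`` is the output of
    :func:`orphanfit.profiles.ranked_promoter_list` (strongest fitness effect
    first). Returns the hit set and the mHG score of the 0/1 hit vector in
    ranked order.
    """
    scores = pssm_scores(dict(ranked_promoters), pssm)
    hits = {name for name, s in scores.items() if s >= hit_threshold}
    labels = [1 if name in hits else 0 for name, _ in ranked_promoters if name in scores]
    if not labels:
        return set(), 1.0
    score, _, _ = mhg(labels)
    return hits, score
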