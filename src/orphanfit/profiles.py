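"""Fitness/expression profile matrices and genomic-region fitness.

The central container is :class:`ProfileMatrix`, a thin wrapper around a
pandas DataFrame (rows = genomic elements: genes, regions, or reactions;
columns = conditions) with a ``normalized`` flag. Missing measurements stay
missing (NaN) and are never imputed; correlations downstream use
pairwise-complete observations.

Region fitness follows the screen convention for non-coding elements: the
fitness of a promoter/UTR in a condition is the arithmetic mean of the raw
per-insertion fitness values of all insertions falling inside the region
(0-based half-open intervals; both strands pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InsertionRecord",
    "GenomicRegion",
    "ProfileMatrix",
    "region_fitness",
    "region_matrix",
    "condition_pair_score",
    "z_normalize",
    "build_vectors",
    "ranked_promoter_list",
    "read_fitness_table",
    "read_insertion_table",
    "read_region_table",
    "write_ranked_fasta",
]

REGION_KINDS = ("promoter", "five_prime_utr", "three_prime_utr", "cds")


@dataclass(frozen=True)
class InsertionRecord:
    """A single transposon insertion with raw per-condition fitness scores."""

    position: int
    scores: Mapping[str, float]
    scaffold: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("insertion position must be >= 0")
        if not self.scores:
            raise ValueError("insertion must carry at least one condition score")


@dataclass(frozen=True)
class GenomicRegion:
    """Typed genomic interval (0-based, half-open) linked to a gene."""

    id: str
    kind: str
    start: int
    end: int
    scaffold: str = ""
    strand: str = "+"
    gene_link: str | None = None
    sigma: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"region {self.id!r}: start must be < end")

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


class ProfileMatrix:
    """Element x condition matrix of fitness or expression scores."""

    def __init__(self, values: pd.DataFrame, normalized: bool = False):
        if values.index.has_duplicates:
            raise ValueError("duplicate row ids in profile matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate condition ids in profile matrix")
        self.values = values.astype(float)
        self.normalized = bool(normalized)

    # -- basic introspection -------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, element_id: str) -> pd.Series:
        if element_id not in self.values.index:
            raise KeyError(f"unknown element id {element_id!r}")
        return self.values.loc[element_id]

    def subset_conditions(self, conditions: Sequence[str]) -> "ProfileMatrix":
        missing = [c for c in conditions if c not in self.values.columns]
        if missing:
            raise KeyError(f"unknown condition ids {missing}")
        return ProfileMatrix(self.values[list(conditions)], normalized=self.normalized)

    def subset_rows(self, ids: Sequence[str]) -> "ProfileMatrix":
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"unknown element ids {missing}")
        return ProfileMatrix(self.values.loc[list(ids)], normalized=self.normalized)

    # -- I/O ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.to_csv(fh, sep="\t", index_label="id")


def region_fitness(
    insertions: Iterable[InsertionRecord],
    region: GenomicRegion,
    condition: str,
    known_conditions: Sequence[str] | None = None,
) -> float:
    """Mean raw insertion fitness within a region for one condition.

    Returns NaN when no insertion lies in the region or none carries the
    condition. ``known_conditions`` (when given) is used to validate the
    condition id.
    """
    if known_conditions is not None and condition not in known_conditions:
        raise KeyError(f"unknown condition id {condition!r}")
    vals = [
        float(ins.scores[condition])
        for ins in insertions
        if region.contains(ins.position)
        and (not region.scaffold or not ins.scaffold or ins.scaffold == region.scaffold)
        and condition in ins.scores
        and np.isfinite(ins.scores[condition])
    ]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def region_matrix(
    insertions: Sequence[InsertionRecord],
    regions: Sequence[GenomicRegion],
    conditions: Sequence[str],
) -> ProfileMatrix:
    """Region x condition matrix of mean insertion fitness (NaN when empty)."""
    data = {
        reg.id: [region_fitness(insertions, reg, c) for c in conditions]
        for reg in regions
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(conditions))
    return ProfileMatrix(df)


def condition_pair_score(
    matrix: ProfileMatrix, element_id: str, cond_l: str, cond_k: str
) -> float:
    """Difference of an element's scores between two conditions (l minus k)."""
    row = matrix.row(element_id)
    for c in (cond_l, cond_k):
        if c not in matrix.values.columns:
            raise KeyError(f"unknown condition id {c!r}")
    return float(row[cond_l] - row[cond_k])


def z_normalize(matrix: ProfileMatrix) -> ProfileMatrix:
    """Z-normalize each condition (column) over its finite entries.

    Uses the population standard deviation (divide by N). Missing entries are
    preserved. A column with fewer than two finite values or zero spread is an
    error naming the condition.
    """
    values = matrix.values.copy()
    for cond in values.columns:
        col = values[cond].to_numpy(dtype=float)
        finite = np.isfinite(col)
        if finite.sum() < 2:
            raise ValueError(f"condition {cond!r}: fewer than 2 finite values")
        mean = col[finite].mean()
        std = col[finite].std(ddof=0)
        if std == 0:
            raise ValueError(f"condition {cond!r}: zero spread, cannot Z-normalize")
        values[cond] = (col - mean) / std
    return ProfileMatrix(values, normalized=True)


def build_vectors(
    matrix: ProfileMatrix, ids: Sequence[str]
) -> dict[str, pd.Series]:
    """Per-element condition-indexed vectors, preserving condition order."""
    return {i: matrix.row(i) for i in ids}


def ranked_promoter_list(
    matrix: ProfileMatrix,
    condition: str | tuple[str, str],
    regions: Sequence[GenomicRegion],
    ascending: bool = True,
) -> list[tuple[str, str]]:
    """Promoters ranked by fitness score for motif-enrichment export.

    ``condition`` is either a single condition id (score per the region mean)
    or a pair ``(l, k)`` scored as the difference l - k. The default ranking
    is ascending (strongest negative fitness effect first); ties break by
    promoter id. Promoters lacking a sequence are excluded with a warning.
    """
    proms = [r for r in regions if r.kind == "promoter"]
    skipped = sum(1 for r in proms if r.sequence is None)
    if skipped:
        warnings.warn(f"{skipped} promoter(s) lack a sequence and were excluded")
    proms = [r for r in proms if r.sequence is not None]
    scored = []
    for r in proms:
        if isinstance(condition, tuple):
            score = condition_pair_score(matrix, r.id, condition[0], condition[1])
        else:
            row = matrix.row(r.id)
            if condition not in matrix.values.columns:
                raise KeyError(f"unknown condition id {condition!r}")
            score = float(row[condition])
        if np.isfinite(score):
            scored.append((score, r.id, r.sequence))
    scored.sort(key=lambda t: (t[0] if ascending else -t[0], t[1]))
    return [(rid, seq) for _, rid, seq in scored]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_fitness_table(path: str | Path) -> ProfileMatrix:
    """Read a gene x condition TSV (first column ids, header = conditions)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    return ProfileMatrix(df)


def read_insertion_table(path: str | Path) -> list[InsertionRecord]:
    """Read a per-insertion TSV: columns ``position``, ``scaffold``, then one
    column per condition with raw strain fitness."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = [c for c in ("position", "scaffold") if c in df.columns]
    if "position" not in meta:
        raise ValueError(f"{path}: insertion table lacks a 'position' column")
    conds = [c for c in df.columns if c not in meta]
    records = []
    for _, row in df.iterrows():
        scores = {c: float(row[c]) for c in conds if np.isfinite(row[c])}
        records.append(
            InsertionRecord(
                position=int(row["position"]),
                scores=scores,
                scaffold=str(row["scaffold"]) if "scaffold" in meta else "",
            )
        )
    return records


def read_region_table(path: str | Path) -> list[GenomicRegion]:
    """Read a BED-like region annotation TSV.

    Columns: scaffold, start, end, id, kind, strand, then optional
    ``gene``, ``sigma`` and ``sequence`` columns.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"scaffold", "start", "end", "id", "kind", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: region table lacks columns {sorted(missing)}")
    regions = []
    for _, row in df.iterrows():
        regions.append(
            GenomicRegion(
                id=str(row["id"]),
                kind=str(row["kind"]),
                start=int(row["start"]),
                end=int(row["end"]),
                scaffold=str(row["scaffold"]),
                strand=str(row["strand"]),
                gene_link=str(row["gene"]) if "gene" in df.columns and pd.notna(row["gene"]) else None,
                sigma=str(row["sigma"]) if "sigma" in df.columns and pd.notna(row["sigma"]) else None,
                sequence=str(row["sequence"]) if "sequence" in df.columns and pd.notna(row["sequence"]) else None,
            )
        )
    return regions


def write_ranked_fasta(ranked: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write a ranked promoter list as FASTA (rank encoded in the header)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(seq), id=rid, description=f"rank={i + 1}")
        for i, (rid, seq) in enumerate(ranked)
    ]
    SeqIO.write(records, str(path), "fasta")
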