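"""Reaction neighborhood graph with greedy currency-metabolite pruning.

Two reactions are neighbors when they share at least one retained species.
Species that participate in very many reactions (H2O, protons, cofactors...)
connect everything to everything and drown the pathway signal, so species
with frequency above a cutoff (default 11) are greedily removed, highest
frequency first, *unless* the removal would leave some reaction that
previously had two or more non-orphan profiled neighbors with fewer than
two — in that case the removal is reverted. The two-neighbor constraint keeps
every reaction embeddable in a linear pathway.

A reaction is *adequate* (scoreable) when it has at least two non-orphan
neighbors possessing profile vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .model_core import MetabolicModel, metabolite_frequencies

__all__ = ["NeighborhoodGraph", "build_adjacency", "greedy_prune", "adequate_reactions"]


@dataclass
class NeighborhoodGraph:
    """Undirected reaction adjacency over shared retained species."""

    nodes: list[str]
    adjacency: dict[str, set[str]]
    removed_species: list[str] = field(default_factory=list)

    def neighbors(self, rid: str) -> set[str]:
        return self.adjacency.get(rid, set())

    @property
    def edges(self) -> set[frozenset[str]]:
        out = set()
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                out.add(frozenset((a, b)))
        return out

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_a\treaction_b\n")
            for e in sorted(tuple(sorted(x)) for x in self.edges):
                fh.write(f"{e[0]}\t{e[1]}\n")


def build_adjacency(
    model: MetabolicModel, retained: set[str] | None = None
) -> NeighborhoodGraph:
    """Edge (r1, r2) iff some retained species occurs in both stoichiometries."""
    if retained is None:
        retained = {s.id for s in model.species}
    else:
        known = {s.id for s in model.species}
        unknown = retained - known
        if unknown:
            raise KeyError(f"retained species not in model: {sorted(unknown)}")
    nodes = [r.id for r in model.reactions]
    adjacency: dict[str, set[str]] = {rid: set() for rid in nodes}
    species_members: dict[str, list[str]] = {}
    for r in model.reactions:
        for sid in r.species_ids:
            if sid in retained:
                species_members.setdefault(sid, []).append(r.id)
    for members in species_members.values():
        for a, b in combinations(members, 2):
            adjacency[a].add(b)
            adjacency[b].add(a)
    return NeighborhoodGraph(nodes=nodes, adjacency=adjacency)


def _profiled_nonorphan_counts(
    model: MetabolicModel, adjacency: dict[str, set[str]], profiled: set[str]
) -> dict[str, int]:
    nonorphan = {r.id for r in model.non_orphans}
    good = nonorphan & profiled
    return {rid: sum(1 for n in nbrs if n in good) for rid, nbrs in adjacency.items()}


def greedy_prune(
    model: MetabolicModel,
    profiled_reactions: Iterable[str],
    cutoff: int = 11,
) -> NeighborhoodGraph:
    """Greedily drop species with frequency > ``cutoff`` from the graph.

    Candidates are visited in descending frequency (ties by species id).
    Frequencies are computed once on the unpruned model. A tentative removal
    is committed only if no reaction that currently has >=2 non-orphan
    profiled neighbors would drop below 2 ("for r or for some other
    reaction" — the constraint is global).

    ``profiled_reactions``: ids of reactions possessing profile vectors
    (typically the rows of the collapsed reaction fitness matrix).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    profiled = set(profiled_reactions)
    freqs = metabolite_frequencies(model)
    candidates = sorted(
        (sid for sid, f in freqs.items() if f > cutoff),
        key=lambda sid: (-freqs[sid], sid),
    )
    retained = {s.id for s in model.species}
    graph = build_adjacency(model, retained)
    removed: list[str] = []
    for sid in candidates:
        baseline = _profiled_nonorphan_counts(model, graph.adjacency, profiled)
        tentative = build_adjacency(model, retained - {sid})
        after = _profiled_nonorphan_counts(model, tentative.adjacency, profiled)
        harmful = any(
            baseline[rid] >= 2 and after[rid] < 2 for rid in graph.nodes
        )
        if harmful:
            continue
        retained.discard(sid)
        graph = tentative
        removed.append(sid)
    graph.removed_species = removed
    return graph


def adequate_reactions(
    model: MetabolicModel,
    graph: NeighborhoodGraph,
    profiled_reactions: Iterable[str],
) -> set[str]:
    """Reactions (orphan or not) with >=2 non-orphan profiled neighbors."""
    counts = _profiled_nonorphan_counts(model, graph.adjacency, set(profiled_reactions))
    return {rid for rid, c in counts.items() if c >= 2}
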