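"""Synthetic toy fixtures: metabolic models, fitness/expression screens,
insertions and regions with planted ground truth.

The generator emulates, at desk scale, the inputs the assignment pipeline
consumes on real data: a genome-scale model with GPR rules and orphans, a
gene x condition fitness screen, per-insertion fitness with promoter/CDS
annotation, and gene x sample expression sets.

Topology: reactions form linear 3-step pathways (end - middle - end) joined
by shared intermediate metabolites, so exactly the pathway middles have two
neighbors and are *adequate* for neighborhood scoring; a designated currency
species is inserted into more reactions than the pruning cutoff. Orphans are
planted on pathway middles (their true gene is recorded, their GPR hidden).

Latent condition profiles: per pathway, the middle latent and the two end
latents are built from three empirically-orthonormalized noise vectors as

    mid  = z0
    end1 = s * z0 + a * z1 + b * z2
    end2 = s * z0 - a * z1 + b * z2

with s = ``signal_strength`` and a, b chosen so the ends correlate at
max(2 s^2 - 1, -s). This "bisector" geometry gives the middle latent
correlation s with each end while the two ends anti-correlate at
2 s^2 - 1 for s >= 1/2 — the smallest feasible value — and become fully
independent at s = 0 (a true null). For the default it means
the planted middle gene is the *strongest* correlate of its reaction's
neighborhood (margin s - s^2, maximal at the default s = 0.5). Each pathway
draws its own empirically-orthonormalized basis, so within-pathway sample
correlations are exact by construction while cross-pathway correlations are
independent O(1/sqrt(n)) noise. True genes observe their reaction's latent
plus N(0, noise_sd^2); decoy genes are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import MetabolicModel, Reaction, parse_gpr, write_model_json
from .profiles import GenomicRegion, InsertionRecord, ProfileMatrix

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "SimulatedFitness",
    "make_toy_model",
    "simulate_fitness",
    "simulate_expression",
    "emit_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic fixture.

    Defaults mirror the real screen's scale where one exists (48 conditions;
    expression sets of 11 and 36 samples; pruning-relevant currency
    multiplicity just above the cutoff 11) and a seconds-scale toy size
    elsewhere (60 reactions / 80 genes).
    """

    seed: int
    n_reactions: int = 60
    n_genes: int = 80
    n_conditions: int = 48
    orphan_fraction: float = 0.1
    currency_species: int = 1
    currency_multiplicity: int = 12
    gpr_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # single / OR / AND
    signal_strength: float = 0.5
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.gpr_mix) - 1.0) > 1e-9:
            raise ValueError("gpr_mix fractions must sum to 1")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_reactions < 1 or self.n_genes < 1 or self.n_conditions < 3:
            raise ValueError("infeasible fixture size")


@dataclass
class GroundTruth:
    """Planted structure of a generated fixture."""

    assignments: dict[str, tuple[str, ...]]
    orphans: set[str]
    chains: list[list[str]]
    adequate: set[str]
    currency: list[str]
    decoy_genes: list[str]
    latents: dict[str, np.ndarray] = field(default_factory=dict)
    conditions: list[str] = field(default_factory=list)
    promoter_of: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedFitness:
    gene_matrix: ProfileMatrix
    insertions: list[InsertionRecord]
    regions: list[GenomicRegion]
    promoter_map: dict[str, list[str]]


def make_toy_model(spec: FixtureSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build the pathway-structured toy model with planted orphans."""
    rng = np.random.default_rng([spec.seed, 0])
    n_chains_full, leftover = divmod(spec.n_reactions, 3)
    chains: list[list[str]] = []
    reactions: list[tuple[str, dict[str, float]]] = []
    for c in range(n_chains_full):
        rids = [f"R{c:02d}_{i}" for i in (1, 2, 3)]
        chains.append(rids)
        for i, rid in enumerate(rids):
            stoich = {f"M{c:02d}_{i}": -1.0, f"M{c:02d}_{i + 1}": 1.0}
            reactions.append((rid, stoich))
    if leftover:
        c = n_chains_full
        rids = [f"R{c:02d}_{i}" for i in range(1, leftover + 1)]
        chains.append(rids)
        for i, rid in enumerate(rids):
            stoich = {f"M{c:02d}_{i}": -1.0, f"M{c:02d}_{i + 1}": 1.0}
            reactions.append((rid, stoich))

    middles = [ch[1] for ch in chains if len(ch) == 3]
    n_orphans = int(round(spec.orphan_fraction * spec.n_reactions))
    if n_orphans > len(middles):
        raise ValueError(
            f"cannot plant {n_orphans} orphans on {len(middles)} pathway middles"
        )
    orphan_ids = set(middles[:n_orphans]) if n_orphans else set()

    # currency species live on middles only, so their removal is harmless;
    # in small models the multiplicity is capped at the number of middles
    # (below the cutoff it is simply never a pruning candidate)
    currency_ids = [f"X{j:02d}" for j in range(spec.currency_species)] if middles else []
    multiplicity = min(spec.currency_multiplicity, len(middles)) if middles else 0
    stoich_by_rid = {rid: st for rid, st in reactions}
    for j, cid in enumerate(currency_ids):
        hosts = [middles[(j + k) % len(middles)] for k in range(multiplicity)]
        for rid in set(hosts):
            stoich_by_rid[rid][cid] = 1.0

    # GPR assignment: multi-gene rules go to pathway ends first
    rid_order = [rid for ch in chains for rid in ch]
    ends = [rid for ch in chains for rid in (ch[0], ch[-1]) if len(ch) >= 2]
    n_or = int(round(spec.gpr_mix[1] * spec.n_reactions))
    n_and = int(round(spec.gpr_mix[2] * spec.n_reactions))
    multi_hosts = ends + [r for r in rid_order if r not in ends]
    or_set = set(multi_hosts[:n_or])
    and_set = set(multi_hosts[n_or : n_or + n_and])
    genes_needed = spec.n_reactions + n_or + n_and
    if genes_needed > spec.n_genes:
        raise ValueError(
            f"gpr_mix needs {genes_needed} genes but only {spec.n_genes} available"
        )
    gene_ids = [f"g{i:03d}" for i in range(spec.n_genes)]
    shuffled = list(gene_ids)
    rng.shuffle(shuffled)
    cursor = 0
    assignments: dict[str, tuple[str, ...]] = {}
    model_reactions: list[Reaction] = []
    for rid in rid_order:
        n_g = 2 if (rid in or_set or rid in and_set) else 1
        genes = tuple(sorted(shuffled[cursor : cursor + n_g]))
        cursor += n_g
        assignments[rid] = genes
        if rid in orphan_ids:
            gpr = None
        elif rid in or_set:
            gpr = parse_gpr(" or ".join(genes))
        elif rid in and_set:
            gpr = parse_gpr(" and ".join(genes))
        else:
            gpr = parse_gpr(genes[0])
        model_reactions.append(Reaction(id=rid, stoich=stoich_by_rid[rid], gpr=gpr))
    decoys = sorted(shuffled[cursor:])

    model = MetabolicModel(reactions=model_reactions)
    truth = GroundTruth(
        assignments=assignments,
        orphans=orphan_ids,
        chains=chains,
        adequate=set(middles),
        currency=currency_ids,
        decoy_genes=decoys,
    )
    return model, truth


def _pattern(rng: np.random.Generator, n: int) -> tuple[np.ndarray, ...]:
    """Three centered, empirically-orthonormal direction vectors, scaled to
    unit per-entry variance."""
    if n < 4:
        raise ValueError("need at least 4 conditions for the latent pattern")
    basis = []
    for _ in range(3):
        v = rng.standard_normal(n)
        v = v - v.mean()
        for u in basis:
            v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        basis.append(v)
    return tuple(v * np.sqrt(n) for v in basis)


def _chain_latents(
    spec_s: float,
    chain: list[str],
    rng: np.random.Generator,
    n: int,
) -> dict[str, np.ndarray]:
    """Latent condition profiles for one pathway.

    At zero signal there is no structure to plant: every reaction draws an
    independent standard-normal profile (so the planted gene is exchangeable
    with decoys, a true null). With signal, the end latents are placed at
    corr(mid, end) = s and corr(end, end) = max(2s^2 - 1, -s): the
    PSD-minimal bisector geometry for s >= 1/2, interpolating toward
    independent ends as s drops to 0. Sample correlations are exact through
    the empirically-orthonormal basis.
    """
    s = spec_s
    if s == 0:
        return {rid: rng.standard_normal(n) for rid in chain}
    z0, z1, z2 = _pattern(rng, n)
    c = max(2 * s**2 - 1.0, -s)
    b2 = max((c - 2 * s**2 + 1.0) / 2.0, 0.0)
    a2 = max(1.0 - s**2 - b2, 0.0)
    a, b = np.sqrt(a2), np.sqrt(b2)
    mid = z0
    end1 = s * z0 + a * z1 + b * z2
    end2 = s * z0 - a * z1 + b * z2
    if len(chain) == 3:
        return {chain[0]: end1, chain[1]: mid, chain[2]: end2}
    if len(chain) == 2:
        return {chain[0]: mid, chain[1]: end1}
    return {chain[0]: mid}


def _gene_vectors(
    truth: GroundTruth,
    latents: dict[str, np.ndarray],
    noise_sd: float,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows: dict[str, np.ndarray] = {}
    for rid in sorted(latents):
        for g in truth.assignments[rid]:
            rows[g] = latents[rid] + noise_sd * rng.standard_normal(n)
    for g in truth.decoy_genes:
        rows[g] = rng.standard_normal(n)
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.sort_index()


def simulate_fitness(
    model: MetabolicModel, truth: GroundTruth, spec: FixtureSpec
) -> SimulatedFitness:
    """Simulate the fitness screen: gene matrix, insertions and regions.

    Insertions inherit the linked gene's condition scores plus fresh
    N(0, noise_sd^2) noise; each gene gets one promoter (150-50 bp upstream)
    and one CDS region, with three insertions per region.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_conditions
    conditions = [f"cond{i:02d}" for i in range(n)]
    latents: dict[str, np.ndarray] = {}
    for chain in truth.chains:
        latents.update(_chain_latents(spec.signal_strength, chain, rng, n))
    gene_df = _gene_vectors(truth, latents, spec.noise_sd, n, rng)
    gene_df.columns = conditions
    truth.latents = latents
    truth.conditions = conditions

    regions: list[GenomicRegion] = []
    insertions: list[InsertionRecord] = []
    promoter_map: dict[str, list[str]] = {}
    bases = "ACGT"
    for i, gene in enumerate(gene_df.index):
        start = 1000 + 2000 * i
        prom_id = f"prom_{gene}"
        seq = "".join(rng.choice(list(bases), size=100))
        regions.append(
            GenomicRegion(
                id=prom_id,
                kind="promoter",
                start=start - 150,
                end=start - 50,
                scaffold="chr",
                strand="+",
                gene_link=gene,
                sequence=seq,
            )
        )
        regions.append(
            GenomicRegion(
                id=f"cds_{gene}",
                kind="cds",
                start=start,
                end=start + 900,
                scaffold="chr",
                strand="+",
                gene_link=gene,
            )
        )
        promoter_map[gene] = [prom_id]
        truth.promoter_of[gene] = prom_id
        gvec = gene_df.loc[gene].to_numpy()
        for reg_start, reg_end in ((start - 150, start - 50), (start, start + 900)):
            for pos in sorted(rng.integers(reg_start, reg_end, size=3)):
                noisy = gvec + spec.noise_sd * rng.standard_normal(n)
                insertions.append(
                    InsertionRecord(
                        position=int(pos),
                        scores=dict(zip(conditions, map(float, noisy))),
                        scaffold="chr",
                    )
                )
    return SimulatedFitness(
        gene_matrix=ProfileMatrix(gene_df),
        insertions=insertions,
        regions=regions,
        promoter_map=promoter_map,
    )


def simulate_expression(
    model: MetabolicModel,
    truth: GroundTruth,
    spec: FixtureSpec,
    n_samples: Sequence[int] = (11, 36),
    reuse_fitness_latents: bool = False,
) -> dict[str, ProfileMatrix]:
    """Simulate expression datasets (default two, of 11 and 36 samples).

    Each dataset carries the same planted pathway geometry as the fitness
    screen but an independent realisation. With ``reuse_fitness_latents``
    and a sample count equal to the fitness condition count, the fitness
    latents are reused verbatim (the degenerate fully-shared case).
    """
    out: dict[str, ProfileMatrix] = {}
    for d, n in enumerate(n_samples):
        rng = np.random.default_rng([spec.seed, 10 + d])
        name = f"expr{d}"
        samples = [f"{name}_s{i:02d}" for i in range(n)]
        if reuse_fitness_latents and truth.latents and n == len(truth.conditions):
            latents = truth.latents
        else:
            latents = {}
            for chain in truth.chains:
                latents.update(
                    _chain_latents(spec.signal_strength, chain, rng, n)
                )
        df = _gene_vectors(truth, latents, spec.noise_sd, n, rng)
        df.columns = samples
        out[name] = ProfileMatrix(df)
    return out


def emit_fixture(
    out_dir: str | Path,
    spec: FixtureSpec,
    with_expression: bool = True,
) -> dict[str, Path]:
    """Generate a full fixture and write it as plain-text files.

    Emits model JSON, fitness TSV, insertion TSV, region TSV, expression
    TSVs and a truth JSON; returns the paths keyed by role. All files
    round-trip through the package's readers.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_model(spec)
    sim = simulate_fitness(model, truth, spec)
    paths: dict[str, Path] = {}

    paths["model"] = out_dir / "model.json"
    write_model_json(model, paths["model"])

    paths["fitness"] = out_dir / "fitness.tsv"
    sim.gene_matrix.to_tsv(paths["fitness"])

    paths["insertions"] = out_dir / "insertions.tsv"
    conds = sim.gene_matrix.col_ids
    with open(paths["insertions"], "w") as fh:
        fh.write("position\tscaffold\t" + "\t".join(conds) + "\n")
        for ins in sim.insertions:
            vals = "\t".join(f"{ins.scores.get(c, float('nan')):.6g}" for c in conds)
            fh.write(f"{ins.position}\t{ins.scaffold}\t{vals}\n")

    paths["regions"] = out_dir / "regions.tsv"
    with open(paths["regions"], "w") as fh:
        fh.write("scaffold\tstart\tend\tid\tkind\tstrand\tgene\tsigma\tsequence\n")
        for r in sim.regions:
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t{r.id}\t{r.kind}\t{r.strand}\t"
                f"{r.gene_link or ''}\t{r.sigma or ''}\t{r.sequence or ''}\n"
            )

    if with_expression:
        expr = simulate_expression(model, truth, spec)
        for name, mat in expr.items():
            p = out_dir / f"expression_{name}.tsv"
            mat.to_tsv(p)
            paths[f"expression_{name}"] = p

    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "assignments": {k: list(v) for k, v in truth.assignments.items()},
                "orphans": sorted(truth.orphans),
                "chains": truth.chains,
                "adequate": sorted(truth.adequate),
                "currency": truth.currency,
                "decoy_genes": truth.decoy_genes,
                "promoter_of": truth.promoter_of,
            },
            fh,
            indent=1,
        )
    return paths
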