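"""Metabolic model container with boolean gene-protein-reaction (GPR) rules.

A genome-scale metabolic model is reduced here to the three ingredients the
assignment pipeline needs: reaction stoichiometry (presence/absence of each
species in each reaction), the boolean GPR rule of each reaction in
disjunctive normal form (an OR over isozyme clauses, an AND over complex
subunits within a clause), and the orphan partition — a reaction is *orphan*
iff it carries no GPR rule at all.

Models can be read from SBML (via cobra, which understands fbc GPR
annotations) or from a small documented JSON dialect::

    {"reactions": [{"id": "R1",
                    "metabolites": {"A_c": -1, "B_c": 1},
                    "gpr": "g1 or (g2 and g3)",
                    "reversible": false}, ...]}

Species in different compartments are distinct species throughout; signs and
magnitudes of stoichiometric coefficients are ignored for neighborhood
purposes (only non-zero presence matters).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GprParseError",
    "GprExpression",
    "Species",
    "Reaction",
    "MetabolicModel",
    "parse_gpr",
    "evaluate_activity",
    "parse_model",
    "metabolite_frequencies",
    "write_model_json",
]


class GprParseError(ValueError):
    """Raised when a GPR boolean expression cannot be parsed."""


@dataclass(frozen=True)
class GprExpression:
    """A GPR rule in disjunctive normal form.

    ``clauses`` is a tuple of frozensets of gene ids: the rule is satisfied if
    for at least one clause every gene in that clause is active (OR over
    clauses, AND within a clause). Clauses are non-empty and de-duplicated.
    """

    clauses: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise GprParseError("GPR expression must have at least one clause")
        if any(len(c) == 0 for c in self.clauses):
            raise GprParseError("empty AND-clause in GPR expression")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clauses:
            out |= c
        return frozenset(out)

    def to_string(self) -> str:
        """Serialize back to a canonical ``(a and b) or c`` string."""
        parts = []
        for clause in sorted(self.clauses, key=lambda c: sorted(c)):
            genes = sorted(clause)
            if len(genes) == 1:
                parts.append(genes[0])
            else:
                parts.append("(" + " and ".join(genes) + ")")
        return " or ".join(parts)


@dataclass
class Species:
    id: str
    compartment: str = ""
    frequency: int = 0


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    gpr: GprExpression | None = None
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def is_orphan(self) -> bool:
        return self.gpr is None

    @property
    def species_ids(self) -> frozenset[str]:
        return frozenset(s for s, c in self.stoich.items() if c != 0)


@dataclass
class MetabolicModel:
    reactions: list[Reaction]
    species: list[Species] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError("model must contain at least one reaction")
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
        known = {s.id for s in self.species}
        referenced: set[str] = set()
        for r in self.reactions:
            referenced |= set(r.stoich)
        for sid in sorted(referenced - known):
            self.species.append(Species(id=sid, compartment=_compartment_of(sid)))
        freqs = metabolite_frequencies(self)
        for s in self.species:
            s.frequency = freqs.get(s.id, 0)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes
        return frozenset(out)

    @property
    def orphans(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_orphan]

    @property
    def non_orphans(self) -> list[Reaction]:
        return [r for r in self.reactions if not r.is_orphan]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


def _compartment_of(species_id: str) -> str:
    # iJO1366-style ids carry the compartment as a suffix, e.g. "h2o_c".
    m = re.search(r"_([a-z])$", species_id)
    return m.group(1) if m else ""


# ---------------------------------------------------------------------------
# GPR boolean parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|&&|\|\||[^\s()&|]+")


def _tokenize(text: str) -> list[str]:
    tokens = []
    for tok in _TOKEN_RE.findall(text):
        low = tok.lower()
        if low == "and" or tok == "&&":
            tokens.append("AND")
        elif low == "or" or tok == "||":
            tokens.append("OR")
        else:
            tokens.append(tok)
    return tokens


def parse_gpr(text: str) -> GprExpression:
    """Parse a boolean gene rule into :class:`GprExpression` (DNF).

    Accepts ``and``/``or`` in any case, ``&&``/``||``, and parentheses.
    Nested expressions are flattened by distributing AND over OR, so the
    result is a flat OR-of-ANDs. Duplicate clauses collapse.

    >>> parse_gpr("g1 or (g2 and g3)").clauses
    (frozenset({'g1'}), frozenset({'g2', 'g3'}))
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GprParseError("empty GPR expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def expect_operand() -> list[frozenset[str]]:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of expression in {text!r}")
        if tok == "(":
            pos += 1
            clauses = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in {text!r}")
            pos += 1
            return clauses
        if tok in (")", "AND", "OR"):
            raise GprParseError(f"missing operand near {tok!r} in {text!r}")
        pos += 1
        return [frozenset([tok.strip()])]

    def parse_and() -> list[frozenset[str]]:
        nonlocal pos
        clauses = expect_operand()
        while peek() == "AND":
            pos += 1
            rhs = expect_operand()
            # distribute AND over OR: cross product of clause sets
            clauses = [a | b for a in clauses for b in rhs]
        return clauses

    def parse_or() -> list[frozenset[str]]:
        nonlocal pos
        clauses = parse_and()
        while peek() == "OR":
            pos += 1
            clauses.extend(parse_and())
        return clauses

    clauses = parse_or()
    if peek() is not None:
        raise GprParseError(f"trailing tokens near {peek()!r} in {text!r}")
    uniq: list[frozenset[str]] = []
    for c in clauses:
        if c not in uniq:
            uniq.append(c)
    return GprExpression(clauses=tuple(uniq))


def evaluate_activity(gpr: GprExpression, status: Mapping[str, bool]) -> bool:
    """Evaluate a DNF rule under a gene activity assignment.

    Every gene appearing in the rule must be present in ``status``.
    """
    for gene in sorted(gpr.genes):
        if gene not in status:
            raise KeyError(f"gene {gene!r} missing from activity status map")
    return any(all(status[g] for g in clause) for clause in gpr.clauses)


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------


def parse_model(path: str | Path) -> MetabolicModel:
    """Read a metabolic model from SBML or the package's JSON dialect.

    Dialect is chosen by extension: ``.json`` uses the JSON reader, anything
    else is handed to cobra's SBML reader. GPR strings are parsed into DNF;
    a malformed GPR raises :class:`GprParseError` naming the reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return _parse_model_json(path)
    return _parse_model_sbml(path)


def _build_reaction(rid: str, stoich: Mapping[str, float], gpr_text: str | None,
                    reversible: bool) -> Reaction:
    gpr = None
    if gpr_text is not None and gpr_text.strip():
        try:
            gpr = parse_gpr(gpr_text)
        except GprParseError as exc:
            raise GprParseError(f"reaction {rid!r}: {exc}") from exc
    return Reaction(id=rid, stoich=dict(stoich), gpr=gpr, reversible=reversible)


def _parse_model_json(path: Path) -> MetabolicModel:
    with open(path) as fh:
        data = json.load(fh)
    raw = data.get("reactions", [])
    if not raw:
        raise ValueError(f"{path}: model has no reactions")
    reactions = [
        _build_reaction(
            str(entry["id"]).strip(),
            {str(k): float(v) for k, v in entry["metabolites"].items()},
            entry.get("gpr"),
            bool(entry.get("reversible", False)),
        )
        for entry in raw
    ]
    return MetabolicModel(reactions=reactions)


def _parse_model_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    cmodel = cobra.io.read_sbml_model(str(path))
    if len(cmodel.reactions) == 0:
        raise ValueError(f"{path}: model has no reactions")
    reactions = []
    for rxn in cmodel.reactions:
        stoich = {met.id: float(coef) for met, coef in rxn.metabolites.items()}
        reactions.append(
            _build_reaction(rxn.id, stoich, rxn.gene_reaction_rule or None,
                            rxn.reversibility)
        )
    species = [Species(id=m.id, compartment=m.compartment or "")
               for m in cmodel.metabolites]
    return MetabolicModel(reactions=reactions, species=species)


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Write the JSON dialect (round-trips through :func:`parse_model`)."""
    payload = {
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoich,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
                "reversible": r.reversible,
            }
            for r in model.reactions
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def metabolite_frequencies(model: MetabolicModel) -> dict[str, int]:
    """Count, per species, the reactions whose stoichiometry references it
    with a non-zero coefficient."""
    freq: dict[str, int] = {s.id: 0 for s in model.species}
    for r in model.reactions:
        for sid in r.species_ids:
            freq[sid] = freq.get(sid, 0) + 1
    return freq
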