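"""Ligand inference from the operon's reaction set.

For each enzyme encoded by a candidate operon, the reaction knowledgebase
supplies metabolic substrates and products.  The proposed effector is the
pathway's primary substrate: a compound consumed by at least one operon
reaction but produced by none, i.e. a source node of the directed
substrate->product compound graph after ubiquitous cofactors are removed.
When several sources exist (branched pathway entry) all are reported,
ranked; when none exists (fully cyclic set) every consumed compound is
returned and the result is flagged ambiguous.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .mining import DivergentPair, Operon

logger = logging.getLogger(__name__)

#: compounds too promiscuous to be informative effectors
DEFAULT_COFACTOR_BLACKLIST = frozenset(
    {
        "h2o", "water", "h+", "proton", "atp", "adp", "amp",
        "nad+", "nadh", "nadp+", "nadph", "coa", "coenzyme a",
        "phosphate", "pi", "diphosphate", "ppi", "co2", "o2",
        "nh3", "ammonia",
    }
)


def normalize_compound(name: str) -> str:
    return name.strip().lower()


@dataclass(frozen=True)
class ReactionEntry:
    """One EC-indexed reaction with its substrate and product compound sets."""

    ec: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"EC {self.ec}: substrates and products must be non-empty")
        if self.substrates & self.products:
            raise ValueError(f"EC {self.ec}: substrates and products overlap")


@dataclass
class ReactionKB:
    """EC -> reactions mapping with a cofactor blacklist.

    Lookup of an unknown EC yields an explicit empty list, never a failure."""

    entries: dict[str, list[ReactionEntry]] = field(default_factory=dict)
    cofactor_blacklist: frozenset[str] = DEFAULT_COFACTOR_BLACKLIST

    def lookup(self, ec: str) -> list[ReactionEntry]:
        return self.entries.get(ec, [])

    @property
    def n_reactions(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass(frozen=True)
class LigandCandidate:
    compound: str
    consumed_by: int
    produced_by: int
    rank: int


@dataclass
class InducibleSystemCandidate:
    """A divergent pair with its proposed effector(s) and screen status."""

    pair: DivergentPair
    ligands: list[LigandCandidate] = field(default_factory=list)
    status: str = "proposed"
    reason: str = ""


def load_reaction_kb(
    path: str | Path,
    cofactor_blacklist: Optional[Iterable[str]] = None,
) -> ReactionKB:
    """Load a TSV knowledgebase with columns ec, substrates, products,
    reversible (substrates/products are ';'-delimited compound names).

    Compound identifiers are case-normalised.  Duplicate (ec, reaction)
    rows are deduplicated with a warning; a row with an empty substrate or
    product field is a parse error naming the line.
    """
    path = Path(path)
    blacklist = (
        frozenset(normalize_compound(c) for c in cofactor_blacklist)
        if cofactor_blacklist is not None
        else DEFAULT_COFACTOR_BLACKLIST
    )
    kb = ReactionKB(cofactor_blacklist=blacklist)
    seen: set[ReactionEntry] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"ec", "substrates", "products", "reversible"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            ec = (row["ec"] or "").strip()
            subs = frozenset(
                normalize_compound(c) for c in (row["substrates"] or "").split(";") if c.strip()
            )
            prods = frozenset(
                normalize_compound(c) for c in (row["products"] or "").split(";") if c.strip()
            )
            if not ec or not subs or not prods:
                raise ValueError(f"{path}:{lineno}: missing ec, substrates or products")
            try:
                entry = ReactionEntry(
                    ec=ec,
                    substrates=subs,
                    products=prods,
                    reversible=str(row["reversible"]).strip().lower() in ("1", "true", "yes"),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if entry in seen:
                logger.warning("%s:%d: duplicate reaction for EC %s skipped", path, lineno, ec)
                continue
            seen.add(entry)
            kb.entries.setdefault(ec, []).append(entry)
    return kb


def write_reaction_kb(kb: ReactionKB, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["ec", "substrates", "products", "reversible"])
        for ec in sorted(kb.entries):
            for entry in kb.entries[ec]:
                writer.writerow(
                    [
                        ec,
                        ";".join(sorted(entry.substrates)),
                        ";".join(sorted(entry.products)),
                        "true" if entry.reversible else "false",
                    ]
                )


def operon_reaction_set(operon: Operon, kb: ReactionKB) -> list[ReactionEntry]:
    """Union of KB reactions over all member-gene EC numbers (set
    semantics: a reaction shared by two genes counts once)."""
    reactions: list[ReactionEntry] = []
    seen: set[ReactionEntry] = set()
    for gene in operon.genes:
        if not gene.ec_numbers:
            logger.debug("%s: no EC numbers, contributes no reactions", gene.gene_id)
            continue
        for ec in gene.ec_numbers:
            hits = kb.lookup(ec)
            if not hits:
                logger.debug("%s: EC %s absent from knowledgebase", gene.gene_id, ec)
            for entry in hits:
                if entry not in seen:
                    seen.add(entry)
                    reactions.append(entry)
    return reactions


def _directed_edges(reactions: Iterable[ReactionEntry], blacklist: frozenset[str]):
    """Yield (substrate_set, product_set) pairs after cofactor removal,
    duplicating reversible reactions in both directions."""
    for rxn in reactions:
        subs = rxn.substrates - blacklist
        prods = rxn.products - blacklist
        if subs and prods:
            yield subs, prods
            if rxn.reversible:
                yield prods, subs


def infer_primary_substrate(
    reactions: list[ReactionEntry], kb: ReactionKB
) -> list[LigandCandidate]:
    """Rank candidate effectors of the operon-encoded pathway.

    Candidates are compounds consumed by at least one reaction; they are
    ranked by (produced_by ascending, consumed_by descending, compound id).
    Rank-1 candidates with ``produced_by == 0`` are graph sources, i.e. the
    pathway's entry compounds.  If no source exists (cyclic set) the
    top-ranked candidate has ``produced_by > 0``, which callers treat as an
    ambiguity flag.
    """
    consumed: Counter[str] = Counter()
    produced: Counter[str] = Counter()
    for subs, prods in _directed_edges(reactions, kb.cofactor_blacklist):
        consumed.update(subs)
        produced.update(prods)
    ranked = sorted(
        consumed,
        key=lambda c: (produced.get(c, 0), -consumed[c], c),
    )
    return [
        LigandCandidate(
            compound=c,
            consumed_by=consumed[c],
            produced_by=produced.get(c, 0),
            rank=i + 1,
        )
        for i, c in enumerate(ranked)
    ]


def compound_graph(reactions: Iterable[ReactionEntry], blacklist: frozenset[str]) -> nx.DiGraph:
    """Directed substrate->product graph with cofactors removed."""
    graph = nx.DiGraph()
    for subs, prods in _directed_edges(reactions, blacklist):
        for s in subs:
            for p in prods:
                graph.add_edge(s, p)
    return graph


def assemble_candidates(
    pairs: list[DivergentPair],
    kb: ReactionKB,
    min_catalytic: int = 2,
    require_connected: bool = True,
) -> list[InducibleSystemCandidate]:
    """Apply the operon filter and ligand inference to every divergent pair.

    Pairs whose operon encodes fewer than ``min_catalytic`` catalytic genes
    are marked ``filtered_out``.  ``require_connected`` additionally demands
    that the operon's reactions form a single weakly connected compound
    graph — a proxy for "one distinct metabolic pathway".
    """
    results: list[InducibleSystemCandidate] = []
    for pair in pairs:
        if pair.operon.n_catalytic < min_catalytic:
            results.append(
                InducibleSystemCandidate(pair=pair, status="filtered_out", reason="min_catalytic")
            )
            continue
        reactions = operon_reaction_set(pair.operon, kb)
        if not reactions:
            results.append(
                InducibleSystemCandidate(pair=pair, status="no_ligand", reason="no_kb_reactions")
            )
            continue
        if require_connected:
            graph = compound_graph(reactions, kb.cofactor_blacklist)
            if graph.number_of_nodes() and not nx.is_weakly_connected(graph):
                results.append(
                    InducibleSystemCandidate(
                        pair=pair, status="filtered_out", reason="disconnected_pathway"
                    )
                )
                continue
        ligands = infer_primary_substrate(reactions, kb)
        if not ligands:
            results.append(
                InducibleSystemCandidate(pair=pair, status="no_ligand", reason="cofactors_only")
            )
            continue
        reason = "ambiguous_cycle" if ligands[0].produced_by > 0 else ""
        results.append(
            InducibleSystemCandidate(pair=pair, ligands=ligands, status="proposed", reason=reason)
        )
    results.sort(key=lambda c: (c.pair.promoter_interval[0], c.pair.promoter_interval[1]))
    return results
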