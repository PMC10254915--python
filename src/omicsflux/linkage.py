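"""Metabolite-gene linkage: connect perturbed metabolites to the network.

For each malignancy-associated metabolite, list the reactions that produce
and consume it, the genes behind those reactions, each gene's differential
expression call and each reaction's differential-flux status — the
machine-readable analogue of annotating a pathway map in red and blue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .expression import DETable, NS
from .flux import DiffFluxTable
from .metabolomics import NOT_PERTURBED, PerturbedMetaboliteSet
from .model_io import MetabolicModel


@dataclass
class MetaboliteNeighborhood:
    """Direct producers/consumers of a metabolite with omics annotations.

    Reversible reactions appear in both lists (their net direction depends
    on conditions) and are flagged in ``reversible``.
    """

    metabolite_id: str
    producing: list[str]
    consuming: list[str]
    reversible: set[str]
    genes: dict[str, list[str]]          # reaction -> sorted gene ids
    gene_calls: dict[str, str] = field(default_factory=dict)
    flux_significant: dict[str, bool] = field(default_factory=dict)

    @property
    def reactions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.producing + self.consuming:
            seen.setdefault(r, None)
        return list(seen)


def metabolite_neighborhood(model: MetabolicModel, metabolite: str,
                            de: DETable | None = None,
                            diff: DiffFluxTable | None = None
                            ) -> MetaboliteNeighborhood:
    """1-step neighborhood of a metabolite, annotated with DE and flux calls.

    Producing reactions have a positive stoichiometric coefficient for the
    metabolite, consuming ones negative; reversible reactions are listed
    under both roles.
    """
    if metabolite not in set(model.metabolite_ids):
        raise KeyError(f"unknown metabolite {metabolite!r}")
    producing, consuming, rev = [], [], set()
    genes: dict[str, list[str]] = {}
    for rxn in model.reactions:
        coef = rxn.stoich.get(metabolite, 0.0)
        if coef == 0.0:
            continue
        if coef > 0 or rxn.reversible:
            producing.append(rxn.id)
        if coef < 0 or rxn.reversible:
            consuming.append(rxn.id)
        if rxn.reversible:
            rev.add(rxn.id)
        genes[rxn.id] = sorted(rxn.gpr.genes()) if rxn.gpr is not None else []

    gene_calls: dict[str, str] = {}
    if de is not None:
        for glist in genes.values():
            for g in glist:
                gene_calls[g] = de.call_of(g)
    flux_sig: dict[str, bool] = {}
    if diff is not None:
        sig = diff.significant_reactions
        flux_sig = {r: r in sig for r in genes}
    return MetaboliteNeighborhood(metabolite, producing, consuming, rev,
                                  genes, gene_calls, flux_sig)


def trace_precursors(model: MetabolicModel, metabolite: str,
                     depth: int = 1) -> set[str]:
    """Metabolites reachable upstream within ``depth`` reaction steps.

    A bounded breadth-first walk over producing reactions (substrates of a
    producer are one step upstream). Depth is capped at 3; this is a
    navigation aid, not an inference of causal precursors.
    """
    if not 1 <= depth <= 3:
        raise ValueError("depth must be between 1 and 3")
    frontier = {metabolite}
    seen: set[str] = set()
    for _ in range(depth):
        nxt: set[str] = set()
        for met in frontier:
            hood = metabolite_neighborhood(model, met)
            for rid in hood.producing:
                rxn = model.reaction(rid)
                nxt |= {m for m, c in rxn.stoich.items() if c < 0}
        nxt -= seen | frontier | {metabolite}
        seen |= nxt
        frontier = nxt
    return seen


def integrate_report(perturbed: PerturbedMetaboliteSet, model: MetabolicModel,
                     de: DETable, diff: DiffFluxTable) -> pd.DataFrame:
    """Integrated metabolite-reaction-gene table for the perturbed set.

    One row per (perturbed metabolite, adjacent reaction, gene) triple, with
    the metabolite's direction, the reaction's role (producing/consuming)
    and flux significance, and the gene's DE call. Metabolites absent from
    the model (e.g. compounds outside the reconstruction) contribute no rows.
    """
    mets_in_model = set(model.metabolite_ids)
    rows = []
    for met, direction in sorted(perturbed.flagged.items()):
        if direction == NOT_PERTURBED or met not in mets_in_model:
            continue
        hood = metabolite_neighborhood(model, met, de=de, diff=diff)
        for rid in hood.reactions:
            roles = []
            if rid in hood.producing:
                roles.append("producing")
            if rid in hood.consuming:
                roles.append("consuming")
            role = "+".join(roles)
            gene_list = hood.genes[rid] or [""]
            for gene in gene_list:
                rows.append({
                    "metabolite": met,
                    "direction": direction,
                    "reaction": rid,
                    "role": role,
                    "reversible": rid in hood.reversible,
                    "flux_significant": hood.flux_significant.get(rid, False),
                    "gene": gene,
                    "gene_call": hood.gene_calls.get(gene, NS) if gene else "",
                })
    columns = ["metabolite", "direction", "reaction", "role", "reversible",
               "flux_significant", "gene", "gene_call"]
    return pd.DataFrame(rows, columns=columns)
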