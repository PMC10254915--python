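"""Synthetic study generators with planted, recorded ground truth.

Three generators emulate the data modalities of a three-cell-line breast
study (one non-malignant control line, two malignant lines, three biological
replicates each) at desk scale:

* :func:`make_toy_network` — a small feasible metabolic network: substrate
  uptake, a linear enzymatic pathway, optionally a three-reaction internal
  cycle with a side product required by biomass (so throttling the cycle
  gene throttles growth), and a biomass drain.
* :func:`simulate_counts` — negative-binomial RNA-seq counts with a planted
  fraction of fold-change genes (random sign) in the malignant groups.
* :func:`simulate_metabolomics` — log-normal relative-area tables with
  planted direction-consistent metabolite shifts in the malignant groups.

Every generator is fully deterministic under a fixed seed and records what
it planted in a :class:`SyntheticTruth`, so downstream recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolomics import (HIGHER_IN_MALIGNANT, LOWER_IN_MALIGNANT,
                           MetaboliteTable)
from .model_io import (MetabolicModel, Reaction, parse_gpr, validate_model)

# genes of the cycle motif; the middle one is the canonical throttle target
CYCLE_GENES = ("g_cyc_1a", "g_cyc_1b", "g_cyc_2", "g_cyc_3")
CYCLE_THROTTLE_GENE = "g_cyc_2"
CYCLE_THROTTLE_REACTION = "RC2"
CYCLE_SIDE_PRODUCT = "P"


@dataclass
class SyntheticTruth:
    """Record of everything a generator planted."""

    de_genes: dict[str, float] = field(default_factory=dict)
    perturbed_metabolites: dict[str, str] = field(default_factory=dict)
    limited_reaction: str | None = None
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "de_genes": self.de_genes,
                "perturbed_metabolites": self.perturbed_metabolites,
                "limited_reaction": self.limited_reaction,
                "seed": self.seed,
            }, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Toy metabolic networks
# ---------------------------------------------------------------------------

def make_toy_network(n_linear: int, with_cycle_motif: bool = False,
                     seed: int = 0) -> MetabolicModel:
    """Build a small feasible model with known choke points.

    The backbone is ``uptake -> A1 -> A2 -> ... -> A_{n+1} -> biomass`` with
    one gene per enzymatic step (``g_lin_i``). With ``with_cycle_motif`` a
    three-reaction carrier cycle (C1 -> C2 -> C3 -> C1) taps A2 and emits a
    side product P that biomass also requires, mimicking a methyl-carrier
    cycle feeding growth; capping the cycle gene's reaction (RC2) then caps
    the biomass optimum. The uptake capacity is drawn in [8, 12] so
    different seeds give different (but structurally identical) instances.
    """
    if n_linear < 2:
        raise ValueError("n_linear must be >= 2")
    rng = np.random.default_rng(seed)
    # substrate availability limits growth in the unperturbed state; an
    # expression cap only binds when a gene is strongly down-regulated
    uptake_cap = float(rng.uniform(8.0, 12.0))

    mets = [f"A{i}" for i in range(1, n_linear + 2)]
    reactions = [
        Reaction("EX_A1", {"A1": 1.0}, 0.0, uptake_cap, None, exchange=True)
    ]
    for i in range(1, n_linear + 1):
        reactions.append(Reaction(
            f"R{i}", {f"A{i}": -1.0, f"A{i + 1}": 1.0}, 0.0, 1000.0,
            parse_gpr(f"g_lin_{i}"), exchange=False))

    biomass_stoich = {mets[-1]: -1.0}
    if with_cycle_motif:
        mets += ["C1", "C2", "C3", CYCLE_SIDE_PRODUCT]
        # carrier cycle tapping the entry metabolite; RC2 emits the side
        # product biomass needs, so each enzymatic step carries the same flux
        reactions.append(Reaction(
            "RC1", {"A1": -1.0, "C1": -1.0, "C2": 1.0}, 0.0, 1000.0,
            parse_gpr("g_cyc_1a and g_cyc_1b")))
        reactions.append(Reaction(
            CYCLE_THROTTLE_REACTION,
            {"C2": -1.0, "C3": 1.0, CYCLE_SIDE_PRODUCT: 1.0}, 0.0, 1000.0,
            parse_gpr(CYCLE_THROTTLE_GENE)))
        reactions.append(Reaction(
            "RC3", {"C3": -1.0, "C1": 1.0}, 0.0, 1000.0,
            parse_gpr("g_cyc_3")))
        biomass_stoich[CYCLE_SIDE_PRODUCT] = -1.0
    reactions.append(Reaction("biomass", biomass_stoich, 0.0, 1000.0, None,
                              exchange=True))

    model = MetabolicModel(mets, reactions, "biomass")
    violations = validate_model(model)
    if violations:  # pragma: no cover - construction is fixed
        raise RuntimeError(f"generated model invalid: {violations}")
    return model


def random_feasible_model(seed: int, max_reactions: int = 6) -> MetabolicModel:
    """Random small stoichiometric model, guaranteed feasible (0 in bounds).

    Reaction count is drawn in [3, max_reactions], stoichiometric
    coefficients in {-2, -1, 1, 2} over random metabolite subsets, and every
    reaction's bounds bracket zero, so v = 0 is always feasible. Used to
    exercise the LP machinery against exhaustive oracles.
    """
    rng = np.random.default_rng(seed)
    n_rxn = int(rng.integers(3, max_reactions + 1))
    n_met = int(rng.integers(2, 5))
    mets = [f"M{i}" for i in range(n_met)]
    reactions = []
    for j in range(n_rxn):
        size = int(rng.integers(1, n_met + 1))
        chosen = rng.choice(n_met, size=size, replace=False)
        stoich = {mets[i]: float(rng.choice([-2, -1, 1, 2])) for i in chosen}
        lb = float(-rng.uniform(0, 10)) if rng.random() < 0.5 else 0.0
        ub = float(rng.uniform(0.5, 10))
        reactions.append(Reaction(f"R{j}", stoich, lb, ub))
    objective = f"R{int(rng.integers(0, n_rxn))}"
    model = MetabolicModel(mets, reactions, objective)
    assert not validate_model(model)
    return model


# ---------------------------------------------------------------------------
# RNA-seq count simulation
# ---------------------------------------------------------------------------

def _sample_names(groups: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    names, mapping = [], {}
    for g, n in groups.items():
        for i in range(1, n + 1):
            name = f"{g}_{i}"
            names.append(name)
            mapping[name] = g
    return names, mapping


def _resolve_control(groups: dict[str, int], control_group: str | None) -> str:
    if control_group is None:
        control_group = "control" if "control" in groups else next(iter(groups))
    if control_group not in groups:
        raise ValueError(f"unknown control group {control_group!r}")
    return control_group


def simulate_counts(n_genes: int, groups: dict[str, int],
                    de_fraction: float, effect_log2fc: float,
                    dispersion: float, mean_depth: float, seed: int,
                    gene_ids: list[str] | None = None,
                    forced_de: dict[str, float] | None = None,
                    control_group: str | None = None,
                    propensity_overrides: dict[str, float] | None = None,
                    length_overrides: dict[str, int] | None = None,
                    ) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Negative-binomial count matrix with planted fold-change genes.

    A fraction ``de_fraction`` of genes carries ``effect_log2fc`` (random
    sign) in every non-control ("malignant") group. ``forced_de`` plants
    specific signed log2 fold changes on named genes (used to throttle a
    metabolic gene); these are recorded in the truth alongside the random
    ones. Counts are NB with variance mu + dispersion * mu^2 (Poisson when
    ``dispersion == 0``). ``propensity_overrides`` pins named genes'
    relative expression weight (the random draw has median 1) and
    ``length_overrides`` their transcript length, for studies that need
    genes on a common expression scale.

    Returns (counts genes x samples, gene lengths in bp, truth).
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    for g, n in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
    control_group = _resolve_control(groups, control_group)
    rng = np.random.default_rng(seed)

    if gene_ids is None:
        gene_ids = [f"gene{i:04d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes),
                        index=gene_ids, name="length_bp")
    for g, length in (length_overrides or {}).items():
        lengths[g] = int(length)

    # per-gene expression propensities (log-normal) -> expected base counts
    propensity = pd.Series(rng.lognormal(mean=0.0, sigma=1.5, size=n_genes),
                           index=gene_ids)
    for g, w in (propensity_overrides or {}).items():
        propensity[g] = float(w)
    propensity = propensity.to_numpy()
    base_mu = mean_depth * propensity / propensity.sum()

    forced_de = dict(forced_de or {})
    unknown = set(forced_de) - set(gene_ids)
    if unknown:
        raise ValueError(f"forced_de genes not in gene universe: {sorted(unknown)}")
    truth = SyntheticTruth(seed=seed)
    n_de = int(round(de_fraction * n_genes))
    if effect_log2fc != 0.0 and n_de > 0:
        candidates = [g for g in gene_ids if g not in forced_de]
        chosen = rng.choice(len(candidates), size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for idx, s in zip(chosen, signs):
            truth.de_genes[candidates[idx]] = float(s * effect_log2fc)
    truth.de_genes.update(forced_de)

    names, mapping = _sample_names(groups)
    lfc = pd.Series(0.0, index=gene_ids)
    for g, v in truth.de_genes.items():
        lfc[g] = v
    mal_factor = np.power(2.0, lfc.to_numpy())

    cols = {}
    for name in names:
        mu = base_mu * (mal_factor if mapping[name] != control_group else 1.0)
        if dispersion > 0:
            r = 1.0 / dispersion
            cols[name] = rng.negative_binomial(r, r / (r + mu))
        else:
            cols[name] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=gene_ids)
    return counts, lengths, truth


# ---------------------------------------------------------------------------
# Metabolomics simulation
# ---------------------------------------------------------------------------

def simulate_metabolomics(metabolite_ids: list[str], groups: dict[str, int],
                          perturbed: dict[str, str], shift_sd: float,
                          seed: int, control_group: str | None = None,
                          replicate_sd: float = 0.15,
                          ) -> tuple[MetaboliteTable, SyntheticTruth]:
    """Log-normal relative-area table with planted group shifts.

    Baseline log10 areas are drawn per metabolite (N(5, 0.5), i.e. areas
    around 1e5 units). Replicate noise has SD ``replicate_sd`` on the log10
    scale; each perturbed metabolite is shifted by ``shift_sd`` replicate
    SDs, with the same sign in every malignant group, in the direction the
    ``perturbed`` map records.
    """
    if shift_sd <= 0:
        raise ValueError("shift_sd must be > 0")
    unknown = set(perturbed) - set(metabolite_ids)
    if unknown:
        raise ValueError(f"perturbed ids not in metabolite list: {sorted(unknown)}")
    for d in perturbed.values():
        if d not in (HIGHER_IN_MALIGNANT, LOWER_IN_MALIGNANT):
            raise ValueError(f"unknown perturbation direction {d!r}")
    control_group = _resolve_control(groups, control_group)
    rng = np.random.default_rng(seed)

    baseline = rng.normal(5.0, 0.5, size=len(metabolite_ids))
    shift = np.zeros(len(metabolite_ids))
    for i, m in enumerate(metabolite_ids):
        if m in perturbed:
            sign = 1.0 if perturbed[m] == HIGHER_IN_MALIGNANT else -1.0
            shift[i] = sign * shift_sd * replicate_sd

    names, mapping = _sample_names(groups)
    cols = {}
    for name in names:
        mu = baseline + (shift if mapping[name] != control_group else 0.0)
        cols[name] = np.power(10.0, rng.normal(mu, replicate_sd))
    values = pd.DataFrame(cols, index=metabolite_ids)
    malignant = {g for g in groups if g != control_group}
    table = MetaboliteTable(values, mapping, malignant)
    table.validate()
    truth = SyntheticTruth(perturbed_metabolites=dict(perturbed), seed=seed)
    return table, truth


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete synthetic three-cell-line study with one shared truth."""

    model: MetabolicModel
    counts: pd.DataFrame
    gene_lengths: pd.Series
    metabolites: MetaboliteTable
    sample_groups: dict[str, str]
    control_group: str
    malignant_groups: set[str]
    truth: SyntheticTruth


def simulate_study(seed: int, n_background_genes: int = 60,
                   groups: dict[str, int] | None = None,
                   throttle: bool = True,
                   throttle_log2fc: float = -3.0,
                   de_fraction: float = 0.1,
                   effect_log2fc: float = 2.0,
                   dispersion: float = 0.01,
                   mean_depth: float = 1e6,
                   metabolite_shift_sd: float = 5.0,
                   n_decoy_metabolites: int = 24) -> SyntheticStudy:
    """Generate a coherent model + counts + metabolomics study.

    The toy network carries the cycle motif; when ``throttle`` is on, the
    cycle gene is planted strongly down in both malignant groups (so the
    cycle reaction's expression bound, hence its flux and the biomass
    optimum, drops) and the cycle's side product is planted as depleted in
    the metabolite table. Decoy metabolites pad the table to the size of a
    typical targeted-metabolomics panel (33 by default).
    """
    if groups is None:
        groups = {"control": 3, "lineA": 3, "lineB": 3}
    control = _resolve_control(groups, None)
    model = make_toy_network(n_linear=4, with_cycle_motif=True, seed=seed)
    model_genes = sorted(model.genes())
    gene_ids = model_genes + [f"bg{i:04d}" for i in range(1, n_background_genes + 1)]

    forced = {CYCLE_THROTTLE_GENE: throttle_log2fc} if throttle else None
    # metabolic genes sit on a common expression scale (housekeeping-level,
    # equal transcript length) so their flux caps are comparable and the
    # planted throttle is the binding constraint
    counts, lengths, truth = simulate_counts(
        n_genes=len(gene_ids), groups=groups, de_fraction=de_fraction,
        effect_log2fc=effect_log2fc, dispersion=dispersion,
        mean_depth=mean_depth, seed=seed, gene_ids=gene_ids,
        forced_de=forced, control_group=control,
        propensity_overrides={g: 2.0 for g in model_genes},
        length_overrides={g: 1000 for g in model_genes})

    met_ids = list(model.metabolite_ids) + \
        [f"decoy{i:02d}" for i in range(1, n_decoy_metabolites + 1)]
    perturbed = {CYCLE_SIDE_PRODUCT: LOWER_IN_MALIGNANT} if throttle else {}
    table, met_truth = simulate_metabolomics(
        met_ids, groups, perturbed, shift_sd=metabolite_shift_sd,
        seed=seed + 1, control_group=control)

    truth.perturbed_metabolites = met_truth.perturbed_metabolites
    truth.limited_reaction = CYCLE_THROTTLE_REACTION if throttle else None
    _, mapping = _sample_names(groups)
    return SyntheticStudy(
        model=model, counts=counts, gene_lengths=lengths, metabolites=table,
        sample_groups=mapping, control_group=control,
        malignant_groups={g for g in groups if g != control}, truth=truth)
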