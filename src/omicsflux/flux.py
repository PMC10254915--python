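"""Expression-constrained flux balance analysis and differential-flux calls.

The procedure: each enzyme-catalyzed reaction's maximal rate is capped in
proportion to the expression of its associated gene(s) (an E-flux-style
constraint); a biomass-maximizing FBA is solved per biological replicate;
reactions whose rates differ between cell lines (t-test, BH FDR <= 0.05,
mean difference > 0.001 mmol h^-1 gDW^-1) are called differentially used;
and a flux-controlling gene is a differentially expressed gene associated
with a differentially used reaction.

Alternate optima are resolved deterministically: after maximizing biomass,
the total flux (L1 norm) is minimized at the fixed optimum, and any residual
degeneracy is removed by lexicographic minimization over reactions in
sorted-id order. Replicate-wise statistics would be meaningless if the
solver returned arbitrary members of the optimal face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .expression import DETable, ExpressionMatrix, NS, bh_adjust
from .model_io import FluxDistribution, GPRExpression, MetabolicModel

#: numerical tolerances: steady state, bound satisfaction, LP slack bands
STEADY_STATE_TOL = 1e-6
BOUND_TOL = 1e-9
_SLACK = 1e-10

ZERO_FLUX = 1e-9  # below this a flux is "zero" for testability filtering


class FBAError(RuntimeError):
    pass


class InfeasibleModelError(FBAError):
    """LP infeasible under the supplied bounds."""


class UnboundedModelError(FBAError):
    """The biomass objective is unbounded (missing caps)."""


# ---------------------------------------------------------------------------
# GPR aggregation and expression-derived bounds
# ---------------------------------------------------------------------------

def aggregate_gpr_expression(gpr: GPRExpression,
                             expression: dict[str, float]) -> float:
    """Collapse a GPR tree over per-gene RPKM values to one scalar.

    AND -> minimum of children (a complex is limited by its scarcest
    subunit); OR -> sum of children (isozymes act in parallel). A gene with
    no expression value counts as 0 under AND (absent evidence must not
    unlock a complex) and is ignored under OR (an OR with no measured gene
    aggregates to 0).
    """
    if gpr.op == "gene":
        val = expression.get(gpr.gene)
        return float(val) if val is not None else 0.0
    child_vals = [aggregate_gpr_expression(c, expression) for c in gpr.children]
    if gpr.op == "and":
        return min(child_vals)
    return sum(child_vals)


@dataclass
class BoundsSet:
    """Per-reaction bounds after expression capping, with provenance.

    ``provenance`` maps each constrained reaction to the GPR-aggregated
    expression value that produced its cap; unconstrained reactions keep the
    model's default bounds and do not appear in ``provenance``.
    """

    lower: dict[str, float]
    upper: dict[str, float]
    k: float
    provenance: dict[str, float] = field(default_factory=dict)


def expression_to_bounds(model: MetabolicModel, expression: dict[str, float],
                         k: float) -> BoundsSet:
    """Cap each GPR-bearing reaction at ``k`` times its aggregated RPKM.

    upper = min(default upper, k * aggregate); for reversible reactions the
    lower bound is tightened symmetrically: lower = max(default lower,
    -k * aggregate). Exchange reactions and reactions without a GPR keep
    their defaults.
    """
    if k <= 0:
        raise ValueError("proportionality constant k must be > 0")
    lower, upper, prov = {}, {}, {}
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.gpr is not None and not rxn.exchange:
            agg = aggregate_gpr_expression(rxn.gpr, expression)
            cap = k * agg
            ub = min(ub, cap)
            if rxn.reversible:
                lb = max(lb, -cap)
            prov[rxn.id] = agg
        lower[rxn.id], upper[rxn.id] = lb, ub
    return BoundsSet(lower, upper, k, prov)


def auto_k(model: MetabolicModel, expr: ExpressionMatrix,
           target_cap: float = 10.0, percentile: float = 95.0) -> float:
    """Scale-pinning rule for the RPKM-to-flux proportionality constant.

    Chooses k so that the ``percentile``-th percentile of the GPR-aggregated
    expression values, over all constrained reactions and all samples,
    maps to ``target_cap`` mmol h^-1 gDW^-1. Only relative comparisons
    between cell lines matter; pinning the scale makes runs comparable.
    """
    aggs = []
    for sample in expr.values.columns:
        emap = expr.sample_expression(sample)
        for rxn in model.reactions:
            if rxn.gpr is not None and not rxn.exchange:
                aggs.append(aggregate_gpr_expression(rxn.gpr, emap))
    aggs = [a for a in aggs if a > 0]
    if not aggs:
        raise ValueError("no positive GPR-aggregated expression values; "
                         "cannot pin k automatically")
    return target_cap / float(np.percentile(aggs, percentile))


# ---------------------------------------------------------------------------
# FBA with deterministic degeneracy resolution
# ---------------------------------------------------------------------------

def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    return res


def fba(model: MetabolicModel, bounds: BoundsSet | None = None,
        sample_id: str = "") -> FluxDistribution:
    """Biomass-maximizing FBA with L1 + lexicographic tie-breaking.

    Maximizes the objective reaction subject to S.v = 0 and the supplied
    (or model-default) bounds; then minimizes total flux sum(|v|) at the
    fixed optimum; then lexicographically minimizes each v_r in sorted
    reaction-id order, so repeated solves of the same inputs are
    bit-identical. The returned solution is verified post hoc against the
    steady-state and bound tolerances.
    """
    S = model.stoichiometric_matrix()
    m, n = S.shape
    rids = model.reaction_ids
    if bounds is None:
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
    else:
        lb = np.array([bounds.lower[r] for r in rids])
        ub = np.array([bounds.upper[r] for r in rids])
    obj_idx = rids.index(model.objective_reaction)

    # stage 1: maximize biomass
    c = np.zeros(n)
    c[obj_idx] = -1.0
    res = _linprog(c, None, None, S, np.zeros(m), list(zip(lb, ub)))
    if res.status == 2:
        binding = [f"{rids[j]} in [{lb[j]:g}, {ub[j]:g}]" for j in range(n)
                   if ub[j] - lb[j] < 1e-12]
        raise InfeasibleModelError(
            "FBA infeasible; pinched bounds: " + (", ".join(binding) or "none")
            + f"; solver: {res.message}")
    if res.status == 3:
        raise UnboundedModelError(f"objective unbounded: {res.message}")
    if res.status != 0:
        raise FBAError(f"LP solver failure: {res.message}")
    opt = -res.fun

    # stage 2: minimize sum |v| at the optimum, in split variables v = p - q
    def split(vec):  # row [p-part, q-part] expressing vec . v
        return np.concatenate([vec, -vec])

    p_ub = np.maximum(ub, 0.0)
    q_ub = np.maximum(-lb, 0.0)
    var_bounds = [(0.0, u) for u in p_ub] + [(0.0, u) for u in q_ub]
    A_eq = np.vstack([np.hstack([S, -S])])
    b_eq = np.zeros(m)
    # original box constraints on v (needed when 0 is outside [lb, ub])
    A_ub = [np.hstack([np.eye(n), -np.eye(n)]),
            np.hstack([-np.eye(n), np.eye(n)])]
    b_ub = [ub, -lb]
    # biomass pinned to the stage-1 optimum (slack band)
    e_obj = np.zeros(n)
    e_obj[obj_idx] = 1.0
    A_ub.append(split(-e_obj)[None, :])
    b_ub.append(np.array([-(opt - _SLACK)]))
    A_ub.append(split(e_obj)[None, :])
    b_ub.append(np.array([opt + _SLACK]))

    l1_cost = np.ones(2 * n)
    res2 = _linprog(l1_cost, np.vstack(A_ub), np.concatenate(b_ub),
                    A_eq, b_eq, var_bounds)
    if res2.status != 0:
        raise FBAError(f"L1 tie-break LP failed: {res2.message}")
    l1_opt = res2.fun

    # stage 3: lexicographic minimization, reactions in sorted-id order
    A_ub.append(l1_cost[None, :])
    b_ub.append(np.array([l1_opt + _SLACK]))
    x = res2.x
    for rid in sorted(rids):
        j = rids.index(rid)
        e = np.zeros(n)
        e[j] = 1.0
        res3 = _linprog(split(e), np.vstack(A_ub), np.concatenate(b_ub),
                        A_eq, b_eq, var_bounds)
        if res3.status != 0:
            raise FBAError(f"lexicographic LP failed at {rid}: {res3.message}")
        vj = res3.x[j] - res3.x[n + j]
        A_ub.append(split(e)[None, :])
        b_ub.append(np.array([vj + _SLACK]))
        A_ub.append(split(-e)[None, :])
        b_ub.append(np.array([-(vj - _SLACK)]))
        x = res3.x

    v = x[:n] - x[n:]
    v[np.abs(v) < BOUND_TOL] = 0.0

    # post-hoc verification, independent of solver status flags
    resid = np.abs(S @ v).max() if m else 0.0
    if resid > STEADY_STATE_TOL:
        raise FBAError(f"steady-state residual {resid:.2e} exceeds tolerance")
    if ((v < lb - 1e-6) | (v > ub + 1e-6)).any():
        raise FBAError("solution violates flux bounds")
    fluxes = pd.Series(v, index=rids, name=sample_id or "flux")
    # report the stage-1 LP optimum: the slack bands used for tie-breaking
    # may shave O(n * slack) off the flux vector's objective entry
    return FluxDistribution(fluxes, float(opt), sample_id)


def replicate_fluxes(model: MetabolicModel, expr: ExpressionMatrix,
                     group: str, k: float) -> list[FluxDistribution]:
    """One expression-constrained FBA solve per replicate of ``group``."""
    samples = expr.samples_of(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples")
    out = []
    for sample in samples:
        emap = expr.sample_expression(sample)
        b = expression_to_bounds(model, emap, k)
        try:
            out.append(fba(model, b, sample_id=sample))
        except FBAError as exc:
            raise FBAError(f"sample {sample!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Brute-force LP oracle (vertex enumeration)
# ---------------------------------------------------------------------------

def brute_force_fba_objective(model: MetabolicModel,
                              bounds: BoundsSet | None = None) -> float | None:
    """Exhaustive vertex-enumeration solution of the FBA LP.

    Enumerates every subset of reactions fixed at a lower or upper bound,
    solves S.v = 0 for the remainder by least squares, keeps feasible
    vertices, and returns the maximal objective value. Exponential in the
    reaction count — intended only as an independent check on tiny models
    (<= ~8 reactions). Returns None when no feasible vertex exists.
    """
    S = model.stoichiometric_matrix()
    m, n = S.shape
    rids = model.reaction_ids
    if bounds is None:
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
    else:
        lb = np.array([bounds.lower[r] for r in rids])
        ub = np.array([bounds.upper[r] for r in rids])
    obj = rids.index(model.objective_reaction)

    best = None
    for size in range(n + 1):
        for fixed in combinations(range(n), size):
            free = [j for j in range(n) if j not in fixed]
            for pattern in product((0, 1), repeat=size):
                v = np.zeros(n)
                for j, at_ub in zip(fixed, pattern):
                    v[j] = ub[j] if at_ub else lb[j]
                rhs = -S[:, list(fixed)] @ v[list(fixed)] if size else np.zeros(m)
                if free:
                    sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                    v[free] = sol
                if np.abs(S @ v).max() > 1e-8:
                    continue
                if ((v < lb - 1e-9) | (v > ub + 1e-9)).any():
                    continue
                val = v[obj]
                if best is None or val > best:
                    best = val
    return best


# ---------------------------------------------------------------------------
# Differential flux
# ---------------------------------------------------------------------------

@dataclass
class DiffFluxTable:
    """Per-reaction differential-flux statistics between two cell lines.

    ``table`` is indexed by reaction with columns ``mean_case``,
    ``mean_control``, ``mean_diff``, ``t``, ``p_value``, ``q_value``,
    ``significant``. Reactions carrying zero flux in every replicate of both
    groups are excluded from testing (untestable hypotheses inflate the
    multiple-testing burden).
    """

    table: pd.DataFrame
    case: str = ""
    control: str = ""

    @property
    def significant_reactions(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def differential_flux(fluxes_case: list[FluxDistribution],
                      fluxes_control: list[FluxDistribution],
                      fdr: float = 0.05, min_diff: float = 0.001,
                      case: str = "", control: str = "") -> DiffFluxTable:
    """t-test per reaction across replicate flux vectors, BH-adjusted.

    A reaction is significant iff q <= ``fdr`` AND |mean difference| >
    ``min_diff`` (mmol h^-1 gDW^-1). With deterministic LP solves,
    exactly-constant replicate fluxes are common; when both groups are
    constant the p-value is defined as 0 if their means differ and 1 if
    they coincide.
    """
    if len(fluxes_case) < 2 or len(fluxes_control) < 2:
        raise ValueError("need >= 2 replicate flux distributions per side")
    A = pd.concat([f.fluxes for f in fluxes_case], axis=1).to_numpy(float)
    B = pd.concat([f.fluxes for f in fluxes_control], axis=1).to_numpy(float)
    rids = fluxes_case[0].fluxes.index

    testable = ~((np.abs(A) < ZERO_FLUX).all(axis=1) &
                 (np.abs(B) < ZERO_FLUX).all(axis=1))
    A, B = A[testable], B[testable]
    idx = rids[testable]
    if len(idx) == 0:
        empty = pd.DataFrame(columns=["mean_case", "mean_control", "mean_diff",
                                      "t", "p_value", "q_value", "significant"])
        return DiffFluxTable(empty, case, control)

    # constant rows are resolved explicitly below; silence scipy's warning
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    const = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    diff = mean_a - mean_b
    equal_means = np.isclose(mean_a, mean_b, rtol=0, atol=ZERO_FLUX)
    p = np.where(const, np.where(equal_means, 1.0, 0.0), p)
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    q = bh_adjust(p)
    significant = (q <= fdr) & (np.abs(diff) > min_diff)

    table = pd.DataFrame({
        "mean_case": mean_a, "mean_control": mean_b, "mean_diff": diff,
        "t": t, "p_value": p, "q_value": q, "significant": significant,
    }, index=idx)
    return DiffFluxTable(table, case, control)


# ---------------------------------------------------------------------------
# Flux-controlling genes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxControllingGene:
    """A (reaction, gene) pair where both flux and expression changed."""

    reaction_id: str
    gene_id: str
    flux_q: float
    gene_call: str


def flux_controlling_genes(diff: DiffFluxTable, de: DETable,
                           model: MetabolicModel) -> list[FluxControllingGene]:
    """Pairs of differentially used reactions and their DE genes.

    A pair is emitted when the reaction is significant in the differential
    flux table AND at least that gene of its GPR is differentially expressed
    (up or down). Genes missing from the DE table count as non-significant.
    """
    out = []
    for rid in sorted(diff.significant_reactions):
        rxn = model.reaction(rid)
        if rxn.gpr is None:
            continue
        for gene in sorted(rxn.gpr.genes()):
            call = de.call_of(gene)
            if call != NS:
                out.append(FluxControllingGene(
                    rid, gene, float(diff.table.at[rid, "q_value"]), call))
    return out
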