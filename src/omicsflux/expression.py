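"""RPKM expression, differential calls, consensus sets and over-representation.

Differential expression follows the classic RPKM / Student's t-test recipe:
per-gene two-sample t on log2(RPKM + 1), Benjamini-Hochberg FDR, and a fold
change computed as the ratio of group mean RPKMs with a small pseudocount.
Defaults are an FDR of 0.01 and a fold-change cutoff of 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass
class ExpressionMatrix:
    """RPKM values (gene x sample) with gene lengths and group labels."""

    values: pd.DataFrame
    gene_lengths: pd.Series
    sample_groups: dict[str, str]

    def validate(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        if (self.gene_lengths.reindex(self.values.index) <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group: {missing}")

    def samples_of(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns
                if self.sample_groups[s] == group]
        if not cols:
            raise ValueError(f"group {group!r} has no samples")
        return cols

    def sample_expression(self, sample: str) -> dict[str, float]:
        """One sample's column as a gene -> RPKM mapping."""
        return self.values[sample].to_dict()


def compute_rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
                 totals: pd.Series | None = None,
                 sample_groups: dict[str, str] | None = None
                 ) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM(g, s) = counts(g, s) * 1e9 / (length(g) * total(s)); ``totals``
    defaults to the per-sample column sums of the count matrix.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise ValueError(f"genes without a length: {missing[:5]}")
    bad = lengths <= 0
    if bad.any():
        raise ValueError(f"non-positive length for genes "
                         f"{list(lengths.index[bad])[:5]}")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    bad_tot = (totals <= 0) | totals.isna()
    if bad_tot.any():
        raise ValueError(f"non-positive mapped-read total for samples "
                         f"{list(totals.index[bad_tot])}")
    rpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(rpkm, lengths.astype(float),
                            dict(sample_groups or {}))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene differential-expression statistics for one contrast.

    ``table`` is indexed by gene with columns ``mean_case``, ``mean_control``,
    ``fold_change``, ``p_value``, ``q_value``, ``call``.
    """

    table: pd.DataFrame
    case: str
    control: str

    def genes_called(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["call"] == direction])

    @property
    def up(self) -> set[str]:
        return self.genes_called(UP)

    @property
    def down(self) -> set[str]:
        return self.genes_called(DOWN)

    def call_of(self, gene: str) -> str:
        if gene not in self.table.index:
            return NS
        return self.table.at[gene, "call"]


def differential_expression(expr: ExpressionMatrix, case: str, control: str,
                            fdr_cutoff: float = 0.01, fc_cutoff: float = 2.0,
                            log_transform: bool = True,
                            pseudocount: float = 0.1) -> DETable:
    """Student's t-test per gene between two groups of RPKM columns.

    The test runs on log2(RPKM + 1) by default (variance stabilization);
    the reported fold change is (mean_case + eps) / (mean_control + eps) on
    the RPKM scale. Genes with zero RPKM in every sample are excluded before
    testing (they carry no information and inflate the correction).
    Calls: ``up`` iff fold_change >= fc_cutoff and q <= fdr_cutoff;
    ``down`` iff fold_change <= 1/fc_cutoff and q <= fdr_cutoff; else ``ns``.
    """
    expr.validate()
    case_cols = expr.samples_of(case)
    ctrl_cols = expr.samples_of(control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs >= 2 replicates")

    vals = expr.values[case_cols + ctrl_cols]
    keep = (vals != 0).any(axis=1)
    vals = vals.loc[keep]

    a = vals[case_cols].to_numpy(float)
    b = vals[ctrl_cols].to_numpy(float)
    ta = np.log2(a + 1.0) if log_transform else a
    tb = np.log2(b + 1.0) if log_transform else b
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(ta, tb, axis=1, equal_var=True)
    # zero pooled variance: identical means -> no evidence; differing -> exact
    bad = ~np.isfinite(p)
    if bad.any():
        equal = np.isclose(ta.mean(axis=1), tb.mean(axis=1))
        p = np.where(bad, np.where(equal, 1.0, 0.0), p)
        t = np.where(np.isfinite(t), t, 0.0)
    q = bh_adjust(p)

    mean_case = a.mean(axis=1)
    mean_ctrl = b.mean(axis=1)
    fc = (mean_case + pseudocount) / (mean_ctrl + pseudocount)

    sig = q <= fdr_cutoff
    call = np.full(len(vals), NS, dtype=object)
    call[sig & (fc >= fc_cutoff)] = UP
    with np.errstate(divide="ignore"):
        call[sig & (fc <= 1.0 / fc_cutoff)] = DOWN

    table = pd.DataFrame({
        "mean_case": mean_case, "mean_control": mean_ctrl,
        "fold_change": fc, "t": t, "p_value": p, "q_value": q, "call": call,
    }, index=vals.index)
    return DETable(table, case=case, control=control)


def consensus_genes(table_a: DETable, table_b: DETable,
                    direction: str) -> set[str]:
    """Genes with the same call in both contrasts (e.g. up in both lines)."""
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be {UP!r} or {DOWN!r}")
    if set(table_a.table.index) != set(table_b.table.index):
        raise ValueError("DE tables do not share a gene universe")
    return table_a.genes_called(direction) & table_b.genes_called(direction)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation per gene set, BH-adjusted.

    ``table`` is indexed by set name with columns ``overlap``, ``set_size``,
    ``query_size``, ``universe_size``, ``p_value``, ``q_value``,
    ``significant``.
    """

    table: pd.DataFrame


def ora_enrichment(query: set[str], gene_sets: dict[str, set[str]],
                   universe: set[str],
                   fdr_cutoff: float = 0.05) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each set's overlap with the query.

    Sets are intersected with the universe first; p is the probability of
    seeing at least the observed overlap when drawing |query| genes from the
    universe without replacement.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query) & set(universe)
    M, N = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & set(universe)
        k = len(members & query)
        n = len(members)
        p = stats.hypergeom.sf(k - 1, M, n, N) if n else 1.0
        rows.append((name, k, n, float(min(p, 1.0))))
    if not rows:
        return EnrichmentResult(pd.DataFrame(
            columns=["overlap", "set_size", "query_size", "universe_size",
                     "p_value", "q_value", "significant"]))
    names, overlaps, sizes, ps = zip(*rows)
    q = bh_adjust(ps)
    table = pd.DataFrame({
        "overlap": overlaps, "set_size": sizes,
        "query_size": N, "universe_size": M,
        "p_value": ps, "q_value": q, "significant": q <= fdr_cutoff,
    }, index=list(names))
    return EnrichmentResult(table)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
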