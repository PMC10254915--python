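"""Metabolomics footprinting: normalization, PCA, clustering, perturbation calls.

Works on a table of relative chromatographic peak areas (metabolites x
samples) from grouped cell-line replicates, one group being the
non-malignant control. Two routes identify malignancy-associated
metabolites:

* a statistical route — Welch t-test of pooled malignant replicates against
  the control, BH-adjusted, plus a per-malignant-line sign-consistency
  requirement;
* a cluster route — hierarchical clustering of autoscaled metabolite
  profiles, flagging clusters whose mean profile separates the control line
  from both malignant lines with a consistent sign (the analogue of reading
  blocks off a heat-map).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.stats.multitest import multipletests

HIGHER_IN_MALIGNANT = "higher_in_malignant"
LOWER_IN_MALIGNANT = "lower_in_malignant"
NOT_PERTURBED = "none"


@dataclass
class MetaboliteTable:
    """Relative-abundance table (metabolite x sample) with group labels."""

    values: pd.DataFrame
    sample_groups: dict[str, str]
    malignant_groups: set[str] = field(default_factory=set)

    def validate(self) -> None:
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if (self.values.values <= 0).any():
            raise ValueError("relative areas must be strictly positive")
        counts = pd.Series(
            [self.sample_groups[s] for s in self.values.columns]).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"groups with fewer than 2 replicates: "
                             f"{sorted(small.index)}")
        unknown = self.malignant_groups - set(self.sample_groups.values())
        if unknown:
            raise ValueError(f"malignant_groups not present in data: "
                             f"{sorted(unknown)}")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    @property
    def control_group(self) -> str:
        ctrl = [g for g in self.groups if g not in self.malignant_groups]
        if len(ctrl) != 1:
            raise ValueError(
                f"expected exactly one non-malignant group, found {ctrl}")
        return ctrl[0]

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    @classmethod
    def from_csv(cls, path, sample_groups: dict[str, str],
                 malignant_groups: set[str]) -> "MetaboliteTable":
        """Read a CSV whose first column is the metabolite name."""
        values = pd.read_csv(path, index_col=0)
        table = cls(values, dict(sample_groups), set(malignant_groups))
        table.validate()
        return table


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_abundances(table: MetaboliteTable,
                         method: str = "autoscale") -> MetaboliteTable:
    """Per-metabolite normalization prior to multivariate analysis.

    ``autoscale``: mean 0, sample SD 1 (n-1 denominator) per metabolite row.
    ``log_autoscale``: log10 transform, then autoscale.
    ``none``: identity.

    A zero-variance metabolite cannot be autoscaled; its row is set to zero
    and a warning is emitted.
    """
    if method == "none":
        return replace(table, values=table.values.copy())
    if method not in ("autoscale", "log_autoscale"):
        raise ValueError(f"unknown normalization method {method!r}")
    vals = table.values.astype(float)
    if method == "log_autoscale":
        vals = np.log10(vals)
    centered = vals.sub(vals.mean(axis=1), axis=0)
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance metabolites set to all-zero under autoscale: "
            f"{list(vals.index[flat])}")
        sd = sd.replace(0, 1.0)
    return replace(table, values=centered.div(sd, axis=0))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Sample scores, metabolite loadings, and per-component variance share."""

    scores: pd.DataFrame       # sample x component
    loadings: pd.DataFrame     # metabolite x component
    variance_fraction: np.ndarray

    def variance_pct(self, k: int) -> float:
        """Percent of total variance carried by component ``k`` (1-based)."""
        return float(self.variance_fraction[k - 1] * 100)


def pca(table: MetaboliteTable) -> PCAResult:
    """PCA with samples as observations and metabolites as variables."""
    X = table.values.to_numpy(float).T  # samples x metabolites
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 metabolites")
    n_comp = min(n, p)
    fit = _SKPCA(n_components=n_comp, svd_solver="full").fit(X)
    comps = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(fit.transform(X), index=table.values.columns,
                          columns=comps)
    loadings = pd.DataFrame(fit.components_.T, index=table.values.index,
                            columns=comps)
    return PCAResult(scores, loadings, fit.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: pd.Series | None  # metabolite -> flat cluster id (1-based)


def cluster_metabolites(table: MetaboliteTable, k: int | None = None,
                        linkage: str = "ward",
                        metric: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of metabolite concentration profiles.

    ``metric='correlation'`` clusters by profile shape; Ward linkage
    requires Euclidean distances.
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    X = table.values.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 metabolites to cluster")
    if k is not None and k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of metabolites {X.shape[0]}")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=table.values.index, name="cluster")
    return ClusterResult(Z, labels)


# ---------------------------------------------------------------------------
# Perturbed-metabolite calling
# ---------------------------------------------------------------------------

@dataclass
class PerturbedMetaboliteSet:
    """Per-metabolite malignancy-association calls with direction.

    ``table`` is indexed by metabolite with columns ``direction``, ``t``,
    ``p``, ``q`` and (optionally) ``cluster``.
    """

    table: pd.DataFrame

    @property
    def flagged(self) -> dict[str, str]:
        sel = self.table[self.table["direction"] != NOT_PERTURBED]
        return dict(sel["direction"])

    def count(self, direction: str) -> int:
        return int((self.table["direction"] == direction).sum())


def _consistent_direction(log_vals: pd.DataFrame, table: MetaboliteTable) -> pd.Series:
    """Per metabolite: direction if every malignant group's mean sits on the
    same side of the control mean, else ``none``."""
    ctrl_mean = log_vals[table.samples_of(table.control_group)].mean(axis=1)
    signs = []
    for g in sorted(table.malignant_groups):
        diff = log_vals[table.samples_of(g)].mean(axis=1) - ctrl_mean
        signs.append(np.sign(diff))
    signs = np.vstack(signs)
    consistent_up = (signs > 0).all(axis=0)
    consistent_down = (signs < 0).all(axis=0)
    out = np.full(log_vals.shape[0], NOT_PERTURBED, dtype=object)
    out[consistent_up] = HIGHER_IN_MALIGNANT
    out[consistent_down] = LOWER_IN_MALIGNANT
    return pd.Series(out, index=log_vals.index)


def call_perturbed_metabolites(table: MetaboliteTable,
                               fdr_cutoff: float = 0.05,
                               log_transform: bool = True,
                               n_clusters: int | None = None
                               ) -> PerturbedMetaboliteSet:
    """Statistical route: pooled-malignant vs control Welch t + BH FDR,
    gated on per-line sign consistency.

    A metabolite is flagged iff its BH-adjusted Welch p-value is at most
    ``fdr_cutoff`` AND each malignant group's mean differs from the control
    mean with the same sign. Tests run on log10 abundances by default
    (relative areas are right-skewed).
    """
    table.validate()
    ctrl = table.control_group
    if not table.malignant_groups:
        raise ValueError("no malignant groups labelled")
    vals = table.values.astype(float)
    log_vals = np.log10(vals) if log_transform else vals

    ctrl_cols = table.samples_of(ctrl)
    mal_cols = [s for g in table.malignant_groups for s in table.samples_of(g)]
    a = log_vals[mal_cols].to_numpy()
    b = log_vals[ctrl_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate rows (no variance anywhere): equal means -> p=1, else p=0
    bad = ~np.isfinite(p)
    if bad.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(bad, np.where(equal, 1.0, 0.0), p)
        t = np.where(np.isfinite(t), t, 0.0)
    q = multipletests(p, method="fdr_bh")[1]

    direction = _consistent_direction(log_vals, table)
    flagged = (q <= fdr_cutoff) & (direction != NOT_PERTURBED).to_numpy()
    direction = direction.where(pd.Series(flagged, index=direction.index),
                                NOT_PERTURBED)
    out = pd.DataFrame({"direction": direction, "t": t, "p": p, "q": q},
                       index=vals.index)
    if n_clusters is not None:
        out["cluster"] = cluster_metabolites(
            normalize_abundances(table, "autoscale"), k=n_clusters).labels
    return PerturbedMetaboliteSet(out)


def perturbed_from_clusters(table: MetaboliteTable,
                            k: int | None = None,
                            max_k: int = 8,
                            min_separation: float = 1.0
                            ) -> PerturbedMetaboliteSet:
    """Cluster route: flag whole clusters that separate control from malignant.

    Profiles are autoscaled and Ward-clustered. A cluster is flagged when its
    mean autoscaled profile differs between pooled malignant and control
    samples by at least ``min_separation`` (in SD units) AND the sign of the
    difference is the same for each malignant group individually. If ``k`` is
    None, every cut in ``2..max_k`` is scored by the smallest separation
    among its flagged clusters, and the sharpest cut wins: dilute cuts that
    merge shifted and unshifted metabolites score low.
    """
    table.validate()
    norm = normalize_abundances(table, "autoscale")
    ks = [k] if k is not None else list(range(2, min(max_k, len(table.values)) + 1))
    best: tuple[float, dict[str, str]] = (0.0, {})
    best_labels = None
    for kk in ks:
        res = cluster_metabolites(norm, k=kk)
        calls: dict[str, str] = {}
        worst_sep = np.inf
        for cid in np.unique(res.labels):
            members = res.labels.index[res.labels == cid]
            profile = norm.values.loc[members].mean(axis=0).to_frame().T
            sub = replace(norm, values=profile)
            direction = _consistent_direction(profile, sub).iloc[0]
            if direction == NOT_PERTURBED:
                continue
            ctrl_mean = profile[sub.samples_of(sub.control_group)].mean(axis=1).iloc[0]
            mal_cols = [s for g in sub.malignant_groups for s in sub.samples_of(g)]
            sep = profile[mal_cols].mean(axis=1).iloc[0] - ctrl_mean
            if abs(sep) >= min_separation:
                worst_sep = min(worst_sep, abs(sep))
                for m in members:
                    calls[m] = direction
        score = worst_sep if calls else 0.0
        if score > best[0]:
            best = (score, calls)
            best_labels = res.labels
    calls = best[1]
    direction = pd.Series(
        [calls.get(m, NOT_PERTURBED) for m in table.values.index],
        index=table.values.index, name="direction")
    out = pd.DataFrame({"direction": direction,
                        "t": np.nan, "p": np.nan, "q": np.nan})
    if best_labels is not None:
        out["cluster"] = best_labels
    return PerturbedMetaboliteSet(out)


# ---------------------------------------------------------------------------
# Whole-table convenience report
# ---------------------------------------------------------------------------

def analyze_metabolite_table(table: MetaboliteTable,
                             fdr_cutoff: float = 0.05) -> dict:
    """Run the full footprinting workflow and return a summary dict.

    Reports PC1/PC2 explained-variance percentages under each normalization
    mode, plus perturbed-metabolite calls from both routes (statistical and
    cluster-based), so the variance decomposition printed for a real
    relative-area table can be checked under every preprocessing choice.
    """
    table.validate()
    summary: dict = {"pca": {}}
    for mode in ("autoscale", "log_autoscale", "none"):
        res = pca(normalize_abundances(table, mode))
        summary["pca"][mode] = {
            "pc1_pct": res.variance_pct(1),
            "pc2_pct": res.variance_pct(2),
            "pc1_plus_pc2_pct": res.variance_pct(1) + res.variance_pct(2),
        }
    stat = call_perturbed_metabolites(table, fdr_cutoff=fdr_cutoff)
    clus = perturbed_from_clusters(table)
    summary["perturbed_statistical"] = stat.flagged
    summary["perturbed_cluster_route"] = clus.flagged
    summary["n_perturbed_cluster_route"] = len(clus.flagged)
    summary["n_higher_in_malignant"] = clus.count(HIGHER_IN_MALIGNANT)
    summary["n_lower_in_malignant"] = clus.count(LOWER_IN_MALIGNANT)
    return summary
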