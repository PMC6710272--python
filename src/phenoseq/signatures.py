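"""Signature construction, background-controlled scoring, cluster
comparison, pseudobulk reconstruction and gene-set overlap enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream

__all__ = [
    "Signature",
    "EnrichmentResult",
    "correlate_with_anchor",
    "build_anchor_signature",
    "score_signature",
    "compare_cluster_scores",
    "make_pseudobulk",
    "overlap_enrichment",
]


@dataclass(frozen=True)
class Signature:
    name: str
    gene_ids: tuple[str, ...]
    anchor: str | None = None
    source: Literal["anchor_correlation", "fixed_list", "deconvolution"] = "fixed_list"

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature genes must be unique")
        if self.anchor is not None and self.anchor in self.gene_ids:
            raise ValueError("anchor may not be a member of its own signature")


def correlate_with_anchor(
    matrix: pd.DataFrame, anchor: str, method: Literal["pearson"] = "pearson"
) -> pd.DataFrame:
    """Pearson correlation of every other gene with the anchor gene.

    Returns a DataFrame (gene, r) sorted by descending r; zero-variance
    genes get r = NaN and are ranked last.  Ties break by gene id so the
    ranking is deterministic.
    """
    if method != "pearson":
        raise ValueError("only Pearson correlation is supported")
    if anchor not in matrix.index:
        raise KeyError(f"anchor gene {anchor!r} not present in the matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 spheroids for correlation")
    anchor_values = matrix.loc[anchor].to_numpy(dtype=float)
    if np.ptp(anchor_values) == 0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance")

    others = matrix.drop(index=anchor)
    x = others.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ac = anchor_values - anchor_values.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ ac / denom, np.nan)

    result = pd.DataFrame({"gene": others.index, "r": r})
    result = result.sort_values(
        by=["r", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return result


def build_anchor_signature(
    matrix: pd.DataFrame, anchor: str, top_k: int = 20
) -> Signature:
    """Signature of the top_k genes most correlated with the anchor
    (anchor itself excluded)."""
    ranked = correlate_with_anchor(matrix, anchor)
    defined = ranked.dropna(subset=["r"])
    if len(defined) < top_k:
        raise ValueError(
            f"only {len(defined)} genes have a defined correlation; need {top_k}"
        )
    genes = tuple(defined["gene"].head(top_k))
    return Signature(name=f"{anchor}_top{top_k}", gene_ids=genes, anchor=anchor,
                     source="anchor_correlation")


def score_signature(
    matrix: pd.DataFrame,
    signature: Signature,
    n_bins: int = 25,
    controls_per_gene: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Background-corrected signature scores on a log-expression matrix.

    Genes are sorted by mean expression and split into ``n_bins``
    equal-size bins; each signature gene contributes ``controls_per_gene``
    control genes sampled from its own bin.  The per-spheroid score is the
    mean expression of the signature genes minus the mean expression of all
    sampled controls, cancelling per-spheroid technical offsets.
    """
    missing = [g for g in signature.gene_ids if g not in matrix.index]
    if missing:
        raise KeyError(f"signature genes absent from the matrix: {missing}")
    if matrix.shape[0] < n_bins:
        raise ValueError(f"need at least {n_bins} genes to form {n_bins} bins")

    means = matrix.mean(axis=1)
    order = means.sort_values(kind="mergesort").index
    bins = np.array_split(np.arange(len(order)), n_bins)
    gene_bin = pd.Series(
        np.concatenate([np.full(len(b), i) for i, b in enumerate(bins)]), index=order
    )

    control_genes: list[str] = []
    for gene in signature.gene_ids:
        bin_members = gene_bin.index[gene_bin == gene_bin[gene]]
        rng = substream(seed, "controls", signature.name, gene)
        replace = len(bin_members) < controls_per_gene
        control_genes.extend(rng.choice(bin_members, size=controls_per_gene, replace=replace))

    signature_mean = matrix.loc[list(signature.gene_ids)].mean(axis=0)
    control_mean = matrix.loc[control_genes].mean(axis=0)
    scores = signature_mean - control_mean
    scores.name = signature.name
    return scores


def compare_cluster_scores(
    scores: pd.Series, labels: pd.Series | Mapping[str, object]
) -> tuple[float, float]:
    """Equal-variance unpaired two-tailed Student's t-test between the two
    clusters; returns (t, p)."""
    labels = pd.Series(labels).reindex(scores.index)
    if labels.isna().any():
        raise ValueError("every scored spheroid needs a cluster label")
    groups = sorted(labels.unique())  # deterministic: first group by label order
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(groups)}")
    a = scores[labels == groups[0]].to_numpy(dtype=float)
    b = scores[labels == groups[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cluster needs at least 2 members")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def make_pseudobulk(
    sc_matrix: pd.DataFrame,
    class_labels: pd.Series | Mapping[str, object],
    n_groups: int = 4,
    n_randomizations: int = 4,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Reconstruct synthetic pooled profiles from single-cell counts.

    Per randomization, each class's cells are shuffled and split into
    ``n_groups`` near-equal groups (sizes differ by at most 1); a group
    profile is the per-gene mean of its member cells.  Returns one
    genes x (classes * n_groups) matrix per randomization with columns
    named ``class_g<g>_r<r>``.
    """
    labels = pd.Series(class_labels).reindex(sc_matrix.columns)
    if labels.isna().any():
        raise ValueError("every cell needs a class label")
    class_cells = {cls: list(labels.index[labels == cls]) for cls in labels.unique()}
    for cls, cells in class_cells.items():
        if len(cells) < n_groups:
            raise ValueError(
                f"class {cls!r} has {len(cells)} cells < {n_groups} groups"
            )

    results = []
    for r in range(n_randomizations):
        profiles = {}
        for cls, cells in class_cells.items():
            rng = substream(seed, "pseudobulk", r, cls)
            shuffled = np.array(cells, dtype=object)
            rng.shuffle(shuffled)
            for g, group in enumerate(np.array_split(shuffled, n_groups)):
                profiles[f"{cls}_g{g}_r{r}"] = sc_matrix[list(group)].mean(axis=1)
        results.append(pd.DataFrame(profiles, index=sc_matrix.index))
    return results


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float


def overlap_enrichment(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric overlap test of a query against each gene set.

    p = P[X >= overlap] with population = universe, successes = set within
    the universe, draws = query; Benjamini-Hochberg q across the tested
    sets.  The result is ranked by q, then p.
    """
    universe_set = list(dict.fromkeys(universe))
    if not universe_set:
        raise ValueError("universe must be non-empty")
    query = list(dict.fromkeys(query_genes))
    outside = set(query) - set(universe_set)
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)}")

    m = len(universe_set)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & set(universe_set)
        overlap = len(in_universe & set(query))
        # P[X >= overlap] for hypergeometric(M=m, n=|set|, N=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(in_universe), n_query))
        rows.append((name, overlap, len(in_universe), n_query, m, min(p, 1.0)))

    result = pd.DataFrame(
        rows,
        columns=["gene_set", "overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    if result.empty:
        result["q_value"] = []
        return result
    result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.sort_values(["q_value", "p_value", "gene_set"]).reset_index(drop=True)
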