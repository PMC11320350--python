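"""Protein-level associations with age deviation and gene-set enrichment.

Each protein (inverse-normal transformed) is regressed on proteomic-age
deviation with the full covariate adjustment; Bonferroni-significant
proteins are mapped to gene symbols and tested for overrepresentation in
each gene set of a collection with an upper-tail hypergeometric test
against a fixed background universe of protein-coding genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "associate_proteins",
    "hypergeom_test",
    "run_gene_set_analysis",
    "map_proteins_to_genes",
]

log = logging.getLogger(__name__)

DEFAULT_BACKGROUND = 20260  # protein-coding gene universe


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    ``background`` may be an explicit symbol set; otherwise only the count
    is known and membership checks are skipped.
    """

    sets: dict[str, frozenset[str]]
    background_size: int = DEFAULT_BACKGROUND
    background: frozenset[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sets = {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        if any(len(s) == 0 for s in self.sets.values()):
            raise ValueError("every gene set must be non-empty")
        if self.sets and self.background_size < max(len(s) for s in self.sets.values()):
            raise ValueError("background smaller than the largest set")

    def __len__(self) -> int:
        return len(self.sets)


def associate_proteins(deviation, matrix_values: pd.DataFrame,
                       covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-protein OLS of deviation on protein + covariates.

    Uses the Frisch-Waugh-Lovell projection: deviation and every protein
    are residualized on [1, covariates] once, then each per-protein slope,
    t-test p, and Bonferroni-adjusted p come from the residual regression
    with the correct degrees of freedom.  Returns a DataFrame indexed by
    protein with columns beta, se, p, bonferroni_p.
    """
    y = np.asarray(deviation, dtype=float)
    X = matrix_values.to_numpy(dtype=float)
    n, m = X.shape
    if len(y) != n:
        raise ValueError("deviation length does not match matrix rows")
    if covariates is not None and len(covariates):
        C = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    else:
        C = np.ones((n, 1))
    q = C.shape[1]
    if np.linalg.matrix_rank(C) < q:
        raise ValueError("rank-deficient covariate design")
    # residualize on the adjustment design
    coef_y, *_ = np.linalg.lstsq(C, y, rcond=None)
    ry = y - C @ coef_y
    coef_X, *_ = np.linalg.lstsq(C, X, rcond=None)
    rX = X - C @ coef_X

    sxx = (rX * rX).sum(axis=0)
    if np.any(sxx <= 0):
        raise ValueError("a protein is collinear with the covariates")
    beta = rX.T @ ry / sxx
    dof = n - q - 1
    resid_ss = (ry * ry).sum() - beta * beta * sxx
    se = np.sqrt(np.maximum(resid_ss / dof, 0.0) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    p = 2 * stats.t.sf(np.abs(tval), dof)
    return pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "bonferroni_p": np.minimum(p * m, 1.0)},
        index=matrix_values.columns,
    )


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = overlap, n = input genes, K = set size, N = background universe.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_gene_set_analysis(sig_genes, collection: GeneSetCollection,
                          min_overlap: int = 5) -> pd.DataFrame:
    """Hypergeometric enrichment of each set; Bonferroni over the collection.

    Sets whose overlap with the input genes is below ``min_overlap`` are
    dropped regardless of p; genes outside an explicit background are
    removed from the input with a warning.  Rows sorted by p.
    """
    genes = set(map(str, sig_genes))
    if not genes:
        raise ValueError("empty input gene list")
    if collection.background is not None:
        outside = genes - collection.background
        if outside:
            log.warning("%d input genes outside the background universe; dropped", len(outside))
            genes -= outside
    n = len(genes)
    m_sets = len(collection)
    rows = []
    for name, members in collection.sets.items():
        k = len(genes & members)
        if k < min_overlap:
            continue
        p = hypergeom_test(k, n, len(members), collection.background_size)
        rows.append({"set": name, "set_size": len(members), "n_input": n,
                     "overlap": k, "p": p, "bonferroni_p": min(p * m_sets, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "set_size", "n_input", "overlap",
                                      "p", "bonferroni_p"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def map_proteins_to_genes(significant_proteins, gene_map) -> list[str]:
    """Union of gene symbols of the given proteins (many-to-many, deduplicated).

    Order of first appearance is preserved.
    """
    seen: dict[str, None] = {}
    for pid in significant_proteins:
        pid = str(pid)
        if pid not in gene_map:
            raise ValueError(f"protein {pid!r} missing from gene map")
        genes = gene_map[pid]
        if isinstance(genes, str):
            genes = (genes,)
        for g in genes:
            seen.setdefault(str(g))
    return list(seen)
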