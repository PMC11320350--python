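"""Core in-memory containers shared across the pipeline.

The cohort table is a plain :class:`pandas.DataFrame` (one row per
participant; survival outcomes as ``time_death``/``died`` plus per-disease
``time_<name>``/``status_<name>`` triples).  The protein matrix gets a thin
wrapper so the missingness mask and the protein-to-gene mapping travel with
the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ProteinMatrix", "default_gene_map"]


def default_gene_map(protein_ids: Sequence[str]) -> dict[str, tuple[str, ...]]:
    """One synthetic gene symbol per protein: PROT0001 -> GENE0001."""
    out = {}
    for i, pid in enumerate(protein_ids):
        out[str(pid)] = (f"GENE{i + 1:04d}",)
    return out


@dataclass
class ProteinMatrix:
    """Participants x proteins continuous expression values.

    Parameters
    ----------
    values
        DataFrame indexed by participant id with protein ids as columns.
        ``NaN`` marks a missing measurement.
    gene_map
        Mapping from protein id to one or more gene symbols.  Defaults to
        synthetic ``GENE####`` symbols, one per protein.
    """

    values: pd.DataFrame
    gene_map: Mapping[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate participant ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.gene_map is None:
            self.gene_map = default_gene_map(list(self.values.columns))
        else:
            norm: dict[str, tuple[str, ...]] = {}
            for pid, genes in dict(self.gene_map).items():
                if isinstance(genes, str):
                    genes = (genes,)
                norm[str(pid)] = tuple(genes)
            self.gene_map = norm
            missing = set(map(str, self.values.columns)) - set(norm)
            if missing:
                raise ValueError(f"gene_map does not cover proteins: {sorted(missing)[:5]} ...")

    @property
    def participant_ids(self) -> pd.Index:
        return self.values.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where the measurement is missing."""
        return self.values.isna()

    @property
    def missing_fraction(self) -> pd.Series:
        """Per-protein fraction of missing values."""
        return self.values.isna().mean(axis=0)

    def subset_proteins(self, keep: Sequence[str]) -> "ProteinMatrix":
        keep = list(keep)
        return ProteinMatrix(self.values[keep].copy(), {p: self.gene_map[p] for p in keep})

    def subset_participants(self, ids: Sequence) -> "ProteinMatrix":
        return ProteinMatrix(self.values.loc[list(ids)].copy(), dict(self.gene_map))

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), dict(self.gene_map))

    def __repr__(self) -> str:  # pragma: no cover
        n, p = self.values.shape
        miss = float(np.asarray(self.values.isna()).mean()) if n * p else 0.0
        return f"ProteinMatrix({n} participants x {p} proteins, {miss:.1%} missing)"
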