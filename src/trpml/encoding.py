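"""One-hot genotype encoding with a fixed, invertible block layout."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from trpml.library import Genotype, PromoterCatalog


class GenotypeOneHotEncoder(TransformerMixin, BaseEstimator):
    """Encode promoter-combination genotypes as block one-hot vectors.

    The layout is deterministic: genes in catalog order, promoters in
    catalog order within each gene block, giving a vector of length
    Σ per-gene promoter counts (30 for the default 5×6 catalog) with
    exactly one 1 per gene block. The encoding is invertible
    (:meth:`inverse_transform`).

    Accepts either a sequence of :class:`~trpml.library.Genotype` or a
    DataFrame with one promoter-name column per gene.
    """

    def __init__(self, catalog: PromoterCatalog | None = None):
        self.catalog = catalog

    def fit(self, X=None, y=None):
        from trpml.library import default_catalog

        cat = self.catalog if self.catalog is not None else default_catalog()
        self.catalog_ = cat
        self.feature_names_: list[str] = []
        self.block_slices_: dict[str, slice] = {}
        start = 0
        for g in cat.genes:
            names = cat.promoter_names(g)
            self.feature_names_.extend(f"{g}={p}" for p in names)
            self.block_slices_[g] = slice(start, start + len(names))
            start += len(names)
        self.n_features_ = start
        return self

    def _indices(self, X) -> np.ndarray:
        cat = self.catalog_
        if isinstance(X, pd.DataFrame):
            idx = np.empty((len(X), len(cat.genes)), dtype=int)
            for j, g in enumerate(cat.genes):
                lut = {p: i for i, p in enumerate(cat.promoter_names(g))}
                col = X[g].to_numpy()
                for r, prom in enumerate(col):
                    if prom not in lut:
                        raise ValueError(f"unknown promoter {prom!r} for gene {g}")
                    idx[r, j] = lut[prom]
            return idx
        idx = np.empty((len(X), len(cat.genes)), dtype=int)
        for r, g in enumerate(X):
            ind = g.indices if isinstance(g, Genotype) else tuple(g)
            for j, (gene, i) in enumerate(zip(cat.genes, ind)):
                if not (0 <= i < len(cat.bins[gene])):
                    raise ValueError(f"promoter index {i} out of range for gene {gene}")
                idx[r, j] = i
        return idx

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "catalog_"):
            self.fit()
        idx = self._indices(X)
        out = np.zeros((idx.shape[0], self.n_features_))
        for j, g in enumerate(self.catalog_.genes):
            out[np.arange(idx.shape[0]), self.block_slices_[g].start + idx[:, j]] = 1.0
        return out

    def inverse_transform(self, X: np.ndarray) -> list[Genotype]:
        if not hasattr(self, "catalog_"):
            self.fit()
        X = np.asarray(X)
        out = []
        for row in X:
            indices = []
            for g in self.catalog_.genes:
                block = row[self.block_slices_[g]]
                ones = np.flatnonzero(block == 1.0)
                if ones.size != 1:
                    raise ValueError(f"block for gene {g} is not one-hot")
                indices.append(int(ones[0]))
            out.append(Genotype(indices=tuple(indices)))
        return out

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.asarray(self.feature_names_, dtype=object)
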