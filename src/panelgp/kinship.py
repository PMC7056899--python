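"""Frequency-weighted identity-by-state genomic relationship matrix.

The relationship between individuals i and j is

    G_ij = (1/L) * sum_l (x_il - 2 p_l)(x_jl - 2 p_l) / (2 p_l (1 - p_l))

with x the A1-dosage and p the in-sample A1 frequency — i.e. twice the
Astle-Balding realized kinship, so diagonals sit near 1 and full-sib
off-diagonals near 0.5.  Missing dosages are mean-imputed to 2p by default;
a pairwise-complete policy is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .genotype_io import GenotypeDataset

__all__ = [
    "GenomicRelationship",
    "allele_frequencies",
    "build_grm",
    "invert_grm",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_sparse",
]

MEAN_IMPUTE = "mean_impute"
PAIRWISE_COMPLETE = "pairwise_complete"


@dataclass
class GenomicRelationship:
    """Symmetric relationship matrix with its construction provenance."""

    matrix: np.ndarray
    frequencies: np.ndarray
    marker_ids: tuple[str, ...]
    missing_policy: str = MEAN_IMPUTE
    ridge: float = 0.0

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=np.float64)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.isfinite(G).all():
            raise ValueError("relationship matrix has non-finite entries")
        if np.abs(G - G.T).max() > 1e-10:
            raise ValueError("relationship matrix is not symmetric")
        self.matrix = G

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def allele_frequencies(dataset: GenotypeDataset) -> np.ndarray:
    """In-sample A1 allele frequency per marker, ignoring missing calls."""
    X = dataset.dosages
    nonmiss = (~np.isnan(X)).sum(axis=0)
    if (nonmiss == 0).any():
        j = int(np.flatnonzero(nonmiss == 0)[0])
        raise ValueError(f"marker {dataset.markers['snp_id'][j]!r} has no non-missing calls")
    return np.nansum(X, axis=0) / (2.0 * nonmiss)


def build_grm(dataset: GenotypeDataset, freqs: np.ndarray | None = None,
              missing_policy: str = MEAN_IMPUTE) -> GenomicRelationship:
    """Build G from a dataset, estimating frequencies in-sample if not given.

    Monomorphic markers (p in {0,1}) carry no relationship information and
    are skipped with zero weight.
    """
    X = dataset.dosages
    p = allele_frequencies(dataset) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape[0] != X.shape[1]:
        raise ValueError("frequency vector length does not match marker count")
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    Xp, pp = X[:, poly], p[poly]
    denom = np.sqrt(2.0 * pp * (1.0 - pp))
    Z = (Xp - 2.0 * pp) / denom
    miss = np.isnan(Z)
    if missing_policy == MEAN_IMPUTE:
        Z = np.where(miss, 0.0, Z)  # dosage 2p maps to standardized 0
        G = (Z @ Z.T) / Z.shape[1]
    elif missing_policy == PAIRWISE_COMPLETE:
        Zm = np.where(miss, 0.0, Z)
        obs = (~miss).astype(np.float64)
        L = obs @ obs.T
        if (L == 0).any():
            raise ValueError("some individual pair shares no non-missing marker")
        G = (Zm @ Zm.T) / L
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    G = (G + G.T) / 2.0
    return GenomicRelationship(
        G, p, tuple(dataset.markers["snp_id"]), missing_policy=missing_policy
    )


def invert_grm(G: np.ndarray | GenomicRelationship, ridge: float = 0.0
               ) -> tuple[np.ndarray, float]:
    """Invert G, escalating a diagonal ridge from 1e-6 if numerically singular.

    Returns (G_inverse, ridge_used); the residual ||G G^-1 - I||_max is
    required to fall below 1e-6 after ridging.
    """
    A = G.matrix if isinstance(G, GenomicRelationship) else np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if np.abs(A - A.T).max() > 1e-8:
        raise ValueError("matrix is not symmetric")
    n = A.shape[0]
    used = float(ridge)
    for _ in range(16):
        try:
            c, low = linalg.cho_factor(A + used * np.eye(n))
            Ainv = linalg.cho_solve((c, low), np.eye(n))
            resid = np.abs((A + used * np.eye(n)) @ Ainv - np.eye(n)).max()
            if resid < 1e-6:
                return Ainv, used
        except linalg.LinAlgError:
            pass
        used = 1e-6 if used == 0.0 else used * 10.0
    raise linalg.LinAlgError("could not invert relationship matrix even with ridge")


def write_grm_tsv(matrix: np.ndarray, ids, path) -> None:
    """Full symmetric matrix as TSV with an ID header row and column."""
    import pandas as pd

    pd.DataFrame(np.asarray(matrix), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t"
    )


def read_grm_tsv(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index)


def write_grm_sparse(matrix: np.ndarray, ids, values_path, ids_path) -> None:
    """Lower triangle as (i, j, value) 1-based text rows plus a companion ID file."""
    A = np.asarray(matrix)
    ids = list(ids)
    with open(ids_path, "w") as fh:
        fh.write("\n".join(str(s) for s in ids) + "\n")
    with open(values_path, "w") as fh:
        for i in range(A.shape[0]):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{float(A[i, j])!r}\n")
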