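"""REML variance components and GBLUP breeding values for the animal model

    y = mu + X b + Z a + e,   a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

with a single genomic random effect.  The restricted likelihood is profiled
over the total variance at a fixed heritability ratio and evaluated in the
eigenbasis of G, so each likelihood evaluation is O(n) after one
eigendecomposition; the one-dimensional profile is then maximized by bounded
scalar optimization.  Breeding values come either from the conditional
expectation  a_hat = sigma_a^2 G[:, obs] V_oo^{-1} (y - X b_hat)  or from the
mixed-model equations with G^{-1}; the two agree and both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genotype_io import GenotypeDataset, PhenotypeTable
from .kinship import GenomicRelationship, build_grm, invert_grm
from .panel_design import SNPPanel

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "GBLUPSolution",
    "GrmEigen",
    "design_matrix",
    "restricted_loglik",
    "fit_reml",
    "solve_gblup",
    "estimate_h2_curve",
]

_H2_LO, _H2_HI = 1e-6, 1.0 - 1e-6
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixedModelSpec:
    """Trait and fixed-effect factors (the intercept is always included)."""

    trait: str
    factors: tuple[str, ...] = ()


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class GBLUPSolution:
    fixed_effects: np.ndarray
    breeding_values: np.ndarray  # one entry per individual in G
    components: VarianceComponents


class GrmEigen:
    """Eigendecomposition of (a sub-block of) G, reused across h2 evaluations."""

    def __init__(self, G: np.ndarray):
        G = np.asarray(G, dtype=float)
        if np.abs(G - G.T).max() > 1e-8:
            raise ValueError("G must be symmetric")
        d, U = linalg.eigh(G)
        if d.max() - d.min() < 1e-8:
            raise ValueError(
                "G is (numerically) a multiple of the identity: sigma_a and "
                "sigma_e are not separately identifiable"
            )
        self.values = d
        self.vectors = U


def design_matrix(phenos: PhenotypeTable, spec: MixedModelSpec, ids
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Response, fixed-effect design, and observation mask aligned to ``ids``.

    Individuals missing the trait or any factor level are excluded from y/X
    (mask False) but keep their position in G for prediction.  Factors are
    reference-coded (first level dropped); the intercept is the overall mean.
    """
    df = phenos.data.reindex(pd.Index(ids))
    y_all = df[spec.trait].astype(float)
    obs = y_all.notna()
    for f in spec.factors:
        if f not in df.columns:
            raise KeyError(f"factor {f!r} not in phenotype table")
        obs &= df[f].notna()
    obs_mask = obs.to_numpy()
    y = y_all.to_numpy()[obs_mask]
    cols = [np.ones(obs_mask.sum())]
    for f in spec.factors:
        dummies = pd.get_dummies(df.loc[obs.to_numpy(), f], drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    return y, X, obs_mask


def _profile(y_t: np.ndarray, X_t: np.ndarray, d: np.ndarray, h2: float):
    """GLS pieces in the eigenbasis at heritability ratio h2 (unit total var)."""
    w = h2 * d + (1.0 - h2)
    winv = 1.0 / w
    Xw = X_t * winv[:, None]
    A = X_t.T @ Xw
    b = linalg.solve(A, Xw.T @ y_t, assume_a="pos")
    r = y_t - X_t @ b
    q = float(r @ (winv * r))
    return w, A, b, q


def restricted_loglik(y, X, eig: GrmEigen, h2: float) -> float:
    """Profiled restricted log-likelihood at heritability ratio ``h2``.

    The total variance sigma_a^2 + sigma_e^2 is profiled out analytically, so
    this is the REML criterion as a function of h2 alone.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2={h2} outside the open interval (0, 1)")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    y_t = eig.vectors.T @ y
    X_t = eig.vectors.T @ X
    w, A, _, q = _profile(y_t, X_t, eig.values, h2)
    sigma2 = q / (n - p)
    _, logdet_A = np.linalg.slogdet(A)
    return -0.5 * (
        (n - p) * (_LOG_2PI + np.log(sigma2) + 1.0)
        + np.log(w).sum()
        + logdet_A
    )


def fit_reml(y, X, G, eig: GrmEigen | None = None, xatol: float = 1e-8
             ) -> VarianceComponents:
    """Maximize the profiled restricted likelihood over h2 in (0, 1).

    ``G`` may be an ndarray, a GenomicRelationship, or None when ``eig`` is
    given.  The standard error of h2 comes from the numerical curvature of
    the profile likelihood at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 phenotyped individuals, got {n}")
    if eig is None:
        A = G.matrix if isinstance(G, GenomicRelationship) else G
        eig = GrmEigen(A)
    y_t = eig.vectors.T @ y
    X_t = eig.vectors.T @ X
    d = eig.values

    def nll(h2: float) -> float:
        w, A_, _, q = _profile(y_t, X_t, d, h2)
        sigma2 = q / (n - p)
        _, logdet_A = np.linalg.slogdet(A_)
        return 0.5 * ((n - p) * (_LOG_2PI + np.log(sigma2) + 1.0)
                      + np.log(w).sum() + logdet_A)

    res = optimize.minimize_scalar(
        nll, bounds=(_H2_LO, _H2_HI), method="bounded", options={"xatol": xatol}
    )
    h2 = float(res.x)
    _, _, _, q = _profile(y_t, X_t, d, h2)
    sigma2_t = q / (n - p)
    loglik = -float(res.fun)

    # curvature of the profile likelihood -> SE of h2
    step = 1e-4
    lo, hi = max(_H2_LO, h2 - step), min(_H2_HI, h2 + step)
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    curv = (-nll(mid + half) + 2.0 * nll(mid) - nll(mid - half)) / half**2
    se_h2 = float(np.sqrt(-1.0 / curv)) if curv < 0 else float("nan")

    boundary = h2 <= _H2_LO + 1e-5 or h2 >= _H2_HI - 1e-5
    flat = abs(nll(_H2_LO + 1e-6) - nll(_H2_HI - 1e-6)) < 1e-10 and not np.isfinite(curv)
    return VarianceComponents(
        sigma2_a=h2 * sigma2_t,
        sigma2_e=(1.0 - h2) * sigma2_t,
        h2=h2,
        se_h2=se_h2,
        loglik=loglik,
        converged=bool(res.success) and not flat,
        boundary=boundary,
    )


def solve_gblup(obs_mask, y, X, G, vc: VarianceComponents, method: str = "conditional"
                ) -> GBLUPSolution:
    """Fixed effects by GLS plus breeding values for every individual in G.

    ``obs_mask`` marks the rows of G with observed phenotypes; ``y`` and ``X``
    hold those rows only, in G order.  Unphenotyped individuals borrow
    information through their G column ("conditional"), identically to the
    all-individual mixed-model equations with absent records ("mme").
    """
    A = G.matrix if isinstance(G, GenomicRelationship) else np.asarray(G, dtype=float)
    obs = np.asarray(obs_mask, dtype=bool)
    n_all = A.shape[0]
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if obs.sum() == 0:
        raise ValueError("no phenotyped individuals")
    if y.shape[0] != obs.sum() or X.shape[0] != obs.sum():
        raise ValueError("y/X rows must match the number of observed individuals")

    if vc.sigma2_a == 0.0:
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        return GBLUPSolution(b, np.zeros(n_all), vc)

    if method == "conditional":
        G_oo = A[np.ix_(obs, obs)]
        V = vc.sigma2_a * G_oo + vc.sigma2_e * np.eye(int(obs.sum()))
        cf = linalg.cho_factor(V)
        Vinv_X = linalg.cho_solve(cf, X)
        b = linalg.solve(X.T @ Vinv_X, Vinv_X.T @ y, assume_a="pos")
        resid = y - X @ b
        a_hat = vc.sigma2_a * (A[:, obs] @ linalg.cho_solve(cf, resid))
    elif method == "mme":
        lam = vc.sigma2_e / vc.sigma2_a
        Ginv, _ = invert_grm(A)
        Z = np.zeros((int(obs.sum()), n_all))
        Z[np.arange(int(obs.sum())), np.flatnonzero(obs)] = 1.0
        p = X.shape[1]
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ginv]])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = linalg.solve(C, rhs, assume_a="sym")
        b, a_hat = sol[:p], sol[p:]
    else:
        raise ValueError(f"unknown method {method!r}")
    return GBLUPSolution(np.asarray(b), np.asarray(a_hat), vc)


def estimate_h2_curve(dataset: GenotypeDataset, phenos: PhenotypeTable,
                      spec: MixedModelSpec, panels: list[SNPPanel]) -> pd.DataFrame:
    """REML heritability per panel, with G rebuilt on each panel's markers.

    Returns a tidy table (density, replicate, h2, se_h2, converged); allele
    frequencies are re-estimated on each panel.  Non-converged fits stay in
    the table flagged False so callers can exclude and count them.
    """
    y, X, obs = None, None, None
    rows = []
    ids = dataset.individual_ids
    y, X, obs = design_matrix(phenos, spec, ids)
    for panel in panels:
        sub = dataset.subset(markers=panel.marker_ids)
        G = build_grm(sub)
        try:
            vc = fit_reml(y, X, G.matrix[np.ix_(obs, obs)])
        except ValueError:
            rows.append((panel.density, panel.replicate_index, np.nan, np.nan, False))
            continue
        rows.append((panel.density, panel.replicate_index, vc.h2, vc.se_h2, vc.converged))
    return pd.DataFrame(rows, columns=["density", "replicate", "h2", "se_h2", "converged"])
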