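"""Replicated k-fold cross-validation of genomic prediction.

Phenotyped individuals are partitioned into k near-equal folds; per fold the
validation phenotypes are masked, variance components are re-estimated on
the training records, GBLUP predicts breeding values for everyone through G
(all individuals stay in G — masking removes phenotypes, not genotypes), and
accuracy is the Pearson correlation between predicted breeding values and
the held-out phenotypes divided by sqrt(h2_ref), where h2_ref is the
full-data, full-panel heritability for the trait.  Results aggregate into
per-density accuracy curves and proportion-of-full-panel-accuracy curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, PhenotypeTable
from .kinship import build_grm
from .panel_design import SNPPanel, full_panel
from .reml_gblup import (MixedModelSpec, VarianceComponents, design_matrix,
                         fit_reml, solve_gblup)

__all__ = [
    "FoldAssignment",
    "CVResult",
    "AccuracyCurve",
    "make_folds",
    "accuracy",
    "run_cv",
    "accuracy_curve",
    "loess_smooth",
    "evaluate_panels",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (1..k) per phenotyped individual, for one CV replicate."""

    ids: tuple[str, ...]
    fold_of: np.ndarray
    k: int
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_of, minlength=self.k + 1)[1:]
        if counts.sum() != len(self.ids) or counts.max() - counts.min() > 1:
            raise ValueError("folds must partition ids into near-equal parts")


@dataclass(frozen=True)
class CVResult:
    density: int
    panel_replicate: int
    cv_replicate: int
    fold: int
    r: float
    accuracy: float
    h2_ref: float


@dataclass
class AccuracyCurve:
    """Per-density aggregation of CV accuracies.

    ``table`` columns: density, mean_accuracy, sd_across_panels,
    proportion_of_full, range_across_panels (max - min of per-panel means).
    """

    table: pd.DataFrame
    full_density: int


def make_folds(ids, k: int = 5, replicate_seeds=(0,)) -> list[FoldAssignment]:
    """Random near-equal partitions, one per replicate seed.

    With n = q*k + r, the first r folds have q+1 members.
    """
    ids = tuple(ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} ids into {k} folds")
    out = []
    sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
    for rep, seed in enumerate(replicate_seeds, start=1):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        start = 0
        for f, size in enumerate(sizes, start=1):
            fold_of[perm[start:start + size]] = f
            start += size
        out.append(FoldAssignment(ids, fold_of, k, rep, int(seed)))
    return out


def accuracy(pred_ebv, observed_y, h2_ref: float) -> float:
    """Pearson r(EBV, phenotype) scaled by 1/sqrt(h2_ref).

    The scaling approximates the correlation with true breeding values, so
    values above 1 are possible and are reported as computed.
    """
    pred = np.asarray(pred_ebv, dtype=float)
    obs = np.asarray(observed_y, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("prediction and observation vectors must match, length >= 3")
    if not (0.0 < h2_ref <= 1.0):
        raise ValueError(f"h2_ref={h2_ref} outside (0, 1]")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("accuracy undefined: constant vector in validation set")
    r = float(np.corrcoef(pred, obs)[0, 1])
    return r / float(np.sqrt(h2_ref))


def run_cv(dataset: GenotypeDataset, phenos: PhenotypeTable, spec: MixedModelSpec,
           panel: SNPPanel, folds: list[FoldAssignment], h2_ref: float,
           fixed_components: VarianceComponents | None = None,
           prediction_sink: dict | None = None) -> list[CVResult]:
    """Cross-validate one panel; returns a CVResult per (replicate, fold).

    G is built on the panel's markers over all individuals (frequencies
    re-estimated on the panel); per training fold, variance components are
    re-fitted unless ``fixed_components`` is supplied, validation phenotypes
    never enter the fit.  Folds whose REML fit fails or does not converge are
    skipped (reported by their absence).  When ``prediction_sink`` is a dict
    it receives the validation EBV vector per (panel replicate, CV replicate,
    fold), which lets callers verify the masking contract directly.
    """
    sub = dataset.subset(markers=panel.marker_ids)
    G = build_grm(sub).matrix
    y, X, obs_mask = design_matrix(phenos, spec, dataset.individual_ids)
    phen_idx = np.flatnonzero(obs_mask)
    results: list[CVResult] = []
    for fa in folds:
        if len(fa.ids) != phen_idx.size:
            raise ValueError("fold assignment does not cover the phenotyped individuals")
        for f in range(1, fa.k + 1):
            val = fa.fold_of == f
            train_mask = np.zeros(dataset.n_individuals, dtype=bool)
            train_mask[phen_idx[~val]] = True
            y_tr, X_tr = y[~val], X[~val]
            if np.linalg.matrix_rank(X_tr) < X_tr.shape[1]:
                continue  # a factor level fell entirely into the validation fold
            try:
                vc = fixed_components or fit_reml(
                    y_tr, X_tr, G[np.ix_(train_mask, train_mask)]
                )
            except ValueError:
                continue
            if not vc.converged:
                continue
            sol = solve_gblup(train_mask, y_tr, X_tr, G, vc)
            pred = sol.breeding_values[phen_idx[val]]
            if prediction_sink is not None:
                prediction_sink[(panel.replicate_index, fa.replicate, f)] = pred.copy()
            try:
                acc = accuracy(pred, y[val], h2_ref)
            except ValueError:
                continue
            r = acc * float(np.sqrt(h2_ref))
            results.append(CVResult(panel.density, panel.replicate_index,
                                    fa.replicate, f, r, acc, h2_ref))
    return results


def accuracy_curve(results: list[CVResult], full_density: int) -> AccuracyCurve:
    """Aggregate fold-level results into the per-density curve.

    Mean and SD conventions: the mean pools every fold of every panel and CV
    replicate at a density; the SD and the max-min range are taken across the
    per-panel mean accuracies, matching how replicate-panel variability is
    usually displayed.
    """
    if not results:
        raise ValueError("no cross-validation results to aggregate")
    df = pd.DataFrame([r.__dict__ for r in results])
    if full_density not in set(df["density"]):
        raise ValueError(f"results lack the full-density ({full_density}) condition")
    per_panel = (
        df.groupby(["density", "panel_replicate"])["accuracy"].mean().reset_index()
    )
    rows = []
    full_mean = df.loc[df["density"] == full_density, "accuracy"].mean()
    for density, grp in df.groupby("density"):
        panel_means = per_panel.loc[per_panel["density"] == density, "accuracy"]
        rows.append(
            {
                "density": density,
                "mean_accuracy": grp["accuracy"].mean(),
                "sd_across_panels": panel_means.std(ddof=1) if len(panel_means) > 1 else 0.0,
                "proportion_of_full": grp["accuracy"].mean() / full_mean,
                "range_across_panels": panel_means.max() - panel_means.min(),
                "n_folds": len(grp),
            }
        )
    table = pd.DataFrame(rows).sort_values("density").reset_index(drop=True)
    return AccuracyCurve(table, full_density)


def loess_smooth(x, y, span: float = 0.75) -> np.ndarray:
    """Local quadratic regression with tricube weights, evaluated at x.

    Report-plot smoothing only; no numeric result depends on it.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 points")
    q = min(n, max(3, int(np.ceil(span * n))))
    out = np.empty(n)
    for i, x0 in enumerate(x):
        dist = np.abs(x - x0)
        idx = np.argsort(dist, kind="stable")[:q]
        dmax = dist[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (dist[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        t = x[idx] - x0
        B = np.column_stack([np.ones(idx.size), t, t**2])
        Bw = B * w[:, None]
        coef, *_ = np.linalg.lstsq(Bw.T @ B, Bw.T @ y[idx], rcond=None)
        out[i] = coef[0]
    return out


def evaluate_panels(dataset: GenotypeDataset, phenos: PhenotypeTable,
                    spec: MixedModelSpec, panels: list[SNPPanel],
                    cv_replicate_seeds, k: int = 5,
                    h2_ref: float | None = None,
                    ) -> tuple[list[CVResult], AccuracyCurve, VarianceComponents]:
    """Full-panel reference fit plus CV over a panel set, aggregated.

    The full marker set is appended as the reference density; its full-data
    REML heritability supplies the accuracy denominator for every density.
    """
    y, X, obs = design_matrix(phenos, spec, dataset.individual_ids)
    G_full = build_grm(dataset).matrix
    vc_full = fit_reml(y, X, G_full[np.ix_(obs, obs)])
    if h2_ref is None:
        h2_ref = vc_full.h2
    ids = tuple(dataset.individual_ids[obs])
    folds = make_folds(ids, k=k, replicate_seeds=cv_replicate_seeds)
    all_panels = list(panels) + [full_panel(dataset)]
    results: list[CVResult] = []
    for panel in all_panels:
        results.extend(run_cv(dataset, phenos, spec, panel, folds, h2_ref))
    curve = accuracy_curve(results, full_density=dataset.n_markers)
    return results, curve, vc_full
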