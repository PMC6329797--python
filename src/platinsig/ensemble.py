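"""GI50 threshold sweeps and AUC-weighted threshold-independent ensembles.

Shifting the GI50 cutoff relabels the panel and yields a different
optimized signature per threshold; the family of signatures is summarized
as a gene-frequency density map over GI50 intervals and combined into a
single ensemble whose decision function is the mean of the component
hyperplane distances weighted by each component's cross-validated AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core_data import DoseResponseTable, ExpressionMatrix, label_by_threshold
from .search import DEFAULT_C_GRID, DEFAULT_SIGMA_GRID, GeneSignature, derive_signature
from .svm import decision_score

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSweepResult:
    thresholds: list[float]
    signatures: dict[float, list[GeneSignature]]
    class_counts: dict[float, tuple[int, int]]  # threshold -> (n_sensitive, n_resistant)

    def all_signatures(self) -> list[GeneSignature]:
        return [s for t in self.thresholds for s in self.signatures[t]]

    def index_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            ns, nr = self.class_counts[t]
            for s in self.signatures[t]:
                rows.append({"threshold": t, "n_sensitive": ns, "n_resistant": nr,
                             "n_genes": len(s.genes), "objective_value": s.objective_value})
        return pd.DataFrame(rows)


def default_threshold_grid(gi50: DoseResponseTable, min_per_class: int = 2) -> list[float]:
    """Midpoints between consecutive unique GI50 values, keeping only cutoffs
    that leave at least ``min_per_class`` samples in each class."""
    u = np.unique(gi50.gi50)
    if len(u) < 3:
        raise ValueError("need at least 3 distinct GI50 values")
    mids = (u[:-1] + u[1:]) / 2.0
    grid = []
    for t in mids:
        ns = int((gi50.gi50 > t).sum())
        nr = len(gi50.gi50) - ns
        if ns >= min_per_class and nr >= min_per_class:
            grid.append(float(t))
    return grid


def sweep_thresholds(
    x: ExpressionMatrix,
    gi50: DoseResponseTable,
    start_genes,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    objective: str = "misclassification",
    threshold_grid: Sequence[float] | None = None,
) -> ThresholdSweepResult:
    """Derive one (or more, on ties) signature per usable GI50 cutoff."""
    grid = list(threshold_grid) if threshold_grid is not None else default_threshold_grid(gi50)
    if not grid:
        raise ValueError("empty threshold grid")
    thresholds: list[float] = []
    signatures: dict[float, list[GeneSignature]] = {}
    counts: dict[float, tuple[int, int]] = {}
    for t in grid:
        y = label_by_threshold(gi50, t)
        if y.n_sensitive < 2 or y.n_resistant < 2:
            logger.info("skipping threshold %.4g: degenerate labeling", t)
            continue
        sigs = derive_signature(x, y, start_genes, C_grid, sigma_grid, objective)
        thresholds.append(float(t))
        signatures[float(t)] = sigs
        counts[float(t)] = (y.n_sensitive, y.n_resistant)
    if not thresholds:
        raise ValueError("no usable thresholds in grid")
    return ThresholdSweepResult(thresholds, signatures, counts)


def gene_frequency_map(
    sweep: ThresholdSweepResult,
    category_map: dict[str, str] | None = None,
    intervals: Sequence[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Fraction of each interval's signatures containing each gene.

    Rows are ``(category, gene)``; columns are GI50 intervals. A gene
    missing from ``category_map`` lands in "uncategorized". By default each
    sweep threshold is its own (degenerate) interval.
    """
    if intervals is None:
        intervals = [(t, t) for t in sweep.thresholds]
    cols = [f"[{lo:g},{hi:g}]" for lo, hi in intervals]
    genes = sorted({g for s in sweep.all_signatures() for g in s.genes})
    cat = {g: (category_map or {}).get(g, "uncategorized") for g in genes}
    out = pd.DataFrame(0.0, index=pd.MultiIndex.from_tuples([(cat[g], g) for g in genes],
                                                            names=["category", "gene"]), columns=cols)
    for (lo, hi), col in zip(intervals, cols):
        sigs = [s for t in sweep.thresholds if lo <= t <= hi for s in sweep.signatures[t]]
        if not sigs:
            continue
        for g in genes:
            out.loc[(cat[g], g), col] = sum(g in s.genes for s in sigs) / len(sigs)
    return out


def plot_frequency_map(freq: pd.DataFrame, path: str | Path) -> None:
    """Render the density matrix as a grayscale heat map image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * freq.shape[1], 1 + 0.25 * freq.shape[0]))
    im = ax.imshow(freq.to_numpy(), cmap="Greys", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(freq.shape[1]), freq.columns, rotation=45, ha="right")
    ax.set_yticks(range(freq.shape[0]), [g for _, g in freq.index])
    fig.colorbar(im, ax=ax, label="signature frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class EnsembleModel:
    """AUC-weighted mean of component hyperplane distances."""

    components: list[GeneSignature]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.components) < 1:
            raise ValueError("ensemble needs at least one component")
        if self.weights.shape != (len(self.components),):
            raise ValueError("one weight per component required")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.weights.sum() == 0:
            raise ValueError("weights sum to zero")

    @property
    def genes(self) -> list[str]:
        return sorted({g for s in self.components for g in s.genes})


def component_auc(sig: GeneSignature) -> float:
    """AUC of a signature's cross-validated held-out scores vs training labels."""
    df = sig.cv.per_fold_predictions
    y = df["true"].to_numpy()
    if len(df) == 0 or len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, df["score"].to_numpy()))


def build_ensemble(
    signatures: Sequence[GeneSignature],
    weight_mode: str = "auc",
    interval: tuple[float, float] | None = None,
    top_k: int | None = None,
) -> EnsembleModel:
    """Combine signatures into an AUC-weighted (or uniform) ensemble.

    ``interval`` keeps only signatures derived within a GI50 threshold
    interval; ``top_k`` keeps the k highest-AUC components. Components with
    undefined AUC are excluded with a warning.
    """
    if weight_mode not in ("auc", "uniform"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    sigs = list(signatures)
    if interval is not None:
        lo, hi = interval
        sigs = [s for s in sigs if lo <= s.gi50_threshold <= hi]
    if not sigs:
        raise ValueError("no signatures left after filtering")
    aucs = np.array([component_auc(s) for s in sigs])
    bad = np.isnan(aucs)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} component(s) with undefined AUC")
        sigs = [s for s, b in zip(sigs, bad) if not b]
        aucs = aucs[~bad]
    if not sigs:
        raise ValueError("all components had undefined AUC")
    if top_k is not None:
        order = np.argsort(-aucs, kind="stable")[:top_k]
        sigs = [sigs[i] for i in order]
        aucs = aucs[order]
    weights = aucs if weight_mode == "auc" else np.ones(len(sigs))
    return EnsembleModel(sigs, weights)


def ensemble_score(e: EnsembleModel, sample: dict[str, float]) -> tuple[float, str]:
    """Weighted-mean composite score and predicted class for one sample."""
    scores = []
    for sig in e.components:
        missing = [g for g in sig.genes if g not in sample]
        if missing:
            raise KeyError(
                f"sample missing gene(s) {', '.join(missing)} required by the "
                f"signature at threshold {sig.gi50_threshold:g}"
            )
        scores.append(decision_score(sig.model, sample))
    s = float(np.dot(e.weights, scores) / e.weights.sum())
    return s, ("sensitive" if s >= 0 else "resistant")


def ensemble_scores_matrix(e: EnsembleModel, x: ExpressionMatrix) -> pd.DataFrame:
    """Composite and per-component scores for every sample of a matrix."""
    comp = np.empty((len(e.components), x.n_samples))
    for i, sig in enumerate(e.components):
        sub = x.subset_genes(sig.genes)
        comp[i] = sig.model.decision_scores(sub.values.T)
    composite = e.weights @ comp / e.weights.sum()
    df = pd.DataFrame(comp.T, index=x.sample_ids,
                      columns=[f"component_{i}" for i in range(len(e.components))])
    df.insert(0, "composite", composite)
    return df
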