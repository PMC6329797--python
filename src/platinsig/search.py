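"""Greedy backwards feature selection (BFS) over cross-validated SVMs.

Starting from the MFA-qualified candidate set, each round evaluates the
LOOCV objective of every leave-one-gene-out subset and removes the gene
whose exclusion yields the lowest cross-validated error (i.e. the gene
contributing the most error), repeating until one gene remains. The
visited subset with the globally lowest objective is the signature; all
tied optima are reported, since equally accurate signatures do occur.

An exhaustive-subset oracle (every non-empty subset, small gene counts
only) is provided for testing the greedy search.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_data import ExpressionMatrix, LabelVector
from .mfa import CandidateGeneSet
from .svm import CvEstimate, SvmHyperparams, SvmModel, loocv, train_svm

DEFAULT_C_GRID = (10.0, 100.0, 1000.0, 1e4, 1e5)
DEFAULT_SIGMA_GRID = (10.0, 100.0, 1000.0)


@dataclass
class GeneSignature:
    """An ordered gene subset with its hyperparameters and trained model."""

    genes: list[str]
    hyperparams: SvmHyperparams
    gi50_threshold: float
    objective: str
    objective_value: float
    model: SvmModel
    cv: CvEstimate
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a signature needs at least one gene")

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "C": self.hyperparams.C,
            "sigma": self.hyperparams.sigma,
            "gi50_threshold": self.gi50_threshold,
            "objective": self.objective,
            "objective_value": self.objective_value,
            "model": self.model.to_dict(),
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GeneSignature":
        d = json.loads(Path(path).read_text())
        model = SvmModel.from_dict(d["model"])
        # objective value is re-attachable without re-running CV
        cv = CvEstimate(d["objective"], d["objective_value"], pd.DataFrame(columns=["sample_id", "true", "predicted", "score"]))
        return cls(
            genes=list(d["genes"]),
            hyperparams=SvmHyperparams(d["C"], d["sigma"]),
            gi50_threshold=float(d["gi50_threshold"]),
            objective=d["objective"],
            objective_value=float(d["objective_value"]),
            model=model,
            cv=cv,
            provenance=list(d.get("provenance", [])),
        )

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance)


def recompute_cv(sig: GeneSignature) -> GeneSignature:
    """Re-run LOOCV from the model's stored training data.

    Used after deserialization, where the held-out per-fold scores (needed
    e.g. for AUC ensemble weights) are not persisted.
    """
    m = sig.model
    x = ExpressionMatrix(m.genes, m.training_sample_ids, m.training_X.T, "zscore")
    y = LabelVector(m.training_sample_ids, m.training_y, sig.gi50_threshold)
    sig.cv = loocv(x, y, sig.hyperparams, sig.objective, genes=sig.genes)
    sig.objective_value = sig.cv.value
    return sig


def _genes_of(start_genes) -> list[str]:
    if isinstance(start_genes, CandidateGeneSet):
        return list(start_genes.genes)
    return list(start_genes)


def _make_signature(x, y, genes, h, objective, value, cv, provenance) -> GeneSignature:
    model = train_svm(x, y, h, genes=genes)
    return GeneSignature(list(genes), h, y.threshold, objective, value, model, cv, provenance)


def backwards_feature_selection(
    x: ExpressionMatrix,
    y: LabelVector,
    start_genes: CandidateGeneSet | Sequence[str],
    h: SvmHyperparams,
    objective: str = "misclassification",
) -> list[GeneSignature]:
    """Greedy backward elimination; returns all co-optimal signatures.

    The first element is the primary signature (earliest-visited optimum);
    any further elements are visited subsets tied at the same objective
    value. Ties between removal candidates are broken lexicographically by
    gene id so the search is reproducible.
    """
    current = _genes_of(start_genes)
    if not current:
        raise ValueError("start gene set is empty")

    visited: list[tuple[list[str], float, CvEstimate]] = []
    provenance: list[dict] = []

    est = loocv(x, y, h, objective, genes=current)
    visited.append((list(current), est.value, est))
    provenance.append({"round": 0, "removed": None, "n_genes": len(current), "value": est.value})

    round_no = 0
    while len(current) > 1:
        round_no += 1
        best_gene = None
        best_val = None
        best_est = None
        for g in sorted(current):
            subset = [gg for gg in current if gg != g]
            e = loocv(x, y, h, objective, genes=subset)
            if best_val is None or e.value < best_val:
                best_gene, best_val, best_est = g, e.value, e
        current = [gg for gg in current if gg != best_gene]
        visited.append((list(current), best_val, best_est))
        provenance.append(
            {"round": round_no, "removed": best_gene, "n_genes": len(current), "value": best_val}
        )

    best_value = min(v for _, v, _ in visited)
    out = []
    for genes, val, cv in visited:
        if val == best_value:
            out.append(_make_signature(x, y, genes, h, objective, val, cv, list(provenance)))
    return out


def exhaustive_subset_oracle(
    x: ExpressionMatrix,
    y: LabelVector,
    genes: Sequence[str],
    h: SvmHyperparams,
    objective: str = "misclassification",
    max_genes: int = 12,
) -> tuple[list[str], float]:
    """Global optimum over every non-empty gene subset (testing oracle).

    Tie-break: lower objective, then fewer genes, then lexicographic order;
    refuses more than ``max_genes`` genes.
    """
    genes = list(genes)
    if len(genes) > max_genes:
        raise ValueError(f"{len(genes)} genes exceeds max_genes={max_genes}")
    best: tuple[float, int, tuple[str, ...]] | None = None
    for k in range(1, len(genes) + 1):
        for subset in itertools.combinations(sorted(genes), k):
            val = loocv(x, y, h, objective, genes=list(subset)).value
            key = (val, k, subset)
            if best is None or key < best:
                best = key
    assert best is not None
    return list(best[2]), best[0]


def derive_signature(
    x: ExpressionMatrix,
    y: LabelVector,
    start_genes: CandidateGeneSet | Sequence[str],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    objective: str = "misclassification",
    grid_per_step: bool = False,
) -> list[GeneSignature]:
    """Grid search wrapped around BFS; returns all co-optimal signatures.

    By default one BFS runs per (C, sigma) pair and the best signature over
    the whole grid wins (ties: lower objective value, then smaller C, then
    smaller sigma). With ``grid_per_step=True`` a single BFS runs in which
    every subset is scored by the best grid pair for that subset.
    """
    if grid_per_step:
        return _derive_grid_per_step(x, y, start_genes, C_grid, sigma_grid, objective)
    best_sigs: list[GeneSignature] = []
    best_key = None
    for C in sorted(set(float(c) for c in C_grid)):
        for s in sorted(set(float(v) for v in sigma_grid)):
            h = SvmHyperparams(C, s)
            sigs = backwards_feature_selection(x, y, start_genes, h, objective)
            key = (sigs[0].objective_value, C, s)
            if best_key is None or key < best_key:
                best_key = key
                best_sigs = sigs
    for sig in best_sigs:
        sig.provenance.append({"round": None, "removed": None, "n_genes": len(sig.genes),
                               "value": sig.objective_value, "grid": [list(map(float, C_grid)), list(map(float, sigma_grid))]})
    return best_sigs


def _derive_grid_per_step(x, y, start_genes, C_grid, sigma_grid, objective) -> list[GeneSignature]:
    from .svm import grid_search

    current = _genes_of(start_genes)
    visited = []
    h0, est0 = grid_search(x, y, C_grid, sigma_grid, objective, genes=current)
    visited.append((list(current), h0, est0))
    while len(current) > 1:
        best = None
        for g in sorted(current):
            subset = [gg for gg in current if gg != g]
            h, e = grid_search(x, y, C_grid, sigma_grid, objective, genes=subset)
            if best is None or e.value < best[3].value:
                best = (g, subset, h, e)
        current = best[1]
        visited.append((list(current), best[2], best[3]))
    best_value = min(e.value for _, _, e in visited)
    out = []
    for genes, h, e in visited:
        if e.value == best_value:
            out.append(_make_signature(x, y, genes, h, objective, e.value, e, []))
    return out
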