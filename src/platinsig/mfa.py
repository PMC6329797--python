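"""Multiple factor analysis (MFA) over grouped variable blocks.

MFA is a PCA generalization for data organized in blocks (here: gene
expression, copy number, and one or more GI50 response variables measured
on the same cell lines). Each variable is standardized, each block is
scaled by the reciprocal of its first singular value so no single block
dominates, and a global PCA is run on the weighted concatenation.
Variable loadings are reported as correlations of the original variables
with the global components (correlation-circle coordinates), so candidate
genes can be selected by the angular proximity of their loading vectors to
the response variable's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MfaResult:
    block_weights: dict[str, float]
    component_scores: np.ndarray  # samples x components
    variable_loadings: pd.DataFrame  # variables x components, in [-1, 1]
    explained_inertia: np.ndarray
    variable_blocks: dict[str, list[str]]  # variable -> blocks containing it
    sample_ids: list[str]

    def loading_vector(self, variable: str, n_components: int = 2, block: str | None = None) -> np.ndarray:
        key = variable if block is None else f"{block}:{variable}"
        if key not in self.variable_loadings.index:
            raise KeyError(f"variable {key!r} not in MFA result")
        return self.variable_loadings.loc[key].to_numpy()[:n_components]


@dataclass
class CandidateGeneSet:
    """Genes whose loading vectors align (directly or inversely) with GI50."""

    genes: list[str]
    direction: dict[str, str]  # gene -> "direct" | "inverse"
    evidence: dict[str, list[str]]  # gene -> blocks that drove selection
    similarity: dict[str, float]  # gene -> signed cosine similarity (strongest block)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("candidate genes must be unique")
        for g in self.genes:
            if g not in self.direction:
                raise ValueError(f"gene {g!r} lacks a direction")


def _standardize(block: np.ndarray) -> np.ndarray:
    # variables x samples; per-variable mean 0 / sd 1 (ddof=1)
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (block - mu) / sd


def run_mfa(
    blocks: list[tuple[str, pd.DataFrame]],
    n_components: int = 2,
    align_to: str | None = None,
) -> MfaResult:
    """Run MFA on named blocks of variables x samples data.

    Parameters
    ----------
    blocks
        ``(name, frame)`` pairs; each frame has variables in rows and the
        same sample columns in the same order.
    n_components
        Number of global components to retain (>= 2).
    align_to
        Optional variable key (``"block:variable"`` or bare variable name);
        component signs are flipped so its loading on component 1 is
        non-negative, resolving PCA sign indeterminacy deterministically.
    """
    if not blocks:
        raise ValueError("at least one block required")
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    name0, ref = blocks[0]
    samples = list(ref.columns)
    for name, frame in blocks:
        if list(frame.columns) != samples:
            raise ValueError(f"block {name!r} has mismatched samples")

    weighted_parts = []
    std_parts = []
    keys = []
    block_weights: dict[str, float] = {}
    variable_blocks: dict[str, list[str]] = {}
    for name, frame in blocks:
        z = _standardize(frame.to_numpy(float))
        s1 = np.linalg.svd(z, compute_uv=False)[0]
        w = 1.0 / s1 if s1 > 0 else 1.0
        block_weights[name] = float(w)
        weighted_parts.append(z * w)
        std_parts.append(z)
        for v in frame.index:
            keys.append(f"{name}:{v}")
            variable_blocks.setdefault(str(v), []).append(name)

    zw = np.vstack(weighted_parts)  # variables x samples
    zstd = np.vstack(std_parts)
    n = len(samples)
    k = min(n_components, min(n - 1, zw.shape[0]))
    u, s, vt = np.linalg.svd(zw.T, full_matrices=False)  # samples x variables
    scores = u[:, :k] * s[:k]
    # loadings as correlations of the original (standardized) variables with scores
    score_sd = scores.std(axis=0, ddof=1)
    score_sd = np.where(score_sd == 0, 1.0, score_sd)
    centred = scores - scores.mean(axis=0)
    load = (zstd @ centred) / ((n - 1) * zstd.std(axis=1, ddof=1, keepdims=True) * score_sd)
    load = np.clip(load, -1.0, 1.0)
    inertia = s**2 / (s**2).sum()

    loadings = pd.DataFrame(load, index=keys, columns=[f"comp{i+1}" for i in range(k)])
    result = MfaResult(block_weights, scores, loadings, inertia[:k], variable_blocks, samples)
    if align_to is not None:
        v = _resolve_key(result, align_to)
        for j in range(k):
            if result.variable_loadings.loc[v].iloc[j] < 0 and j == 0:
                result.component_scores[:, j] *= -1
                result.variable_loadings.iloc[:, j] *= -1
    return result


def _resolve_key(r: MfaResult, variable: str) -> str:
    if variable in r.variable_loadings.index:
        return variable
    matches = [k for k in r.variable_loadings.index if k.split(":", 1)[1] == variable]
    if not matches:
        raise KeyError(f"variable {variable!r} not in MFA result")
    return matches[0]


def variable_angle(r: MfaResult, a: str, b: str, n_components: int = 2) -> float:
    """Angle in degrees between two variables' loading vectors, in [0, 180]."""
    va = r.variable_loadings.loc[_resolve_key(r, a)].to_numpy()[:n_components]
    vb = r.variable_loadings.loc[_resolve_key(r, b)].to_numpy()[:n_components]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-length loading vector")
    cos = float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def select_correlated_genes(
    r: MfaResult,
    response_variable: str,
    min_abs_similarity: float = 0.5,
    n_components: int = 2,
    min_representation: float = 0.45,
) -> CandidateGeneSet:
    """Select genes whose loadings align with the response variable's.

    A gene qualifies when, in any block carrying it, (a) the cosine
    similarity between its loading vector (first ``n_components``
    components) and the response variable's exceeds ``min_abs_similarity``
    in absolute value, and (b) the gene is adequately represented in that
    component plane: its loading-vector length (the square root of the
    variance share the retained components explain for it) is at least
    ``min_representation``. Without (b), short noise loadings pointing
    anywhere would pass a pure angular cutoff by chance; requiring
    representation quality before reading the correlation circle is
    standard MFA practice. The sign of the strongest similarity sets the
    direction (positive -> direct, negative -> inverse).
    """
    resp_key = _resolve_key(r, response_variable)
    vr = r.variable_loadings.loc[resp_key].to_numpy()[:n_components]
    nr = np.linalg.norm(vr)
    if nr == 0:
        raise ValueError("response variable has a zero-length loading vector")

    genes: list[str] = []
    direction: dict[str, str] = {}
    evidence: dict[str, list[str]] = {}
    similarity: dict[str, float] = {}
    for key in r.variable_loadings.index:
        if key == resp_key:
            continue
        block, var = key.split(":", 1)
        v = r.variable_loadings.loc[key].to_numpy()[:n_components]
        nv = np.linalg.norm(v)
        if nv == 0 or nv < min_representation:
            continue
        cos = float(v @ vr / (nv * nr))
        if abs(cos) > min_abs_similarity:
            if var not in direction or abs(cos) > abs(similarity[var]):
                direction[var] = "direct" if cos > 0 else "inverse"
                similarity[var] = cos
            if var not in evidence:
                genes.append(var)
                evidence[var] = []
            evidence[var].append(block)
    return CandidateGeneSet(genes, direction, evidence, similarity)
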