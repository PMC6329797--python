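"""Core data containers and file I/O.

Expression matrices are genes x samples; dose-response tables carry one
continuous GI50 (or IC50) value per sample on a -log10 molar scale, so a
*larger* GI50 means the line is inhibited at a lower concentration, i.e.
more sensitive. Binary sensitive/resistant labels are derived by
thresholding GI50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SENSITIVE = "sensitive"
RESISTANT = "resistant"

PLATFORMS = ("microarray", "rnaseq", "zscore")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate {what}: {', '.join(dupes)}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifiers and a platform tag.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``; units depend on ``platform`` (log2 intensity for
    microarray, RSEM abundance for rnaseq, dimensionless for zscore).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: str = "microarray"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = []
        missing = []
        for g in genes:
            try:
                idx.append(self.gene_ids.index(g))
            except ValueError:
                missing.append(g)
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx], self.platform)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, idx], self.platform)


@dataclass
class DoseResponseTable:
    """Per-sample continuous GI50 on a -log10 molar scale (higher = more sensitive)."""

    sample_ids: list[str]
    gi50: np.ndarray
    drug: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gi50 = np.asarray(self.gi50, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        if self.gi50.shape != (len(self.sample_ids),):
            raise ValueError("one GI50 value required per sample")
        if not np.all(np.isfinite(self.gi50)):
            raise ValueError("GI50 values must be finite")

    def median(self) -> float:
        return float(np.median(self.gi50))


@dataclass
class LabelVector:
    """Binary sensitive/resistant labels at a given GI50 cutoff.

    ``y`` is 1 for sensitive, 0 for resistant (sensitive iff gi50 strictly
    above the threshold; ties are resistant).
    """

    sample_ids: list[str]
    y: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("one label per sample required")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("labels must be 0 (resistant) or 1 (sensitive)")

    @property
    def labels(self) -> list[str]:
        return [SENSITIVE if v else RESISTANT for v in self.y]

    @property
    def n_sensitive(self) -> int:
        return int(self.y.sum())

    @property
    def n_resistant(self) -> int:
        return int((1 - self.y).sum())


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_in_rows",
    platform: str = "microarray",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV or CSV, header row + id column).

    ``orientation`` is ``"genes_in_rows"`` or ``"samples_in_rows"``; the result
    always has genes in rows.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric value at row {row!r}, column {col!r} in {path}")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}")
    if orientation == "samples_in_rows":
        df = df.T
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(float), platform)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    m.to_frame().to_csv(path, sep=sep)


def read_dose_response(path: str | Path, drug: str = "") -> DoseResponseTable:
    """Read a two-column (sample_id, gi50) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"expected two columns (sample_id, gi50) in {path}")
    return DoseResponseTable(list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float), drug)


def write_dose_response(d: DoseResponseTable, path: str | Path) -> None:
    pd.DataFrame({"sample_id": d.sample_ids, "gi50": d.gi50}).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; '#' starts a comment."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def intersect_genes(model_genes: Sequence[str], available: Iterable[str]) -> list[str]:
    """Genes shared between a model and a dataset, with a warning for the rest.

    Identifier conversion is out of scope; when cell-line and patient data
    disagree, the usable universe is their intersection (order of
    ``model_genes`` preserved).
    """
    avail = set(available)
    common = [g for g in model_genes if g in avail]
    dropped = [g for g in model_genes if g not in avail]
    if dropped:
        warnings.warn(f"genes absent from dataset dropped: {', '.join(dropped)}")
    return common


# ---------------------------------------------------------------------------
# Transformations


def zscore_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores across samples (ddof=1); output platform 'zscore'.

    Zero-variance genes become all-zero rows with a warning so degenerate
    fixtures still run.
    """
    if m.platform == "zscore":
        raise ValueError("matrix is already z-scored")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        names = [m.gene_ids[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance genes mapped to zeros: {', '.join(names)}")
        sd = np.where(sd == 0, 1.0, sd)
    z = (m.values - mu) / sd
    z[flat, :] = 0.0
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), z, "zscore")


def label_by_threshold(d: DoseResponseTable, threshold: float) -> LabelVector:
    """Sensitive iff gi50 > threshold (ties resistant)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return LabelVector(list(d.sample_ids), (d.gi50 > threshold).astype(int), float(threshold))


def filter_low_expression(
    candidates: Iterable[str],
    patients: ExpressionMatrix,
    min_value: float = 5.0,
    majority_fraction: float = 0.5,
) -> list[str]:
    """Drop candidate genes barely expressed in the patient data.

    A gene is removed when its value falls below ``min_value`` in strictly
    more than ``majority_fraction`` of patients (RSEM < 5.0 in the majority,
    by default). Candidates absent from the matrix are excluded with a
    warning; survivor order is preserved.
    """
    if patients.platform != "rnaseq":
        raise ValueError("low-expression filtering expects RSEM-scale (rnaseq) patient data")
    kept = []
    missing = []
    for g in candidates:
        if g not in patients.gene_ids:
            missing.append(g)
            continue
        frac_low = float((patients.gene_row(g) < min_value).mean())
        if frac_low > majority_fraction:
            continue
        kept.append(g)
    if missing:
        warnings.warn(f"candidate genes absent from patient matrix: {', '.join(missing)}")
    return kept
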