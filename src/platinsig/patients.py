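"""Patient-cohort application and evaluation of cell-line-trained models.

Cell-line signatures are applied to patient z-scored expression without
retraining; outcome labels come from time-to-recurrence against a chosen
post-treatment threshold (recurrence at or before the threshold ->
resistant; disease-free beyond it -> sensitive; disease-free patients
censored before the threshold are excluded as uninformative). Reports
carry per-class accuracies, sensitivity/specificity, and a rank-sum
(Mann-Whitney) AUC over decision scores, optionally stratified by a
covariate such as smoking history. A stratified k-fold patient-only
cross-validation retrains SVM weights on patient data with the signature's
genes and hyperparameters fixed. Per-drug sensitivity probabilities
combine under an independence rule for combination chemotherapy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_data import ExpressionMatrix
from .ensemble import EnsembleModel, ensemble_scores_matrix
from .svm import SvmHyperparams, SvmModel


@dataclass
class PatientCohort:
    """Patient expression (patients as samples) plus outcome metadata.

    ``outcomes`` is indexed by patient id with columns ``recurrence``
    (0/1) and ``time_months`` (time to recurrence, or follow-up time for
    disease-free patients); ``covariates`` holds optional free-form
    columns (smoking status, stage, nodal status, ...).
    """

    expression: ExpressionMatrix
    outcomes: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        need = {"recurrence", "time_months"}
        if not need.issubset(self.outcomes.columns):
            raise ValueError(f"outcomes must have columns {sorted(need)}")
        missing = set(self.expression.sample_ids) - set(self.outcomes.index.astype(str))
        if missing:
            raise ValueError(f"patients without outcomes: {', '.join(sorted(missing)[:5])}")
        if (self.outcomes["time_months"] < 0).any():
            raise ValueError("times must be non-negative")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.expression.sample_ids)


@dataclass
class OutcomeLabeling:
    recurrence_threshold: float  # months
    labels: pd.Series  # patient -> "sensitive" | "resistant" | "excluded"

    @property
    def n_excluded(self) -> int:
        return int((self.labels == "excluded").sum())


def label_outcomes(c: PatientCohort, recurrence_threshold: float) -> OutcomeLabeling:
    """Binary outcome labels from time-to-recurrence.

    Resistant: recurrence at time <= threshold. Sensitive: disease-free
    with follow-up > threshold. Excluded: disease-free with follow-up <=
    threshold (too short to be informative).
    """
    if recurrence_threshold <= 0:
        raise ValueError("recurrence threshold must be positive")
    lab = {}
    for pid in c.patient_ids:
        rec = int(c.outcomes.loc[pid, "recurrence"])
        t = float(c.outcomes.loc[pid, "time_months"])
        if rec and t <= recurrence_threshold:
            lab[pid] = "resistant"
        elif t > recurrence_threshold:
            # recurrence after the threshold counts as sensitive at this horizon
            lab[pid] = "sensitive"
        else:
            lab[pid] = "excluded"
    return OutcomeLabeling(float(recurrence_threshold), pd.Series(lab, name="label"))


def predict_cohort(model: SvmModel | EnsembleModel, c: PatientCohort) -> pd.DataFrame:
    """Per-patient decision score (hu) and predicted class.

    The cohort expression must be z-scored; all model genes must be
    present (cross-platform identifier mismatches are not resolved here).
    """
    x = c.expression
    if x.platform != "zscore":
        raise ValueError("cohort expression must be z-scored before prediction")
    if isinstance(model, EnsembleModel):
        missing = [g for g in model.genes if g not in x.gene_ids]
        if missing:
            raise KeyError(f"cohort is missing model genes: {', '.join(missing)}")
        scores = ensemble_scores_matrix(model, x)["composite"].to_numpy()
    else:
        missing = [g for g in model.genes if g not in x.gene_ids]
        if missing:
            raise KeyError(f"cohort is missing model genes: {', '.join(missing)}")
        scores = model.decision_scores(x.subset_genes(model.genes).values.T)
    return pd.DataFrame(
        {"score_hu": scores, "predicted": np.where(scores >= 0, "sensitive", "resistant")},
        index=x.sample_ids,
    )


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney U) formulation, ties mid-ranked."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(scores)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class EvaluationReport:
    n_sensitive: int
    n_resistant: int
    accuracy: float
    accuracy_sensitive: float  # fraction of true-sensitive patients called sensitive
    accuracy_resistant: float
    sensitivity: float  # = accuracy_sensitive (sensitive is the positive class)
    specificity: float
    auc: float  # NaN when a class is absent
    per_stratum: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_sensitive", "n_resistant", "accuracy", "accuracy_sensitive",
              "accuracy_resistant", "sensitivity", "specificity", "auc")}
        if self.per_stratum:
            d["per_stratum"] = {k: v.to_dict() for k, v in self.per_stratum.items()}
        return d


def _report(pred: pd.DataFrame, truth: pd.Series) -> EvaluationReport:
    ids = truth.index
    yhat = (pred.loc[ids, "predicted"] == "sensitive").to_numpy()
    ytrue = (truth == "sensitive").to_numpy()
    tp = int((yhat & ytrue).sum())
    tn = int((~yhat & ~ytrue).sum())
    fp = int((yhat & ~ytrue).sum())
    fn = int((~yhat & ytrue).sum())
    n1, n0 = tp + fn, tn + fp
    acc_s = tp / n1 if n1 else float("nan")
    acc_r = tn / n0 if n0 else float("nan")
    auc = mann_whitney_auc(pred.loc[ids, "score_hu"].to_numpy(), ytrue.astype(int))
    return EvaluationReport(
        n_sensitive=n1, n_resistant=n0,
        accuracy=(tp + tn) / (n1 + n0),
        accuracy_sensitive=acc_s, accuracy_resistant=acc_r,
        sensitivity=acc_s, specificity=acc_r, auc=auc,
    )


def evaluate(
    pred: pd.DataFrame,
    labeling: OutcomeLabeling,
    strata: pd.Series | Mapping[str, str] | None = None,
) -> EvaluationReport:
    """Accuracy/sensitivity/specificity/AUC over non-excluded patients."""
    truth = labeling.labels[labeling.labels != "excluded"]
    truth = truth[truth.index.isin(pred.index)]
    if len(truth) == 0:
        raise ValueError("no non-excluded patients to evaluate")
    report = _report(pred, truth)
    if strata is not None:
        strata = pd.Series(strata)
        for value in sorted(strata.loc[truth.index].dropna().unique()):
            ids = truth.index[strata.loc[truth.index] == value]
            if len(ids):
                report.per_stratum[str(value)] = _report(pred, truth.loc[ids])
    return report


def kfold_patient_cv(
    genes: Sequence[str],
    hyperparams: SvmHyperparams,
    c: PatientCohort,
    labeling: OutcomeLabeling,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold CV on patient data with fixed genes/hyperparameters.

    Only SVM weights are re-learned per fold; gene set and (C, sigma) come
    from the cell-line-derived signature. Held-out predictions from all
    folds are pooled into a single report.
    """
    truth = labeling.labels[labeling.labels != "excluded"]
    ids = [p for p in c.patient_ids if p in truth.index]
    x = c.expression.subset_samples(ids)
    y = (truth.loc[ids] == "sensitive").to_numpy().astype(int)
    if y.sum() < k or (1 - y).sum() < k:
        raise ValueError(f"each class needs at least k={k} members")
    X = x.subset_genes(list(genes)).values.T
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(ids))
    for tr, te in skf.split(X, y):
        svc = SVC(C=hyperparams.C, kernel="rbf", gamma=hyperparams.gamma)
        svc.fit(X[tr], y[tr])
        scores[te] = svc.decision_function(X[te])
    pred = pd.DataFrame(
        {"score_hu": scores, "predicted": np.where(scores >= 0, "sensitive", "resistant")},
        index=ids,
    )
    return _report(pred, truth.loc[ids])


@dataclass
class DrugCombination:
    """Per-drug sensitivity probabilities, optionally with pooled pair terms.

    ``pairs`` maps a pair of drug names to a shared-feature estimate d_ij
    replacing the two individual terms in paired mode.
    """

    singles: dict[str, float]
    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in list(self.singles.values()) + list(self.pairs.values()):
            if not 0.0 <= v <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def combine_drug_probabilities(
    d: DrugCombination | Sequence[float],
    mode: str = "independent",
) -> tuple[float, float]:
    """(p_sensitive, p_resistant) for a drug combination.

    Independent mode: p_sensitive = 1 - prod(1 - d_i). Paired mode
    replaces each pooled pair's two terms with the supplied d_ij:
    p_sensitive = 1 - (1 - d_12) * (1 - d_3) * ... * (1 - d_k).
    """
    if mode not in ("independent", "paired"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(d, DrugCombination):
        terms = dict(d.singles)
        if mode == "paired":
            for (a, b), v in d.pairs.items():
                if a not in terms or b not in terms:
                    raise KeyError(f"pair ({a}, {b}) references unknown drugs")
                del terms[a], terms[b]
                terms[f"{a}+{b}"] = v
        probs = list(terms.values())
    else:
        probs = [float(v) for v in d]
        if mode == "paired":
            raise ValueError("paired mode requires a DrugCombination with pair estimates")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    p_resistant = float(np.prod([1.0 - p for p in probs]))
    return 1.0 - p_resistant, p_resistant
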