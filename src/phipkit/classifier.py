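"""Disease-status prediction from gene-level enrichment profiles.

An L1-penalized logistic regression is fit on log-transformed normalized
gene signal (reads-per-100k, pseudocounted, log10) and evaluated with
stratified k-fold cross-validation: the out-of-fold predicted probabilities
are pooled into a single ROC curve and AUC.  Coefficients reported for
ranking come from one final fit on all samples at the same penalty.

The feature transform uses only each sample's own total read count (no
cross-sample statistics), so applying it before the fold split leaks no
information between training and test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .counts_io import CountMatrix, SampleSheet, ValidationError

DEFAULT_SCALE = 1e5  # reads per 100k
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_LOG_BASE = 10.0


@dataclass
class FeatureMatrix:
    """Log-transformed normalized signal, genes × samples, with the exact
    transform recorded so it can be reproduced."""

    x: pd.DataFrame
    transform_spec: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.x.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.x.columns)


@dataclass
class CVResult:
    """Pooled cross-validation outcome of the serology classifier."""

    fold_assignment: pd.Series  # sample_id → test-fold index
    oof_probability: pd.Series  # sample_id → out-of-fold P(case)
    labels: pd.Series  # sample_id → 0/1
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    coefficients: pd.Series  # gene → weight from the final full-data fit
    l1_strength: float

    def top_genes(self, n: int = 20) -> pd.Series:
        return self.coefficients.reindex(
            self.coefficients.abs().sort_values(ascending=False).index
        ).head(n)


def build_features(
    gene_counts: CountMatrix,
    sheet: SampleSheet,
    scale: float = DEFAULT_SCALE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = DEFAULT_LOG_BASE,
) -> FeatureMatrix:
    """log(scale × pseudocounted read proportion) for case/control samples.

    With the defaults this is log10 of reads-per-100k: a gene at exactly 1%
    of a sample's reads maps to log10(1000) = 3.  Mock-IP samples are
    excluded.
    """
    if gene_counts.level != "gene":
        raise ValidationError("build_features expects gene-level counts")
    keep = [s for s in gene_counts.sample_ids
            if s in sheet.sample_ids and sheet.role_of(s) != "mock_ip"]
    cases = [s for s in keep if sheet.role_of(s) == "case"]
    controls = [s for s in keep if sheet.role_of(s) == "control"]
    if not cases or not controls:
        raise ValidationError("need at least one case and one control sample")
    c = gene_counts.counts[keep].to_numpy(dtype=float) + pseudocount
    prop = c / c.sum(axis=0, keepdims=True)
    x = np.log(scale * prop) / np.log(log_base)
    return FeatureMatrix(
        x=pd.DataFrame(x, index=gene_counts.counts.index, columns=keep),
        transform_spec={"scale": scale, "pseudocount": pseudocount,
                        "log_base": log_base},
    )


def fit_evaluate(
    fm: FeatureMatrix,
    sheet: SampleSheet,
    folds: int = 5,
    l1_strength: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of an L1 logistic regression (liblinear).

    ``l1_strength`` is scikit-learn's inverse regularization C.  Fold
    splits are seeded and stratified by label; the single reported AUC is
    computed from the pooled out-of-fold probabilities.
    """
    samples = fm.sample_ids
    y = pd.Series(
        [1 if sheet.role_of(s) == "case" else 0 for s in samples],
        index=samples, name="label",
    )
    if y.sum() < folds or (len(y) - y.sum()) < folds:
        raise ValidationError("each class needs at least `folds` samples")
    X = fm.x.to_numpy(dtype=float).T  # samples × genes

    def new_model() -> LogisticRegression:
        # lasso-penalized logistic likelihood, liblinear coordinate descent
        return LogisticRegression(l1_ratio=1.0, C=l1_strength, solver="liblinear",
                                  max_iter=2000, random_state=seed)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_idx = pd.Series(index=pd.Index(samples), dtype=int, name="fold")
    oof = pd.Series(index=pd.Index(samples), dtype=float, name="p_case")
    for k, (tr, te) in enumerate(skf.split(X, y)):
        model = new_model().fit(X[tr], y.iloc[tr])
        oof.iloc[te] = model.predict_proba(X[te])[:, 1]
        fold_idx.iloc[te] = k

    auc = float(roc_auc_score(y, oof))
    fpr, tpr, thr = roc_curve(y, oof)
    final = new_model().fit(X, y)
    coefficients = pd.Series(final.coef_.ravel(), index=fm.gene_ids, name="coef")
    return CVResult(
        fold_assignment=fold_idx,
        oof_probability=oof,
        labels=y,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=auc,
        coefficients=coefficients,
        l1_strength=l1_strength,
    )
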