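"""The ImGene nodal-stage predictor.

Two feature blocks — mIHC image features (ImFeatures: metacluster and CN
abundances) and genomic features (GeneFeatures: gene indicators, TMB, MATH,
mutation count) — each feed an SVM tuned by leave-one-out cross-validation
over a (C, kernel, gamma) grid.  Sub-model decision scores are min-max
calibrated on the training set; a classification cutoff is the score with
the highest validation accuracy.  A logistic regression integrates the two
calibrated scores:

    Z  = b0 + b_Im * ImScore + b_Gene * GeneScore
    Pr = exp(Z) / (1 + exp(Z))

with the intercept overridable to a fixed published value (3.51) for
formula-reproduction checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import LeaveOneOut
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from imgene.stats import InputError

logger = logging.getLogger(__name__)

#: default hyperparameter grid; the tuned parameters are the penalty C,
#: the kernel, and (for RBF) gamma
DEFAULT_GRID = {
    "C": [0.01, 0.1, 1.0, 10.0, 100.0],
    "kernel": ["linear", "rbf"],
    "gamma": [0.001, 0.01, 0.1, 1.0],
}


def select_features(coefficients: dict[str, float] | pd.Series, k: int = 10
                    ) -> list[str]:
    """Names of the k largest-|coefficient| features; ties lexicographic."""
    coeffs = pd.Series(coefficients)
    if coeffs.empty:
        raise InputError("no coefficients supplied")
    if len(coeffs) <= k:
        if len(coeffs) < k:
            logger.info("only %d features available (k=%d)", len(coeffs), k)
        return sorted(coeffs.index)
    order = sorted(coeffs.index, key=lambda n: (-abs(coeffs[n]), n))
    return sorted(order[:k])


def block_coefficients(X: pd.DataFrame, y, seed: int = 0) -> pd.Series:
    """Ranking coefficients for a feature block: L2 logistic regression on
    standardized features."""
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    lr = LogisticRegression(max_iter=2000, random_state=seed)
    lr.fit(Xs, np.asarray(y))
    return pd.Series(lr.coef_[0], index=X.columns)


@dataclass
class BlockModel:
    """A fitted single-block SVM with its score calibration and cutoff."""

    svm: SVC
    scaler: StandardScaler
    features: list[str]
    C: float
    kernel: str
    gamma: float | str
    loocv_accuracy: float
    score_min: float = 0.0
    score_max: float = 1.0
    cutoff: float = 0.5

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        """Decision scores min-max calibrated to [0, 1] on the training range."""
        Xs = self.scaler.transform(X[self.features].to_numpy(dtype=float))
        raw = self.svm.decision_function(Xs)
        span = self.score_max - self.score_min
        if span <= 0:
            return np.full(len(raw), 0.5)
        return np.clip((raw - self.score_min) / span, 0.0, 1.0)


def _grid_points(grid: dict) -> list[tuple[float, str, float | str]]:
    pts = []
    for C in grid["C"]:
        for kernel in grid["kernel"]:
            if kernel == "linear":
                pts.append((C, kernel, "scale"))
            else:
                for gamma in grid["gamma"]:
                    pts.append((C, kernel, gamma))
    return pts


def fit_block_svm(X: pd.DataFrame, y, grid: dict | None = None,
                  seed: int = 0) -> BlockModel:
    """Grid search maximizing leave-one-out CV accuracy, then refit.

    Zero-variance features are dropped with a warning.  The first grid
    point (in fixed grid order) among the LOOCV-accuracy maximizers wins,
    so duplicated data yield identical hyperparameters.
    """
    grid = grid or DEFAULT_GRID
    yv = np.asarray(y).astype(int)
    if len(np.unique(yv)) < 2:
        raise InputError("both classes required")
    X = pd.DataFrame(X)
    variances = X.var(axis=0)
    dead = list(variances.index[variances == 0])
    if dead:
        logger.warning("dropping zero-variance features: %s", dead)
        X = X.drop(columns=dead)
    feats = list(X.columns)
    scaler = StandardScaler().fit(X.to_numpy(dtype=float))
    Xs = scaler.transform(X.to_numpy(dtype=float))

    loo = LeaveOneOut()
    splits = list(loo.split(Xs))
    best = None
    for C, kernel, gamma in _grid_points(grid):
        correct = 0
        for tr, te in splits:
            if len(np.unique(yv[tr])) < 2:
                continue
            svm = SVC(C=C, kernel=kernel, gamma=gamma, random_state=seed)
            svm.fit(Xs[tr], yv[tr])
            correct += int(svm.predict(Xs[te])[0] == yv[te][0])
        acc = correct / len(splits)
        if best is None or acc > best[0]:
            best = (acc, C, kernel, gamma)
    acc, C, kernel, gamma = best
    svm = SVC(C=C, kernel=kernel, gamma=gamma, random_state=seed)
    svm.fit(Xs, yv)
    raw = svm.decision_function(Xs)
    return BlockModel(svm=svm, scaler=scaler, features=feats, C=C,
                      kernel=kernel, gamma=gamma, loocv_accuracy=acc,
                      score_min=float(raw.min()), score_max=float(raw.max()))


def choose_cutoff(scores, labels) -> float:
    """Score cutoff maximizing accuracy; ties resolve to the lower cutoff.

    Candidate cutoffs are the observed scores (and 0), so the choice never
    uses information beyond the provided (validation) scores and labels.
    """
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels).astype(int)
    candidates = np.unique(np.concatenate([[0.0], s]))
    best_cut, best_acc = candidates[0], -1.0
    for c in candidates:
        acc = float(np.mean((s >= c).astype(int) == yv))
        if acc > best_acc:
            best_acc, best_cut = acc, float(c)
    return best_cut


def integrate(im_score, gene_score, beta_im: float, beta_gene: float,
              intercept: float = 3.51):
    """Pr = expit(intercept + beta_Im * im_score + beta_Gene * gene_score)."""
    im = np.asarray(im_score, dtype=float)
    gene = np.asarray(gene_score, dtype=float)
    if not (np.all(np.isfinite(im)) and np.all(np.isfinite(gene))):
        raise InputError("scores must be finite")
    z = intercept + beta_im * im + beta_gene * gene
    out = expit(z)
    return float(out) if out.ndim == 0 else out


@dataclass
class EvalReport:
    auc: float | None
    f1: float
    accuracy: float


def evaluate(probabilities, cutoff: float, labels) -> EvalReport:
    """Rank-based ROC AUC plus F1 and accuracy at the given cutoff."""
    p = np.asarray(probabilities, dtype=float)
    yv = np.asarray(labels).astype(int)
    if len(np.unique(yv)) < 2:
        logger.warning("single-class labels: AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(yv, p))
    pred = (p >= cutoff).astype(int)
    return EvalReport(auc=auc,
                      f1=float(f1_score(yv, pred, zero_division=0)),
                      accuracy=float(accuracy_score(yv, pred)))


@dataclass
class ImGeneModel:
    """The integrated predictor: two block SVMs plus the fusion logistic."""

    im_block: BlockModel
    gene_block: BlockModel
    intercept: float
    beta_im: float
    beta_gene: float
    cutoff: float = 0.5

    def predict_proba(self, im_features: pd.DataFrame,
                      gene_features: pd.DataFrame) -> np.ndarray:
        return integrate(self.im_block.scores(im_features),
                         self.gene_block.scores(gene_features),
                         self.beta_im, self.beta_gene, self.intercept)


def train_imgene(im_features: pd.DataFrame, gene_features: pd.DataFrame,
                 labels: pd.Series, seed: int = 0, val_fraction: float = 0.3,
                 k_features: int = 10, grid: dict | None = None
                 ) -> tuple[ImGeneModel, dict[str, EvalReport]]:
    """Train the full ImGene model and report it against monomodal baselines.

    Patients present in only one block are dropped (logged).  The cohort is
    split into a training and a validation part (stratified); feature
    selection, SVM tuning and the integration logistic use the training
    part, cutoffs are chosen on validation scores, and the returned
    EvalReports are computed on the validation part.
    """
    labels = pd.Series(labels)
    common = im_features.index.intersection(gene_features.index).intersection(
        labels.index)
    dropped = (len(set(im_features.index) | set(gene_features.index)
                   | set(labels.index)) - len(common))
    if dropped:
        logger.info("dropped %d patients without matched features", dropped)
    im = im_features.loc[common]
    gene = gene_features.loc[common]
    y = labels.loc[common].astype(int)

    rng = np.random.default_rng(seed)
    val_idx = []
    for cls in (0, 1):
        ids = np.array(common[y == cls])
        n_val = max(1, int(round(val_fraction * len(ids))))
        val_idx.extend(rng.choice(ids, size=n_val, replace=False))
    val_mask = common.isin(val_idx)
    tr, va = common[~val_mask], common[val_mask]

    blocks: dict[str, BlockModel] = {}
    for name, feats in (("im", im), ("gene", gene)):
        coef = block_coefficients(feats.loc[tr], y.loc[tr], seed=seed)
        selected = select_features(coef, k=k_features)
        model = fit_block_svm(feats.loc[tr, selected], y.loc[tr],
                              grid=grid, seed=seed)
        model.cutoff = choose_cutoff(model.scores(feats.loc[va]), y.loc[va])
        blocks[name] = model

    im_tr = blocks["im"].scores(im.loc[tr])
    gene_tr = blocks["gene"].scores(gene.loc[tr])
    fusion = LogisticRegression(max_iter=2000, random_state=seed)
    fusion.fit(np.column_stack([im_tr, gene_tr]), y.loc[tr])
    model = ImGeneModel(im_block=blocks["im"], gene_block=blocks["gene"],
                        intercept=float(fusion.intercept_[0]),
                        beta_im=float(fusion.coef_[0][0]),
                        beta_gene=float(fusion.coef_[0][1]))
    model.cutoff = choose_cutoff(model.predict_proba(im.loc[va], gene.loc[va]),
                                 y.loc[va])

    reports = {
        "imgene": evaluate(model.predict_proba(im.loc[va], gene.loc[va]),
                           model.cutoff, y.loc[va]),
        "im_only": evaluate(blocks["im"].scores(im.loc[va]),
                            blocks["im"].cutoff, y.loc[va]),
        "gene_only": evaluate(blocks["gene"].scores(gene.loc[va]),
                              blocks["gene"].cutoff, y.loc[va]),
    }
    return model, reports


# ---------------------------------------------------------------------------
# feature construction from upstream stages
# ---------------------------------------------------------------------------

def build_feature_blocks(composition: pd.DataFrame,
                         cn_freq: pd.DataFrame | None,
                         muts: pd.DataFrame, summary: pd.DataFrame,
                         genes: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble ImFeatures (composition + CN abundances) and GeneFeatures
    (gene indicators + TMB/MATH/mutation count), aligned on patients."""
    im = composition.add_prefix("frac_")
    if cn_freq is not None:
        im = im.join(cn_freq.rename(columns=lambda c: f"cn{c}_frac"), how="inner")
    gene_ind = pd.DataFrame(
        {g: summary.index.isin(set(muts.loc[muts["gene"] == g, "patient_id"]))
         for g in genes}, index=summary.index).astype(float)
    gene_block = pd.concat([gene_ind, summary[["tmb", "mutation_count"]],
                            summary["math"].fillna(0.0)], axis=1)
    common = im.index.intersection(gene_block.index)
    return im.loc[common], gene_block.loc[common]
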