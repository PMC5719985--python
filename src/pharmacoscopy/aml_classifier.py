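"""Retrospective response classification over a drug-combination matrix.

Twenty AML bone-marrow samples (ten later achieving complete remission on
induction therapy, ten non-responders) were screened ex vivo through a
combination matrix of the three first-line drugs — 125 unique
drug-concentration combinations, four technical replicates.  Per matrix
point, an axis-aligned threshold separates the two classes; thresholds are
weighted by each point's AUROC, forming a decision surface ("ideal
separating hyperplane") over the grid.  A patient's integrated response
score is the AUROC-weighted mean of +-1 indicators of their mean readout
lying on the responder side of each threshold:

    score = sum_j w_j s_j / sum_j w_j,   s_j in {+1, -1},  w_j = AUROC_j

The score lies in [-1, 1]; leave-k-out cross-validation (k per class)
refits the surface on the training remainder and classifies held-out
patients by their score relative to a training-derived cut.

Three readouts are supported: ``rbf`` (relative blast fraction),
``total_blasts_rel`` (marker-positive viable count, DMSO-relative) and
``total_cells_rel`` (all viable cells, DMSO-relative).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

RESPONDER = "complete_remission"
NON_RESPONDER = "non_responder"
READOUTS = ("rbf", "total_blasts_rel", "total_cells_rel")


@dataclass
class DrugMatrixProfile:
    """One patient's replicate readouts over the combination matrix.

    ``values`` maps readout name -> DataFrame indexed by matrix point id
    (1..n_points) with one column per technical replicate.  All readouts
    are DMSO-normalised (control mean 1).
    """

    patient_id: str
    label: str
    values: dict[str, pd.DataFrame]

    def point_means(self, readout: str) -> np.ndarray:
        return self.values[readout].mean(axis=1).to_numpy()


@dataclass
class HyperplaneModel:
    """Axis-aligned per-point decision surface.

    orientation +1: the responder-like side of point j is *below* the
    threshold (stronger kill); -1: above.  Weights are per-point AUROCs
    after orientation, hence always in [0.5, 1].
    """

    point_ids: np.ndarray
    thresholds: np.ndarray
    weights: np.ndarray
    orientations: np.ndarray
    readout: str


@dataclass
class IntegratedScore:
    patient_id: str
    score: float
    readout: str


@dataclass
class CVResult:
    readout: str
    n_runs: int
    accuracies: np.ndarray
    mean_accuracy: float
    mean_auroc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray


def auroc(values_pos, values_neg, lower_is_positive: bool = False) -> float:
    """Area under the ROC curve by the Mann-Whitney convention.

    Probability that a random positive ranks on the positive side of a
    random negative; ties count 0.5.  With ``lower_is_positive`` smaller
    values indicate the positive class (the usual orientation for kill
    readouts).
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    x = np.r_[pos, neg]
    if lower_is_positive:
        x = -x
    if np.all(x == x[0]):
        return 0.5
    return float(roc_auc_score(y, x))


def _stack(profiles: list[DrugMatrixProfile], readout: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(patients x points) matrix of per-point replicate means, labels, point ids."""
    point_ids = profiles[0].values[readout].index.to_numpy()
    X = np.vstack([p.point_means(readout) for p in profiles])
    y = np.array([1 if p.label == RESPONDER else 0 for p in profiles])
    return X, y, point_ids


def _pointwise_auroc_lower(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column AUROC for 'lower value = responder', ties 0.5 (vectorised)."""
    ranks = stats.rankdata(X, axis=0)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    r_pos = ranks[y == 1].sum(axis=0)
    u_higher = r_pos - n_pos * (n_pos + 1) / 2
    return 1.0 - u_higher / (n_pos * n_neg)


def _fit_arrays(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit thresholds/weights/orientations from a (patients x points) matrix."""
    n, n_points = X.shape
    auc_lower = _pointwise_auroc_lower(X, y)
    orient = np.where(auc_lower >= 0.5, 1, -1)
    weights = np.where(auc_lower >= 0.5, auc_lower, 1.0 - auc_lower)

    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    # candidate threshold i sits between sorted positions i and i+1
    cand = (Xs[:-1] + Xs[1:]) / 2.0  # (n-1, points)
    resp_below = np.cumsum(ys, axis=0)[:-1]
    n_resp = y.sum()
    n_below = np.arange(1, n)[:, None]
    # accuracy when responder side is 'below'
    acc_plus = (resp_below + (n - n_resp) - (n_below - resp_below)) / n
    acc = np.where(orient == 1, acc_plus, 1.0 - acc_plus)

    mid = (X[y == 1].mean(axis=0) + X[y == 0].mean(axis=0)) / 2.0
    best = acc.max(axis=0)
    # tie-break: nearest candidate to the class-mean midpoint
    penalty = np.where(acc == best, np.abs(cand - mid), np.inf)
    pick = penalty.argmin(axis=0)
    thresholds = cand[pick, np.arange(n_points)]
    return thresholds, weights, orient


def _scores_arrays(
    X: np.ndarray, thresholds: np.ndarray, weights: np.ndarray, orient: np.ndarray
) -> np.ndarray:
    """Integrated scores for every row of X under a fitted surface."""
    on_side = np.where(orient == 1, X < thresholds, X > thresholds)
    s = np.where(on_side, 1.0, -1.0)
    return (s * weights).sum(axis=1) / weights.sum()


def fit_hyperplane(profiles: list[DrugMatrixProfile], readout: str = "rbf") -> HyperplaneModel:
    """Fit per-point thresholds, orientations and AUROC weights.

    Orientation is chosen so that each point's AUROC (for its
    responder-like side) is >= 0.5.  The threshold is the midpoint between
    consecutive sorted training values that maximises training accuracy at
    that point; among equally accurate candidates the one closest to the
    midpoint of the two class means is taken.
    """
    labels = {p.label for p in profiles}
    if labels != {RESPONDER, NON_RESPONDER}:
        raise ValueError(f"training set must contain both classes, got {sorted(labels)}")
    X, y, point_ids = _stack(profiles, readout)
    thresholds, weights, orient = _fit_arrays(X, y)
    return HyperplaneModel(point_ids, thresholds, weights, orient, readout)


def integrated_response_score(profile: DrugMatrixProfile, model: HyperplaneModel) -> IntegratedScore:
    """AUROC-weighted mean of per-point +-1 side indicators; in [-1, 1]."""
    v = profile.point_means(model.readout)
    on_responder_side = np.where(
        model.orientations == 1, v < model.thresholds, v > model.thresholds
    )
    s = np.where(on_responder_side, 1.0, -1.0)
    score = float((model.weights * s).sum() / model.weights.sum())
    return IntegratedScore(profile.patient_id, score, model.readout)


def _training_cut(train_scores: np.ndarray, train_y: np.ndarray) -> float:
    """Midpoint between training-score class means; 0 when classes coincide."""
    m1 = train_scores[train_y == 1].mean()
    m0 = train_scores[train_y == 0].mean()
    if np.isclose(m1, m0):
        return 0.0
    return float((m1 + m0) / 2.0)


def _roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC step curve (fpr, tpr) for 'higher score = responder'."""
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    tpr = np.r_[0.0, tp / max(ys.sum(), 1)]
    fpr = np.r_[0.0, fp / max((1 - ys).sum(), 1)]
    return fpr, tpr


def leave_k_out_cv(
    profiles: list[DrugMatrixProfile],
    readout: str = "rbf",
    k_per_class: int = 2,
    fpr_grid_size: int = 101,
) -> CVResult:
    """Leave-k-out-per-class cross-validation of the hyperplane classifier.

    Every combination of k responders and k non-responders is held out once
    (C(n1,k)*C(n0,k) runs; 2025 for the 10+10 preset at k=2).  Each run
    refits the surface on the remainder only, scores all patients, and
    classifies the held-out ones against the training-score cut.  The mean
    ROC is averaged vertically on a fixed false-positive-rate grid.
    """
    resp = [p for p in profiles if p.label == RESPONDER]
    non = [p for p in profiles if p.label == NON_RESPONDER]
    if k_per_class < 1 or k_per_class >= min(len(resp), len(non)):
        raise ValueError(
            f"k_per_class must be >= 1 and < class size ({len(resp)}, {len(non)})"
        )
    X, y, point_ids = _stack(profiles, readout)
    resp_idx = np.flatnonzero(y == 1)
    non_idx = np.flatnonzero(y == 0)

    fpr_grid = np.linspace(0.0, 1.0, fpr_grid_size)
    tpr_sum = np.zeros_like(fpr_grid)
    accuracies = []
    aurocs = []
    for held_r in itertools.combinations(resp_idx, k_per_class):
        for held_n in itertools.combinations(non_idx, k_per_class):
            held = np.array(held_r + held_n)
            train_mask = np.ones(len(profiles), bool)
            train_mask[held] = False
            thresholds, weights, orient = _fit_arrays(X[train_mask], y[train_mask])
            scores = _scores_arrays(X, thresholds, weights, orient)
            cut = _training_cut(scores[train_mask], y[train_mask])
            pred = (scores[held] > cut).astype(int)
            accuracies.append(float((pred == y[held]).mean()))
            hp, hn = scores[held][:k_per_class], scores[held][k_per_class:]
            aurocs.append(
                float(np.mean((hp[:, None] > hn) + 0.5 * (hp[:, None] == hn)))
            )
            fpr, tpr = _roc_points(scores[held], y[held])
            # step interpolation: TPR attained at FPR <= g
            idx = np.searchsorted(fpr, fpr_grid, side="right") - 1
            tpr_sum += tpr[idx]
    n_runs = len(accuracies)
    return CVResult(
        readout=readout,
        n_runs=n_runs,
        accuracies=np.asarray(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        mean_auroc=float(np.mean(aurocs)),
        fpr_grid=fpr_grid,
        mean_tpr=tpr_sum / n_runs,
    )


def readout_comparison(
    profiles: list[DrugMatrixProfile],
    readouts: tuple[str, ...] = READOUTS,
    k_per_class: int = 2,
) -> pd.DataFrame:
    """Cross-validated accuracy and AUROC for each cell-death readout.

    On cohorts where only the marker-positive subpopulation carries the
    class signal and blast fractions vary, the expected ordering is
    RBF >= total blasts >= total cells.
    """
    rows = []
    for readout in readouts:
        cv = leave_k_out_cv(profiles, readout=readout, k_per_class=k_per_class)
        rows.append(
            {
                "readout": readout,
                "mean_accuracy": cv.mean_accuracy,
                "mean_auroc": cv.mean_auroc,
                "n_runs": cv.n_runs,
            }
        )
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list[DrugMatrixProfile]) -> pd.DataFrame:
    """Long-format (patient, label, point_id, readout, replicate, value) table."""
    rows = []
    for p in profiles:
        for readout, df in p.values.items():
            long = df.stack()
            for (point, rep), val in long.items():
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "label": p.label,
                        "point_id": point,
                        "readout": readout,
                        "replicate": rep,
                        "value": val,
                    }
                )
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[DrugMatrixProfile]:
    profiles = []
    for pid, sub in df.groupby("patient_id", sort=True):
        label = sub["label"].iloc[0]
        values = {}
        for readout, rsub in sub.groupby("readout"):
            values[readout] = rsub.pivot(
                index="point_id", columns="replicate", values="value"
            )
        profiles.append(DrugMatrixProfile(str(pid), str(label), values))
    return profiles


def group_mean_heatmap(profiles: list[DrugMatrixProfile], readout: str = "rbf") -> pd.DataFrame:
    """Per-matrix-point class means, SEs, and one-sided Welch test (CR < NR)."""
    X, y, point_ids = _stack(profiles, readout)
    cr, nr = X[y == 1], X[y == 0]
    p = stats.ttest_ind(cr, nr, axis=0, equal_var=False, alternative="less").pvalue
    return pd.DataFrame(
        {
            "point_id": point_ids,
            "mean_cr": cr.mean(axis=0),
            "se_cr": cr.std(axis=0, ddof=1) / np.sqrt(len(cr)),
            "mean_nr": nr.mean(axis=0),
            "se_nr": nr.std(axis=0, ddof=1) / np.sqrt(len(nr)),
            "p_one_sided": p,
        }
    )
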