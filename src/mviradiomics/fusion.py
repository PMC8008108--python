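"""Top-model fusion and model comparison.

The three best-ranked (selector, classifier) models are fused either by
plurality voting (PV: majority of the members' hard labels) or by weighted
fusion (WF: a linear combination ``H(x) = sum_i w_i c_i(x)`` of member
probabilities with weights proportional to each member's validation
accuracy, ``w_i = acc_i / sum_k acc_k``).  Gains from fusion are quantified
by the categorical two-class Net Reclassification Improvement on predicted
labels, and model groups are compared by the Kruskal-Wallis rank test with
Bonferroni-corrected pairwise follow-ups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, ACC, SEN, SPE of probabilistic scores against binary truth."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = auc_mann_whitney(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "AUC": auc,
        "ACC": (tp + tn) / len(labels),
        "SEN": tp / (tp + fn) if tp + fn else 0.0,
        "SPE": tn / (tn + fp) if tn + fp else 0.0,
    }


# --------------------------------------------------------------------------
# fusion
# --------------------------------------------------------------------------

def plurality_vote(votes: np.ndarray) -> int:
    """Majority label of L binary hard votes; even-L ties go to the
    positive class (logged convention)."""
    votes = np.asarray(votes).astype(int)
    if votes.size < 2:
        raise ValueError("plurality vote needs at least 2 members")
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be binary")
    ones = int(votes.sum())
    zeros = votes.size - ones
    return 1 if ones >= zeros else 0


def compute_weights(accs) -> np.ndarray:
    """Validation-accuracy-proportional weights ``w_i = acc_i / sum(acc)``."""
    a = np.asarray(accs, dtype=float)
    if (a <= 0).any():
        raise ValueError("validation accuracies must be positive")
    return a / a.sum()


def weighted_fusion(
    member_probs: np.ndarray, weights: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Fused score ``H(x) = sum_i w_i c_i(x)`` and thresholded label.

    ``member_probs`` has shape (L,) for one case or (L, n) for a batch.
    """
    p = np.asarray(member_probs, dtype=float)
    if p.ndim == 1:
        p = p[:, None]  # L members, one case
    w = np.asarray(weights, dtype=float)
    if p.shape[0] != w.size:
        raise ValueError(
            f"{p.shape[0]} member probability rows but {w.size} weights"
        )
    if ((p < 0) | (p > 1)).any():
        raise ValueError("member probabilities must lie in [0, 1]")
    h = w @ p
    return h, (h >= threshold).astype(int)


def plurality_vote_batch(
    member_probs: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """PV labels for a batch: members vote with their own hard thresholds."""
    p = np.atleast_2d(np.asarray(member_probs, dtype=float))
    votes = (p >= threshold).astype(int)
    ones = votes.sum(axis=0)
    return (ones >= (votes.shape[0] - ones)).astype(int)


@dataclass
class EnsembleSpec:
    """A fused top-L model: member ids, their validation accuracies, mode."""

    members: list[str]
    validation_accuracies: np.ndarray
    mode: str = "WF"  # or "PV"

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.mode not in ("WF", "PV"):
            raise ValueError("mode must be 'WF' or 'PV'")
        self.validation_accuracies = np.asarray(
            self.validation_accuracies, dtype=float
        )
        if len(self.validation_accuracies) != len(self.members):
            raise ValueError("one validation accuracy per member required")

    @property
    def weights(self) -> np.ndarray:
        return compute_weights(self.validation_accuracies)

    def fuse(self, member_probs: np.ndarray, threshold: float = 0.5):
        """Fused scores and labels for a (L, n) probability matrix."""
        if self.mode == "WF":
            return weighted_fusion(member_probs, self.weights, threshold)
        labels = plurality_vote_batch(member_probs, threshold)
        return labels.astype(float), labels


# --------------------------------------------------------------------------
# NRI
# --------------------------------------------------------------------------

@dataclass
class NRIResult:
    """Categorical two-class net reclassification improvement."""

    nri: float
    event_up: float
    event_down: float
    nonevent_up: float
    nonevent_down: float
    baseline: str = "baseline"
    new: str = "new"


def nri(
    baseline_pred: np.ndarray,
    new_pred: np.ndarray,
    truth: np.ndarray,
    baseline_name: str = "baseline",
    new_name: str = "new",
) -> NRIResult:
    """NRI of ``new`` over ``baseline`` on predicted binary labels.

    ``NRI = [P(up|event) - P(down|event)] - [P(up|nonevent) - P(down|nonevent)]``
    where "up" is a move to the higher risk category (0 -> 1).
    """
    b = np.asarray(baseline_pred).astype(int)
    n = np.asarray(new_pred).astype(int)
    t = np.asarray(truth).astype(int)
    if not (len(b) == len(n) == len(t)):
        raise ValueError("prediction/truth lengths differ")
    events = t == 1
    nonevents = t == 0
    if not events.any() or not nonevents.any():
        raise ValueError("NRI requires both events and non-events")
    up = (n == 1) & (b == 0)
    down = (n == 0) & (b == 1)
    e_up = up[events].mean()
    e_down = down[events].mean()
    ne_up = up[nonevents].mean()
    ne_down = down[nonevents].mean()
    return NRIResult(
        nri=float((e_up - e_down) - (ne_up - ne_down)),
        event_up=float(e_up),
        event_down=float(e_down),
        nonevent_up=float(ne_up),
        nonevent_down=float(ne_down),
        baseline=baseline_name,
        new=new_name,
    )


def nri_matrix(predictions: dict[str, np.ndarray], truth: np.ndarray) -> pd.DataFrame:
    """Pairwise NRI table: entry (row, col) = NRI of row-model over col-model.

    Antisymmetric by construction: ``M[a, b] = -M[b, a]``.
    """
    names = list(predictions)
    m = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        val = nri(predictions[b], predictions[a], truth, b, a).nri
        m.loc[a, b] = val
        m.loc[b, a] = -val
    return m


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

def feature_group_test(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test plus Bonferroni-corrected pairwise tests.

    Pairwise comparisons use the two-sample Mann-Whitney U (the two-group
    special case of Kruskal-Wallis); adjusted p = min(1, p * n_pairs).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    samples = list(arrays.values())
    if np.ptp(np.concatenate(samples)) == 0:
        omnibus_p = 1.0  # all observations identical: no evidence of difference
    else:
        _, omnibus_p = stats.kruskal(*samples)
    pairs = list(itertools.combinations(arrays, 2))
    rows = []
    for a, b in pairs:
        if np.ptp(np.concatenate([arrays[a], arrays[b]])) == 0:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * len(pairs))),
            }
        )
    return {
        "omnibus_p": float(omnibus_p),
        "pairwise": pd.DataFrame(rows),
        "n_pairs": len(pairs),
    }
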