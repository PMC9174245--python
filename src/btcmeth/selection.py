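"""Biomarker filtering, replication, ROC evaluation and panel search.

The selection funnel mirrors a multi-cohort biomarker study:

1. keep islands hypermethylated in tumours (Δβ > 0.20, combined
   p < 0.05) whose normal-tissue mean β stays ≤ 0.20 — high normal β
   usually reflects methylation heterogeneity of non-tumour cells, not
   a usable marker;
2. require replication (Δβ > 0.20) in independent tumour cohorts;
3. drop markers also altered (|Δβ| > 0.20) in any other-cancer cohort,
   leaving disease-specific candidates;
4. quantify the replication overlap with an upper-tail hypergeometric
   test;
5. exhaustively search small marker combinations (size ≤ 3 by default)
   scored by validation AUC / sensitivity / specificity, with per-marker
   thresholds fit on training data only and an any-marker-positive (OR)
   combination rule.

The search is a transparent re-specification of proprietary
panel-ranking tools: it reproduces the observable contract — a
deterministic ranked list of compact panels — with explicit tie-breaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MarkerSet",
    "RocCurve",
    "BiomarkerPanel",
    "MarkerPanelClassifier",
    "filter_hyper_normal_low",
    "replicate_in",
    "specificity_filter",
    "overlap_enrichment",
    "roc",
    "choose_threshold",
    "panel_search",
]

DELTA_THRESH = 0.20
P_THRESH = 0.05
NORMAL_MAX = 0.20
MAX_CANDIDATES = 40


@dataclass(frozen=True)
class MarkerSet:
    """An ordered set of candidate CGI ids with filter provenance."""

    cgi_ids: tuple[str, ...]
    provenance: tuple[str, ...] = ()
    untestable: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.cgi_ids)

    def __iter__(self):
        return iter(self.cgi_ids)

    def narrowed(self, kept, tag: str, untestable=()) -> "MarkerSet":
        kept = tuple(c for c in self.cgi_ids if c in set(kept))
        return MarkerSet(
            cgi_ids=kept,
            provenance=self.provenance + (tag,),
            untestable=tuple(untestable),
        )


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class BiomarkerPanel:
    """One candidate marker combination with its fitted thresholds."""

    markers: tuple[str, ...]
    thresholds: dict[str, float]
    train_auc: float
    train_sensitivity: float
    train_specificity: float
    validation: dict[str, dict[str, float]] = field(default_factory=dict)
    fully_evaluated: bool = True

    @property
    def size(self) -> int:
        return len(self.markers)

    def mean_validation(self, key: str) -> float:
        vals = [v[key] for v in self.validation.values() if key in v]
        return float(np.mean(vals)) if vals else float("nan")


def filter_hyper_normal_low(
    records: pd.DataFrame,
    delta_thresh: float = DELTA_THRESH,
    p_thresh: float = P_THRESH,
    normal_max: float = NORMAL_MAX,
) -> MarkerSet:
    """Somatically hypermethylated islands with low normal-tissue β."""
    keep = records.index[
        (records["delta_beta"] > delta_thresh)
        & (records["combined_p"] < p_thresh)
        & (records["mean_beta_normal"] <= normal_max)
    ]
    return MarkerSet(tuple(keep), provenance=("hyper_normal_low",))


def replicate_in(
    marker_set: MarkerSet,
    other_records: pd.DataFrame,
    delta_thresh: float = DELTA_THRESH,
    require_normal_low: bool = False,
    normal_max: float = NORMAL_MAX,
    tag: str = "replicated",
) -> MarkerSet:
    """Keep markers whose hypermethylation replicates in another cohort.

    Markers absent from the other cohort are counted untestable and
    reported separately — never silently kept.
    """
    present = [c for c in marker_set if c in other_records.index]
    absent = [c for c in marker_set if c not in other_records.index]
    sub = other_records.loc[present]
    ok = sub["delta_beta"] > delta_thresh
    if require_normal_low:
        ok &= sub["mean_beta_normal"] <= normal_max
    return marker_set.narrowed(sub.index[ok], tag, untestable=absent)


def specificity_filter(
    marker_set: MarkerSet,
    other_cancers: dict[str, pd.DataFrame],
    delta_thresh: float = DELTA_THRESH,
) -> MarkerSet:
    """Remove markers altered (|Δβ| > threshold) in ANY other cancer.

    A marker missing from an other-cancer cohort cannot be excluded by
    it (counted as not-excluded there).
    """
    excluded: set[str] = set()
    for records in other_cancers.values():
        present = [c for c in marker_set if c in records.index]
        d = records.loc[present, "delta_beta"]
        excluded |= set(d.index[d.abs() > delta_thresh])
    kept = [c for c in marker_set if c not in excluded]
    return marker_set.narrowed(kept, "disease_specific")


def overlap_enrichment(
    k_overlap: int, n_set_a: int, n_set_b: int, n_universe: int
) -> float:
    """Upper-tail hypergeometric P(X ≥ k) for a set overlap.

    Draw ``n_set_a`` items from a universe of ``n_universe`` containing
    ``n_set_b`` successes; ``k_overlap`` is the observed overlap.
    Computed via the survival function, stable in log space.
    """
    if not (
        0 <= k_overlap <= min(n_set_a, n_set_b) <= n_universe
        and max(n_set_a, n_set_b) <= n_universe
    ):
        raise ValueError(
            f"inconsistent counts k={k_overlap}, |A|={n_set_a}, "
            f"|B|={n_set_b}, N={n_universe}"
        )
    return float(stats.hypergeom.sf(k_overlap - 1, n_universe, n_set_b,
                                    n_set_a))


def roc(scores, labels) -> RocCurve:
    """Empirical ROC curve and AUC (ties get half credit)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def choose_threshold(scores, labels, criterion: str = "youden") -> float:
    """Pick a positivity threshold (call positive iff score ≥ threshold).

    ``youden`` maximises TPR − FPR; ``accuracy`` maximises
    (TP + TN) / total. Candidate thresholds are the midpoints between
    consecutive distinct scores, the minimum score (call everything
    positive) and +inf (call everything negative); ties break toward
    the higher, more specific threshold. With all scores tied the
    result is +inf.
    """
    if criterion not in ("youden", "accuracy"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection needs both classes")
    u = np.unique(s)
    candidates = np.concatenate(
        [[np.inf], (u[1:] + u[:-1]) / 2.0, [u[0]]]
    )
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    best_val, best_thr = -np.inf, np.inf
    for t in candidates:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        if criterion == "youden":
            val = tp / n_pos - fp / n_neg
        else:
            tn = n_neg - fp
            val = (tp + tn) / len(y)
        # strict > keeps the highest (first-seen are higher) threshold on ties
        if val > best_val or (val == best_val and t > best_thr):
            best_val, best_thr = val, float(t)
    return best_thr


class MarkerPanelClassifier(BaseEstimator, ClassifierMixin):
    """Threshold-per-marker OR-rule classifier over CGI mean β.

    ``fit`` learns one positivity threshold per marker on the training
    samples (Youden by default); ``predict`` calls a sample positive if
    ANY member marker's β reaches its threshold; ``decision_function``
    returns the panel's continuous score (max member β by default),
    the score used for panel ROC analysis.

    Parameters
    ----------
    markers : sequence of str
        CGI ids forming the panel (columns of X).
    criterion : {'youden', 'accuracy'}
        Threshold-selection rule.
    score_agg : {'max', 'mean'}
        Continuous panel score aggregation.

    Attributes
    ----------
    thresholds_ : dict
        Fitted per-marker threshold.
    classes_ : ndarray
        Class labels (0 = normal, 1 = tumour).
    """

    def __init__(self, markers=(), criterion: str = "youden",
                 score_agg: str = "max"):
        self.markers = markers
        self.criterion = criterion
        self.score_agg = score_agg

    def _matrix(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [m for m in self.markers if m not in X.columns]
        if missing:
            raise KeyError(f"markers absent from input: {missing}")
        return X[list(self.markers)]

    def fit(self, X, y):
        """Fit per-marker thresholds on samples × markers β values."""
        if len(self.markers) == 0:
            raise ValueError("panel needs at least one marker")
        if self.score_agg not in ("max", "mean"):
            raise ValueError(f"unknown score_agg {self.score_agg!r}")
        Xm = self._matrix(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self.thresholds_ = {
            m: choose_threshold(Xm[m].to_numpy(), y, self.criterion)
            for m in self.markers
        }
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        Xm = self._matrix(X)
        agg = Xm.max(axis=1) if self.score_agg == "max" else Xm.mean(axis=1)
        return agg.to_numpy()

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        Xm = self._matrix(X)
        calls = np.zeros(len(Xm), dtype=bool)
        for m in self.markers:
            calls |= Xm[m].to_numpy() >= self.thresholds_[m]
        return calls.astype(int)


def _binary_metrics(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _labels_from_sheet(cgi_meth: pd.DataFrame, sheet: pd.DataFrame):
    y = (sheet.loc[cgi_meth.columns, "group"] == "tumour").astype(int)
    return cgi_meth.T, y.to_numpy()  # samples × CGIs


def panel_search(
    train_cgi_meth: pd.DataFrame,
    train_sheet: pd.DataFrame,
    candidates: MarkerSet,
    validation: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    max_size: int = 3,
    criterion: str = "youden",
    score_agg: str = "max",
) -> list[BiomarkerPanel]:
    """Exhaustively rank marker combinations of size ≤ ``max_size``.

    Parameters
    ----------
    train_cgi_meth, train_sheet
        Training island × sample matrix and its sample sheet; per-marker
        thresholds are fit here only.
    candidates
        At most 40 candidate CGIs (exhaustive search).
    validation
        Mapping cohort name → (cgi_meth, sheet); every panel is scored
        on every cohort. Panels with a member missing from some cohort
        are only partially evaluated and rank below fully evaluated
        ones.

    Returns
    -------
    list of BiomarkerPanel, best first. Ranking key: fully evaluated
    first, then mean validation AUC, mean sensitivity, mean specificity
    (all descending), then panel size ascending, then marker ids — a
    total, deterministic order independent of candidate input order.
    """
    ids = tuple(sorted(candidates))
    if len(ids) == 0:
        raise ValueError("no candidate markers to search")
    if len(ids) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(ids)} candidates exceed the exhaustive-search cap "
            f"({MAX_CANDIDATES}); pre-filter first"
        )
    Xtr, ytr = _labels_from_sheet(
        train_cgi_meth.loc[train_cgi_meth.index.intersection(ids)],
        train_sheet,
    )
    missing_train = [m for m in ids if m not in Xtr.columns]
    if missing_train:
        raise KeyError(f"candidates absent from training data: {missing_train}")

    # thresholds are per marker, independent of the panel: fit once
    thresholds = {
        m: choose_threshold(Xtr[m].to_numpy(), ytr, criterion) for m in ids
    }
    val_data = {
        name: _labels_from_sheet(cm, sh) for name, (cm, sh) in
        validation.items()
    }

    panels: list[BiomarkerPanel] = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(ids, size):
            clf = MarkerPanelClassifier(
                markers=combo, criterion=criterion, score_agg=score_agg
            )
            clf.thresholds_ = {m: thresholds[m] for m in combo}
            clf.classes_ = np.array([0, 1])
            tr_pred = clf.predict(Xtr)
            tr_sens, tr_spec = _binary_metrics(tr_pred, ytr)
            tr_auc = float(roc_auc_score(ytr, clf.decision_function(Xtr)))
            panel = BiomarkerPanel(
                markers=combo,
                thresholds=dict(clf.thresholds_),
                train_auc=tr_auc,
                train_sensitivity=tr_sens,
                train_specificity=tr_spec,
            )
            for name, (Xv, yv) in val_data.items():
                if any(m not in Xv.columns for m in combo):
                    panel.fully_evaluated = False
                    continue
                pred = clf.predict(Xv)
                sens, spec = _binary_metrics(pred, yv)
                auc = float(roc_auc_score(yv, clf.decision_function(Xv)))
                panel.validation[name] = {
                    "auc": auc, "sensitivity": sens, "specificity": spec
                }
            if not panel.validation:
                panel.fully_evaluated = False
            panels.append(panel)

    def key(p: BiomarkerPanel):
        return (
            0 if p.fully_evaluated else 1,
            -(p.mean_validation("auc") if p.validation else -np.inf),
            -(p.mean_validation("sensitivity") if p.validation else -np.inf),
            -(p.mean_validation("specificity") if p.validation else -np.inf),
            p.size,
            p.markers,
        )

    panels.sort(key=key)
    return panels


def panels_to_frame(panels: list[BiomarkerPanel]) -> pd.DataFrame:
    """Flatten a ranked panel list for TSV/JSON export."""
    rows = []
    for rank, p in enumerate(panels, start=1):
        rows.append(
            {
                "rank": rank,
                "markers": "|".join(p.markers),
                "size": p.size,
                "train_auc": p.train_auc,
                "train_sensitivity": p.train_sensitivity,
                "train_specificity": p.train_specificity,
                "mean_val_auc": p.mean_validation("auc"),
                "mean_val_sensitivity": p.mean_validation("sensitivity"),
                "mean_val_specificity": p.mean_validation("specificity"),
                "fully_evaluated": p.fully_evaluated,
            }
        )
    return pd.DataFrame(rows)
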