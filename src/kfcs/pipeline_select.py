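"""Forward classification and the threshold / channel selection machinery.

The forward path turns each epoch into a per-channel importance feature
vector (connectivity -> binarize -> K-order importance) and scores it with a
cross-validated RBF SVM.  Selection sweeps the binarization threshold over
the observed weight range, pools per-subject optima into a general optimal
threshold value (GOTV), groups channels by montage proximity and greedily
picks core channels by leave-one-out accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import ConnectivityMatrix, CsEnParams, connectivity_matrix, normalize_matrix
from .io_epochs import BRAKING, EpochSet, Montage, synthetic_montage
from .kprop import feature_vector, node_importance
from .netgraph import binarize
from .preprocess import DEFAULT_BAND, bandpass_epochs

__all__ = [
    "FeatureTable",
    "SweepResult",
    "GotvSummary",
    "KfcsConfig",
    "SubjectResult",
    "KfcsResult",
    "train_and_score",
    "compute_matrices",
    "features_at_threshold",
    "threshold_sweep",
    "gotv_summary",
    "knn_channel_groups",
    "select_core_nodes",
    "run_kfcs",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Epochs x channels importance features with binary labels."""

    X: np.ndarray
    labels: list[str]
    channel_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (epochs x channels)")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per row required")
        if len(set(self.labels)) > 2:
            raise ValueError("labels must be binary")
        if len(self.channel_labels) != self.X.shape[1]:
            raise ValueError("one channel label per column required")

    @property
    def y(self) -> np.ndarray:
        return np.array([1 if lb == BRAKING else 0 for lb in self.labels])

    def restrict(self, columns: Sequence[int]) -> "FeatureTable":
        cols = list(columns)
        return FeatureTable(self.X[:, cols], list(self.labels),
                            [self.channel_labels[c] for c in cols],
                            self.subject_id)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.channel_labels) + "\n")
            for lb, row in zip(self.labels, self.X):
                fh.write(lb + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class SweepResult:
    """Cross-validated accuracy across a threshold grid for one subject."""

    grid: np.ndarray
    accuracies: np.ndarray
    best_tri: float
    best_accuracy: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        if not np.any(np.isclose(self.grid, self.best_tri)):
            raise ValueError("best_tri must be a grid point")


@dataclass
class GotvSummary:
    """Per-subject optimal thresholds pooled into mean and sample sd."""

    thresholds: list[float]
    mean: float
    sd: float

    @property
    def mean_report(self) -> float:
        """Mean rounded to 2 decimals, the reporting convention."""
        return round(self.mean, 2)

    @property
    def sd_report(self) -> float:
        """Sample sd rounded to 3 decimals, the reporting convention."""
        return round(self.sd, 3)


@dataclass(frozen=True)
class KfcsConfig:
    """End-to-end pipeline settings."""

    csen: CsEnParams = CsEnParams()
    grid_size: int = 50
    folds: int = 10
    seed: int = 0
    edge_rule: str = "ge"
    knn_k: int = 3
    band: tuple[float, float] = DEFAULT_BAND
    normalize: bool = True
    feature_ordering: str = "channel"
    svm_c: float = 1.0


@dataclass
class SubjectResult:
    subject_id: str
    sweep: SweepResult
    adaptive_tri: float
    core_channels: list[int]
    baseline_accuracy: float
    final_accuracy: float


@dataclass
class KfcsResult:
    subjects: dict[str, SubjectResult]
    gotv: GotvSummary
    config: KfcsConfig

    @property
    def mean_final_accuracy(self) -> float:
        return float(np.mean([s.final_accuracy for s in self.subjects.values()]))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _make_svm(c: float = 1.0) -> Pipeline:
    # features standardized per training fold; gamma='scale' follows the
    # 1/(n_features * var) convention
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=c, gamma="scale")),
    ])


def train_and_score(features: FeatureTable, folds: int = 10, seed: int = 0,
                    svm_c: float = 1.0) -> float:
    """Stratified k-fold cross-validated accuracy of the standardized RBF SVM."""
    y = features.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} epochs for {folds}-fold CV "
            f"(have {counts.tolist()})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_make_svm(svm_c), features.X, y, cv=cv,
                             scoring="accuracy")
    return float(scores.mean())


def _loocv_accuracy(features: FeatureTable, svm_c: float = 1.0) -> float:
    scores = cross_val_score(_make_svm(svm_c), features.X, features.y,
                             cv=LeaveOneOut(), scoring="accuracy")
    return float(scores.mean())


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

def compute_matrices(
    epochs: EpochSet,
    params: CsEnParams = CsEnParams(),
    normalize: bool = True,
) -> list[ConnectivityMatrix]:
    """One (optionally min-max normalized) connectivity matrix per epoch."""
    mats = []
    for k in range(len(epochs)):
        m = connectivity_matrix(epochs.epochs[k], params,
                                channel_labels=list(epochs.channel_labels))
        mats.append(normalize_matrix(m) if normalize else m)
    return mats


def features_at_threshold(
    matrices: Sequence[ConnectivityMatrix],
    labels: Sequence[str],
    tri: float,
    rule: str = "ge",
    ordering: str = "channel",
    subject_id: str = "",
) -> FeatureTable:
    """Binarize every epoch's matrix at ``tri`` and extract importance features."""
    rows = []
    for m in matrices:
        iv = node_importance(binarize(m, tri, rule=rule))
        rows.append(feature_vector(iv, ordering=ordering))
    chans = matrices[0].channel_labels or [str(i) for i in range(matrices[0].n_channels)]
    return FeatureTable(np.vstack(rows), list(labels), list(chans), subject_id)


def threshold_sweep(
    epochs: EpochSet,
    grid_size: int = 50,
    params: CsEnParams = CsEnParams(),
    folds: int = 10,
    seed: int = 0,
    rule: str = "ge",
    normalize: bool = True,
    matrices: Sequence[ConnectivityMatrix] | None = None,
    svm_c: float = 1.0,
) -> SweepResult:
    """Cross-validated accuracy at ``grid_size`` evenly spaced thresholds.

    The grid spans the global min..max off-diagonal weight across the
    subject's matrices.  Ties at the maximum accuracy resolve to the
    smallest threshold.  Pass precomputed ``matrices`` to avoid repeating
    the entropy computation.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if matrices is None:
        matrices = compute_matrices(epochs, params, normalize=normalize)
    lo = min(float(m.offdiag().min()) for m in matrices)
    hi = max(float(m.offdiag().max()) for m in matrices)
    if hi == lo:
        raise ValueError("degenerate matrices: zero weight range")
    grid = np.linspace(lo, hi, grid_size)
    accs = np.empty(grid_size)
    for g, tri in enumerate(grid):
        table = features_at_threshold(matrices, epochs.labels, tri, rule=rule,
                                      subject_id=epochs.subject_id)
        accs[g] = train_and_score(table, folds=folds, seed=seed, svm_c=svm_c)
    best = int(np.argmax(accs))  # argmax returns the first (smallest-tri) maximum
    logger.info("sweep %s: best acc %.3f at tri %.4f", epochs.subject_id,
                accs[best], grid[best])
    return SweepResult(grid, accs, float(grid[best]), float(accs[best]),
                       epochs.subject_id)


def gotv_summary(best_tris: Sequence[float]) -> GotvSummary:
    """Pool per-subject optimal thresholds: mean and sample (n-1) sd."""
    tris = [float(t) for t in best_tris]
    if not tris:
        raise ValueError("empty threshold list")
    mean = float(np.mean(tris))
    if len(tris) == 1:
        warnings.warn("single-subject GOTV: sample sd undefined, reported as 0")
        sd = 0.0
    else:
        sd = float(np.std(tris, ddof=1))
    return GotvSummary(tris, mean, sd)


# ---------------------------------------------------------------------------
# Channel grouping and core-node selection
# ---------------------------------------------------------------------------

def knn_channel_groups(montage: Montage, k: int,
                       channel_labels: Sequence[str]) -> list[list[int]]:
    """For each channel i: the group {i} + its k nearest montage neighbours.

    Distance ties break toward the lower channel index; the result is fully
    deterministic and invariant to uniform montage scaling.
    """
    n = len(channel_labels)
    if k >= n:
        raise ValueError(f"k={k} must be < n_channels={n}")
    coords = montage.coords(channel_labels)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    groups = []
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))  # distance, then index
        neighbours = [int(j) for j in order if j != i][:k]
        groups.append(sorted([i] + neighbours))
    return groups


def select_core_nodes(
    features: FeatureTable,
    groups: Sequence[Sequence[int]],
    seed: int = 0,
    svm_c: float = 1.0,
) -> list[int]:
    """Greedy core-channel selection by leave-one-out accuracy.

    Each group i (centred on channel i) is scored by the LOOCV accuracy of
    the SVM restricted to its columns; groups are ranked by accuracy (ties
    toward the lower centre index) and their centres added greedily while
    the accumulated core set's LOOCV accuracy keeps improving.
    """
    if not groups:
        raise ValueError("empty group list")
    n = features.X.shape[1]
    covered = set()
    for g in groups:
        covered.update(g)
    if covered != set(range(n)):
        raise ValueError("groups must cover all channels")
    group_acc = np.array([
        _loocv_accuracy(features.restrict(g), svm_c=svm_c) for g in groups
    ])
    ranked = np.lexsort((np.arange(len(groups)), -group_acc))
    core = [int(ranked[0])]
    best = _loocv_accuracy(features.restrict(core), svm_c=svm_c)
    for centre in ranked[1:]:
        candidate = core + [int(centre)]
        acc = _loocv_accuracy(features.restrict(candidate), svm_c=svm_c)
        if acc > best:
            core, best = candidate, acc
        else:
            break
    logger.info("core channels %s (LOOCV acc %.3f)", core, best)
    return core


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _adaptive_threshold(sweep: SweepResult, gotv: GotvSummary) -> float:
    """Best-accuracy grid point within GOTV +/- 1 sd; nearest point if the
    window is empty."""
    lo, hi = gotv.mean - gotv.sd, gotv.mean + gotv.sd
    mask = (sweep.grid >= lo) & (sweep.grid <= hi)
    if not mask.any():
        return float(sweep.grid[np.argmin(np.abs(sweep.grid - gotv.mean))])
    idx = np.flatnonzero(mask)
    return float(sweep.grid[idx[np.argmax(sweep.accuracies[idx])]])


def run_kfcs(
    subjects: Mapping[str, EpochSet],
    config: KfcsConfig = KfcsConfig(),
    montage: Montage | None = None,
) -> KfcsResult:
    """Full pipeline over a cohort of epoch sets.

    Per subject: band-pass, per-epoch connectivity, threshold sweep.  Then
    the per-subject optima pool into the GOTV; each subject is re-evaluated
    at its adaptive threshold (best grid point within one sd of the GOTV)
    with montage-grouped core-channel selection, and the final stratified
    k-fold accuracy on the selected channels is reported alongside the
    all-channel baseline.  Deterministic given ``config.seed``.
    """
    if not subjects:
        raise ValueError("no subjects")
    sweeps: dict[str, SweepResult] = {}
    mats: dict[str, list[ConnectivityMatrix]] = {}
    cleaned: dict[str, EpochSet] = {}
    for idx, (sid, epochs) in enumerate(sorted(subjects.items())):
        es = bandpass_epochs(epochs, *config.band)
        cleaned[sid] = es
        mats[sid] = compute_matrices(es, config.csen, normalize=config.normalize)
        sweeps[sid] = threshold_sweep(
            es, grid_size=config.grid_size, params=config.csen,
            folds=config.folds, seed=config.seed + idx, rule=config.edge_rule,
            matrices=mats[sid], svm_c=config.svm_c,
        )
    gotv = gotv_summary([sweeps[sid].best_tri for sid in sorted(subjects)])
    results: dict[str, SubjectResult] = {}
    for idx, sid in enumerate(sorted(subjects)):
        es = cleaned[sid]
        tri = _adaptive_threshold(sweeps[sid], gotv)
        table = features_at_threshold(mats[sid], es.labels, tri,
                                      rule=config.edge_rule,
                                      ordering=config.feature_ordering,
                                      subject_id=sid)
        mont = montage if montage is not None else synthetic_montage(
            table.channel_labels)
        groups = knn_channel_groups(mont, config.knn_k, table.channel_labels)
        core = select_core_nodes(table, groups, seed=config.seed + idx,
                                 svm_c=config.svm_c)
        baseline = train_and_score(table, folds=config.folds,
                                   seed=config.seed + idx, svm_c=config.svm_c)
        final = train_and_score(table.restrict(core), folds=config.folds,
                                seed=config.seed + idx, svm_c=config.svm_c)
        results[sid] = SubjectResult(sid, sweeps[sid], tri, core, baseline, final)
        logger.info("%s: tri %.4f core %s baseline %.3f final %.3f",
                    sid, tri, core, baseline, final)
    return KfcsResult(results, gotv, config)
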