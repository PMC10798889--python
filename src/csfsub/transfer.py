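"""Cross-cohort subtype transfer with nested panels and balanced random forests.

Replication cohorts detect different protein panels, so classifiers are
trained on nested intersections of the discovery proteins with the
replication sets (largest overlap first, up to four panels).  Each training
repeat uses one shared 80/20 split across panels, SCUT class balancing
(SMOTE oversampling of minorities, cluster-centre undersampling of
majorities toward the mean class size) and a seeded random forest; held-out
accuracies are retained per repeat.  Predictions for a replication cohort
average class probabilities over repeats of the largest panel its proteins
cover, assigning each sample to the argmax subtype.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ContractError
from .io import SampleMetadata


@dataclasses.dataclass
class PanelSet:
    """Nested protein panels plus the cohort ordering that produced them."""

    panels: list[list[str]]
    cohort_order: list[str]

    def serving_panel(self, proteins: Sequence[str]) -> int:
        """Index of the largest panel fully contained in ``proteins``."""
        available = set(proteins)
        for idx, panel in enumerate(self.panels):
            if set(panel) <= available:
                return idx
        raise ContractError("no panel is covered by the supplied proteins")


def match_panels(
    discovery_proteins: Sequence[str],
    replication_protein_sets: Mapping[str, Sequence[str]],
    max_panels: int = 4,
) -> PanelSet:
    """Build nested panels by intersecting replication sets in overlap order.

    Cohorts are visited by descending overlap with the discovery proteins
    (ties broken lexicographically by cohort name); each panel is the
    running intersection.  An empty intersection is an error naming the
    offending cohort.
    """
    disc = set(discovery_proteins)
    if not disc or not replication_protein_sets:
        raise ContractError("protein sets must be non-empty")
    order = sorted(
        replication_protein_sets,
        key=lambda c: (-len(disc & set(replication_protein_sets[c])), str(c)),
    )
    panels: list[list[str]] = []
    current = disc
    for cohort in order[:max_panels]:
        current = current & set(replication_protein_sets[cohort])
        if not current:
            raise ContractError(
                f"no proteins shared with cohort {cohort!r}"
            )
        panels.append(sorted(current))
    return PanelSet(panels=panels, cohort_order=list(order[:max_panels]))


def scale_replication(
    matrix: pd.DataFrame, meta: SampleMetadata
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each protein to the replication cohort's own controls.

    ``matrix`` is proteins x samples on the log2 scale.  Proteins whose
    control s.d. is zero (or with <2 control observations) are dropped with
    a warning so a cohort-wide multiplicative batch factor cancels exactly
    for the rest.
    """
    groups = meta.groups()
    controls = [s for s in matrix.columns if groups.get(s) == "control"]
    if len(controls) < 2:
        raise ContractError("need at least 2 controls in the replication cohort")
    ctrl = matrix[controls]
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    n_ok = ctrl.notna().sum(axis=1)
    bad = (sd == 0) | sd.isna() | (n_ok < 2)
    notes = [f"protein {p} dropped: degenerate control scale" for p in matrix.index[bad]]
    kept = matrix.loc[~bad]
    scaled = kept.sub(mean[~bad], axis=0).div(sd[~bad], axis=0)
    return scaled, notes


def _smote_points(
    X: np.ndarray, n_new: int, rng: np.random.Generator, k_neighbors: int = 5
) -> np.ndarray:
    n = len(X)
    k = min(k_neighbors, n - 1)
    # pairwise distances within the class
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbors = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    other = neighbors[base, pick]
    return X[base] + u[:, None] * (X[other] - X[base])


def scut_balance(
    features, labels, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """SCUT-style class balancing toward the mean class size.

    Minority classes are oversampled with SMOTE (interpolation between a
    member and one of its ``k_neighbors`` nearest same-class neighbors);
    majority classes are undersampled by keeping the members nearest to
    k-means cluster centres.  Classes of size one are an error.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("need at least two classes")
    if counts.min() < 2:
        raise ContractError("every class needs at least two members")
    target = int(round(counts.mean()))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out_X, out_y = [], []
    for cls, count in zip(classes, counts):
        Xc = X[y == cls]
        if count == target:
            keep = Xc
        elif count < target:
            extra = _smote_points(Xc, target - count, rng, k_neighbors)
            keep = np.vstack([Xc, extra])
        else:
            km = KMeans(
                n_clusters=target,
                n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(Xc)
            reps = []
            for centre in km.cluster_centers_:
                idx = int(np.argmin(((Xc - centre) ** 2).sum(axis=1)))
                reps.append(Xc[idx])
            keep = np.asarray(reps)
        out_X.append(keep)
        out_y.append(np.full(len(keep), cls))
    return np.vstack(out_X), np.concatenate(out_y)


@dataclasses.dataclass
class RepeatResult:
    seed: int
    test_samples: list[str]
    forests: list[RandomForestClassifier]
    accuracies: list[float]


@dataclasses.dataclass
class ClassifierEnsemble:
    panels: PanelSet
    classes_: np.ndarray
    repeats: list[RepeatResult]
    n_repeats: int
    ntree: int
    seed: int

    def accuracy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.accuracies for r in self.repeats],
            columns=[f"panel_{i}" for i in range(len(self.panels.panels))],
        )


def train_subtype_classifiers(
    values: pd.DataFrame,
    labels: pd.Series,
    panels: PanelSet,
    n_repeats: int = 100,
    ntree: int = 1000,
    seed: int = 0,
    test_fraction: float = 0.2,
    balance: bool = True,
    max_redraws: int = 10,
) -> ClassifierEnsemble:
    """Repeatedly train one forest per panel on shared, balanced 80/20 splits.

    ``values`` is proteins x samples (discovery, control-scaled); ``labels``
    maps sample_id to subtype.  A repeat's split is redrawn (at most
    ``max_redraws`` times, logged via the repeat seed) when a subtype is
    missing from the training portion.
    """
    samples = [s for s in values.columns if s in labels.index]
    if not samples:
        raise ContractError("labels cover no sample")
    y_all = labels.loc[samples].to_numpy()
    classes = np.unique(y_all)
    if len(classes) < 2:
        raise ContractError("need at least two subtypes")
    feature_frames = [
        values.loc[panel, samples].T.to_numpy(dtype=float)
        for panel in panels.panels
    ]
    n = len(samples)
    n_test = max(1, int(round(test_fraction * n)))
    root = np.random.SeedSequence(seed)
    repeat_seeds = root.spawn(n_repeats)
    repeats: list[RepeatResult] = []
    for r, seq in enumerate(repeat_seeds):
        rng = np.random.default_rng(seq)
        for attempt in range(max_redraws + 1):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if set(classes) <= set(y_all[train_idx]):
                break
        else:
            raise ContractError(
                f"repeat {r}: a subtype was absent from training after "
                f"{max_redraws} redraws"
            )
        forests, accs = [], []
        for p_idx, feats in enumerate(feature_frames):
            X_train, y_train = feats[train_idx], y_all[train_idx]
            if balance:
                X_train, y_train = scut_balance(
                    X_train, y_train, seed=int(rng.integers(0, 2**31 - 1))
                )
            clf = RandomForestClassifier(
                n_estimators=ntree,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(X_train, y_train)
            acc = float(
                (clf.predict(feats[test_idx]) == y_all[test_idx]).mean()
            )
            forests.append(clf)
            accs.append(acc)
        repeats.append(
            RepeatResult(
                seed=int(seq.generate_state(1)[0]),
                test_samples=[samples[i] for i in test_idx],
                forests=forests,
                accuracies=accs,
            )
        )
    return ClassifierEnsemble(
        panels=panels,
        classes_=classes,
        repeats=repeats,
        n_repeats=n_repeats,
        ntree=ntree,
        seed=seed,
    )


def predict_subtypes(
    ensemble: ClassifierEnsemble,
    replication: pd.DataFrame,
    aggregate: str = "mean",
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Predict subtype labels for a scaled replication matrix (proteins x samples).

    Per-sample probabilities are the mean over repeats of each forest's vote
    fractions for the largest applicable panel (``aggregate='best'`` uses
    the single repeat with the highest held-out accuracy instead).  Labels
    are the argmax class; exact ties go to the lowest class index and are
    flagged.
    """
    p_idx = ensemble.panels.serving_panel(replication.index)
    panel = ensemble.panels.panels[p_idx]
    X = replication.loc[panel].T.to_numpy(dtype=float)
    sample_ids = list(replication.columns)
    classes = ensemble.classes_

    def proba_of(repeat: RepeatResult) -> np.ndarray:
        clf = repeat.forests[p_idx]
        raw = clf.predict_proba(X)
        out = np.zeros((len(X), len(classes)))
        for j, cls in enumerate(clf.classes_):
            out[:, list(classes).index(cls)] = raw[:, j]
        return out

    if aggregate == "best":
        best = max(ensemble.repeats, key=lambda r: r.accuracies[p_idx])
        probs = proba_of(best)
    else:
        probs = np.mean([proba_of(r) for r in ensemble.repeats], axis=0)
    flags = []
    idx = np.argmax(probs, axis=1)
    for i in range(len(X)):
        if np.sum(probs[i] == probs[i, idx[i]]) > 1:
            flags.append(f"sample {sample_ids[i]}: probability tie")
    labels = pd.Series(
        [classes[j] for j in idx], index=sample_ids, name="subtype"
    )
    prob_df = pd.DataFrame(probs, index=sample_ids, columns=list(classes))
    return labels, prob_df, flags
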