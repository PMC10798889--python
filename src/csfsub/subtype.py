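"""Consensus NMF subtyping with cophenetic / fit-improvement / silhouette selection.

Selected proteins are affinely rescaled into [1, 2] per protein, then for
each candidate rank k the positive matrix is factorized with seeded
multiplicative updates minimizing generalized Kullback-Leibler divergence,
repeated over independent random initializations.  Sample co-clustering
across runs yields a consensus matrix; candidate ranks are admissible when
the consensus-clustering silhouette exceeds 0.5 and the fit improvement over
rank k-1 is at least twice the improvement measured on a column-permuted
random reference.  Among admissible ranks the one with the highest
cophenetic coefficient wins (ties to the smallest k).  The best-run factors
provide dual cluster labels: samples by argmax of H columns, proteins by
argmax of W rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .exceptions import ContractError, DomainError
from .io import SampleMetadata
from .normalize import NormalizedMatrix

_EPS = 1e-12

Loss = Literal["kl", "frobenius"]


def scale_to_1_2(values: pd.DataFrame, proteins: Sequence[str] | None = None) -> pd.DataFrame:
    """Affinely map each protein's values into [1, 2], preserving order.

    Constant proteins map to 1.5.
    """
    sub = values.loc[list(proteins)] if proteins is not None else values
    if sub.empty:
        raise ContractError("protein subset is empty")
    lo = sub.min(axis=1)
    hi = sub.max(axis=1)
    span = hi - lo
    constant = span == 0
    span = span.replace(0, 1.0)
    out = sub.sub(lo, axis=0).div(span, axis=0) + 1.0
    out.loc[constant] = 1.5
    return out


@dataclasses.dataclass
class NMFRun:
    W: np.ndarray
    H: np.ndarray
    residual: float
    converged: bool
    objective_history: np.ndarray

    def sample_labels(self) -> np.ndarray:
        """0-based argmax component per sample (column of H)."""
        return np.argmax(self.H, axis=0)


def _kl_objective(X: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    return float(np.sum(X * np.log(X / WH) - X + WH))


def _nmf_single(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    loss: Loss,
) -> NMFRun:
    n, m = X.shape
    scale = np.sqrt(X.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * 2.0 * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * 2.0 * scale
    history = []
    prev = np.inf
    converged = False
    if loss == "kl":
        for _ in range(max_iter):
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            obj = _kl_objective(X, W @ H)
            history.append(obj)
            if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
                converged = True
                break
            prev = obj
    else:
        for _ in range(max_iter):
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ X) / np.maximum(W.T @ WH, _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= (X @ H.T) / np.maximum(WH @ H.T, _EPS)
            obj = float(np.linalg.norm(X - W @ H) ** 2)
            history.append(obj)
            if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
                converged = True
                break
            prev = obj
    return NMFRun(
        W=W,
        H=H,
        residual=history[-1],
        converged=converged,
        objective_history=np.asarray(history),
    )


def nmf_factorize(
    X,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    loss: Loss = "kl",
) -> list[NMFRun]:
    """Run seeded multiplicative-update NMF ``n_runs`` times.

    Each run draws an independent random initialization from a child of
    ``seed``; the objective is non-increasing within every run and runs are
    bit-reproducible from the seed.
    """
    arr = np.asarray(X, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise DomainError("NMF input must be strictly positive and finite")
    if not 1 <= k < min(arr.shape):
        raise ContractError(f"rank k={k} out of range for shape {arr.shape}")
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    return [
        _nmf_single(arr, k, np.random.default_rng(s), max_iter, tol, loss)
        for s in seeds
    ]


def consensus_matrix(runs: Sequence[NMFRun]) -> np.ndarray:
    """Fraction of runs in which each sample pair shares an argmax component."""
    if len(runs) < 2:
        raise ContractError("need at least 2 runs for a consensus matrix")
    m = runs[0].H.shape[1]
    C = np.zeros((m, m))
    for run in runs:
        labels = run.sample_labels()
        C += (labels[:, None] == labels[None, :]).astype(float)
    C /= len(runs)
    np.fill_diagonal(C, 1.0)
    return C


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Correlation between consensus distances and their dendrogram distances.

    Average-linkage hierarchical clustering on ``1 - C``; degenerate
    (zero-variance) distance sets return 1 by convention.
    """
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        return 1.0
    Z = linkage(condensed, method="average")
    coph, _ = cophenet(Z, condensed)
    if np.isnan(coph):
        return 1.0
    return float(coph)


def consensus_and_cophenetic(runs: Sequence[NMFRun], k: int | None = None):
    """Consensus matrix plus its cophenetic stability coefficient."""
    C = consensus_matrix(runs)
    return C, cophenetic_coefficient(C)


def consensus_labels(C: np.ndarray, k: int) -> np.ndarray:
    """Cut the average-linkage tree of (1 - C) into k clusters (labels 1..k)."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def silhouette(labels, distance) -> float:
    """Mean silhouette width over samples on a precomputed distance matrix.

    Singleton clusters contribute 0.  Requires at least two clusters, a
    symmetric distance matrix and a zero diagonal.
    """
    lab = np.asarray(labels)
    D = np.asarray(distance, dtype=float)
    n = len(lab)
    if D.shape != (n, n):
        raise ContractError("distance matrix shape mismatch")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ContractError("distance must be symmetric with zero diagonal")
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ContractError("silhouette needs at least two clusters")
    sizes = {c: int((lab == c).sum()) for c in clusters}
    scores = np.zeros(n)
    for i in range(n):
        own = lab[i]
        if sizes[own] == 1:
            scores[i] = 0.0
            continue
        mask_own = lab == own
        a = D[i, mask_own].sum() / (sizes[own] - 1)
        b = np.inf
        for c in clusters:
            if c == own:
                continue
            b = min(b, D[i, lab == c].mean())
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


@dataclasses.dataclass
class SubtypeModel:
    """Consensus-NMF model across candidate ranks with the selected solution."""

    k_range: tuple[int, ...]
    metrics: pd.DataFrame  # index k: fit, fit_rand, cophenetic, silhouette, rho, admissible
    selected_k: int | None
    consensus: dict[int, np.ndarray]
    best_runs: dict[int, NMFRun]
    sample_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    patient_labels: pd.Series | None = None
    protein_cluster_labels: pd.Series | None = None
    ties: list[str] = dataclasses.field(default_factory=list)

    def labels_for_k(self, k: int) -> pd.Series:
        run = self.best_runs[k]
        return pd.Series(
            run.sample_labels() + 1, index=list(self.sample_ids), name="subtype"
        )

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "k_range": list(self.k_range),
            "selected_k": self.selected_k,
            "sample_ids": list(self.sample_ids),
            "protein_ids": list(self.protein_ids),
            "ties": self.ties,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        self.metrics.to_csv(path / "metrics.tsv", sep="\t", index_label="k")
        if self.patient_labels is not None:
            self.patient_labels.rename("subtype").to_csv(
                path / "patient_labels.tsv", sep="\t", index_label="sample_id"
            )
        if self.protein_cluster_labels is not None:
            self.protein_cluster_labels.rename("cluster").to_csv(
                path / "protein_clusters.tsv", sep="\t", index_label="protein"
            )
        if self.selected_k is not None:
            run = self.best_runs[self.selected_k]
            pd.DataFrame(run.W, index=list(self.protein_ids)).to_csv(
                path / "W.tsv", sep="\t", index_label="protein"
            )
            pd.DataFrame(run.H, columns=list(self.sample_ids)).to_csv(
                path / "H.tsv", sep="\t", index_label="component"
            )
            pd.DataFrame(
                self.consensus[self.selected_k],
                index=list(self.sample_ids),
                columns=list(self.sample_ids),
            ).to_csv(path / "consensus.tsv", sep="\t", index_label="sample_id")


def assign_dual_clusters(model: SubtypeModel) -> tuple[pd.Series, pd.Series]:
    """Label samples by argmax of H columns and proteins by argmax of W rows.

    Labels are 1-based; ties break toward the lowest component and are
    recorded on the model.
    """
    if model.selected_k is None:
        raise ContractError("model has no selected_k")
    run = model.best_runs[model.selected_k]
    H, W = run.H, run.W
    patient = np.argmax(H, axis=0)
    for j in range(H.shape[1]):
        if np.sum(H[:, j] == H[patient[j], j]) > 1:
            model.ties.append(f"sample {model.sample_ids[j]} tied")
    protein = np.argmax(W, axis=1)
    for i in range(W.shape[0]):
        if np.sum(W[i, :] == W[i, protein[i]]) > 1:
            model.ties.append(f"protein {model.protein_ids[i]} tied")
    patient_labels = pd.Series(
        patient + 1, index=list(model.sample_ids), name="subtype"
    )
    protein_labels = pd.Series(
        protein + 1, index=list(model.protein_ids), name="cluster"
    )
    model.patient_labels = patient_labels
    model.protein_cluster_labels = protein_labels
    return patient_labels, protein_labels


def _permute_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row's values across samples (random reference)."""
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = X[i, rng.permutation(X.shape[1])]
    return out


def select_k(
    X,
    k_range: Iterable[int] = range(2, 11),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    loss: Loss = "kl",
    silhouette_min: float = 0.5,
    rho_min: float = 2.0,
    rule: Literal["largest_admissible", "max_cophenetic"] = "largest_admissible",
    sample_ids: Sequence[str] | None = None,
    protein_ids: Sequence[str] | None = None,
) -> SubtypeModel:
    """Fit consensus NMF across ranks and apply the three-criterion selection.

    Fit at each rank is the best-run residual; the improvement ratio is
    ``rho(k) = [fit(k-1) - fit(k)] / [fit_rand(k-1) - fit_rand(k)]`` with the
    random reference a per-protein column permutation of X.  Admissible ranks
    need silhouette > ``silhouette_min`` and ``rho >= rho_min``.  The default
    rule picks the largest admissible rank: coarse merges of true clusters
    are perfectly stable, so maximizing cophenetic over admissible ranks
    (``rule="max_cophenetic"``, ties to the smallest k) systematically
    under-splits, while the fit-improvement ratio collapses right above the
    true rank.  Cophenetic stays reported per rank either way.  If no rank
    is admissible ``selected_k`` is None and the metric table is still
    returned.
    """
    if isinstance(X, pd.DataFrame):
        protein_ids = protein_ids or list(X.index)
        sample_ids = sample_ids or list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
        protein_ids = protein_ids or [f"p{i}" for i in range(arr.shape[0])]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ContractError("k_range must contain integers >= 2")

    root = np.random.SeedSequence(seed)
    s_rand, s_real, s_ref = root.spawn(3)
    X_rand = _permute_columns(arr, np.random.default_rng(s_rand))

    fit_ks = sorted(set(ks) | {k - 1 for k in ks})
    real_seeds = {k: s for k, s in zip(fit_ks, s_real.spawn(len(fit_ks)))}
    rand_seeds = {k: s for k, s in zip(fit_ks, s_ref.spawn(len(fit_ks)))}

    fits: dict[int, float] = {}
    fits_rand: dict[int, float] = {}
    runs_at: dict[int, list[NMFRun]] = {}
    for k in fit_ks:
        seeds = real_seeds[k].spawn(n_runs)
        runs = [
            _nmf_single(arr, k, np.random.default_rng(s), max_iter, tol, loss)
            for s in seeds
        ]
        runs_at[k] = runs
        fits[k] = min(r.residual for r in runs)
        rseeds = rand_seeds[k].spawn(n_runs)
        rruns = [
            _nmf_single(X_rand, k, np.random.default_rng(s), max_iter, tol, loss)
            for s in rseeds
        ]
        fits_rand[k] = min(r.residual for r in rruns)

    rows = []
    consensus: dict[int, np.ndarray] = {}
    best_runs: dict[int, NMFRun] = {}
    for k in ks:
        runs = runs_at[k]
        C = consensus_matrix(runs)
        coph = cophenetic_coefficient(C)
        labels = consensus_labels(C, k)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        if len(np.unique(labels)) < 2:
            sil = np.nan
        else:
            sil = silhouette(labels, D)
        num = fits[k - 1] - fits[k]
        den = fits_rand[k - 1] - fits_rand[k]
        if den <= 0:
            rho = np.inf if num > 0 else np.nan
        else:
            rho = num / den
        admissible = bool(
            np.isfinite(sil) and sil > silhouette_min
            and not np.isnan(rho) and rho >= rho_min
        )
        rows.append(
            {
                "k": k,
                "fit": fits[k],
                "fit_rand": fits_rand[k],
                "cophenetic": coph,
                "silhouette": sil,
                "rho": rho,
                "admissible": admissible,
            }
        )
        consensus[k] = C
        # representative run: argmax labels most consistent with the consensus
        # partition (near-tied residuals can differ wildly in labeling), ties
        # broken by residual
        best_runs[k] = min(
            runs,
            key=lambda r: (-adjusted_rand_score(labels, r.sample_labels()), r.residual),
        )

    metrics = pd.DataFrame(rows).set_index("k")
    admissible_ks = metrics.index[metrics["admissible"]]
    if len(admissible_ks) == 0:
        selected = None
    elif rule == "max_cophenetic":
        best_coph = metrics.loc[admissible_ks, "cophenetic"].max()
        winners = [
            k for k in admissible_ks
            if metrics.loc[k, "cophenetic"] == best_coph
        ]
        selected = int(min(winners))
    else:
        selected = int(max(admissible_ks))

    model = SubtypeModel(
        k_range=tuple(ks),
        metrics=metrics,
        selected_k=selected,
        consensus=consensus,
        best_runs=best_runs,
        sample_ids=tuple(sample_ids),
        protein_ids=tuple(protein_ids),
    )
    if selected is not None:
        assign_dual_clusters(model)
    return model


def fit_subtypes(
    norm: NormalizedMatrix,
    proteins: Sequence[str],
    meta: SampleMetadata,
    k_range: Iterable[int] = range(2, 11),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    loss: Loss = "kl",
    rule: Literal["largest_admissible", "max_cophenetic"] = "largest_admissible",
) -> SubtypeModel:
    """Scale selected proteins to [1, 2] over AD samples and run model selection."""
    groups = meta.groups()
    ad_samples = [s for s in norm.sample_ids if groups.get(s) == "AD"]
    if len(ad_samples) < 4:
        raise ContractError("too few AD samples to cluster")
    values = norm.values.loc[list(proteins), ad_samples].dropna(axis=0, how="any")
    X = scale_to_1_2(values)
    return select_k(
        X,
        k_range=k_range,
        n_runs=n_runs,
        seed=seed,
        max_iter=max_iter,
        tol=tol,
        loss=loss,
        rule=rule,
    )
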