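"""Synthetic TMT cohort generator with planted subtypes and batch structure.

The generative model mirrors what the downstream pipeline assumes: samples
are randomized into 16-channel plexes (14 samples + 2 pooled references),
protein base abundances are log-normal, each planted subtype shifts its
signature proteins up or down on the log2 scale, and multiplicative per-plex
and per-channel factors emulate TMT batch effects.  Missingness is applied
as whole (protein, plex) blocks.

Protein-level structure (base abundances, signature membership, directions)
is drawn from a stream keyed only by ``config.seed``, so a replication
cohort generated from the same config shares the discovery signatures while
having independent samples and batch factors.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import IntensityMatrix, PlexLayout, SampleMetadata, channel_key

PLEX_SAMPLES = 14
REF_CHANNELS = ("ch15", "ch16")
SAMPLE_CHANNELS = tuple(f"ch{i:02d}" for i in range(1, PLEX_SAMPLES + 1))


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generative model."""

    n_controls: int = 180
    n_ad: int = 400
    k_true: int = 5
    subtype_proportions: tuple[float, ...] | None = None
    n_proteins: int = 400
    signature_size: int = 40
    effect_size: float = 2.0
    batch_sd: float = 0.25
    channel_sd: float = 0.1
    noise_sd: float = 0.3
    missing_plex_fraction: float = 0.0
    signature_overlap: float = 0.0
    #: probability that a signature protein is down- rather than up-shifted
    down_fraction: float = 0.5
    confound_strength: float = 0.0
    strict_plex_fill: bool = False
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.subtype_proportions is None:
            return np.full(self.k_true, 1.0 / self.k_true)
        return np.asarray(self.subtype_proportions, dtype=float)

    def validate(self) -> None:
        if self.n_controls <= 0 or self.n_ad <= 0 or self.n_proteins <= 0:
            raise ConfigError("sample and protein counts must be positive")
        if self.k_true <= 0 or self.signature_size <= 0:
            raise ConfigError("k_true and signature_size must be positive")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        for name in ("batch_sd", "channel_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_plex_fraction <= 1.0:
            raise ConfigError("missing_plex_fraction must be in [0, 1]")
        if not 0.0 <= self.signature_overlap <= 1.0:
            raise ConfigError("signature_overlap must be in [0, 1]")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise ConfigError("down_fraction must be in [0, 1]")
        props = self.proportions()
        if len(props) != self.k_true:
            raise ConfigError("subtype_proportions length must equal k_true")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("subtype_proportions must lie on the simplex")
        if self.k_true * self.signature_size > self.n_proteins:
            raise ConfigError("signatures do not fit into n_proteins")
        n = self.n_controls + self.n_ad
        if self.strict_plex_fill and n % PLEX_SAMPLES != 0:
            raise ConfigError(
                f"{n} samples cannot fill {PLEX_SAMPLES}-sample plexes exactly"
            )


@dataclasses.dataclass
class GroundTruth:
    """Planted truth: per-sample subtype and per-subtype protein signatures."""

    subtype_of: dict[str, int | None]
    #: subtype -> {protein: +1 (up) or -1 (down)}
    signatures: dict[int, dict[str, int]]
    warnings: list[str] = dataclasses.field(default_factory=list)

    def ad_labels(self) -> pd.Series:
        items = {s: k for s, k in self.subtype_of.items() if k is not None}
        return pd.Series(items, name="subtype")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_of": self.subtype_of,
            "signatures": {
                str(k): sig for k, sig in self.signatures.items()
            },
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            subtype_of={
                s: (None if k is None else int(k))
                for s, k in payload["subtype_of"].items()
            },
            signatures={
                int(k): {p: int(d) for p, d in sig.items()}
                for k, sig in payload["signatures"].items()
            },
            warnings=list(payload.get("warnings", [])),
        )


def _protein_structure(config: SyntheticConfig):
    """Protein base abundances and subtype signatures, keyed by config.seed only."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    proteins = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    base_log2 = rng.normal(14.0, 1.5, size=config.n_proteins)
    order = rng.permutation(config.n_proteins)
    signatures: dict[int, dict[str, int]] = {}
    n_shared = int(math.floor(config.signature_overlap * config.signature_size))
    for k in range(1, config.k_true + 1):
        start = (k - 1) * config.signature_size
        idx = list(order[start : start + config.signature_size])
        if n_shared and k > 1:
            prev = list(signatures[k - 1].keys())[:n_shared]
            own = [proteins[i] for i in idx[: config.signature_size - n_shared]]
            members = own + prev
        else:
            members = [proteins[i] for i in idx]
        dirs = rng.choice(
            [-1, 1], size=len(members),
            p=[config.down_fraction, 1.0 - config.down_fraction],
        )
        signatures[k] = {p: int(d) for p, d in zip(members, dirs)}
    return proteins, base_log2, signatures


def _make_layout(sample_ids: Sequence[str]) -> PlexLayout:
    rows = []
    n_plex = math.ceil(len(sample_ids) / PLEX_SAMPLES)
    for p in range(n_plex):
        plex_id = f"plex{p + 1:02d}"
        chunk = sample_ids[p * PLEX_SAMPLES : (p + 1) * PLEX_SAMPLES]
        for ch, sid in zip(SAMPLE_CHANNELS, chunk):
            rows.append((plex_id, ch, "sample", sid))
        for ch in REF_CHANNELS:
            rows.append((plex_id, ch, "reference", np.nan))
    return PlexLayout(
        pd.DataFrame(rows, columns=["plex_id", "channel_id", "role", "sample_id"])
    )


def _sample_metadata(
    config: SyntheticConfig, rng: np.random.Generator, cohort_id: str
):
    n = config.n_controls + config.n_ad
    sample_ids = [f"{cohort_id}S{i:04d}" for i in range(1, n + 1)]
    group = ["control"] * config.n_controls + ["AD"] * config.n_ad
    subtype = np.full(n, -1)
    subtype[config.n_controls :] = rng.choice(
        np.arange(1, config.k_true + 1), size=config.n_ad, p=config.proportions()
    )
    cognitive = np.array(["NC"] * n, dtype=object)
    cognitive[config.n_controls :] = rng.choice(
        ["NC", "MCI", "dementia"], size=config.n_ad, p=[0.25, 0.25, 0.5]
    )
    tau = np.array(["normal"] * n, dtype=object)
    tau[config.n_controls :] = rng.choice(
        ["normal", "abnormal"], size=config.n_ad, p=[0.3, 0.7]
    )
    age = rng.normal(65.0, 8.0, size=n)
    if config.confound_strength:
        # optional confounding: shift age by planted subtype index
        shift = np.where(subtype > 0, subtype - (config.k_true + 1) / 2.0, 0.0)
        age = age + config.confound_strength * shift
    sex = rng.choice(["male", "female"], size=n)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": group,
                "cognitive_state": cognitive,
                "tau_status": tau,
                "age": np.round(age, 1),
                "sex": sex,
                "cohort_id": cohort_id,
            }
        )
    )
    subtype_of = {
        sid: (None if s < 0 else int(s)) for sid, s in zip(sample_ids, subtype)
    }
    return meta, subtype_of


def _assemble_matrix(
    config: SyntheticConfig,
    proteins: list[str],
    base_log2: np.ndarray,
    signatures: dict[int, dict[str, int]],
    subtype_of: dict[str, int | None],
    meta: SampleMetadata,
    rng: np.random.Generator,
) -> tuple[IntensityMatrix, PlexLayout]:
    sample_ids = meta.sample_ids
    n, p = len(sample_ids), len(proteins)
    protein_pos = {prot: i for i, prot in enumerate(proteins)}

    shift = np.zeros((p, n))
    for j, sid in enumerate(sample_ids):
        k = subtype_of[sid]
        if k is None:
            continue
        for prot, direction in signatures[k].items():
            shift[protein_pos[prot], j] = direction * config.effect_size

    log2_vals = (
        base_log2[:, None] + shift + rng.normal(0.0, config.noise_sd, size=(p, n))
    )
    raw = np.exp2(log2_vals)

    plex_order = rng.permutation(n)
    ordered_samples = [sample_ids[i] for i in plex_order]
    layout = _make_layout(ordered_samples)

    columns: dict[str, np.ndarray] = {}
    plex_ids = layout.plex_ids
    batch = np.exp(rng.normal(0.0, config.batch_sd, size=len(plex_ids)))
    sample_col = {sid: raw[:, j] for j, sid in enumerate(sample_ids)}
    for pi, plex_id in enumerate(plex_ids):
        sub = layout.frame[layout.frame["plex_id"] == plex_id]
        smp = sub[sub["role"] == "sample"]
        plex_samples = list(smp["sample_id"])
        pooled = np.mean([sample_col[s] for s in plex_samples], axis=0)
        for _, row in sub.iterrows():
            chan_factor = math.exp(rng.normal(0.0, config.channel_sd))
            base = (
                pooled if row["role"] == "reference" else sample_col[row["sample_id"]]
            )
            key = channel_key(row["plex_id"], row["channel_id"])
            columns[key] = base * batch[pi] * chan_factor

    values = pd.DataFrame(columns, index=proteins)
    values = values[layout.channel_keys]

    if config.missing_plex_fraction > 0:
        mask = rng.random((p, len(plex_ids))) < config.missing_plex_fraction
        # keep every protein observed in at least one plex
        all_missing = mask.all(axis=1)
        if all_missing.any():
            keep = rng.integers(0, len(plex_ids), size=int(all_missing.sum()))
            mask[np.where(all_missing)[0], keep] = False
        for pi, plex_id in enumerate(plex_ids):
            keys = layout.plex_keys(plex_id)
            rows = np.where(mask[:, pi])[0]
            if len(rows):
                values.iloc[rows, [values.columns.get_loc(k) for k in keys]] = np.nan

    return IntensityMatrix(values, layout), layout


def generate_cohort(
    config: SyntheticConfig, cohort_id: str = "DISC"
) -> tuple[IntensityMatrix, PlexLayout, SampleMetadata, GroundTruth]:
    """Generate a full synthetic cohort; identical seeds give identical output."""
    config.validate()
    proteins, base_log2, signatures = _protein_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    meta, subtype_of = _sample_metadata(config, rng, cohort_id)
    matrix, layout = _assemble_matrix(
        config, proteins, base_log2, signatures, subtype_of, meta, rng
    )
    truth = GroundTruth(subtype_of=subtype_of, signatures=signatures)
    return matrix, layout, meta, truth


def generate_replication_cohort(
    config: SyntheticConfig,
    panel_fraction: float,
    seed: int,
    cohort_id: str = "REP",
) -> tuple[IntensityMatrix, PlexLayout, SampleMetadata, GroundTruth]:
    """Generate an independent cohort sharing the discovery signatures.

    Only a random ``panel_fraction`` of the discovery proteins is retained,
    emulating replication datasets with smaller detected panels.  Batch
    factors, plex randomization and sample draws are independent of the
    discovery cohort (driven by ``seed``).
    """
    if not 0.0 < panel_fraction <= 1.0:
        raise ConfigError("panel_fraction must be in (0, 1]")
    config.validate()
    proteins, base_log2, signatures = _protein_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    meta, subtype_of = _sample_metadata(config, rng, cohort_id)

    n_keep = int(math.floor(panel_fraction * len(proteins)))
    keep_idx = np.sort(rng.choice(len(proteins), size=n_keep, replace=False))
    kept = [proteins[i] for i in keep_idx]
    kept_set = set(kept)
    kept_signatures = {
        k: {p: d for p, d in sig.items() if p in kept_set}
        for k, sig in signatures.items()
    }
    truth = GroundTruth(subtype_of=subtype_of, signatures=kept_signatures)
    if all(len(sig) == 0 for sig in kept_signatures.values()):
        truth.warnings.append("no signature protein survived the panel subset")

    matrix, layout = _assemble_matrix(
        config, kept, base_log2[keep_idx], kept_signatures, subtype_of, meta, rng
    )
    return matrix, layout, meta, truth


def subtype_recovery_power(
    config: SyntheticConfig,
    n_grid: Sequence[int],
    n_reps: int,
    seed: int,
    k_range: Sequence[int] | None = None,
    n_runs: int = 10,
    alpha: float = 0.05,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Estimate subtype-recovery power over a grid of cohort sizes.

    For each cohort size ``n`` the full normalize -> select -> subtype
    pipeline runs on ``n_reps`` seeded cohorts; reported per size are mean
    adjusted Rand index against the planted labels and the fraction of
    replicates whose model selection picked ``k_true``.  Pipeline failures
    on a replicate are recorded, not fatal.
    """
    from sklearn.metrics import adjusted_rand_score

    from .normalize import normalize_pipeline
    from .select import select_ad_proteins
    from .subtype import fit_subtypes

    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if k_range is None:
        k_range = range(2, min(config.k_true + 3, 9))
    frac_ad = config.n_ad / (config.n_ad + config.n_controls)
    seeds = np.random.SeedSequence(seed).generate_state(len(n_grid) * n_reps)
    rows = []
    pos = 0
    for n in n_grid:
        n_ad = max(2 * config.k_true, int(round(n * frac_ad)))
        n_controls = max(4, n - n_ad)
        aris, hits, failures = [], 0, 0
        for _ in range(n_reps):
            rep_seed = int(seeds[pos])
            pos += 1
            cfg = dataclasses.replace(
                config, n_ad=n_ad, n_controls=n_controls, seed=rep_seed
            )
            try:
                matrix, layout, meta, truth = generate_cohort(cfg)
                norm = normalize_pipeline(matrix, layout, meta)
                sel = select_ad_proteins(norm, meta, alpha=alpha)
                model = fit_subtypes(
                    norm,
                    sel.selected_proteins,
                    meta,
                    k_range=k_range,
                    n_runs=n_runs,
                    seed=rep_seed,
                    max_iter=max_iter,
                )
                k_sel = model.selected_k
                if k_sel is None:
                    # fall back to best cophenetic for the ARI readout
                    k_sel = int(model.metrics["cophenetic"].idxmax())
                    labels = model.labels_for_k(k_sel)
                else:
                    labels = model.patient_labels
                true = truth.ad_labels()
                common = [s for s in labels.index if s in true.index]
                aris.append(
                    adjusted_rand_score(true.loc[common], labels.loc[common])
                )
                hits += int(model.selected_k == config.k_true)
            except Exception:  # noqa: BLE001 - replicate failure is data, not a crash
                failures += 1
        rows.append(
            {
                "n": n,
                "mean_ari": float(np.mean(aris)) if aris else np.nan,
                "frac_k_true": hits / n_reps,
                "n_failed": failures,
            }
        )
    return pd.DataFrame(rows)
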