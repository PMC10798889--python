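"""Cohort-level tabular I/O: layouts, metadata, intensity matrices and results.

Canonical on-disk format is tab-separated text; comma-separated input is
accepted through the ``sep`` argument.  Missing values are written as empty
cells and read back as NaN — never as zero, because zero is a legal
intensity.  Protein identifiers are opaque strings matched by exact equality.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ContractError,
    DomainError,
    DuplicateRecordError,
    LayoutMismatchError,
)

CHANNEL_SEP = ":"

#: canonical enum levels, matched case-insensitively on read
GROUP_LEVELS = {"control": "control", "ad": "AD"}
COGNITIVE_LEVELS = {"nc": "NC", "mci": "MCI", "dementia": "dementia"}
TAU_LEVELS = {"normal": "normal", "abnormal": "abnormal"}
SEX_LEVELS = {"male": "male", "m": "male", "female": "female", "f": "female"}


def channel_key(plex_id: str, channel_id: str) -> str:
    """Build the column key used for a (plex, channel) pair."""
    return f"{plex_id}{CHANNEL_SEP}{channel_id}"


def split_channel_key(key: str) -> tuple[str, str]:
    plex_id, _, channel_id = key.partition(CHANNEL_SEP)
    if not channel_id:
        raise LayoutMismatchError(f"malformed channel key {key!r}")
    return plex_id, channel_id


@dataclasses.dataclass(frozen=True)
class PlexLayout:
    """Mapping from TMT channels to samples or pooled reference roles.

    ``frame`` has columns ``plex_id``, ``channel_id``, ``role`` (``sample`` or
    ``reference``) and ``sample_id`` (empty for references).  Every plex holds
    exactly two reference channels and at most fourteen sample channels.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"plex_id", "channel_id", "role", "sample_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise LayoutMismatchError(f"layout missing columns {sorted(missing)}")
        bad_roles = set(self.frame["role"]) - {"sample", "reference"}
        if bad_roles:
            raise DomainError(f"unknown channel roles {sorted(bad_roles)}")
        keys = self.frame["plex_id"].astype(str) + CHANNEL_SEP + self.frame[
            "channel_id"
        ].astype(str)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise DuplicateRecordError(f"channel mapped twice: {dup}")
        samples = self.frame.loc[self.frame["role"] == "sample", "sample_id"]
        if samples.isna().any() or (samples == "").any():
            raise LayoutMismatchError("sample channel without sample_id")
        if samples.duplicated().any():
            dup = samples[samples.duplicated()].iloc[0]
            raise DuplicateRecordError(f"sample mapped twice: {dup}")
        for plex_id, sub in self.frame.groupby("plex_id"):
            n_ref = int((sub["role"] == "reference").sum())
            n_smp = int((sub["role"] == "sample").sum())
            if n_ref != 2:
                raise LayoutMismatchError(
                    f"plex {plex_id} has {n_ref} reference channels, expected 2"
                )
            if n_smp > 14:
                raise LayoutMismatchError(
                    f"plex {plex_id} has {n_smp} sample channels, expected <= 14"
                )

    @property
    def plex_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["plex_id"]))

    @property
    def channel_keys(self) -> list[str]:
        return [
            channel_key(p, c)
            for p, c in zip(self.frame["plex_id"], self.frame["channel_id"])
        ]

    def reference_keys(self, plex_id: str) -> list[str]:
        sub = self.frame[
            (self.frame["plex_id"] == plex_id) & (self.frame["role"] == "reference")
        ]
        return [channel_key(p, c) for p, c in zip(sub["plex_id"], sub["channel_id"])]

    def sample_keys(self, plex_id: str) -> list[str]:
        sub = self.frame[
            (self.frame["plex_id"] == plex_id) & (self.frame["role"] == "sample")
        ]
        return [channel_key(p, c) for p, c in zip(sub["plex_id"], sub["channel_id"])]

    def plex_keys(self, plex_id: str) -> list[str]:
        sub = self.frame[self.frame["plex_id"] == plex_id]
        return [channel_key(p, c) for p, c in zip(sub["plex_id"], sub["channel_id"])]

    def sample_to_key(self) -> dict[str, str]:
        sub = self.frame[self.frame["role"] == "sample"]
        return {
            s: channel_key(p, c)
            for s, p, c in zip(sub["sample_id"], sub["plex_id"], sub["channel_id"])
        }


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical annotations with normalized enum levels."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "cognitive_state", "tau_status"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DomainError(f"metadata missing columns {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()].iloc[0]
            raise DuplicateRecordError(f"duplicate sample_id {dup!r}")
        controls = self.frame[self.frame["group"] == "control"]
        bad = controls[
            (controls["cognitive_state"] != "NC")
            | (controls["tau_status"] != "normal")
        ]
        if len(bad):
            raise DomainError(
                "controls must have cognitive_state NC and tau_status normal; "
                f"offending sample {bad['sample_id'].iloc[0]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups(self) -> pd.Series:
        return self.frame.set_index("sample_id")["group"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = set(sample_ids)
        return SampleMetadata(
            self.frame[self.frame["sample_id"].isin(ids)].reset_index(drop=True)
        )


@dataclasses.dataclass
class IntensityMatrix:
    """Raw reporter intensities, proteins x (plex, channel) columns.

    ``values`` is indexed by protein accession; columns are ``plex:channel``
    keys ordered as in the layout.  Missing values are NaN and must form
    whole-plex blocks per protein.
    """

    values: pd.DataFrame
    layout: PlexLayout

    def __post_init__(self) -> None:
        self.values.index.name = "protein"
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DuplicateRecordError(f"duplicate protein ID {dup!r}")
        if ((self.values < 0).any().any()):
            raise DomainError("negative intensity values are not allowed")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.layout)


def _normalize_enum(series: pd.Series, mapping: Mapping[str, str], name: str) -> pd.Series:
    def convert(value):
        if pd.isna(value) or value == "":
            return np.nan
        key = str(value).strip().lower()
        if key not in mapping:
            raise DomainError(f"unknown {name} level {value!r}")
        return mapping[key]

    return series.map(convert)


def read_layout(path: str | Path, sep: str = "\t") -> PlexLayout:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame["sample_id"] = frame["sample_id"].replace("", np.nan)
    return PlexLayout(frame)


def write_layout(layout: PlexLayout, path: str | Path, sep: str = "\t") -> None:
    layout.frame.to_csv(path, sep=sep, index=False, na_rep="")


def read_metadata(path: str | Path, sep: str = "\t") -> SampleMetadata:
    """Read and validate a sample metadata table, normalizing enum levels."""
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    frame["group"] = _normalize_enum(frame["group"], GROUP_LEVELS, "group")
    frame["cognitive_state"] = _normalize_enum(
        frame["cognitive_state"], COGNITIVE_LEVELS, "cognitive_state"
    )
    frame["tau_status"] = _normalize_enum(frame["tau_status"], TAU_LEVELS, "tau_status")
    if "sex" in frame.columns:
        frame["sex"] = _normalize_enum(frame["sex"], SEX_LEVELS, "sex")
    if "age" in frame.columns:
        frame["age"] = pd.to_numeric(frame["age"], errors="coerce")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path, sep: str = "\t") -> None:
    meta.frame.to_csv(path, sep=sep, index=False, na_rep="")


def read_intensity_matrix(
    path: str | Path, layout: PlexLayout, sep: str = "\t"
) -> IntensityMatrix:
    """Read a protein x channel intensity table and validate it against a layout.

    The first column holds protein IDs; the remaining column names must be
    ``plex:channel`` keys known to the layout, and every layout channel must
    be present.
    """
    frame = pd.read_csv(path, sep=sep, index_col=0)
    expected = layout.channel_keys
    unknown = [c for c in frame.columns if c not in set(expected)]
    if unknown:
        raise LayoutMismatchError(f"columns absent from layout: {unknown}")
    missing = [c for c in expected if c not in set(frame.columns)]
    if missing:
        raise LayoutMismatchError(f"layout channels missing from file: {missing}")
    frame = frame[expected]
    frame.index = frame.index.astype(str)
    return IntensityMatrix(frame.astype(float), layout)


def write_intensity_matrix(
    matrix: IntensityMatrix, path: str | Path, sep: str = "\t"
) -> None:
    matrix.values.to_csv(path, sep=sep, index_label="protein", na_rep="")


def read_value_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a generic protein x sample value table (e.g. normalized values)."""
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    return frame.astype(float)


def write_value_matrix(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index_label="protein", na_rep="")


def convert_mapt_to_ttau(mapt_abundance):
    """Harmonize TMT MAPT reporter abundance to the Innotest t-tau scale (pg/ml).

    Applies the linear conversion ``-309.16 + 0.01 * MAPT``.  Accepts scalars
    or arrays; negative abundances are rejected.
    """
    arr = np.asarray(mapt_abundance, dtype=float)
    if np.any(arr < 0):
        raise DomainError("MAPT abundance must be non-negative")
    out = -309.16 + 0.01 * arr
    if np.isscalar(mapt_abundance) or arr.ndim == 0:
        return float(out)
    return out


def write_subtype_assignments(
    labels: Sequence,
    probabilities,
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    sep: str = "\t",
    tol: float = 1e-6,
) -> None:
    """Write per-sample subtype labels and class probabilities.

    ``probabilities`` is a samples x subtypes array or DataFrame whose rows
    must sum to one within ``tol``.
    """
    probs = pd.DataFrame(probabilities)
    if len(labels) != len(probs):
        raise ContractError(
            f"{len(labels)} labels but {len(probs)} probability rows"
        )
    sums = probs.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > tol):
        raise ContractError("probability rows must sum to 1")
    if sample_ids is None:
        sample_ids = [str(i) for i in probs.index]
    if len(sample_ids) != len(probs):
        raise ContractError("sample_ids length mismatch")
    out = pd.DataFrame({"sample_id": list(sample_ids), "subtype": list(labels)})
    for col in probs.columns:
        out[f"p_{col}"] = probs[col].to_numpy()
    out.to_csv(path, sep=sep, index=False)


def read_subtype_assignments(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return frame
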