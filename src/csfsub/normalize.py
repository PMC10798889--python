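"""Two-step internal reference scaling, then log2 + control z-scaling.

Step 1 equalizes per-channel medians within each plex to the mean of the two
reference-channel medians.  Step 2 computes, per protein, a per-plex
correction factor from the pooled reference channels (geometric mean across
plexes of the mean reference value), making reference values identical
across plexes.  Proteins without any usable reference observation are
excluded with a recorded reason.  Finally values are log2-transformed and
z-scored to the control group so positive/negative values read as
above/below normal; reference channels are dropped.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ContractError, DegenerateChannelError
from .io import IntensityMatrix, PlexLayout, SampleMetadata

Statistic = Literal["median", "sum"]


@dataclasses.dataclass
class NormalizedMatrix:
    """Log2, control-z-scored protein values (proteins x sample_ids)."""

    values: pd.DataFrame
    excluded: pd.DataFrame  # columns: protein, stage, reason
    report: dict

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _exclusion_frame(rows: list[tuple[str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["protein", "stage", "reason"])


def within_plex_scale(
    matrix: IntensityMatrix,
    layout: PlexLayout | None = None,
    statistic: Statistic = "median",
) -> IntensityMatrix:
    """Scale every channel of each plex so its summary matches the reference target.

    The per-channel summary is the median (or sum, behind the flag) of the
    channel's non-missing protein intensities; the target is the mean of the
    two reference channels' summaries in that plex.
    """
    layout = layout or matrix.layout
    values = matrix.values.copy()
    agg = "median" if statistic == "median" else "sum"
    factors: dict[str, float] = {}
    for plex_id in layout.plex_ids:
        keys = layout.plex_keys(plex_id)
        summaries = getattr(values[keys], agg)(axis=0, skipna=True)
        ref_keys = layout.reference_keys(plex_id)
        target = float(summaries[ref_keys].mean())
        for key in keys:
            s = summaries[key]
            if np.isnan(s):
                # whole channel missing: nothing to scale
                factors[key] = np.nan
                continue
            if s == 0:
                raise DegenerateChannelError(
                    f"channel {key} has zero {statistic}; cannot scale"
                )
            factors[key] = target / s
            values[key] = values[key] * factors[key]
    out = IntensityMatrix(values, layout)
    out.within_plex_factors = factors  # type: ignore[attr-defined]
    return out


def between_plex_irs(
    matrix: IntensityMatrix, layout: PlexLayout | None = None
) -> tuple[IntensityMatrix, pd.DataFrame, pd.DataFrame]:
    """Per-protein internal reference scaling across plexes.

    For each protein, the two reference channels of plex ``p`` are averaged
    into ``r_p``; all channels of plex ``p`` are multiplied by ``G / r_p``
    where ``G`` is the geometric mean of ``r_p`` over plexes where the
    protein is observed.  Returns the corrected matrix, an exclusion table
    and the per-(protein, plex) factor table.
    """
    layout = layout or matrix.layout
    values = matrix.values.copy()
    plex_ids = layout.plex_ids
    ref_keys = {p: layout.reference_keys(p) for p in plex_ids}
    plex_keys = {p: layout.plex_keys(p) for p in plex_ids}

    # r[protein, plex] = mean of the two reference channels (NaN if unavailable)
    r = pd.DataFrame(
        {p: values[ref_keys[p]].mean(axis=1, skipna=False) for p in plex_ids}
    )
    observed = pd.DataFrame(
        {p: values[plex_keys[p]].notna().any(axis=1) for p in plex_ids}
    )
    usable = r.notna() & (r > 0) & observed

    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log(r.where(usable))
    gmean = np.exp(logr.mean(axis=1, skipna=True))  # NaN when no usable plex

    factors = gmean.to_numpy()[:, None] / r.to_numpy()
    factors = np.where(usable.to_numpy(), factors, np.nan)
    factor_table = pd.DataFrame(factors, index=values.index, columns=plex_ids)

    exclusions: list[tuple[str, str, str]] = []
    fully_excluded = usable.sum(axis=1) == 0
    for prot in values.index[fully_excluded & observed.any(axis=1)]:
        exclusions.append(
            (prot, "between_plex_irs", "no reference observation in any plex")
        )
    # plex-level degeneracy: observed but reference missing/zero in that plex
    partial = observed & ~usable
    for prot in values.index[partial.any(axis=1) & ~fully_excluded]:
        for p in plex_ids:
            if partial.loc[prot, p]:
                exclusions.append(
                    (prot, "between_plex_irs", f"unusable reference in {p}")
                )
                values.loc[prot, plex_keys[p]] = np.nan

    for p in plex_ids:
        col_factor = factor_table[p].to_numpy()
        values[plex_keys[p]] = values[plex_keys[p]].mul(col_factor, axis=0)

    drop = values.index[fully_excluded]
    values = values.drop(index=drop)
    factor_table = factor_table.drop(index=drop)
    return (
        IntensityMatrix(values, layout),
        _exclusion_frame(exclusions),
        factor_table,
    )


def log2_zscore_to_controls(
    matrix: IntensityMatrix,
    meta: SampleMetadata,
    layout: PlexLayout | None = None,
) -> NormalizedMatrix:
    """Log2-transform and z-score each protein to the control group.

    Reference channels are dropped and columns are renamed to sample IDs.
    Proteins with fewer than two non-missing control observations or zero
    control s.d. are excluded with a reason.
    """
    layout = layout or matrix.layout
    key_of = layout.sample_to_key()
    sample_ids = [s for s in meta.sample_ids if s in key_of]
    if not sample_ids:
        raise ContractError("no metadata sample appears in the layout")
    values = matrix.values[[key_of[s] for s in sample_ids]].copy()
    values.columns = sample_ids
    if (values <= 0).any().any():
        raise ContractError("all intensities must be positive before log2")
    log2 = np.log2(values)

    groups = meta.groups()
    controls = [s for s in sample_ids if groups.get(s) == "control"]
    if not controls:
        raise ContractError("no control samples available for z-scaling")
    ctrl = log2[controls]
    n_ctrl = ctrl.notna().sum(axis=1)
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)

    exclusions: list[tuple[str, str, str]] = []
    bad_n = n_ctrl < 2
    bad_sd = (~bad_n) & ((sd == 0) | sd.isna())
    for prot in log2.index[bad_n]:
        exclusions.append((prot, "zscore", "fewer than 2 control observations"))
    for prot in log2.index[bad_sd]:
        exclusions.append((prot, "zscore", "zero control s.d."))
    keep = ~(bad_n | bad_sd)
    z = log2.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)

    report = {
        "n_controls": len(controls),
        "control_mean_log2": mean[keep].to_dict(),
        "control_sd_log2": sd[keep].to_dict(),
    }
    return NormalizedMatrix(z, _exclusion_frame(exclusions), report)


def normalize_pipeline(
    matrix: IntensityMatrix,
    layout: PlexLayout | None = None,
    meta: SampleMetadata | None = None,
    statistic: Statistic = "median",
) -> NormalizedMatrix:
    """Run within-plex scaling, IRS and control z-scaling in sequence."""
    if meta is None:
        raise ContractError("sample metadata is required")
    layout = layout or matrix.layout
    step1 = within_plex_scale(matrix, layout, statistic=statistic)
    step2, excluded_irs, factor_table = between_plex_irs(step1, layout)
    norm = log2_zscore_to_controls(step2, meta, layout)
    norm.excluded = pd.concat([excluded_irs, norm.excluded], ignore_index=True)
    norm.report["within_plex_factors"] = getattr(step1, "within_plex_factors", {})
    norm.report["irs_factors"] = {
        p: factor_table[p].dropna().to_dict() for p in factor_table.columns
    }
    return norm
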