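"""Subtype profiling: per-protein linear-model contrasts and set enrichment.

Contrasts come from ordinary least squares of protein level on a group
factor (controls + subtypes), optionally adjusted for covariates, with
estimated marginal means evaluated at covariate grand means.  A protein
enters a contrast only when both compared groups have at least five
non-missing observations.  Over-representation of protein sets is tested
with the one-sided hypergeometric tail and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ContractError, DomainError
from .io import SampleMetadata
from .normalize import NormalizedMatrix

MIN_OBS_PER_GROUP = 5


def _design(groups: pd.Series, covariates: pd.DataFrame | None):
    """Treatment-coded design matrix with 'control' as the reference level."""
    levels = list(pd.unique(groups))
    if "control" in levels:
        levels = ["control"] + sorted(str(l) for l in levels if l != "control")
    else:
        levels = sorted(str(l) for l in levels)
    gs = groups.astype(str)
    X = pd.DataFrame({"Intercept": np.ones(len(groups))}, index=groups.index)
    for lev in levels[1:]:
        X[f"g_{lev}"] = (gs == lev).astype(float)
    if covariates is not None:
        for col in covariates.columns:
            X[col] = covariates[col].astype(float)
    return X, levels


def _encode_covariates(
    meta: SampleMetadata, sample_ids: Sequence[str], covariates: Sequence[str] | None
) -> pd.DataFrame | None:
    if not covariates:
        return None
    mf = meta.frame.set_index("sample_id").loc[list(sample_ids)]
    out = pd.DataFrame(index=mf.index)
    for cov in covariates:
        if cov not in mf.columns:
            raise ContractError(f"covariate {cov!r} not in metadata")
        col = mf[cov]
        if col.dtype == object:
            codes = pd.Categorical(col).codes.astype(float)
            codes[codes < 0] = np.nan
            out[cov] = codes
        else:
            out[cov] = col.astype(float)
    return out


def estimated_marginal_means(
    y: pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-level model-predicted means with covariates at their grand means."""
    X, levels = _design(groups, covariates)
    fit = sm.OLS(y.astype(float), X).fit()
    cov_part = 0.0
    if covariates is not None:
        for col in covariates.columns:
            cov_part += fit.params[col] * covariates[col].mean()
    emms = {}
    for lev in levels:
        val = fit.params["Intercept"] + cov_part
        if f"g_{lev}" in fit.params:
            val += fit.params[f"g_{lev}"]
        emms[lev] = val
    return pd.Series(emms, name="emm")


def differential_abundance(
    norm: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    meta: SampleMetadata | None = None,
    covariates: Sequence[str] | None = None,
    min_obs: int = MIN_OBS_PER_GROUP,
) -> pd.DataFrame:
    """All pairwise group contrasts (EMM differences) per protein.

    ``labels`` maps sample_id to 'control' or a subtype label; samples not
    in ``labels`` are ignored.  Returns one row per (protein, group_a,
    group_b) with effect (EMM_a - EMM_b), two-tailed p, direction and the
    inclusion flag from the >= ``min_obs`` observations-per-group rule.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    labels = pd.Series(labels).astype(str)
    samples = [s for s in values.columns if s in labels.index]
    if not samples:
        raise ContractError("labels cover no sample in the matrix")
    groups = labels.loc[samples]
    if groups.nunique() < 2:
        raise ContractError("need controls plus at least one subtype")
    cov_df = _encode_covariates(meta, samples, covariates) if covariates else None

    rows = []
    for protein in values.index:
        y = values.loc[protein, samples]
        ok = y.notna()
        if cov_df is not None:
            ok &= cov_df.notna().all(axis=1).to_numpy()
        yv = y[ok]
        gv = groups[ok]
        cv = cov_df.loc[yv.index] if cov_df is not None else None
        counts = gv.value_counts()
        X, levels = _design(gv, cv)
        fit = None
        flagged = ""
        if len(yv) > X.shape[1] and gv.nunique() >= 2:
            fit = sm.OLS(yv.astype(float), X).fit()
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                # pinv keeps group contrasts estimable; flag for the caller
                flagged = "rank-deficient design"
        else:
            flagged = "insufficient data"
        pairs = list(itertools.combinations(levels, 2))
        for lev_b, lev_a in pairs:  # report subtype-vs-control as subtype minus control
            n_a = int(counts.get(lev_a, 0))
            n_b = int(counts.get(lev_b, 0))
            included = n_a >= min_obs and n_b >= min_obs and fit is not None
            effect = p = np.nan
            if included:
                contrast = np.zeros(X.shape[1])
                names = list(X.columns)
                if f"g_{lev_a}" in names:
                    contrast[names.index(f"g_{lev_a}")] += 1.0
                if f"g_{lev_b}" in names:
                    contrast[names.index(f"g_{lev_b}")] -= 1.0
                test = fit.t_test(contrast)
                effect = float(np.atleast_1d(test.effect)[0])
                p = float(np.atleast_1d(test.pvalue).ravel()[0])
            reason = flagged or (
                "" if n_a >= min_obs and n_b >= min_obs
                else f"fewer than {min_obs} observations in a group"
            )
            rows.append(
                {
                    "protein": protein,
                    "group_a": lev_a,
                    "group_b": lev_b,
                    "n_a": n_a,
                    "n_b": n_b,
                    "effect": effect,
                    "p": p,
                    "direction": (
                        "up" if effect > 0 else "down" if effect < 0 else "none"
                    ) if included else "none",
                    "included": bool(included),
                    "reason": reason,
                    "covariates": ",".join(covariates) if covariates else "",
                }
            )
    return pd.DataFrame(rows)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def hypergeometric_enrichment(
    hits: Sequence[str],
    universe: Sequence[str],
    term_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided over-representation test per term set with BH q-values.

    Terms are intersected with the universe; empty intersections are
    skipped.  ``p = P(X >= observed overlap)`` under the hypergeometric
    null.
    """
    uni = set(universe)
    if not uni:
        raise ContractError("universe is empty")
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ContractError("hits must be a subset of the universe")
    M = len(uni)
    n_hits = len(hit_set)
    rows = []
    for term, members in term_sets.items():
        members_u = set(members) & uni
        if not members_u:
            continue
        k = len(hit_set & members_u)
        K = len(members_u)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_hits))
        expected = K * n_hits / M
        rows.append(
            {
                "term": term,
                "hits_in_set": k,
                "set_size": K,
                "hits_total": n_hits,
                "universe_size": M,
                "direction": "over" if k > expected else "under",
                "p": min(max(p, np.nextafter(0, 1)), 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    return table


def enrichment_hits(
    diff: pd.DataFrame,
    subtype: str,
    direction: str = "up",
    p_threshold: float = 0.05,
) -> list[str]:
    """Default hit rule: proteins differing from controls at p < threshold."""
    sub = diff[
        (diff["group_a"] == str(subtype))
        & (diff["group_b"] == "control")
        & diff["included"]
        & (diff["p"] < p_threshold)
    ]
    if direction in ("up", "down"):
        sub = sub[sub["direction"] == direction]
    return list(sub["protein"])
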