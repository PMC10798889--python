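"""AD-related protein screening via Kruskal-Wallis tests.

Each fully observed protein is tested AD vs control overall and with the AD
group stratified by cognitive state (NC / MCI / dementia) and by tau status
(normal / abnormal), each stratum against the full control group; a protein
is selected when any stratum reaches ``p < alpha``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError
from .io import SampleMetadata
from .normalize import NormalizedMatrix

STRATA = ("overall", "NC", "MCI", "dementia", "tau_normal", "tau_abnormal")


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-squared p-value from mid-ranks with tie correction.

    ``groups`` labels each observation; at least two distinct groups with one
    observation each are required.  All-identical values give (0, 1).
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise ContractError("values and groups must have equal length")
    levels = np.unique(g)
    if len(levels) < 2:
        raise ContractError("kruskal_wallis needs at least two groups")
    n = len(x)
    ranks = stats.rankdata(x)
    rank_sums = np.array([ranks[g == lev].sum() for lev in levels])
    counts = np.array([(g == lev).sum() for lev in levels])
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / counts) - 3.0 * (n + 1)
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom == 0.0:  # every value identical
        return 0.0, 1.0
    h = h / denom
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, len(levels) - 1))
    return float(h), min(max(p, np.nextafter(0, 1)), 1.0)


@dataclasses.dataclass
class SelectionResult:
    """Per-protein screening statistics and the selected set."""

    table: pd.DataFrame  # index protein; H_<stratum>, p_<stratum>, selected
    alpha: float
    strata_tested: tuple[str, ...]
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def selected_proteins(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def _stratum_masks(meta_frame: pd.DataFrame) -> dict[str, pd.Series]:
    ad = meta_frame["group"] == "AD"
    return {
        "overall": ad,
        "NC": ad & (meta_frame["cognitive_state"] == "NC"),
        "MCI": ad & (meta_frame["cognitive_state"] == "MCI"),
        "dementia": ad & (meta_frame["cognitive_state"] == "dementia"),
        "tau_normal": ad & (meta_frame["tau_status"] == "normal"),
        "tau_abnormal": ad & (meta_frame["tau_status"] == "abnormal"),
    }


def select_ad_proteins(
    norm: NormalizedMatrix, meta: SampleMetadata, alpha: float = 0.05
) -> SelectionResult:
    """Screen fully observed proteins for AD-relatedness in any stratum.

    Only proteins observed in every sample are tested.  Each AD stratum is
    compared against the full control group; empty strata are skipped with a
    warning.  Selection is the union of any-stratum ``p < alpha``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ContractError("alpha must be in (0, 1]")
    mf = meta.frame[meta.frame["sample_id"].isin(norm.sample_ids)]
    mf = mf.set_index("sample_id").loc[norm.sample_ids].reset_index()
    controls = mf["sample_id"][mf["group"] == "control"].tolist()
    if not controls:
        raise ContractError("no controls present")
    masks = _stratum_masks(mf)

    complete = norm.values.dropna(axis=0, how="any")
    notes: list[str] = []
    data = complete.to_numpy()
    col_of = {s: i for i, s in enumerate(complete.columns)}
    ctrl_idx = np.array([col_of[s] for s in controls])

    results: dict[str, np.ndarray] = {}
    for stratum in STRATA:
        ids = mf["sample_id"][masks[stratum]].tolist()
        if not ids:
            notes.append(f"stratum {stratum} is empty; skipped")
            results[f"H_{stratum}"] = np.full(len(complete), np.nan)
            results[f"p_{stratum}"] = np.full(len(complete), np.nan)
            continue
        idx = np.array([col_of[s] for s in ids])
        labels = np.array([0] * len(ctrl_idx) + [1] * len(idx))
        cols = np.concatenate([ctrl_idx, idx])
        hs = np.empty(len(complete))
        ps = np.empty(len(complete))
        for i in range(len(complete)):
            hs[i], ps[i] = kruskal_wallis(data[i, cols], labels)
        results[f"H_{stratum}"] = hs
        results[f"p_{stratum}"] = ps

    table = pd.DataFrame(results, index=complete.index)
    pcols = [f"p_{s}" for s in STRATA]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table["selected"] = (table[pcols] < alpha).any(axis=1)
    if alpha == 1.0:
        table["selected"] = table[pcols].notna().any(axis=1)
    return SelectionResult(
        table=table, alpha=alpha, strata_tested=STRATA, warnings=notes
    )
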