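import numpy as np
import pandas as pd
import pytest

from csfsub import (
    SyntheticConfig,
    generate_cohort,
    normalize_pipeline,
    select_ad_proteins,
    fit_subtypes,
)
from csfsub.io import IntensityMatrix, PlexLayout, SampleMetadata


SMALL_CFG = SyntheticConfig(
    seed=21, k_true=3, n_ad=200, n_controls=90, n_proteins=200, signature_size=25
)


@pytest.fixture(scope="session")
def small_cohort():
    """3-subtype strong-separation cohort used across module tests."""
    matrix, layout, meta, truth = generate_cohort(SMALL_CFG)
    return SMALL_CFG, matrix, layout, meta, truth


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    _, matrix, layout, meta, _ = small_cohort
    return normalize_pipeline(matrix, layout, meta)


@pytest.fixture(scope="session")
def small_selection(small_cohort, small_norm):
    _, _, _, meta, _ = small_cohort
    return select_ad_proteins(small_norm, meta, alpha=0.05)


@pytest.fixture(scope="session")
def small_model(small_cohort, small_norm, small_selection):
    _, _, _, meta, _ = small_cohort
    return fit_subtypes(
        small_norm,
        small_selection.selected_proteins,
        meta,
        k_range=(2, 3, 4, 5),
        n_runs=8,
        seed=21,
        max_iter=500,
        tol=1e-5,
    )


def toy_layout(n_plex=1, n_samples=14, prefix="S"):
    """Minimal valid layout: n_samples sample channels + 2 refs per plex."""
    rows = []
    counter = 1
    for p in range(1, n_plex + 1):
        plex = f"plex{p:02d}"
        for c in range(1, n_samples + 1):
            rows.append((plex, f"ch{c:02d}", "sample", f"{prefix}{counter:03d}"))
            counter += 1
        rows.append((plex, "ch15", "reference", np.nan))
        rows.append((plex, "ch16", "reference", np.nan))
    return PlexLayout(
        pd.DataFrame(rows, columns=["plex_id", "channel_id", "role", "sample_id"])
    )


def toy_matrix(layout, proteins, fill):
    """IntensityMatrix with a constant or callable fill per (protein, column)."""
    cols = layout.channel_keys
    if callable(fill):
        data = {
            c: [fill(p, c) for p in proteins] for c in cols
        }
    else:
        data = {c: [fill] * len(proteins) for c in cols}
    return IntensityMatrix(pd.DataFrame(data, index=proteins), layout)


def toy_metadata(sample_ids, n_controls):
    n = len(sample_ids)
    group = ["control"] * n_controls + ["AD"] * (n - n_controls)
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": group,
                "cognitive_state": ["NC"] * n_controls
                + ["dementia"] * (n - n_controls),
                "tau_status": ["normal"] * n_controls
                + ["abnormal"] * (n - n_controls),
                "age": 65.0,
                "sex": "female",
                "cohort_id": "TOY",
            }
        )
    )
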