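"""Data-level summaries: PCA scores, PA-matched log2-ratio matrices, reports.

Figure-style rendering is out of scope; these functions emit the numbers a
figure would plot (sample coordinates, ratio matrices, clustering orders)
as plain tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import indexed_metadata, select_samples


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component coordinates of the samples.

    Samples are observations and mean-centered probes the variables.  The
    sign convention fixes each component so its largest-magnitude loading is
    positive, making scores reproducible across runs.  Returns the scores
    (samples x PC1..PCk) and the explained-variance fractions.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    X = matrix.to_numpy(dtype=float).T  # samples x probes
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        raise ValueError(f"{n_components} components exceed the matrix rank ({rank})")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def log2_ratio_matrix(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pa_table: pd.DataFrame,
    pa_tolerance_h: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Exposed-vs-control log2 ratios at matched Predicted Ages.

    For every exposed condition (high concentration x regime x harvest) the
    unexposed condition with the nearest mean PA is chosen as reference; the
    column holds mean exposed log2 minus mean control log2 per probe.
    Conditions without a control within ``pa_tolerance_h`` are skipped with a
    warning.  The matching log records each column's control condition and PA
    gap.
    """
    meta = indexed_metadata(metadata, matrix)
    high = float(meta["concentration_uM"].max())

    def _group_pa(ids: list[str]) -> float:
        return float(pa_table.loc[ids, "pa_h"].mean())

    controls = []
    for (regime, h), grp in meta[meta["concentration_uM"] == 0.0].groupby(
        ["regime", "harvest_h"]
    ):
        ids = list(grp["sample_id"])
        controls.append((regime, float(h), ids, _group_pa(ids)))

    columns: dict[str, pd.Series] = {}
    log: dict[str, dict] = {}
    for (regime, h), grp in meta[meta["concentration_uM"] == high].groupby(
        ["regime", "harvest_h"]
    ):
        ids = list(grp["sample_id"])
        pa = _group_pa(ids)
        best = min(controls, key=lambda c: abs(c[3] - pa))
        gap = abs(best[3] - pa)
        name = f"{regime}_t{h:g}"
        if gap > pa_tolerance_h:
            warnings.warn(
                f"no control within {pa_tolerance_h} h of PA {pa:.1f} for {name}; skipped",
                stacklevel=2,
            )
            continue
        columns[name] = matrix[ids].mean(axis=1) - matrix[best[2]].mean(axis=1)
        log[name] = {
            "exposed_pa_h": pa,
            "control_regime": best[0],
            "control_harvest_h": best[1],
            "control_pa_h": best[3],
            "pa_gap_h": gap,
        }
    return pd.DataFrame(columns, index=matrix.index), log


def cluster_order(matrix: pd.DataFrame, axis: int = 0) -> list:
    """Leaf order of average-linkage hierarchical clustering (Euclidean)."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis == 1:
        data = data.T
        labels = list(matrix.columns)
    if len(labels) < 2:
        return labels
    order = leaves_list(linkage(data, method="average", metric="euclidean"))
    return [labels[i] for i in order]


@dataclass
class RunReport:
    """Provenance and headline numbers of one pipeline run."""

    seed: int
    config: dict
    n_samples: int
    n_probes_input: int
    n_probes_present: int
    qc_failures: list[str]
    pa_by_condition: dict[str, dict]
    delay_estimates: list[dict]
    de_counts: dict[str, dict]
    washout_unique: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=_jsonable))


def _jsonable(obj):
    if is_dataclass(obj):
        return asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def pa_condition_table(pa_table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD Predicted Age per condition (the study's staging table)."""
    meta = indexed_metadata(metadata)
    joined = pa_table.join(
        meta.set_index("sample_id")[["concentration_uM", "regime"]], how="left"
    )
    grouped = joined.groupby(["harvest_h", "concentration_uM", "regime"])
    out = grouped["pa_h"].agg(["mean", "std", "count"]).reset_index()
    out.columns = ["harvest_h", "concentration_uM", "regime", "pa_mean_h", "pa_sd_h", "n"]
    return out


def pa_from_harvest(metadata: pd.DataFrame) -> pd.DataFrame:
    """A covariate table using harvest time in place of Predicted Age.

    The delay-blind alternative to staging; used to demonstrate why PA
    adjustment is needed.
    """
    meta = indexed_metadata(metadata)
    return pd.DataFrame(
        {"pa_h": meta["harvest_h"].astype(float), "harvest_h": meta["harvest_h"]},
        index=meta["sample_id"],
    )
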