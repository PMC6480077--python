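"""MOR signal score and two-class patient stratification.

The MOR signal score condenses the eight-marker plasma profile of one
patient into a single number meant to track µ-opioid-receptor stimulation:

    score = −Σ ΔCq(up markers) + Σ ΔCq(down markers)

Since lower ΔCq means more abundant miRNA, the score rises when the
up-regulated markers are abundant and the down-regulated markers are
scarce — the profile seen in opioid-treated subjects. Equivalently, on
−ΔCq values as reports print them, score = Σ(−ΔCq, up) − Σ(−ΔCq, down).

Patients are stratified by agglomerative clustering of their marker ΔCq
profiles cut at two clusters; the cluster with the higher mean score is
class 1 (putative high MOR signal, expected poor responders to further
opioid dosing), the other class 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .signature_selection import MarkerPanel, default_mor_panel

__all__ = [
    "ClusteringSpec",
    "ClusteringError",
    "ScoreTable",
    "mor_signal_score",
    "score_cohort",
    "classify_patients",
    "score_report",
]

UNASSIGNED = "unassigned"


class ClusteringError(ValueError):
    """Patient stratification is impossible or degenerate."""


@dataclass(frozen=True)
class ClusteringSpec:
    """Agglomerative clustering settings for patient stratification.

    Defaults — correlation distance with complete linkage — group patients
    by the *shape* of their marker profile rather than by overall ΔCq
    offset. On the eight-marker feature space this separates the mirrored
    high-up/low-down vs low-up/high-down signatures cleanly, whereas
    Euclidean distance on raw ΔCq is dominated by per-patient abundance
    offsets and tends to split off single outliers.
    """

    distance: str = "correlation"
    linkage: str = "complete"
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.linkage in ("ward", "centroid", "median") and self.distance != "euclidean":
            raise ValueError(f"{self.linkage} linkage requires euclidean distance")


@dataclass
class ScoreTable:
    """Per-patient scores, class labels and the marker inputs used.

    ``table`` is indexed by patient id with columns ``score`` (NaN when any
    marker is missing), ``class_label`` (1, 2 or ``unassigned``) and one
    column per panel marker holding the ΔCq input. ``merges`` holds the
    dendrogram merge list (scipy linkage matrix) when clustering ran.
    """

    table: pd.DataFrame
    panel: MarkerPanel
    spec: ClusteringSpec | None = None
    merges: np.ndarray | None = None

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def class_labels(self) -> pd.Series:
        return self.table["class_label"]


def mor_signal_score(delta_cq_row, panel: MarkerPanel | None = None) -> float:
    """Score one patient: −Σ ΔCq(up) + Σ ΔCq(down); NaN if any marker missing."""
    panel = panel or default_mor_panel()
    row = pd.Series(delta_cq_row, dtype=float)
    missing = [a for a in panel.assays if a not in row.index]
    if missing:
        raise KeyError(f"panel assays missing from input row: {missing}")
    values = row[list(panel.assays)]
    if values.isna().any():
        return float("nan")
    return float(-values[list(panel.up_assays)].sum() + values[list(panel.down_assays)].sum())


def score_cohort(delta_cq: pd.DataFrame, panel: MarkerPanel | None = None) -> ScoreTable:
    """Score every patient row of a ΔCq matrix (no class assignment)."""
    panel = panel or default_mor_panel()
    missing = [a for a in panel.assays if a not in delta_cq.columns]
    if missing:
        raise KeyError(f"panel assays missing from ΔCq matrix: {missing}")
    markers = delta_cq[list(panel.assays)].astype(float)
    score = -markers[list(panel.up_assays)].sum(axis=1, min_count=len(panel.up_assays)) + markers[
        list(panel.down_assays)
    ].sum(axis=1, min_count=len(panel.down_assays))
    score[markers.isna().any(axis=1)] = np.nan
    table = pd.concat([score.rename("score"), markers], axis=1)
    table.insert(1, "class_label", UNASSIGNED)
    table.index.name = "patient"
    return ScoreTable(table=table, panel=panel)


def classify_patients(
    delta_cq: pd.DataFrame,
    panel: MarkerPanel | None = None,
    spec: ClusteringSpec | None = None,
) -> ScoreTable:
    """Stratify patients into putative high/low MOR-signal classes.

    Hierarchical clustering on the panel ΔCq feature space under ``spec``,
    dendrogram cut at two clusters; the cluster with the higher mean MOR
    signal score becomes class 1. Patients with incomplete marker rows are
    labeled ``unassigned`` and excluded from the clustering.

    Raises
    ------
    ClusteringError
        Fewer than 3 complete marker rows, or all complete rows identical
        (every pairwise distance zero — no two-class structure exists).
    """
    panel = panel or default_mor_panel()
    spec = spec or ClusteringSpec()
    st = score_cohort(delta_cq, panel)
    markers = st.table[list(panel.assays)]
    complete = markers.notna().all(axis=1)
    X = markers.loc[complete].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ClusteringError(
            f"need >= 3 patients with complete marker rows, have {X.shape[0]}"
        )
    if np.allclose(X, X[0], atol=0.0):
        raise ClusteringError("all complete marker rows are identical; clustering is degenerate")
    if spec.distance == "correlation" and np.any(np.std(X, axis=1) == 0):
        flat = markers.loc[complete].index[np.std(X, axis=1) == 0].tolist()
        raise ClusteringError(
            f"constant marker rows have undefined correlation distance: {flat}"
        )

    merges = linkage(X, method=spec.linkage, metric=spec.distance)
    raw_labels = fcluster(merges, t=spec.n_clusters, criterion="maxclust")

    labels = pd.Series(raw_labels, index=markers.index[complete])
    # deterministic orientation: the cluster with higher mean score is class 1
    means = st.scores.loc[labels.index].groupby(labels).mean().sort_values(ascending=False)
    rank_of = {cluster: rank + 1 for rank, cluster in enumerate(means.index)}
    st.table["class_label"] = UNASSIGNED
    st.table.loc[labels.index, "class_label"] = labels.map(rank_of)
    st.spec = spec
    st.merges = merges
    return st


def score_report(st: ScoreTable, decimals: int = 1) -> pd.DataFrame:
    """Ranked per-patient report: descending score, missing scores last.

    Scores and marker values are presented in −ΔCq units (higher = more
    abundant) rounded to ``decimals``; ties keep patient-id order.
    """
    table = st.table.sort_index(kind="mergesort")
    order = (-table["score"]).rank(method="first", na_option="bottom")
    table = table.iloc[np.argsort(order.to_numpy(), kind="stable")]
    out = pd.DataFrame(index=table.index)
    out["score"] = table["score"].round(decimals)
    out["class_label"] = table["class_label"]
    for assay in st.panel.assays:
        out[f"neg_delta_cq:{assay}"] = (-table[assay]).round(decimals)
    return out
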