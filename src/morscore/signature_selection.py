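"""Selection of opioid-regulated marker miRNAs from paired pre/post panels.

Healthy subjects dosed once with an opioid provide paired plasma panels:
ΔCq before treatment and 24 h after. For every assay the change
ΔΔCq = ΔCq(24 h) − ΔCq(0 h) is tested against zero with a paired t-test,
and q-values are obtained with the Benjamini–Hochberg step-up procedure
within each drug's panel. Assays significant (q below threshold) and
changed in the same direction under *both* drugs form the common
signature; the markers with the largest mean |ΔΔCq| are kept as the final
up/down panel. Because lower Cq means more template, a *negative* mean
ΔΔCq marks an upregulated miRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedPanel",
    "MarkerPanel",
    "CommonSignature",
    "UP",
    "DOWN",
    "paired_differential",
    "common_signature",
    "select_top_markers",
    "default_mor_panel",
    "DEFAULT_UP_ASSAYS",
    "DEFAULT_DOWN_ASSAYS",
]

UP = "up"
DOWN = "down"

#: Plasma miRNAs upregulated after single-dose MOR-agonist treatment.
DEFAULT_UP_ASSAYS: tuple[str, ...] = (
    "hsa-miR-423-3p",
    "hsa-let-7a-5p",
    "hsa-miR-26a-5p",
    "hsa-let-7f-5p",
)
#: Plasma miRNAs downregulated after single-dose MOR-agonist treatment.
DEFAULT_DOWN_ASSAYS: tuple[str, ...] = (
    "hsa-miR-144-3p",
    "hsa-miR-451a",
    "hsa-miR-215",
    "hsa-miR-363-3p",
)


@dataclass
class PairedPanel:
    """Paired pre/post ΔCq grids (subjects × assays) for one drug."""

    pre: pd.DataFrame
    post: pd.DataFrame
    drug_label: str = ""

    def __post_init__(self) -> None:
        if not self.pre.index.equals(self.post.index) or not self.pre.columns.equals(
            self.post.columns
        ):
            raise ValueError("pre and post grids must share subject and assay ids in order")
        self.pre = self.pre.astype(float)
        self.post = self.post.astype(float)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.pre.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.pre.columns)

    def changes(self) -> pd.DataFrame:
        """ΔΔCq = post − pre; NaN wherever either member is missing."""
        return self.post - self.pre


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered up/down marker miRNA lists used for signature scoring."""

    up_assays: tuple[str, ...]
    down_assays: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_assays", tuple(self.up_assays))
        object.__setattr__(self, "down_assays", tuple(self.down_assays))
        overlap = set(self.up_assays) & set(self.down_assays)
        if overlap:
            raise ValueError(f"up/down marker lists overlap: {sorted(overlap)}")

    @property
    def assays(self) -> tuple[str, ...]:
        return self.up_assays + self.down_assays

    def swapped(self) -> "MarkerPanel":
        return MarkerPanel(self.down_assays, self.up_assays)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"up_assays": list(self.up_assays), "down_assays": list(self.down_assays)},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(tuple(doc["up_assays"]), tuple(doc["down_assays"]))


def default_mor_panel() -> MarkerPanel:
    """The fixed 4-up/4-down plasma miRNA panel for MOR signal scoring."""
    return MarkerPanel(DEFAULT_UP_ASSAYS, DEFAULT_DOWN_ASSAYS)


# ---------------------------------------------------------------------------
# Paired differential testing
# ---------------------------------------------------------------------------

def paired_differential(panel: PairedPanel) -> pd.DataFrame:
    """Per-assay paired t-test of ΔΔCq against zero, with BH q-values.

    Only subjects with both pre and post present contribute to an assay.
    Assays with fewer than 2 complete pairs carry no test result (NaN).
    Zero-variance nonzero differences are degenerate: reported with p=0
    (and q from BH as usual) plus ``degenerate=True`` rather than aborting
    a panel-wide run; zero-variance all-zero differences get t=0, p=1.

    Returns a DataFrame indexed by assay with columns ``mean_change``,
    ``t_stat``, ``df``, ``p_value``, ``q_value``, ``n_pairs``,
    ``direction`` (``up`` when mean ΔΔCq < 0), ``degenerate``.
    """
    diffs = panel.changes().to_numpy(dtype=float)
    n_pairs = np.sum(~np.isnan(diffs), axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(np.where(np.isnan(diffs), np.nan, diffs), axis=0)
        sd = np.nanstd(diffs, axis=0, ddof=1)

    testable = n_pairs >= 2
    if not np.any(testable):
        raise ValueError("no assay has >= 2 complete pre/post pairs; nothing to test")

    df = np.where(testable, n_pairs - 1, 0).astype(float)
    se = np.full(diffs.shape[1], np.nan)
    np.divide(sd, np.sqrt(np.maximum(n_pairs, 1)), out=se, where=testable)

    t_stat = np.full(diffs.shape[1], np.nan)
    p_value = np.full(diffs.shape[1], np.nan)
    degenerate = np.zeros(diffs.shape[1], dtype=bool)

    zero_var = testable & (sd == 0)
    regular = testable & (sd > 0)
    t_stat[regular] = mean[regular] / se[regular]
    p_value[regular] = 2 * stats.t.sf(np.abs(t_stat[regular]), df[regular])
    # zero-variance conventions: identical nonzero shift -> maximal evidence
    nz = zero_var & (mean != 0)
    t_stat[nz] = np.sign(mean[nz]) * np.inf
    p_value[nz] = 0.0
    degenerate[zero_var] = True
    z0 = zero_var & (mean == 0)
    t_stat[z0] = 0.0
    p_value[z0] = 1.0

    q_value = np.full(diffs.shape[1], np.nan)
    q_value[testable] = multipletests(p_value[testable], method="fdr_bh")[1]

    direction = np.where(mean < 0, UP, np.where(mean > 0, DOWN, "none"))
    direction = np.where(testable, direction, "untested")

    out = pd.DataFrame(
        {
            "mean_change": mean,
            "t_stat": t_stat,
            "df": np.where(testable, df, np.nan),
            "p_value": p_value,
            "q_value": q_value,
            "n_pairs": n_pairs,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=pd.Index(panel.assay_ids, name="assay"),
    )
    return out


# ---------------------------------------------------------------------------
# Common signature across two drugs, and top-k marker selection
# ---------------------------------------------------------------------------

class CommonSignature(NamedTuple):
    panel: MarkerPanel
    conflicts: tuple[str, ...]  # significant in both drugs but opposite direction


def common_signature(
    a: pd.DataFrame, b: pd.DataFrame, q_threshold: float = 0.05
) -> CommonSignature:
    """Assays significant and same-direction under both drugs.

    ``a`` and ``b`` are :func:`paired_differential` results sharing an
    assay id space. Assays with q < ``q_threshold`` in both, changed the
    same way, enter the panel; assays significant in both but with
    conflicting directions are excluded and reported.
    """
    shared = a.index.intersection(b.index)
    a = a.loc[shared]
    b = b.loc[shared]
    sig = (a["q_value"] < q_threshold) & (b["q_value"] < q_threshold)
    same = a["direction"] == b["direction"]
    up = shared[(sig & same & (a["direction"] == UP)).to_numpy()]
    down = shared[(sig & same & (a["direction"] == DOWN)).to_numpy()]
    conflict = shared[
        (
            sig
            & ~same
            & a["direction"].isin([UP, DOWN])
            & b["direction"].isin([UP, DOWN])
        ).to_numpy()
    ]
    return CommonSignature(MarkerPanel(tuple(up), tuple(down)), tuple(conflict))


def select_top_markers(
    panel: MarkerPanel, ref: pd.DataFrame, k_up: int = 4, k_down: int = 4
) -> MarkerPanel:
    """Keep the k markers per direction with the clearest expression change.

    "Clearest" is the largest |mean ΔΔCq| in the reference differential
    result ``ref``; ties break by smaller q-value, then by assay id. If k
    exceeds the available assays, all are kept with a warning.
    """
    ref = ref.rename_axis("assay")
    missing = [x for x in panel.assays if x not in ref.index]
    if missing:
        raise KeyError(f"panel assays absent from reference result: {missing}")

    def top(assays: tuple[str, ...], k: int) -> tuple[str, ...]:
        if k > len(assays):
            warnings.warn(
                f"requested top {k} markers but only {len(assays)} available; keeping all",
                stacklevel=3,
            )
            k = len(assays)
        sub = ref.loc[list(assays)]
        order = sub.assign(abs_change=sub["mean_change"].abs()).sort_values(
            by=["abs_change", "q_value", "assay"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        return tuple(order.index[:k])

    return MarkerPanel(top(panel.up_assays, k_up), top(panel.down_assays, k_down))
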