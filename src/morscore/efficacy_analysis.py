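"""ΔVAS derivation and association of MOR signal score with analgesic efficacy.

Pain intensity is self-reported once daily on a 0–100 mm Visual Analog
Scale (VAS). Around an opioid switch on day 1:

* Baseline VAS  = mean VAS over days −3, −2, −1 and 1 (pre-switch),
* Treatment VAS = mean VAS over days 2, 3 and 4 (on the new opioid),
* ΔVAS          = Treatment VAS − Baseline VAS  (negative = pain improved).

Each window averages whatever days are available; a fully missing window
makes ΔVAS missing for that patient. Association between the MOR signal
score and ΔVAS is evaluated two ways: Spearman rank correlation of score
vs ΔVAS, and Fisher's exact test of the 2×2 table class (1/2) ×
(ΔVAS > 0 vs ΔVAS ≤ 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASELINE_DAYS",
    "TREATMENT_DAYS",
    "VALID_DAYS",
    "VasSeries",
    "BaselineResult",
    "DeltaVasResult",
    "SpearmanResult",
    "FisherResult",
    "baseline_vas",
    "delta_vas",
    "efficacy_summary",
    "read_vas_table",
    "vas_series_from_frame",
    "spearman_assoc",
    "fisher_enrichment",
    "association_report",
]

BASELINE_DAYS: tuple[int, ...] = (-3, -2, -1, 1)
TREATMENT_DAYS: tuple[int, ...] = (2, 3, 4)
VALID_DAYS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3, 4)


@dataclass
class VasSeries:
    """Daily VAS records (mm) for one patient, keyed by study-day index."""

    patient_id: str
    records: dict[int, float]

    def __post_init__(self) -> None:
        self.records = {int(d): float(v) for d, v in self.records.items()}
        bad_days = sorted(set(self.records) - set(VALID_DAYS))
        if bad_days:
            raise ValueError(f"{self.patient_id}: day indices outside {VALID_DAYS}: {bad_days}")
        bad_vals = {d: v for d, v in self.records.items() if not 0 <= v <= 100}
        if bad_vals:
            raise ValueError(f"{self.patient_id}: VAS values outside [0, 100] mm: {bad_vals}")


class BaselineResult(NamedTuple):
    value: float  # mm, NaN when no baseline day available
    n_days: int


class DeltaVasResult(NamedTuple):
    delta: float  # mm, NaN when either window is empty
    baseline: float
    treatment: float
    n_baseline_days: int
    n_treatment_days: int


def _window_mean(v: VasSeries, days: tuple[int, ...]) -> tuple[float, int]:
    present = [v.records[d] for d in days if d in v.records]
    if not present:
        return float("nan"), 0
    return float(np.mean(present)), len(present)


def baseline_vas(v: VasSeries) -> BaselineResult:
    """Mean VAS over available pre-switch days (−3, −2, −1, 1)."""
    return BaselineResult(*_window_mean(v, BASELINE_DAYS))


def delta_vas(v: VasSeries) -> DeltaVasResult:
    """Treatment-window mean (days 2–4) minus baseline; NaN if a window is empty."""
    base, n_base = _window_mean(v, BASELINE_DAYS)
    treat, n_treat = _window_mean(v, TREATMENT_DAYS)
    return DeltaVasResult(treat - base, base, treat, n_base, n_treat)


def efficacy_summary(series: list[VasSeries] | dict[str, VasSeries]) -> pd.DataFrame:
    """Per-patient baseline/treatment/ΔVAS table with contributing-day counts."""
    if isinstance(series, dict):
        series = list(series.values())
    rows = {}
    for v in series:
        if v.patient_id in rows:
            raise ValueError(f"duplicate patient id {v.patient_id}")
        rows[v.patient_id] = delta_vas(v)._asdict()
    out = pd.DataFrame.from_dict(rows, orient="index").rename(
        columns={"delta": "delta_vas", "baseline": "baseline_vas", "treatment": "treatment_vas"}
    )
    out.index.name = "patient"
    return out[["baseline_vas", "treatment_vas", "delta_vas", "n_baseline_days", "n_treatment_days"]]


def vas_series_from_frame(frame: pd.DataFrame) -> list[VasSeries]:
    """Build per-patient series from a long table (patient, day, vas_mm)."""
    required = {"patient", "day", "vas_mm"}
    if not required <= set(frame.columns):
        raise ValueError(f"VAS table requires columns {sorted(required)}")
    if frame.duplicated(subset=["patient", "day"]).any():
        raise ValueError("duplicate (patient, day) records")
    out = []
    for pid, grp in frame.groupby("patient", sort=False):
        recs = {
            int(d): float(v)
            for d, v in zip(grp["day"], grp["vas_mm"])
            if pd.notna(v)
        }
        out.append(VasSeries(str(pid), recs))
    return out


def read_vas_table(path, sep: str | None = None) -> list[VasSeries]:
    """Read a long VAS table with columns patient, day, vas_mm."""
    raw = pd.read_csv(path, sep=sep, engine="python")
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    try:
        return vas_series_from_frame(raw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------

class SpearmanResult(NamedTuple):
    rho: float
    p_value: float  # two-sided, t-approximation
    n: int
    p_exact: float | None = None  # exhaustive permutation p, small n only


class FisherResult(NamedTuple):
    table: tuple[tuple[int, int], tuple[int, int]]  # rows class 1/2 × (ΔVAS>0, ΔVAS<=0)
    p_value: float  # two-sided
    odds_ratio: float  # sample OR; Haldane 0.5 correction when a cell is 0
    n: int


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: share of y-permutations with |rho| >= |rho_obs|."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        hits += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


def spearman_assoc(scores, dvas, exact: bool | None = None) -> SpearmanResult:
    """Spearman rank correlation between score and ΔVAS.

    Missing pairs are excluded listwise. ``rho`` uses mid-ranks; the
    two-sided p comes from the t-approximation
    t = rho·sqrt((n−2)/(1−rho²)) on n−2 df. An exhaustive-permutation p
    is additionally reported when n ≤ 10 (or on request via ``exact``).
    """
    s = pd.Series(scores, dtype=float)
    d = pd.Series(dvas, dtype=float)
    s, d = s.align(d, join="inner")
    keep = s.notna() & d.notna()
    x = s[keep].to_numpy()
    y = d[keep].to_numpy()
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete (score, ΔVAS) pairs, have {n}")
    if np.all(y == y[0]) or np.all(x == x[0]):
        return SpearmanResult(float("nan"), float("nan"), n, None)
    rho, p = stats.spearmanr(x, y)
    p_exact = None
    if exact is None:
        exact = n <= 10
    if exact:
        if n > 10:
            raise ValueError("exact permutation p supported only for n <= 10")
        p_exact = _exact_spearman_p(x, y, rho)
    return SpearmanResult(float(rho), float(p), n, p_exact)


def fisher_enrichment(classes, dvas) -> FisherResult:
    """Fisher's exact test for enrichment of non-improving patients in class 1.

    Builds the 2×2 table rows = class 1/2, columns = ΔVAS > 0 vs ΔVAS ≤ 0
    over patients with both a class and a ΔVAS, and computes the two-sided
    p by summing hypergeometric probabilities of tables no more probable
    than the observed one. The odds ratio is the sample (cross-product)
    ratio, with the Haldane 0.5 continuity correction applied for display
    when any cell is zero.
    """
    c = pd.Series(classes)
    d = pd.Series(dvas, dtype=float)
    c, d = c.align(d, join="inner")
    keep = d.notna() & c.isin([1, 2, "1", "2"])
    c = c[keep].astype(int)
    d = d[keep]
    for cls in (1, 2):
        if (c == cls).sum() == 0:
            raise ValueError(f"class {cls} has zero evaluable patients")
    a = int(((c == 1) & (d > 0)).sum())
    b = int(((c == 1) & (d <= 0)).sum())
    cc = int(((c == 2) & (d > 0)).sum())
    dd = int(((c == 2) & (d <= 0)).sum())
    table = ((a, b), (cc, dd))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, cc, dd) == 0:
        odds = ((a + 0.5) * (dd + 0.5)) / ((b + 0.5) * (cc + 0.5))
    else:
        odds = (a * dd) / (b * cc)
    return FisherResult(table, float(p), float(odds), a + b + cc + dd)


def association_report(score_table, efficacy: pd.DataFrame) -> dict:
    """Join scores/classes with ΔVAS and run both association tests.

    ``score_table`` is a :class:`morscore.mor_scoring.ScoreTable`;
    ``efficacy`` comes from :func:`efficacy_summary`. Returns a JSON-ready
    dict with the evaluable roster, Spearman and Fisher results; the Fisher
    test is skipped (with a reason) when fewer than two classes are
    represented among evaluable patients.
    """
    st = score_table.table
    joined = st.join(efficacy["delta_vas"], how="inner")
    if joined.empty:
        raise ValueError("no shared patient ids between scores and efficacy table")
    joined = joined.sort_index(kind="mergesort")
    evaluable = joined[joined["score"].notna() & joined["delta_vas"].notna()]

    sp = spearman_assoc(evaluable["score"], evaluable["delta_vas"], exact=len(evaluable) <= 10)
    report: dict = {
        "n_patients": int(len(joined)),
        "n_evaluable": int(len(evaluable)),
        "evaluable_patients": list(map(str, evaluable.index)),
        "spearman": {
            "rho": sp.rho,
            "p_value": sp.p_value,
            "n": sp.n,
            "p_exact": sp.p_exact,
        },
    }
    classed = evaluable[evaluable["class_label"].isin([1, 2])]
    n_classes = classed["class_label"].nunique()
    if n_classes < 2:
        report["fisher"] = {
            "skipped": f"only {n_classes} class(es) represented among evaluable patients"
        }
    else:
        fe = fisher_enrichment(classed["class_label"], classed["delta_vas"])
        report["fisher"] = {
            "table": [list(r) for r in fe.table],
            "p_value": fe.p_value,
            "odds_ratio": fe.odds_ratio,
            "n": fe.n,
        }
    return report
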