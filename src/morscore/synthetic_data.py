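"""Synthetic qPCR panels and patient cohorts for end-to-end testing.

Two generators cover the pipeline's inputs without any external data:

* :func:`generate_healthy_panel` — paired pre/post raw Cq panels for a
  small healthy-subject drug study, with effects planted on chosen assays
  (an upregulated miRNA gets a *lower* post-treatment Cq). Internal
  controls receive only small random drift so that ΔCq normalization
  remains anchored.
* :func:`generate_patient_cohort` — a cancer-pain cohort whose latent
  MOR-signal class drives both the eight-marker ΔCq profile (mirrored
  between classes, a fixed cycle separation apart) and the daily VAS
  trajectory (class 1 worsens, class 2 improves after the switch, by
  ``dvas_effect`` mm between class means).

Every generator takes a single seeded :class:`numpy.random.Generator`
derived from ``SynthConfig.seed`` and writes ground-truth tables so tests
compare against the truth files, never against generator internals.
Measurement noise is Gaussian on the Cq scale (log-scale noise is
approximately Gaussian in cycles); VAS values are clipped to [0, 100] mm
and the clipping rate is reported.

:func:`table2_fixture` returns the packaged 25-patient reference cohort
(marker −ΔCq values, ΔVAS, dose ratio, severe-adverse-event flags); the
published score column is available separately as *expected output* via
:func:`table2_expected_scores` and is never used as an input.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .qpcr_panel_io import (
    DEFAULT_CONTROL_ASSAYS,
    CqMatrix,
    DeltaCqMatrix,
    NormalizationConfig,
    apply_detection_filter,
    normalize,
    write_cq_table,
)
from .signature_selection import (
    DEFAULT_DOWN_ASSAYS,
    DEFAULT_UP_ASSAYS,
    MarkerPanel,
    PairedPanel,
    default_mor_panel,
)

__all__ = [
    "SynthConfig",
    "HealthyPanelData",
    "PatientCohortData",
    "generate_healthy_panel",
    "generate_patient_cohort",
    "table2_fixture",
    "table2_expected_scores",
]

_DEFAULT_PLANTED_UP = {a: 1.0 for a in DEFAULT_UP_ASSAYS}
_DEFAULT_PLANTED_DOWN = {a: 1.0 for a in DEFAULT_DOWN_ASSAYS}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Healthy-subject panel: ``n_subjects_healthy`` subjects × ``n_assays``
    assays (the serum/plasma focus panel measures 179), planted effect
    sizes in cycles, per-measurement Cq noise ``cq_noise_sd`` and
    internal-control drift ``control_drift_sd``.

    Patient cohort: ``n_patients`` patients split by ``class_proportions``
    into latent high/low MOR-signal classes whose marker means sit
    ``marker_separation`` cycles apart (within-class SD
    ``marker_noise_sd``); daily VAS has mean ``vas_baseline_mean`` ±
    ``vas_baseline_sd`` across patients, day-to-day noise
    ``vas_day_noise_sd``, and an expected between-class ΔVAS difference of
    ``dvas_effect`` mm. ``missing_day_rate``/``missing_assay_rate`` inject
    missingness.
    """

    seed: int
    # healthy-subject paired panel
    n_subjects_healthy: int = 6
    n_assays: int = 179
    planted_up: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PLANTED_UP))
    planted_down: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PLANTED_DOWN))
    cq_noise_sd: float = 0.5
    control_drift_sd: float = 0.1
    # patient cohort
    n_patients: int = 25
    class_proportions: tuple[float, float] = (0.68, 0.32)
    marker_separation: float = 2.0
    marker_noise_sd: float = 0.7
    vas_baseline_mean: float = 14.0
    vas_baseline_sd: float = 10.0
    dvas_effect: float = 4.0
    vas_day_noise_sd: float = 5.0
    missing_day_rate: float = 0.05
    missing_assay_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cq_noise_sd", "control_drift_sd", "marker_noise_sd",
                     "vas_baseline_sd", "vas_day_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_day_rate", "missing_assay_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted_up and planted_down must be disjoint")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _assay_ids(cfg: SynthConfig) -> list[str]:
    """Panel assay ids: internal controls + default markers + simulated filler."""
    named = list(DEFAULT_CONTROL_ASSAYS) + list(DEFAULT_UP_ASSAYS) + list(DEFAULT_DOWN_ASSAYS)
    extra = [a for a in cfg.planted_up | cfg.planted_down if a not in named]
    named += extra
    n_fill = cfg.n_assays - len(named)
    if n_fill < 0:
        raise ValueError(f"n_assays={cfg.n_assays} smaller than the {len(named)} named assays")
    return named + [f"miR-sim-{i:03d}" for i in range(n_fill)]


class HealthyPanelData(NamedTuple):
    panel: PairedPanel          # normalized ΔCq pre/post
    cq_pre: CqMatrix            # raw Cq, detection-filtered
    cq_post: CqMatrix
    truth: pd.DataFrame         # assay, planted effect (cycles), direction


def generate_healthy_panel(cfg: SynthConfig, drug_label: str = "hydromorphone",
                           out_dir: str | Path | None = None) -> HealthyPanelData:
    """Paired pre/post Cq panels with planted drug effects.

    Each assay gets a baseline Cq (controls low/stable, targets spread
    across the detectable range); each subject a per-sample loading offset
    shared by both timepoints, which the ΔCq normalization must cancel.
    Planted up-assays have their post Cq lowered by the configured effect,
    down-assays raised; internal controls receive only drift.
    """
    assays = _assay_ids(cfg)
    missing = [a for a in (set(cfg.planted_up) | set(cfg.planted_down)) if a not in assays]
    if missing:
        raise ValueError(f"planted assays not on the panel: {missing}")
    rng = cfg.rng(stream=zlib.crc32(drug_label.encode()))
    n, m = cfg.n_subjects_healthy, len(assays)
    subjects = [f"{drug_label[:3]}-s{i+1}" for i in range(n)]

    is_control = np.isin(assays, DEFAULT_CONTROL_ASSAYS)
    baseline = rng.normal(28.0, 3.0, size=m)
    baseline[is_control] = rng.normal(22.0, 1.0, size=is_control.sum())
    loading = rng.normal(0.0, 1.0, size=n)  # per-sample extraction/input offset

    effect = np.zeros(m)
    for a, e in cfg.planted_up.items():
        effect[assays.index(a)] = -abs(e)  # upregulated: lower post Cq
    for a, e in cfg.planted_down.items():
        effect[assays.index(a)] = abs(e)
    effect[is_control] = 0.0

    def draw(shift: np.ndarray) -> pd.DataFrame:
        noise = rng.normal(0.0, cfg.cq_noise_sd, size=(n, m))
        drift = np.zeros((n, m))
        drift[:, is_control] = rng.normal(0.0, cfg.control_drift_sd, size=(n, is_control.sum()))
        cq = baseline + shift + loading[:, None] + noise + drift
        if cfg.missing_assay_rate > 0:
            cq[rng.random((n, m)) < cfg.missing_assay_rate] = np.nan
        return pd.DataFrame(np.clip(cq, 1.0, None), index=subjects, columns=assays)

    cq_pre = CqMatrix(draw(np.zeros(m)))
    cq_post = CqMatrix(draw(effect))
    norm_cfg = NormalizationConfig()
    cq_pre = apply_detection_filter(cq_pre, norm_cfg)
    cq_post = apply_detection_filter(cq_post, norm_cfg)
    panel = PairedPanel(
        pre=normalize(cq_pre, norm_cfg).delta_cq,
        post=normalize(cq_post, norm_cfg).delta_cq,
        drug_label=drug_label,
    )
    truth = pd.DataFrame(
        {
            "assay": assays,
            "planted_effect_cycles": effect,
            "direction": np.where(effect < 0, "up", np.where(effect > 0, "down", "none")),
            "is_control": is_control,
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cq_table(cq_pre, out_dir / f"{drug_label}_pre_cq.tsv")
        write_cq_table(cq_post, out_dir / f"{drug_label}_post_cq.tsv")
        truth.to_csv(out_dir / f"{drug_label}_truth.tsv", sep="\t", index=False)
    return HealthyPanelData(panel, cq_pre, cq_post, truth)


class PatientCohortData(NamedTuple):
    marker_delta_cq: pd.DataFrame  # patients × 8 markers, ΔCq
    vas: pd.DataFrame              # long: patient, day, vas_mm
    truth: pd.DataFrame            # patient, latent class, expected ΔVAS
    clipping_rate: float           # share of VAS draws clipped into [0, 100]


def generate_patient_cohort(cfg: SynthConfig, panel: MarkerPanel | None = None,
                            out_dir: str | Path | None = None) -> PatientCohortData:
    """Cohort whose latent class drives both markers and VAS response.

    Class 1 (high MOR signal): up markers abundant (−ΔCq high, i.e. ΔCq
    shifted down) and down markers scarce; expected ΔVAS shifted up by
    ``dvas_effect/2`` (poor responders). Class 2 is the mirror image.
    Marker class means sit on Table-2-like per-assay baselines.
    """
    panel = panel or default_mor_panel()
    rng = cfg.rng(stream=1)
    n = cfg.n_patients
    patients = [f"p{i+1:02d}" for i in range(n)]
    latent = np.where(rng.random(n) < cfg.class_proportions[0], 1, 2)

    markers = list(panel.assays)
    k_up = len(panel.up_assays)
    # per-assay baseline ΔCq around which both classes sit
    base = rng.normal(2.0, 1.5, size=len(markers))
    sign = np.array([-1.0] * k_up + [1.0] * (len(markers) - k_up))  # class-1 shift direction in ΔCq
    shift = np.where(latent[:, None] == 1, 1.0, -1.0) * sign * (cfg.marker_separation / 2.0)
    delta = base + shift + rng.normal(0.0, cfg.marker_noise_sd, size=(n, len(markers)))
    if cfg.missing_assay_rate > 0:
        delta[rng.random(delta.shape) < cfg.missing_assay_rate] = np.nan
    marker_delta_cq = pd.DataFrame(delta, index=patients, columns=markers)
    marker_delta_cq.index.name = "patient"

    days = np.array([-3, -2, -1, 1, 2, 3, 4])
    patient_baseline = rng.normal(cfg.vas_baseline_mean, cfg.vas_baseline_sd, size=n)
    class_shift = np.where(latent == 1, +cfg.dvas_effect / 2.0, -cfg.dvas_effect / 2.0)
    raw_rows = []
    n_draws = n_clipped = 0
    for i, pid in enumerate(patients):
        for day in days:
            if rng.random() < cfg.missing_day_rate:
                continue
            mean = patient_baseline[i] + (class_shift[i] if day >= 2 else 0.0)
            value = mean + rng.normal(0.0, cfg.vas_day_noise_sd)
            clipped = min(max(value, 0.0), 100.0)
            n_draws += 1
            n_clipped += clipped != value
            raw_rows.append((pid, int(day), round(clipped, 1)))
    vas = pd.DataFrame(raw_rows, columns=["patient", "day", "vas_mm"])

    truth = pd.DataFrame(
        {
            "patient": patients,
            "latent_class": latent,
            "expected_dvas_mm": class_shift,
            "baseline_mean_mm": patient_baseline,
        }
    )
    clipping_rate = n_clipped / n_draws if n_draws else 0.0
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        marker_delta_cq.to_csv(out_dir / "cohort_marker_delta_cq.tsv", sep="\t", na_rep="NA")
        vas.to_csv(out_dir / "cohort_vas.tsv", sep="\t", index=False)
        truth.to_csv(out_dir / "cohort_truth.tsv", sep="\t", index=False)
    return PatientCohortData(marker_delta_cq, vas, truth, clipping_rate)


# ---------------------------------------------------------------------------
# Packaged reference cohort
# ---------------------------------------------------------------------------

def _table2_raw() -> pd.DataFrame:
    with resources.files("morscore.data").joinpath("table2.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t", index_col="patient")
    return raw


def table2_fixture() -> pd.DataFrame:
    """The packaged 25-patient reference cohort, as inputs only.

    Columns: the eight marker −ΔCq values (higher = more abundant),
    ``delta_vas`` (mm, NaN for the two patients whose VAS records were
    incomplete), ``dose_ratio`` and ``sae``. The published score column is
    deliberately excluded; see :func:`table2_expected_scores`.
    """
    raw = _table2_raw()
    out = raw.drop(columns=["mor_signal_score"])
    out["sae"] = out["sae"].fillna("") == "+"
    return out


def table2_expected_scores() -> pd.Series:
    """Published per-patient MOR signal scores (expected output, 1 dp)."""
    return _table2_raw()["mor_signal_score"].rename("expected_score")
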