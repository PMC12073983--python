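"""Two-phase study pipeline mirroring the blinded design.

Phase 1 computes each patient's HFO area from signals alone. Phase 2 joins
the clinical table (resections, outcomes) and computes the cohort statistics.
The API enforces the ordering: clinical data cannot enter before phase 1 has
completed, which encodes the blinding contract of the study design.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from . import stats as st
from .area import compute_hfo_area
from .config import AnalysisConfig
from .containers import HfoArea, PatientRecord, Recording
from .detection import rate_matrix_from_epochs
from .outcome import (
    build_confusion,
    conclusive_rate,
    resection_status,
    rv_comparator,
)
from .preprocessing import apply_exclusions, make_bipolar, resample_to_2000, segment_epochs

logger = logging.getLogger(__name__)


def analyse_recording(rec: Recording, config: AnalysisConfig | None = None) -> HfoArea:
    """Signals-only analysis of one patient: preprocess, detect, define area."""
    config = config or AnalysisConfig()
    rec = resample_to_2000(rec)
    rec = make_bipolar(rec)
    rec = apply_exclusions(rec)
    epochs = segment_epochs(rec, config.epoch_length_s)
    rates, _events = rate_matrix_from_epochs(epochs, config)
    return compute_hfo_area(rates, config)


class StudyRun:
    """Stateful two-phase run over a cohort of recordings."""

    def __init__(self, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.areas: dict[str, HfoArea | None] = {}
        self._phase1_done = False

    def run_phase1(self, recordings: Mapping[str, Recording]) -> dict[str, HfoArea | None]:
        """Compute HFO areas; a patient failing analysis is recorded as None
        (no prediction) and the run continues."""
        for pid, rec in recordings.items():
            try:
                self.areas[pid] = analyse_recording(rec, self.config)
            except ValueError as exc:
                logger.warning("patient %s failed phase 1: %s", pid, exc)
                self.areas[pid] = None
        self._phase1_done = True
        return dict(self.areas)

    def set_precomputed_areas(self, areas: Mapping[str, HfoArea | None]) -> None:
        """Accept phase-1 results computed elsewhere (e.g. the CLI `area` stage)."""
        self.areas = dict(areas)
        self._phase1_done = True

    def run_phase2(self, clinical: pd.DataFrame) -> dict:
        """Join clinical data and compute all cohort statistics.

        Refuses to run before phase 1 has completed (blinding contract).
        """
        if not self._phase1_done:
            raise RuntimeError(
                "clinical data refused: phase 1 (blinded HFO analysis) has not completed"
            )
        patients = []
        for row in clinical.itertuples(index=False):
            area = self.areas.get(row.patient_id)
            patients.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    centre_id=str(row.centre),
                    hfo_area=area,
                    resected_channels=frozenset(row.resected_channels),
                    ilae=int(row.ilae),
                    electrode_type=str(row.electrode_type),
                    age=row.age,
                    sex=str(row.sex),
                    pathology=int(row.pathology),
                    n_channels=getattr(row, "n_channels", None),
                    n_resected_channels=len(row.resected_channels),
                    follow_up_months=float(row.follow_up_months),
                )
            )
        return cohort_report(patients, self.config)


def per_centre_tables(patients: list[PatientRecord]) -> dict:
    """Per-centre counts used by the pooled analyses."""
    out: dict[str, dict] = {}
    for p in patients:
        if not p.conclusive:
            continue
        d = out.setdefault(p.centre_id, {"TP": 0, "TN": 0, "FP": 0, "FN": 0})
        cr = resection_status(p.hfo_area, p.resected_channels)
        good = p.seizure_free
        if cr and good:
            d["TN"] += 1
        elif cr:
            d["FN"] += 1
        elif good:
            d["FP"] += 1
        else:
            d["TP"] += 1
    return out


def cohort_report(patients: list[PatientRecord], config: AnalysisConfig | None = None) -> dict:
    """All cohort statistics as a JSON-serializable dict."""
    config = config or AnalysisConfig()
    level = config.ci_level
    conclusive = [p for p in patients if p.conclusive]
    n_concl, n_total, pct = conclusive_rate(patients)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": n_total,
        "n_conclusive": n_concl,
        "conclusive_pct": pct,
        "patients": [
            {
                "patient_id": p.patient_id,
                "centre": p.centre_id,
                "conclusive": p.conclusive,
                "area_channels": sorted(p.hfo_area.channels) if p.conclusive else [],
                "cr_hfo": (
                    resection_status(p.hfo_area, p.resected_channels) if p.conclusive else None
                ),
                "ilae": p.ilae,
            }
            for p in patients
        ],
    }

    cm = build_confusion(conclusive)
    report["confusion"] = cm.as_dict()
    report["hfo_summary"] = st.diagnostic_summary(cm, level).as_dict()
    rv = rv_comparator(conclusive)
    report["rv_confusion"] = rv.as_dict()
    report["rv_summary"] = st.diagnostic_summary(rv, level).as_dict()

    t1neg, t2neg, good = [], [], []
    for p in conclusive:
        t1neg.append(resection_status(p.hfo_area, p.resected_channels))
        t2neg.append(True)  # RV test: every included patient is a negative call
        good.append(p.seizure_free)
    try:
        r = st.relative_npv_test(t1neg, t2neg, good, level)
        report["relative_npv"] = {
            "rnpv": r.rnpv, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "log_se": r.log_se, "p_value": r.p_value,
        }
    except ValueError as exc:
        report["relative_npv"] = {"error": str(exc)}

    tables = per_centre_tables(patients)
    centres = sorted(tables)
    prop = [(tables[c]["TN"], tables[c]["TN"] + tables[c]["FN"]) for c in centres]
    ors = [
        (tables[c]["TN"], tables[c]["FP"], tables[c]["FN"], tables[c]["TP"])
        for c in centres
    ]
    srocs = [
        (tables[c]["TP"], tables[c]["FP"], tables[c]["TN"], tables[c]["FN"])
        for c in centres
    ]
    for key, fn in (
        ("pooled_ilae1_given_cr", lambda: st.pooled_proportion(
            prop, level, config.meta_transform, labels=centres)),
        ("pooled_or", lambda: st.pooled_or(ors, level, labels=centres)),
    ):
        try:
            report[key] = fn().as_dict()
        except ValueError as exc:
            report[key] = {"error": str(exc)}
    try:
        s = st.sroc(srocs, level, seed=config.seed)
        report["sroc"] = {
            "pooled_sensitivity": s.pooled_sensitivity, "sens_ci": list(s.sens_ci),
            "pooled_specificity": s.pooled_specificity, "spec_ci": list(s.spec_ci),
            "auc": s.auc, "auc_ci": list(s.auc_ci), "method": s.method,
            "auc_label": s.auc_label(),
        }
    except ValueError as exc:
        report["sroc"] = {"error": str(exc)}

    try:
        lm = st.outcome_lm(conclusive, level)
        report["outcome_lm"] = {
            "effects": lm.table.reset_index().rename(columns={"index": "effect"}).to_dict("records"),
            "dropped": lm.dropped,
            "n": lm.n,
        }
    except ValueError as exc:
        report["outcome_lm"] = {"error": str(exc)}

    return report


def run_pipeline(
    recordings: Mapping[str, Recording],
    clinical: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict:
    """End-to-end study: phase 1 on signals, then phase 2 with clinical data."""
    run = StudyRun(config)
    run.run_phase1(recordings)
    return run.run_phase2(clinical)
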