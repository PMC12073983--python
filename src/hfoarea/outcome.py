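"""Outcome prediction: HFO-area vs resection, patient-level confusion cells.

A patient whose HFO area lies entirely inside the resected volume is
"crHFO-area" (complete resection). The prediction is that incomplete
resection leads to recurrent seizures, so:

    TP: non-crHFO-area and recurrent seizures (ILAE 2-6)
    TN: crHFO-area and seizure free (ILAE 1)
    FP: non-crHFO-area but seizure free
    FN: crHFO-area but recurrent seizures

Inconclusive patients (no HFO area defined) receive no prediction and are
excluded from the confusion matrix. The clinical-practice comparator (the
resected volume as its own test) is degenerate by the inclusion criteria:
every seizure focus was resected, so TP = FP = 0 and the comparator reduces
to TN = #ILAE1, FN = #ILAE2-6.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .containers import ConfusionMatrix, HfoArea, PatientRecord


def resection_status(
    area: HfoArea,
    resected: Iterable[str],
    contacts_in_rv: Iterable[str] | None = None,
    channel_contacts: Mapping[str, Sequence[str]] | None = None,
) -> bool:
    """True iff every HFO-area channel was resected (crHFO-area).

    Two input styles: a channel-level resected list (the centre names bipolar
    channels directly), or contact-level data via ``contacts_in_rv`` +
    ``channel_contacts`` — then a bipolar channel counts as resected iff both
    of its physical contacts lie in the resection volume.
    """
    if not area.conclusive:
        raise ValueError("no prediction for this patient: HFO area inconclusive")
    resected = set(resected)
    if contacts_in_rv is not None:
        if channel_contacts is None:
            raise ValueError("contact-level input requires channel_contacts mapping")
        rv = set(contacts_in_rv)
        for ch in area.channels:
            contacts = channel_contacts.get(ch)
            if contacts is None:
                raise ValueError(f"no contact mapping for channel {ch!r}")
            if not set(contacts) <= rv:
                return False
        return True
    return area.channels <= resected


def confusion_label(cr_hfo: bool, ilae: int) -> str:
    """Map (complete resection?, ILAE class) to the confusion cell."""
    if ilae not in range(1, 7):
        raise ValueError(f"ilae must be in 1..6, got {ilae}")
    seizure_free = ilae == 1
    if cr_hfo:
        return "TN" if seizure_free else "FN"
    return "FP" if seizure_free else "TP"


def build_confusion(patients: Sequence[PatientRecord]) -> ConfusionMatrix:
    """Aggregate confusion cells over conclusive patients only."""
    cells = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    n_conclusive = 0
    for p in patients:
        if not p.conclusive:
            continue
        n_conclusive += 1
        cr = resection_status(p.hfo_area, p.resected_channels)
        cells[confusion_label(cr, p.ilae)] += 1
    if n_conclusive == 0:
        raise ValueError("all patients inconclusive: no confusion matrix")
    return ConfusionMatrix(**cells)


def rv_comparator(patients: Sequence[PatientRecord]) -> ConfusionMatrix:
    """Clinical-practice comparator over the same (conclusive) patients:
    TN = seizure-free count, FN = recurrent-seizure count, TP = FP = 0."""
    conclusive = [p for p in patients if p.conclusive]
    if not conclusive:
        raise ValueError("all patients inconclusive: no comparator")
    tn = sum(p.seizure_free for p in conclusive)
    return ConfusionMatrix(TP=0, TN=tn, FP=0, FN=len(conclusive) - tn)


def conclusive_rate(patients: Sequence[PatientRecord]) -> tuple[int, int, float]:
    """(n_conclusive, n_total, percent conclusive) over a cohort."""
    if not patients:
        raise ValueError("empty cohort")
    n = len(patients)
    k = sum(p.conclusive for p in patients)
    return k, n, 100.0 * k / n
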