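"""Pair repetitions across modalities, apply exclusion rules, keep the books.

The devices record autonomously with no shared clock, so repetitions are
paired by within-set order.  Exclusion rules mirror the validation study
design:

* stream devices (markers, IMUs): repetitions lost to flagged connectivity
  gaps are excluded individually (``connection_issue``) and the remainder
  pairs by order; any residual count mismatch discards the whole set
  (``segmentation_error``);
* black-box per-rep exports: trailing slow extras consistent with re-rack
  movements are stripped as ``ghost_rep``; repetitions the device's own log
  marks as lost are ``connection_issue``; any remaining duplicate/missed
  recognition excludes the entire set (``segmentation_error``);
* the plausibility filter removes pairs whose device metrics fail
  Vpeak > Vmean (``validity_check``); a criterion-side failure is routed to
  ``segmentation_error`` instead, since the criterion defines truth and its
  failure signals a processing defect.

The accounting table reconciles every attempted repetition against pairs
plus exclusions, one row per device.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .segmentation import RepMetrics, SLOW

PARAMETERS = ("vmean", "vpeak", "vprop")
STRATA = ("total", "fast", "slow")

#: vmean below which a trailing black-box entry is treated as a re-rack ghost;
#: re-rack excursions are leisurely (< ~0.18 m/s) while even terminal
#: exhaustion repetitions stay near 0.3 m/s, so the bands do not overlap
GHOST_VMEAN_MAX = 0.22


class Reason(str, Enum):
    CONNECTION_ISSUE = "connection_issue"
    SEGMENTATION_ERROR = "segmentation_error"
    VALIDITY_CHECK = "validity_check"
    GHOST_REP = "ghost_rep"
    PARTICIPANT_EXCLUDED = "participant_excluded"
    HANDLING_ERROR = "handling_error"
    SET_EXCLUDED = "set_excluded"


@dataclass
class ExclusionRecord:
    set_id: str
    device: str
    reason: Reason
    rep_index: int | None = None
    detail: str = ""


@dataclass
class RepPair:
    """One matched repetition: device metrics against criterion metrics."""

    set_id: str
    rep_index: int
    device: str
    device_metrics: RepMetrics
    criterion_metrics: RepMetrics

    @property
    def spectrum(self) -> str:
        # spectrum classification always follows the criterion's duration
        return self.criterion_metrics.spectrum


@dataclass
class PairedObservation:
    """One (device value, criterion value) pair for a single parameter."""

    set_id: str
    rep_index: int
    device: str
    parameter: str
    device_value: float
    criterion_value: float
    spectrum: str


def expand_pairs(pairs: list[RepPair]) -> list[PairedObservation]:
    obs = []
    for p in pairs:
        for param in PARAMETERS:
            obs.append(
                PairedObservation(
                    set_id=p.set_id,
                    rep_index=p.rep_index,
                    device=p.device,
                    parameter=param,
                    device_value=getattr(p.device_metrics, param),
                    criterion_value=getattr(p.criterion_metrics, param),
                    spectrum=p.spectrum,
                )
            )
    return obs


def pair_by_order(
    device_reps: dict[str, list[RepMetrics | None]],
    criterion_reps: dict[str, list[RepMetrics]],
    device_kind: str,
    device_name: str = "device",
    dropout_log: list[tuple[str, int]] | None = None,
) -> tuple[list[RepPair], list[ExclusionRecord]]:
    """Pair device and criterion repetitions set by set, by within-set order.

    ``device_reps`` may contain ``None`` placeholders where a stream
    repetition was swallowed by a flagged gap.  ``dropout_log`` lists
    (set_id, rep_index) entries a black-box device reported as lost.
    """
    if device_kind not in ("stream", "blackbox"):
        raise ValueError("device_kind must be 'stream' or 'blackbox'")
    dropout_log = dropout_log or []
    pairs: list[RepPair] = []
    exclusions: list[ExclusionRecord] = []

    for set_id, crit in criterion_reps.items():
        dev = list(device_reps.get(set_id, []))
        if device_kind == "blackbox":
            dev = _prepare_blackbox_set(dev, crit, set_id, device_name,
                                        dropout_log, exclusions)
        if len(dev) != len(crit):
            # duplicated or missed recognition: the entire set is excluded
            exclusions.extend(
                ExclusionRecord(set_id, device_name, Reason.SEGMENTATION_ERROR, i,
                                detail="set excluded: unexplained count mismatch")
                for i in range(len(crit))
            )
            continue
        for i, (dm, cm) in enumerate(zip(dev, crit)):
            if dm is None:
                exclusions.append(
                    ExclusionRecord(set_id, device_name, Reason.CONNECTION_ISSUE, i)
                )
            else:
                pairs.append(RepPair(set_id, i, device_name, dm, cm))
    return pairs, exclusions


def _prepare_blackbox_set(
    dev: list[RepMetrics],
    crit: list[RepMetrics],
    set_id: str,
    device_name: str,
    dropout_log: list[tuple[str, int]],
    exclusions: list[ExclusionRecord],
) -> list[RepMetrics | None]:
    """Strip ghost extras and re-insert logged dropouts as placeholders.

    Returns a slot list aligned with the criterion repetitions: ``None``
    marks a device-logged connectivity loss.  If recognition miscounts
    remain, the returned length will not match the criterion's, which the
    caller turns into a whole-set exclusion.
    """
    # surplus trailing entries slower than any plausible squat are re-rack
    # ghosts (the device appends them after the genuine repetitions); only
    # the surplus is stripped so a slow genuine repetition is never dropped
    logged = sorted(i for s, i in dropout_log if s == set_id)
    expected = len(crit) - len(logged)
    while len(dev) > expected and dev and dev[-1].vmean < GHOST_VMEAN_MAX:
        dev = dev[:-1]
        exclusions.append(ExclusionRecord(set_id, device_name, Reason.GHOST_REP))
    # re-insert the logged losses at their recorded within-set positions
    for i in logged:
        if i <= len(dev):
            dev = dev[:i] + [None] + dev[i:]
    return dev


def apply_validity_filter(
    pairs: list[RepPair],
) -> tuple[list[RepPair], list[ExclusionRecord]]:
    """Remove pairs failing the Vpeak > Vmean plausibility gate."""
    kept: list[RepPair] = []
    exclusions: list[ExclusionRecord] = []
    for p in pairs:
        if not p.criterion_metrics.valid:
            exclusions.append(
                ExclusionRecord(p.set_id, p.device, Reason.SEGMENTATION_ERROR,
                                p.rep_index, detail="criterion failed validity check")
            )
        elif not p.device_metrics.valid:
            exclusions.append(
                ExclusionRecord(p.set_id, p.device, Reason.VALIDITY_CHECK, p.rep_index)
            )
        else:
            kept.append(p)
    return kept, exclusions


ACCOUNTING_COLUMNS = [
    "Total",
    "Fast",
    "Slow",
    "ConnectionIssue",
    "SegmentationError",
    "ValidityCheck",
    "Ghost Reps",
    "Participant Excluded",
    "Handling Error",
]

_REASON_COLUMN = {
    Reason.CONNECTION_ISSUE: "ConnectionIssue",
    Reason.SEGMENTATION_ERROR: "SegmentationError",
    Reason.VALIDITY_CHECK: "ValidityCheck",
    Reason.GHOST_REP: "Ghost Reps",
    Reason.PARTICIPANT_EXCLUDED: "Participant Excluded",
    Reason.HANDLING_ERROR: "Handling Error",
    Reason.SET_EXCLUDED: "SegmentationError",
}


def accounting_table(
    pairs: list[RepPair],
    exclusions: list[ExclusionRecord],
    devices: list[str] | None = None,
) -> pd.DataFrame:
    """Per-device repetition accounting (pairs by spectrum, losses by reason).

    Ghost entries are spurious additions rather than losses, so for every
    device: attempted repetitions = Total + all exclusion columns except
    ``Ghost Reps``.
    """
    if devices is None:
        devices = sorted({p.device for p in pairs} | {e.device for e in exclusions})
    rows = {}
    for dev in devices:
        row = dict.fromkeys(ACCOUNTING_COLUMNS, 0)
        for p in pairs:
            if p.device == dev:
                row["Total"] += 1
                row["Slow" if p.spectrum == SLOW else "Fast"] += 1
        for e in exclusions:
            if e.device == dev:
                row[_REASON_COLUMN[e.reason]] += 1
        rows[dev] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=ACCOUNTING_COLUMNS)


def format_accounting(table: pd.DataFrame) -> str:
    return table.rename_axis("Device").reset_index().to_string(index=False)
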