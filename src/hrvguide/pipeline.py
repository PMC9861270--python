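"""End-to-end device-validation study: cleaning, HRV, agreement, reliability.

Reproduces the structure of a two-device validation analysis: every
recording is trimmed of its stabilization minute, artifact-corrected and
gated; per subject the LnrMSSD of the ultra-short (1-min) and short
(5-min) windows is computed for each device, position and trial; then
three statistical families are produced:

* device agreement (ECG vs app) per position, on 5-min LnrMSSD,
* duration agreement (1 min vs 5 min) per device and position,
* trial-retrial reliability (ICC, SEM, MDC) per device and position.

Bonferroni scaling uses the size of each comparison family (2 device
comparisons, 4 duration comparisons).
"""
from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .agreement_stats import MDC_FACTOR, PairedSample, compare, reliability
from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError
from .hrv_metrics import analyze_recording
from .preprocessing import clean_series, trim_stabilization
from .rr_io import Device, Position, RRSeries

__all__ = ["run_validation_study"]

logger = logging.getLogger(__name__)

_POSITIONS = (Position.SUPINE, Position.SEATED)
_DEVICES = (Device.ECG, Device.APP)


def _process_recordings(recordings, trim_seconds, exclusions, cleaning_rows):
    """Clean every recording and compute windowed LnrMSSD.

    Returns {(subject, position, device, trial): (ln_1min, ln_5min)}.
    """
    hrv: dict = {}
    for rec in recordings:
        trial = int(rec.extra.get("trial", 1))
        key = (rec.subject_id, rec.position, rec.device, trial)
        name = f"{rec.subject_id}/{rec.position.value}/{rec.device.value}/t{trial}"
        try:
            trimmed = trim_stabilization(rec, trim_seconds)
            report = clean_series(trimmed)
        except ValidationError as exc:
            exclusions.append(f"{name}: {exc}")
            continue
        cleaning_rows.append(
            {
                "subject": rec.subject_id,
                "position": rec.position.value,
                "device": rec.device.value,
                "trial": trial,
                "n_beats": len(trimmed),
                "n_corrected": report.n_corrected,
                "fraction_corrected": report.fraction_corrected,
                "accepted": report.accepted,
            }
        )
        if not report.accepted:
            exclusions.append(
                f"{name}: rejected by the 20% corrected-beats gate "
                f"(fraction {report.fraction_corrected:.2f})"
            )
            continue
        try:
            ultra, short = analyze_recording(report.corrected)
        except ValidationError as exc:
            exclusions.append(f"{name}: {exc}")
            continue
        if ultra.ln_rmssd is None or short.ln_rmssd is None:
            exclusions.append(f"{name}: LnrMSSD undefined (constant window)")
            continue
        hrv[key] = (ultra.ln_rmssd, short.ln_rmssd)
    return hrv


def _subject_means(hrv, exclusions):
    """Trial-averaged LnrMSSD per (subject, position, device), both windows.

    Subjects missing a device cell for a position are dropped from that
    position's paired analyses (unpaired → excluded with a logged warning).
    """
    cells = defaultdict(dict)
    subjects = sorted({k[0] for k in hrv})
    for subject in subjects:
        for position in _POSITIONS:
            for device in _DEVICES:
                vals = [
                    v for (s, p, d, _t), v in hrv.items()
                    if s == subject and p == position and d == device
                ]
                if vals:
                    cells[(subject, position)][device] = (
                        float(np.mean([v[0] for v in vals])),
                        float(np.mean([v[1] for v in vals])),
                    )
    for (subject, position), devs in list(cells.items()):
        if len(devs) < 2:
            exclusions.append(
                f"{subject}/{position.value}: unpaired (missing a device), excluded"
            )
            del cells[(subject, position)]
    return cells


def run_validation_study(
    recordings: Iterable[RRSeries],
    out_dir,
    trim_seconds: float = 60.0,
    ci_level: float = 0.90,
    min_subjects: int = 3,
) -> dict:
    """Run the full validation analysis and write its report bundle.

    ``recordings`` carry subject/position/device metadata and a ``trial``
    number in ``extra``.  Writes ``hrv_results.csv``,
    ``device_agreement.csv``, ``duration_agreement.csv``,
    ``reliability.csv``, ``cleaning_reports.csv`` and ``summary.txt`` to
    ``out_dir`` and returns the bundle as a dict of DataFrames plus the
    exclusion log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exclusions: list[str] = []
    cleaning_rows: list[dict] = []

    recordings = list(recordings)
    hrv = _process_recordings(recordings, trim_seconds, exclusions, cleaning_rows)
    n_subjects = len({k[0] for k in hrv})
    if n_subjects < min_subjects:
        raise InsufficientDataError(
            f"validation study requires >= {min_subjects} subjects with usable "
            f"recordings, have {n_subjects}"
        )
    cells = _subject_means(hrv, exclusions)

    hrv_rows = [
        {
            "subject": s,
            "position": p.value,
            "device": d.value,
            "trial": t,
            "ln_rmssd_1min": v[0],
            "ln_rmssd_5min": v[1],
        }
        for (s, p, d, t), v in sorted(hrv.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value, kv[0][3]))
    ]

    # --- device agreement: ECG vs app per position, 5-min LnrMSSD -------
    device_rows = []
    for position in _POSITIONS:
        subjects = sorted(s for (s, p) in cells if p == position)
        if len(subjects) < 3:
            exclusions.append(f"device agreement {position.value}: fewer than 3 paired subjects")
            continue
        x = [cells[(s, position)][Device.ECG][1] for s in subjects]
        y = [cells[(s, position)][Device.APP][1] for s in subjects]
        rep = compare(PairedSample(np.array(x), np.array(y), ("ecg", "app")), n_comparisons=2)
        device_rows.append(_agreement_row({"position": position.value}, rep))

    # --- duration agreement: 1 min vs 5 min per device and position -----
    duration_rows = []
    for device in _DEVICES:
        for position in _POSITIONS:
            subjects = sorted(s for (s, p) in cells if p == position)
            if len(subjects) < 3:
                continue
            x = [cells[(s, position)][device][0] for s in subjects]
            y = [cells[(s, position)][device][1] for s in subjects]
            rep = compare(PairedSample(np.array(x), np.array(y), ("1min", "5min")), n_comparisons=4)
            duration_rows.append(
                _agreement_row({"device": device.value, "position": position.value}, rep)
            )

    # --- trial-retrial reliability per device and position --------------
    reliability_rows = []
    for device in _DEVICES:
        for position in _POSITIONS:
            t1, t2 = [], []
            for subject in sorted({k[0] for k in hrv}):
                a = hrv.get((subject, position, device, 1))
                b = hrv.get((subject, position, device, 2))
                if a is not None and b is not None:
                    t1.append(a[1])
                    t2.append(b[1])
            if len(t1) < 3:
                exclusions.append(
                    f"reliability {device.value}/{position.value}: fewer than 3 "
                    "subjects with both trials"
                )
                continue
            try:
                rel = reliability(np.array(t1), np.array(t2), ci_level)
            except UndefinedStatisticError as exc:
                exclusions.append(f"reliability {device.value}/{position.value}: {exc}")
                continue
            reliability_rows.append(
                {
                    "device": device.value,
                    "position": position.value,
                    "n": rel.n,
                    "trial_diff_mean": rel.trial_mean_diff[0],
                    "trial_diff_sd": rel.trial_mean_diff[1],
                    "icc": rel.icc,
                    "icc_ci_lower": rel.icc_ci[0],
                    "icc_ci_upper": rel.icc_ci[1],
                    "icc_interpretation": rel.icc_interpretation,
                    "sem_percent": rel.sem_percent,
                    "sem_abs": rel.sem_abs,
                    "mdc_abs": rel.mdc_abs,
                }
            )

    bundle = {
        "hrv_results": pd.DataFrame(hrv_rows),
        "device_agreement": pd.DataFrame(device_rows),
        "duration_agreement": pd.DataFrame(duration_rows),
        "reliability": pd.DataFrame(reliability_rows),
        "cleaning_reports": pd.DataFrame(cleaning_rows),
        "exclusions": exclusions,
    }
    for name in ("hrv_results", "device_agreement", "duration_agreement", "reliability", "cleaning_reports"):
        bundle[name].to_csv(out_dir / f"{name}.csv", index=False)
    _write_summary(out_dir / "summary.txt", bundle)
    for line in exclusions:
        logger.warning(line)
    return bundle


def _agreement_row(base: dict, rep) -> dict:
    row = dict(base)
    row.update(
        {
            "n": rep.n,
            "mean_diff": rep.mean_diff,
            "p_value": rep.p_value,
            "cohens_d": rep.cohens_d,
            "d_interpretation": rep.d_interpretation,
            "md_ci_lower": rep.effect_ci[0],
            "md_ci_upper": rep.effect_ci[1],
            "pearson_r": rep.pearson_r,
            "r_interpretation": rep.r_interpretation,
            "bias": rep.bias,
            "loa_lower": rep.loa_lower,
            "loa_upper": rep.loa_upper,
        }
    )
    return row


def _write_summary(path: Path, bundle: dict) -> None:
    parts = []
    for title, key in (
        ("Device agreement (ECG vs app, 5-min LnrMSSD)", "device_agreement"),
        ("Duration agreement (1 min vs 5 min LnrMSSD)", "duration_agreement"),
        ("Trial-retrial reliability (5-min LnrMSSD)", "reliability"),
    ):
        frame = bundle[key]
        parts.append(title)
        parts.append(frame.to_string(index=False) if len(frame) else "(no results)")
        parts.append("")
    rel = bundle["reliability"]
    if len(rel):
        assert np.allclose(rel["mdc_abs"], MDC_FACTOR * rel["sem_abs"])
        parts.append(f"Consistency: MDC column equals {MDC_FACTOR:.4f} x SEM column.")
    if bundle["exclusions"]:
        parts.append("Exclusions:")
        parts.extend(f"  - {line}" for line in bundle["exclusions"])
    path.write_text("\n".join(parts) + "\n")
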