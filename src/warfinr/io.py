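"""CSV reading/writing for paired samples and time courses.

Two plain-text dialects are used throughout the package:

* paired samples: ``patient_id,time_days,inr,factor_vii_pct``
* time courses:   ``dose_mg_day,time_days,inr,factor_vii_pct``

Parsing is strict — a renamed column, non-numeric cell or duplicate
(patient, time) row raises :class:`~warfinr.errors.ParseError` naming the
offending line. Unit plausibility is checked on read: factor VII in
(0, 200] % of baseline, INR in (0.5, 20], time positive.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path

import numpy as np

from .calibrate import TimeCourse
from .errors import ParseError
from .predict import PairedSample

__all__ = ["read_samples", "write_samples", "read_time_courses", "write_time_courses"]

SAMPLE_HEADER = ["patient_id", "time_days", "inr", "factor_vii_pct"]
TIMECOURSE_HEADER = ["dose_mg_day", "time_days", "inr", "factor_vii_pct"]


def _open_rows(path: str | Path, expected_header: list[str]):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    if rows[0] != expected_header:
        raise ParseError(
            f"{path}, line 1: expected header {','.join(expected_header)!r}, "
            f"got {','.join(rows[0])!r}"
        )
    return path, rows[1:]


def _number(path, lineno, name, raw) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"{path}, line {lineno}: non-numeric {name} {raw!r}") from None


def _check_units(path, lineno, t, inr, vii) -> None:
    if t <= 0:
        raise ParseError(f"{path}, line {lineno}: time_days must be positive, got {t}")
    if not 0.5 < inr <= 20:
        raise ParseError(f"{path}, line {lineno}: INR {inr} outside the plausible range (0.5, 20]")
    if not 0 < vii <= 200:
        raise ParseError(
            f"{path}, line {lineno}: factor_vii_pct {vii} outside the plausible range (0, 200]"
        )


def read_samples(path: str | Path) -> dict[str, list[PairedSample]]:
    """Read paired samples grouped by patient, sorted by time."""
    path, rows = _open_rows(path, SAMPLE_HEADER)
    by_patient: dict[str, list[PairedSample]] = defaultdict(list)
    seen: set[tuple[str, float]] = set()
    for lineno, row in enumerate(rows, start=2):
        if len(row) != 4:
            raise ParseError(f"{path}, line {lineno}: expected 4 columns, got {len(row)}")
        pid = row[0].strip()
        if not pid:
            raise ParseError(f"{path}, line {lineno}: empty patient_id")
        t = _number(path, lineno, "time_days", row[1])
        inr = _number(path, lineno, "inr", row[2])
        vii = _number(path, lineno, "factor_vii_pct", row[3])
        _check_units(path, lineno, t, inr, vii)
        if (pid, t) in seen:
            raise ParseError(f"{path}, line {lineno}: duplicate sample for patient {pid!r} at day {t}")
        seen.add((pid, t))
        by_patient[pid].append(PairedSample(t=t, inr=inr, vii=vii))
    return {pid: sorted(ss, key=lambda s: s.t) for pid, ss in by_patient.items()}


def write_samples(path: str | Path, samples: dict[str, list[PairedSample]]) -> None:
    """Write paired samples in the canonical dialect (deterministic order)."""
    lines = [",".join(SAMPLE_HEADER)]
    for pid in sorted(samples):
        for s in sorted(samples[pid], key=lambda s: s.t):
            lines.append(f"{pid},{s.t:.6g},{s.inr:.12g},{s.vii:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_time_courses(path: str | Path) -> list[TimeCourse]:
    """Read per-dose time courses, one :class:`TimeCourse` per dose level."""
    path, rows = _open_rows(path, TIMECOURSE_HEADER)
    by_dose: dict[float, list[tuple[float, float, float]]] = defaultdict(list)
    for lineno, row in enumerate(rows, start=2):
        if len(row) != 4:
            raise ParseError(f"{path}, line {lineno}: expected 4 columns, got {len(row)}")
        dose = _number(path, lineno, "dose_mg_day", row[0])
        t = _number(path, lineno, "time_days", row[1])
        inr = _number(path, lineno, "inr", row[2])
        vii = _number(path, lineno, "factor_vii_pct", row[3])
        _check_units(path, lineno, t, inr, vii)
        by_dose[dose].append((t, inr, vii))
    out = []
    for dose in sorted(by_dose):
        pts = sorted(by_dose[dose])
        arr = np.asarray(pts, dtype=float)
        out.append(TimeCourse(dose=dose, times=arr[:, 0], inr=arr[:, 1], vii=arr[:, 2]))
    return out


def write_time_courses(path: str | Path, courses: list[TimeCourse]) -> None:
    lines = [",".join(TIMECOURSE_HEADER)]
    for tc in sorted(courses, key=lambda c: c.dose):
        for t, i, v in zip(tc.times, tc.inr, tc.vii):
            lines.append(f"{tc.dose:g},{t:.6g},{i:.12g},{v:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")
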