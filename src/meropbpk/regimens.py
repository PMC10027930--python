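"""Dosing panels evaluated in the dose-finding simulations.

The CKD panels range from conventional 30-min infusions to prolonged 3-h
infusions, with total daily doses stepped down as renal function worsens;
the hemodialysis panel covers 0.25-1 g given once daily or twice daily.
"""

from __future__ import annotations

from .hemodialysis import DialysisSettings
from .pbpk_core import DosingRegimen
from .pta import PDTarget

WEEK_H = 7 * 24.0


def _panel(entries, n_days: float):
    out = []
    for dose_mg, interval, inf_h in entries:
        n = int(round(n_days * 24.0 / interval))
        dose_g = dose_mg / 1000.0
        label = f"{dose_g:g} g q{interval:g}h / {inf_h:g} h inf"
        out.append(DosingRegimen(dose_mg, interval, inf_h, n_doses=n, label=label))
    return out


def ckd_regimens(stage: int, n_days: float = 3.0):
    """Dosing panel per CKD stage (doses in mg, both infusion durations)."""
    base = {
        3: [(1000.0, 6.0), (1000.0, 8.0), (500.0, 8.0)],
        4: [(1000.0, 8.0), (500.0, 8.0)],
        5: [(1000.0, 8.0), (500.0, 8.0), (500.0, 12.0), (1000.0, 24.0)],
    }
    if stage not in base:
        raise ValueError(f"no dosing panel for stage {stage!r}")
    entries = [(d, iv, inf) for (d, iv) in base[stage] for inf in (0.5, 3.0)]
    return _panel(entries, n_days)


def ihd_regimens(n_days: float = 7.0):
    """Hemodialysis dosing panel (30-min infusions)."""
    entries = [
        (250.0, 24.0, 0.5),
        (250.0, 12.0, 0.5),
        (500.0, 24.0, 0.5),
        (500.0, 12.0, 0.5),
        (1000.0, 24.0, 0.5),
    ]
    labels = ["0.25 g once daily", "0.25 g q12h", "0.5 g once daily",
              "0.5 g q12h", "1 g once daily"]
    panel = _panel(entries, n_days)
    return [DosingRegimen(r.dose_amount, r.interval, r.infusion_duration,
                          n_doses=r.n_doses, label=lab)
            for r, lab in zip(panel, labels)]


def default_ihd_settings() -> DialysisSettings:
    """4-h sessions, BFR 200 / DFR 500 / KoA 188 mL/min, Mon-Wed-Fri;
    doses on dialysis days start at session start."""
    return DialysisSettings(bfr=200.0, dfr=500.0, koa=188.0,
                            session_duration=4.0, session_starts=(0.0, 48.0, 96.0))


def ihd_windows(threshold: float = 0.40):
    """Evaluation windows within the simulated first week.

    'on-dialysis' is the 24-h dosing day containing the mid-week session
    (48-72 h, so accumulation history is included); 'off-dialysis' is the
    following inter-dialytic day (72-96 h).
    """
    return [
        PDTarget(threshold, (48.0, 72.0), label="on-dialysis"),
        PDTarget(threshold, (72.0, 96.0), label="off-dialysis"),
    ]
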