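"""Static HTML timeline of per-visit CD scores.

One row of squares per model (forward-only LSTM above, BiLSTM below when both
are present); each square is one visit, labelled with its ordinal and age,
carrying its diagnosis codes as a hover tooltip, and colored on a diverging
scale — red for positive contributions, white for neutral, blue for negative
— normalized per row by the row's maximum absolute score. A highlighted
subset of visits (the most predictive window) gets a yellow outline. The file
is self-contained: no scripts, no network resources.
"""
from __future__ import annotations

import html
from dataclasses import dataclass, field

import numpy as np

from .ehr import PatientRecord

__all__ = ["TimelineSpec", "score_to_color", "render_timeline"]


@dataclass
class TimelineSpec:
    patient: PatientRecord
    rows: dict[str, list[float]]  # model name -> per-visit scores, visit order
    highlight: frozenset[int] = field(default_factory=frozenset)  # visit ordinals

    def __post_init__(self) -> None:
        for name, scores in self.rows.items():
            if len(scores) != self.patient.n_visits:
                raise ValueError(f"row {name!r}: {len(scores)} scores for "
                                 f"{self.patient.n_visits} visits")
            if not np.all(np.isfinite(scores)):
                raise ValueError(f"row {name!r}: non-finite scores")


def score_to_color(score: float, scale: float) -> str:
    """Map a score to an rgb() string on a symmetric blue-white-red ramp.

    ``scale`` is the row's max |score|; zero (or an all-zero row) maps to
    white, +scale to full red and -scale to full blue, linearly in between.
    """
    v = 0.0 if scale <= 0 else max(-1.0, min(1.0, score / scale))
    if v >= 0:
        other = int(round(255 * (1.0 - v)))
        return f"rgb(255,{other},{other})"
    other = int(round(255 * (1.0 + v)))
    return f"rgb({other},{other},255)"


_STYLE = """
body { font-family: sans-serif; }
.row { margin: 12px 0; white-space: nowrap; }
.rowlabel { display: inline-block; width: 90px; font-weight: bold; }
.visit { display: inline-block; width: 64px; height: 48px; margin: 1px;
         border: 1px solid #999; text-align: center; font-size: 11px;
         vertical-align: middle; padding-top: 6px; box-sizing: border-box; }
.visit.highlight { border: 3px solid #e6c200; }
"""


def render_timeline(spec: TimelineSpec, path: str | None = None) -> str:
    """Render the timeline as a self-contained HTML string (optionally written
    to ``path``); deterministic — identical specs give identical bytes."""
    if not spec.rows or any(len(s) == 0 for s in spec.rows.values()):
        raise ValueError("empty score list")
    patient = spec.patient
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>Visit timeline {html.escape(patient.patient_id)}</title>",
        f"<style>{_STYLE}</style></head><body>",
        f"<h2>Patient {html.escape(patient.patient_id)}</h2>",
        "<p>Red is positive, white is neutral and blue is negative; "
        "hover a visit for its diagnosis codes. A yellow outline marks the "
        "most predictive subset of visits.</p>",
    ]
    for name, scores in spec.rows.items():
        scale = float(np.max(np.abs(scores))) if scores else 0.0
        parts.append("<div class='row'>")
        parts.append(f"<span class='rowlabel'>{html.escape(name)}</span>")
        for visit, score in zip(patient.visits, scores):
            classes = "visit highlight" if visit.ordinal in spec.highlight else "visit"
            tooltip = html.escape(
                f"codes: {', '.join(sorted(visit.codes))} | score: {score:+.4f}",
                quote=True,
            )
            label = f"{visit.ordinal}<br>{visit.age_years:.1f}y"
            parts.append(
                f"<span class='{classes}' title=\"{tooltip}\" "
                f"style='background-color:{score_to_color(score, scale)}'>{label}</span>"
            )
        parts.append("</div>")
    parts.append("</body></html>")
    text = "\n".join(parts)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
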