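"""Semi-quantitative histological vulnerability grading of plaque sections.

Each excised plaque section is graded on six ordinal scales; in every scale
a lower score indicates a more stable plaque:

* atheroma/necrosis extent: <10% -> 0, 10-50% -> 1, >50% -> 2
* fibrous cap thickness: >=800 um -> 0, 400-800 -> 1, 200-400 -> 2, <200 -> 3
* inflammation: inflamed -> 1, not inflamed -> 0
* cholesterol: present -> 1, absent -> 0
* CD68 / CD163 immunopositivity: 0% -> 0, up to 5% -> 1, 5-10% -> 2, >10% -> 3

Boundary convention (the prose bins are ambiguous at their edges): each
boundary belongs to the bin that keeps the grading monotone and exhaustive
— 10% necrosis -> 1, 50% -> 1; caps of exactly 200/400/800 um -> 2/1/0;
markers at exactly 5%/10% -> 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .synthetic import HistologyRaw


@dataclass
class HistologyScorecard:
    """Ordinal vulnerability scores of one plaque section."""

    atheroma_score: int  # 0..2
    cap_score: int  # 0..3
    inflammation_score: int  # 0..1
    cholesterol_score: int  # 0..1
    cd68_score: int  # 0..3
    cd163_score: int  # 0..3


def _marker_score(pct: float, name: str) -> int:
    if not (0 <= pct <= 100):
        raise ValueError(f"{name} must lie in [0, 100], got {pct}")
    if pct == 0:
        return 0
    if pct <= 5:
        return 1
    if pct <= 10:
        return 2
    return 3


def score_histology(raw: HistologyRaw) -> HistologyScorecard:
    """Grade one section's raw measurements (deterministic)."""
    if not (0 <= raw.necrosis_pct <= 100):
        raise ValueError(f"necrosis_pct must lie in [0, 100], got {raw.necrosis_pct}")
    if raw.cap_thickness <= 0:
        raise ValueError(f"cap_thickness must be positive, got {raw.cap_thickness}")

    if raw.necrosis_pct < 10:
        atheroma = 0
    elif raw.necrosis_pct <= 50:
        atheroma = 1
    else:
        atheroma = 2

    t = raw.cap_thickness
    if t >= 800:
        cap = 0
    elif t >= 400:
        cap = 1
    elif t >= 200:
        cap = 2
    else:
        cap = 3

    return HistologyScorecard(
        atheroma_score=atheroma,
        cap_score=cap,
        inflammation_score=1 if raw.inflamed else 0,
        cholesterol_score=1 if raw.cholesterol_present else 0,
        cd68_score=_marker_score(raw.cd68_pct, "cd68_pct"),
        cd163_score=_marker_score(raw.cd163_pct, "cd163_pct"),
    )


def score_table(raws: dict[str, HistologyRaw]) -> pd.DataFrame:
    """Score a set of sections keyed by patient id (CSV-ready)."""
    rows = []
    for pid, raw in raws.items():
        row = {"id": pid}
        row.update(asdict(score_histology(raw)))
        rows.append(row)
    return pd.DataFrame(rows)
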