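"""Landing Error Scoring System (LESS) aggregation.

The LESS is a 17-item jump-landing error checklist scored from video by a
trained rater. Fifteen items are binary errors (0/1); the last two — sagittal
joint displacement and overall impression — are graded 0/1/2, so the worst
possible jump scores 19. Each athlete performs three jump-landing trials; the
median of the three jump scores is the athlete's LESS score, and a median of
5 or less labels the athlete not-at-risk (NR), strictly more than 5 at-risk
(R).

Only the numeric aggregation lives here; item values are inputs (from a human
rater or from :mod:`aclrisk.synth`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 17
N_JUMPS = 3

#: max allowed value per item, 1-indexed item number -> cap.
#: Items 1-15 are binary error flags; 16 (sagittal joint displacement:
#: soft/average/stiff) and 17 (overall impression) take 0/1/2.
ITEM_MAX = {i: 1 for i in range(1, 16)} | {16: 2, 17: 2}

MAX_SCORE = sum(ITEM_MAX.values())  # 19
RISK_THRESHOLD = 5  # median score <= 5  =>  NR


def score_jump(items: Sequence[int]) -> int:
    """Sum the 17 item scores of one jump-landing trial.

    Parameters
    ----------
    items:
        17 integers, item 1 first. Items 1-15 must be 0/1, items 16-17 0/1/2.
    """
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    total = 0
    for idx, value in enumerate(items, start=1):
        v = int(value)
        if v != value or not 0 <= v <= ITEM_MAX[idx]:
            raise ValueError(
                f"item {idx} value {value!r} outside its allowed range "
                f"0..{ITEM_MAX[idx]}"
            )
        total += v
    return total


def median_of_three(scores: Sequence[float]) -> float:
    """Middle order statistic of the three per-jump scores."""
    if len(scores) != N_JUMPS:
        raise ValueError(f"expected {N_JUMPS} jump scores, got {len(scores)}")
    return float(sorted(scores)[1])


def risk_label(median_score: float) -> str:
    """``"NR"`` (not at risk) iff the median LESS score is <= 5, else ``"R"``."""
    return "NR" if median_score <= RISK_THRESHOLD else "R"


@dataclass
class LESSRecord:
    """Item scores for one athlete: 3 jumps x 17 items."""

    items: np.ndarray  # (3, 17) int array
    athlete_id: str | int | None = None
    per_jump_scores: list[int] = field(init=False)
    median_score: float = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        if self.items.shape != (N_JUMPS, N_ITEMS):
            raise ValueError(
                f"items must be {N_JUMPS}x{N_ITEMS}, got {self.items.shape}"
            )
        self.per_jump_scores = [score_jump(row) for row in self.items]
        self.median_score = median_of_three(self.per_jump_scores)
        self.label = risk_label(self.median_score)


# ---------------------------------------------------------------------------
# I/O: JSON (one object per athlete) and a 17-column CSV (one row per jump)

def records_to_json(records: Iterable[LESSRecord], path: str | Path) -> None:
    payload = [
        {
            "athlete_id": r.athlete_id,
            "items": r.items.tolist(),
            "per_jump_scores": r.per_jump_scores,
            "median_score": r.median_score,
            "label": r.label,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def records_from_json(path: str | Path) -> list[LESSRecord]:
    payload = json.loads(Path(path).read_text())
    return [LESSRecord(np.array(d["items"]), d.get("athlete_id")) for d in payload]


def records_to_csv(records: Iterable[LESSRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        for j, row in enumerate(r.items, start=1):
            rows.append(
                {"athlete_id": r.athlete_id, "jump": j}
                | {f"item_{i}": int(v) for i, v in enumerate(row, start=1)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[LESSRecord]:
    df = pd.read_csv(path)
    item_cols = [f"item_{i}" for i in range(1, N_ITEMS + 1)]
    records = []
    for athlete, group in df.groupby("athlete_id", sort=False):
        group = group.sort_values("jump")
        records.append(LESSRecord(group[item_cols].to_numpy(), athlete))
    return records
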