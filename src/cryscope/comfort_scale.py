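"""COMFORT behavioural distress scores, one assessment per cry episode.

Six items — alertness, agitation, crying, body movements, muscular
tone and facial tension — each rated 1 (calm) to 5 (stressed); the
total ranges 6-30 with larger values meaning higher arousal.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

ITEMS = ("alertness", "agitation", "crying", "body_movements",
         "muscular_tone", "facial_tension")


@dataclass(frozen=True)
class ComfortScore:
    alertness: int
    agitation: int
    crying: int
    body_movements: int
    muscular_tone: int
    facial_tension: int
    total: int


class ComfortValidationError(ValueError):
    pass


def validate_and_total(items) -> ComfortScore:
    """Range-check six integer items and compute the total score."""
    vals = list(items)
    if len(vals) != 6:
        raise ComfortValidationError(f"expected 6 items, got {len(vals)}")
    checked = []
    for name, v in zip(ITEMS, vals):
        iv = int(v)
        if iv != v or not (1 <= iv <= 5):
            raise ComfortValidationError(
                f"item {name!r} = {v!r} outside the integer 1-5 scale"
            )
        checked.append(iv)
    return ComfortScore(*checked, total=sum(checked))


def score_table(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-episode table of item scores and add totals.

    Input needs the six item columns plus ``episode_id`` and
    ``condition``.  Invalid rows are reported in a ``valid`` column
    with a diagnostic rather than silently dropped.
    """
    rows = []
    for _, rec in records.iterrows():
        row = {
            "episode_id": rec["episode_id"], "condition": rec["condition"],
        }
        try:
            score = validate_and_total([rec[i] for i in ITEMS])
            row.update(asdict(score))
            row["valid"] = True
            row["error"] = ""
        except ComfortValidationError as exc:
            for i in ITEMS:
                row[i] = rec.get(i)
            row["total"] = None
            row["valid"] = False
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
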