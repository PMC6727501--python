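"""Static dashboard payloads: the item-difficulty vs residual bubble chart.

The payload mirrors the "KIDNAP" display psychometricians use for
person-fit inspection: item difficulty on the Y axis (harder items on
top), standardized residual Z on the X axis, bubble size proportional
to the difficulty's standard error, a vertical detection line at the Z
threshold, and the case's own ability as a distinct bubble.  Items to
the right of the line are beyond expectation — the up-coding direction.
Output is deterministic JSON (plus a minimal self-contained HTML view)
so reports can be diffed and served statically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from .detection import CaseScore, case_scores_to_frame
from .evaluation import EvalTable
from .rasch import NormModel
from .schema import FeeItemSchema

PAYLOAD_FORMAT = "drgrasch-kidnap/1"


def kidnap_payload(
    score: CaseScore,
    model: NormModel,
    schema: FeeItemSchema | None = None,
) -> dict:
    """Bubble-chart payload for one scored case.

    Item bubbles are ordered by difficulty descending (hardest on top);
    ``flagged`` marks bubbles past the threshold for distinct styling.
    Raises on an unscorable case.
    """
    if score.status != "scored" or score.ability is None:
        raise ValueError(f"case {score.case_id} is unscorable; no payload")
    labels = {}
    if schema is not None:
        labels = {it.item_id: it.label for it in schema.items}
    se_by_item = {it.item_id: it.se for it in model.items}
    delta_by_item = model.deltas()
    items = [
        {
            "item_id": c.item_id,
            "label": labels.get(c.item_id, c.item_id),
            "y": delta_by_item[c.item_id],
            "x": c.z,
            "size": se_by_item[c.item_id],
            "raw_fee": c.raw_fee,
            "flagged": c.item_id in score.flagged_items,
        }
        for c in score.cells
    ]
    items.sort(key=lambda b: (-b["y"], b["item_id"]))
    return {
        "format": PAYLOAD_FORMAT,
        "case": {
            "case_id": score.case_id,
            "drg": score.drg_code,
            "year": score.year,
            "outfit_mnsq": score.outfit_mnsq,
        },
        "case_bubble": {"y": score.ability.theta, "marker": "case"},
        "threshold": score.threshold,
        "side": score.side,
        "items": items,
    }


def _payload_html(payload: dict) -> str:
    """Self-contained SVG bubble chart for one payload (no scripts,
    no external assets, no timestamps)."""
    items = payload["items"]
    ys = [b["y"] for b in items] + [payload["case_bubble"]["y"]]
    xs = [b["x"] for b in items] + [0.0, payload["threshold"] + 0.5]
    y_lo, y_hi = min(ys) - 0.5, max(ys) + 0.5
    x_lo, x_hi = min(xs) - 0.5, max(xs) + 0.5
    w, h, pad = 640, 420, 45

    def sx(x):
        return pad + (x - x_lo) / (x_hi - x_lo) * (w - 2 * pad)

    def sy(y):
        return h - pad - (y - y_lo) / (y_hi - y_lo) * (h - 2 * pad)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}">',
        f'<line x1="{sx(payload["threshold"]):.1f}" y1="{pad}" '
        f'x2="{sx(payload["threshold"]):.1f}" y2="{h - pad}" '
        'stroke="#c00" stroke-dasharray="4 3"/>',
    ]
    sizes = [b["size"] for b in items] or [1.0]
    smax = max(sizes)
    for b in items:
        r = 4 + 10 * (b["size"] / smax)
        fill = "#d62728" if b["flagged"] else "#1f77b4"
        parts.append(
            f'<circle cx="{sx(b["x"]):.1f}" cy="{sy(b["y"]):.1f}" '
            f'r="{r:.1f}" fill="{fill}" fill-opacity="0.65">'
            f'<title>{b["label"]}: z={b["x"]:.2f}, '
            f'difficulty={b["y"]:.2f}</title></circle>'
        )
    cb = payload["case_bubble"]
    parts.append(
        f'<circle cx="{sx(0.0):.1f}" cy="{sy(cb["y"]):.1f}" r="8" '
        f'fill="#ffbf00" stroke="#333"><title>case ability '
        f'{cb["y"]:.2f}</title></circle>'
    )
    parts.append("</svg>")
    case = payload["case"]
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{case['case_id']}</title></head><body>"
        f"<h2>Case {case['case_id']} — DRG {case['drg']}</h2>"
        f"<p>outfit MNSQ {case['outfit_mnsq']:.2f}; "
        f"threshold Z &gt; {payload['threshold']:.1f}; red bubbles are "
        "beyond expectation (probable deduction)</p>" + "".join(parts)
        + "</body></html>"
    )


def render_report(
    scores: Sequence[CaseScore],
    models: Mapping[str, NormModel],
    out_dir: str | Path,
    schema: FeeItemSchema | None = None,
    eval_tables: Mapping[str, EvalTable] | None = None,
    html: bool = True,
) -> list[Path]:
    """Write one payload per scored case plus an index.

    Deterministic and idempotent: no timestamps, stable ordering —
    rerunning on the same inputs produces byte-identical files.
    Raises on an empty result set.
    """
    scored = [s for s in scores if s.status == "scored"]
    if not scored:
        raise ValueError("no scored cases; refusing to write an empty report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    index = {"format": "drgrasch-report-index/1", "cases": []}
    for s in sorted(scored, key=lambda s: s.case_id):
        payload = kidnap_payload(s, models[s.drg_code], schema)
        p = out / f"case_{s.case_id}.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        written.append(p)
        if html:
            ph = out / f"case_{s.case_id}.html"
            ph.write_text(_payload_html(payload), encoding="utf-8")
            written.append(ph)
        index["cases"].append(
            {
                "case_id": s.case_id,
                "drg": s.drg_code,
                "year": s.year,
                "outfit_mnsq": s.outfit_mnsq,
                "case_flagged": s.case_flagged,
                "flagged_items": sorted(s.flagged_items),
                "payload": p.name,
            }
        )
    ip = out / "index.json"
    with open(ip, "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)
    written.append(ip)
    cells = out / "cells.csv"
    case_scores_to_frame(scored).to_csv(cells, index=False)
    written.append(cells)
    if eval_tables:
        for name, table in eval_tables.items():
            tp = out / f"eval_{name}.csv"
            table.to_frame().to_csv(tp, index=False)
            written.append(tp)
    return written
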