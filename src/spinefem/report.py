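"""Pre/post comparison reports: ROM and stress-maxima ratios, mobility
shares, and model-vs-radiograph angle validation."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from spinefem.levels import FULL_CHAIN, segment_span


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def percent_1dp(ratio: float) -> float:
    return round(100.0 * ratio, 1)


def fold_3sf(ratio: float) -> float:
    return round_sig(ratio, 3)


@dataclass
class ComparisonRow:
    scope: str
    pre_value: float
    post_value: float
    ratio: float | None
    percent: float | None  # 100*ratio, 1 decimal
    fold: float | None  # ratio, 3 significant figures
    direction: str  # increase | decrease | unchanged
    note: str = ""


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow]
    mobility_shares: dict[str, dict[str, float]] = field(default_factory=dict)
    angle_validation: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def row(self, scope: str) -> ComparisonRow:
        for r in self.rows:
            if r.scope == scope:
                return r
        raise KeyError(f"no comparison row for scope {scope!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "rows": [r.__dict__ for r in self.rows],
            "mobility_shares": self.mobility_shares,
            "angle_validation": self.angle_validation,
            "meta": self.meta,
        }
        s = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_markdown(self) -> str:
        lines = ["| scope | pre | post | percent | fold | direction |",
                 "|---|---|---|---|---|---|"]
        for r in self.rows:
            pct = f"{r.percent}%" if r.percent is not None else "-"
            fold = f"{r.fold}" if r.fold is not None else "-"
            lines.append(
                f"| {r.scope} | {r.pre_value:g} | {r.post_value:g} | {pct} | {fold} | {r.direction} |"
            )
        return "\n".join(lines)


def compare(
    pre_summary: dict[str, float], post_summary: dict[str, float]
) -> ComparisonReport:
    """Post/pre ratio rows for matching scopes.

    Percentages round to 1 decimal; fold changes to 3 significant figures.
    Rows with non-positive pre values are flagged and carry no ratio.
    """
    pre_keys, post_keys = set(pre_summary), set(post_summary)
    if pre_keys != post_keys:
        raise ValueError(
            f"scope mismatch: only-pre={sorted(pre_keys - post_keys)}, "
            f"only-post={sorted(post_keys - pre_keys)}"
        )
    rows = []
    for scope in pre_summary:
        pre, post = float(pre_summary[scope]), float(post_summary[scope])
        if pre <= 0:
            rows.append(
                ComparisonRow(scope, pre, post, None, None, None, "undefined",
                              note="non-positive pre value; no ratio")
            )
            continue
        ratio = post / pre
        if post > pre:
            direction = "increase"
        elif post < pre:
            direction = "decrease"
        else:
            direction = "unchanged"
        rows.append(
            ComparisonRow(scope, pre, post, ratio, percent_1dp(ratio), fold_3sf(ratio), direction)
        )
    return ComparisonReport(rows=rows)


def mobility_share(
    rom_rows: dict[str, float],
    block: str,
    levels: tuple[str, ...] | list[str] = FULL_CHAIN,
) -> float:
    """Share (percent, 1 decimal) of total flexion ROM carried by a block.

    The total is the sum of the given non-overlapping block rows ("Total"
    entries are ignored); overlapping blocks are rejected.
    """
    rows = {k: float(v) for k, v in rom_rows.items() if k.lower() != "total"}
    if block not in rows:
        raise KeyError(f"block {block!r} not among ROM rows {sorted(rows)}")
    spans = {k: segment_span(k, levels) for k in rows}
    keys = sorted(rows)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            overlap = spans[a] & spans[b]
            if overlap:
                raise ValueError(
                    f"overlapping ROM blocks {a!r} and {b!r} (shared unit segments)"
                )
    total = sum(rows.values())
    if total <= 0:
        raise ValueError("total ROM must be > 0")
    return round(100.0 * rows[block] / total, 1)


def validation_summary(
    model_angles: dict[str, float], radiograph_angles: dict[str, float]
) -> list[dict]:
    """Absolute model-vs-radiograph discrepancies per paired angle."""
    missing = set(model_angles) ^ set(radiograph_angles)
    if missing:
        raise ValueError(f"unpaired angles: {sorted(missing)}")
    rows = []
    for name in model_angles:
        m, r = float(model_angles[name]), float(radiograph_angles[name])
        rows.append(
            {
                "angle": name,
                "model_deg": m,
                "radiograph_deg": r,
                "discrepancy_deg": round(abs(m - r), 6),
            }
        )
    return rows
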