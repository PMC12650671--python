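"""Vertebral level labels and segment bookkeeping.

The canonical chain runs caudal to cranial starting at L5 (index 0), the
vertebra every model is grown from: L5..L1, T12..T1, C7.
"""

from __future__ import annotations

FULL_CHAIN: tuple[str, ...] = (
    "L5",
    "L4",
    "L3",
    "L2",
    "L1",
    "T12",
    "T11",
    "T10",
    "T9",
    "T8",
    "T7",
    "T6",
    "T5",
    "T4",
    "T3",
    "T2",
    "T1",
    "C7",
)


def default_levels(n: int) -> list[str]:
    """First ``n`` levels of the canonical L5->C7 chain (caudal first)."""
    if n < 2:
        raise ValueError(f"need at least 2 vertebrae, got {n}")
    if n > len(FULL_CHAIN):
        raise ValueError(f"at most {len(FULL_CHAIN)} levels supported, got {n}")
    return list(FULL_CHAIN[:n])


def level_index(levels: list[str] | tuple[str, ...], label: str) -> int:
    try:
        return list(levels).index(label)
    except ValueError:
        raise KeyError(f"level {label!r} not in model (have {list(levels)})") from None


def is_lumbar(label: str) -> bool:
    return label.startswith("L")


def is_thoracic(label: str) -> bool:
    return label.startswith("T")


def parse_segment(label: str) -> tuple[str, str]:
    """Split a segment label like ``"C7-T10"`` into (cranial, caudal) levels."""
    parts = label.split("-")
    if len(parts) != 2:
        raise ValueError(f"bad segment label {label!r}; expected 'UPPER-LOWER'")
    return parts[0], parts[1]


def segment_span(label: str, levels: list[str] | tuple[str, ...] = FULL_CHAIN) -> set[int]:
    """Unit-segment indices covered by a block label.

    Unit segment i joins level i to level i+1 (caudal to cranial); the span
    of "C7-T10" is every unit segment between T10 and C7.
    """
    upper, lower = parse_segment(label)
    iu = level_index(levels, upper)
    il = level_index(levels, lower)
    lo, hi = (il, iu) if il < iu else (iu, il)
    if lo == hi:
        raise ValueError(f"segment {label!r} spans zero levels")
    return set(range(lo, hi))
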