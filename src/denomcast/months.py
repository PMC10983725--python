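"""Calendar-month encoding.

Centre-months are keyed by ISO "YYYY-MM" strings in files and by integer
month indices internally, counted from a configurable epoch (default
2017-11, the first surveillance month, index 0).  Gaps in a centre's series
are allowed; the AR(1) correlation decays with the integer month distance.
"""

from __future__ import annotations

EPOCH_YEAR = 2017
EPOCH_MONTH = 11  # November 2017 -> index 0


def month_to_index(ym: str, epoch: tuple[int, int] = (EPOCH_YEAR, EPOCH_MONTH)) -> int:
    """Convert an ISO "YYYY-MM" string to an integer month index."""
    try:
        y_s, m_s = ym.strip().split("-")
        y, m = int(y_s), int(m_s)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"unparseable year_month {ym!r}; expected 'YYYY-MM'") from exc
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range in {ym!r}")
    return (y - epoch[0]) * 12 + (m - epoch[1])


def index_to_month(idx: int, epoch: tuple[int, int] = (EPOCH_YEAR, EPOCH_MONTH)) -> str:
    """Convert an integer month index back to an ISO "YYYY-MM" string."""
    total = epoch[0] * 12 + (epoch[1] - 1) + int(idx)
    return f"{total // 12:04d}-{total % 12 + 1:02d}"
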