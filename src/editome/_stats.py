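"""Small shared summary helpers."""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def share_table(counts: Mapping[str, int], denominator: int | None = None) -> pd.DataFrame:
    """Counts plus percentages rounded to 1 decimal, sorted by count.

    ``denominator`` defaults to the sum of the counts; pass it explicitly when
    the percentage base differs from the listed categories.
    """
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = denominator if denominator is not None else sum(counts.values())
    df = pd.DataFrame(items, columns=["category", "count"]).set_index("category")
    if total > 0:
        df["percent"] = [round(100.0 * c / total, 1) for c in df["count"]]
    else:
        df["percent"] = 0.0
    return df
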