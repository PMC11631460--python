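"""Thresholding adjusted p-values into calls, K-of-N summaries, one-hit filter."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CallMatrix, KofN, Level, ProbeDataset, PValueTable, k_of_n_from_calls


def make_calls(adjusted: PValueTable, cutoff: float, level: Level = "probe") -> CallMatrix:
    """Call feature/sample pairs with adjusted p strictly below ``cutoff``."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    return CallMatrix(adjusted.values < cutoff, cutoff, level)


def k_of_n(calls: CallMatrix) -> list[KofN]:
    """Per feature: k = number of positive samples called, n = number of positive samples."""
    return k_of_n_from_calls(calls.calls)


def one_hit_filter(
    calls: CallMatrix, adjusted: PValueTable, data: ProbeDataset
) -> tuple[CallMatrix, PValueTable]:
    """Remove isolated single-sample probe calls (one pass).

    A called probe/sample pair survives iff the previous or next probe of the
    same protein (positional rank order, tiling-agnostic) is called in the
    same sample, or the probe is called in at least one other positive
    sample.  Removed entries become False and their adjusted p is set to 1.
    The filter is applied once, not iterated to a fixed point, so a removal
    can leave a formerly supported neighbour orphaned.
    """
    if calls.level != "probe":
        raise ValueError("the one-hit filter applies at the probe level only")
    order = data.protein_probe_order()
    # probes ordered by (protein, start); matrix in that order
    ordered_ids = order.index
    c = calls.calls.loc[ordered_ids].to_numpy(copy=True)
    protein = order["protein_id"].to_numpy()

    prev_same = np.zeros_like(c)
    prev_same[1:] = c[:-1] & (protein[1:] == protein[:-1])[:, None]
    next_same = np.zeros_like(c)
    next_same[:-1] = c[1:] & (protein[1:] == protein[:-1])[:, None]
    row_calls = c.sum(axis=1)
    other_sample = (row_calls[:, None] - c.astype(int)) > 0
    keep = c & (prev_same | next_same | other_sample)

    filtered_calls = pd.DataFrame(keep, index=ordered_ids, columns=calls.calls.columns)
    filtered_calls = filtered_calls.loc[calls.calls.index]
    removed = calls.calls & ~filtered_calls
    adj = adjusted.values.copy()
    adj[removed] = 1.0
    return (
        CallMatrix(filtered_calls, calls.cutoff, calls.level),
        PValueTable("adjusted", adj),
    )
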