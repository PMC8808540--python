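"""Recovery metrics: how well pipeline output matches the planted truth.

All matching is by >= 1 bp overlap, the same identity convention the
pipeline itself uses.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .intervals import overlaps_any
from .types import GenomicInterval, Peak


def _as_intervals(items: Sequence) -> list[GenomicInterval]:
    return [it.interval if isinstance(it, Peak) else it for it in items]


def recall_precision(
    called: Sequence, truth: Sequence
) -> tuple[float, float]:
    """(recall, precision) of called regions against truth regions,
    matched by >= 1 bp overlap."""
    called_iv, truth_iv = _as_intervals(called), _as_intervals(truth)
    if not truth_iv:
        return float("nan"), (float("nan") if not called_iv else 0.0)
    if not called_iv:
        return 0.0, float("nan")
    truth_hit = overlaps_any(truth_iv, called_iv)
    called_hit = overlaps_any(called_iv, truth_iv)
    return float(truth_hit.mean()), float(called_hit.mean())


def set_jaccard(called: Sequence, truth: Sequence) -> float:
    """Set-level Jaccard: matched truth regions over (matched truth +
    unmatched truth + unmatched called)."""
    called_iv, truth_iv = _as_intervals(called), _as_intervals(truth)
    if not truth_iv and not called_iv:
        return 1.0
    if not truth_iv or not called_iv:
        return 0.0
    tp = int(overlaps_any(truth_iv, called_iv).sum())
    fn = len(truth_iv) - tp
    fp = int((~overlaps_any(called_iv, truth_iv)).sum())
    return tp / (tp + fn + fp)


def differential_recovery(
    up_called: Sequence,
    down_called: Sequence,
    truth: Sequence[tuple[GenomicInterval, str, float]],
) -> dict:
    """Sign-aware recovery of planted condition-differential regions.

    A truth region counts as recovered iff a called region of the matching
    direction overlaps it.  Also reports the fraction of called regions
    not overlapping any truth region (the empirical false-discovery
    proportion at region level).
    """
    truth_up = [iv for iv, d, _f in truth if d == "up_in_MUT"]
    truth_down = [iv for iv, d, _f in truth if d == "down_in_MUT"]
    up_iv, down_iv = _as_intervals(up_called), _as_intervals(down_called)
    rec_num = rec_den = 0
    for truth_side, called_side in ((truth_up, up_iv), (truth_down, down_iv)):
        rec_den += len(truth_side)
        if truth_side and called_side:
            rec_num += int(overlaps_any(truth_side, called_side).sum())
    all_truth = truth_up + truth_down
    called_all = up_iv + down_iv
    if called_all:
        fp = int((~overlaps_any(called_all, all_truth)).sum()) if all_truth else len(called_all)
        fdp = fp / len(called_all)
    else:
        fdp = 0.0
    recall = rec_num / rec_den if rec_den else float("nan")
    return {
        "recall": recall,
        "false_discovery_proportion": fdp,
        "n_truth": rec_den,
        "n_called": len(called_all),
    }
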