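"""Sequence-conditioned amplitude averaging (tree diagrams).

Trial-by-trial amplitudes are averaged according to the pattern of up to
three preceding stimuli.  In *collapsed* mode (equiprobable category) the
symbol ``a`` denotes the current event and ``b`` the other one, so order-m
patterns are the 2^m histories ending in ``a`` (e.g. first order ``aa``
repetition vs ``ba`` alternation).  In *anchored* mode (biased category)
``a`` is fixed to the rare event and ``b`` to the frequent one, and the
2^(m+1) patterns split by the final symbol — separate trees for rare-final
and frequent-final trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import StimulusSequence

__all__ = ["TreeTable", "sequence_labels", "average_by_sequence",
           "grand_average", "write_tree_csv"]

MAX_ORDER = 3


@dataclass
class TreeTable:
    """Mean amplitude and trial count per history pattern at one order."""

    order: int
    mode: str                    # 'collapsed' or 'anchored'
    labels: list
    means: np.ndarray            # μV; NaN where a pattern never occurred
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"order": self.order, "pattern": self.labels,
                             "mean_uV": self.means, "count": self.counts})


def sequence_labels(order: int, mode: str = "collapsed") -> list:
    """History-pattern labels at the given order (0..3).

    Collapsed mode: 2^order labels ending in ``a``; anchored mode:
    2^(order+1) labels, those ending in ``a`` (rare) first.
    """
    if not 0 <= order <= MAX_ORDER:
        raise ValueError(f"order must lie in 0..{MAX_ORDER}")
    if mode not in ("collapsed", "anchored"):
        raise ValueError("mode must be 'collapsed' or 'anchored'")
    finals = ["a"] if mode == "collapsed" else ["a", "b"]
    labels = []
    for final in finals:
        # oldest-position-fastest enumeration gives aa, ba / aaa, baa, aba, bba
        for hist in product("ab", repeat=order):
            labels.append("".join(reversed(hist)) + final)
    return labels


def _trial_label(events: np.ndarray, n: int, order: int, mode: str,
                 rare_code: int) -> str:
    cur = events[n - 1]
    if mode == "collapsed":
        hist = "".join("a" if events[n - 1 - j] == cur else "b"
                       for j in range(order, 0, -1))
        return hist + "a"
    sym = lambda e: "a" if e == rare_code else "b"
    hist = "".join(sym(events[n - 1 - j]) for j in range(order, 0, -1))
    return hist + sym(cur)


def average_by_sequence(amplitudes, seq: StimulusSequence, order: int,
                        mode: str = "collapsed") -> TreeTable:
    """Average one amplitude trace by its order-m stimulus history.

    Trials with fewer than ``order`` predecessors are excluded.  Patterns
    that never occur get count 0 and a NaN mean.  Anchored mode requires
    the sequence to carry its probability category (to identify the rare
    event).
    """
    amplitudes = np.asarray(amplitudes, dtype=float).ravel()
    if amplitudes.size != seq.N:
        raise ValueError("amplitude trace must align with the sequence")
    labels = sequence_labels(order, mode)
    if mode == "anchored":
        if seq.probs is None:
            raise ValueError("anchored mode needs the sequence's probability "
                             "category to identify the rare event")
        rare_code = int(np.argmin(seq.probs)) + 1
    else:
        rare_code = 0
    idx = {lab: i for i, lab in enumerate(labels)}
    sums = np.zeros(len(labels))
    counts = np.zeros(len(labels), dtype=int)
    for n in range(order + 1, seq.N + 1):
        lab = _trial_label(seq.events, n, order, mode, rare_code)
        i = idx[lab]
        sums[i] += amplitudes[n - 1]
        counts[i] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TreeTable(order=order, mode=mode, labels=labels, means=means,
                     counts=counts)


def grand_average(tables: list) -> TreeTable:
    """Equal-weight average of per-participant tree tables (ERP convention).

    Patterns a participant never saw are skipped for that participant;
    counts are summed across participants.
    """
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    if any(t.labels != first.labels or t.order != first.order for t in tables):
        raise ValueError("tables must share order and labels")
    means = np.vstack([t.means for t in tables])
    counts = np.vstack([t.counts for t in tables])
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(np.where(counts > 0, means, np.nan), axis=0)
    return TreeTable(order=first.order, mode=first.mode, labels=first.labels,
                     means=grand, counts=counts.sum(axis=0))


def write_tree_csv(tables, path, participants=None) -> None:
    """Tree CSV: order, pattern, mean_uV, count (+ participant if given)."""
    frames = []
    tables = [tables] if isinstance(tables, TreeTable) else list(tables)
    for i, t in enumerate(tables):
        df = t.to_frame()
        if participants is not None:
            df["participant"] = participants[i]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)
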