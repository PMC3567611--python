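"""Stimulus sequences and the indicator/input signals that excite the observer models.

A block of trials is an ordered sequence of event codes ``s(1..N)`` with
``s(n) ∈ {1..K}`` (1-based codes, matching the standard notation for
K-ary choice tasks).  Two per-event signals are derived from a sequence:

``d_k(ν)``
    the occurrence indicator, ``d_k(ν) = 1`` iff ``s(ν) = k`` (ν ≥ 1);
``g_k(ν)``
    the model-exciting input signal, equal to ``d_k(ν)`` for ν ≥ 1 and to
    the uniform prior ``1/K`` for ν ≤ 0.  The infinite uniform prefix is
    what makes every filter start from the uniform prior ``1/K``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSequence",
    "IndicatorSignal",
    "generate_sequence",
    "indicator_d",
    "input_signal_g",
    "write_sequence_csv",
    "read_sequence_csv",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered block of stimulus event codes.

    Parameters
    ----------
    events : numpy.ndarray
        Integer codes, each in ``{1..K}``, length ``N``.
    K : int
        Alphabet size, at least 2.
    probs : tuple of float, optional
        True per-event probabilities of the block (the probability
        category, e.g. ``(0.5, 0.5)`` or ``(0.3, 0.7)``).
    seed : int, optional
        Seed used for generation; absent for read-in data.
    """

    events: np.ndarray
    K: int
    probs: tuple | None = None
    seed: int | None = None

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=np.int64)
        object.__setattr__(self, "events", ev)
        if self.K < 2:
            raise ValueError(f"alphabet size K must be >= 2, got {self.K}")
        if ev.ndim != 1 or ev.size < 1:
            raise ValueError("events must be a non-empty 1-d array")
        if ev.min() < 1 or ev.max() > self.K:
            raise ValueError("every event code must lie in {1..K}")
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if p.size != self.K:
                raise ValueError("probs must have length K")
            object.__setattr__(self, "probs", tuple(float(x) for x in p))

    @property
    def N(self) -> int:
        return int(self.events.size)

    def __len__(self) -> int:
        return self.N


@dataclass(frozen=True)
class IndicatorSignal:
    """Per-trial values of ``d_k`` or ``g_k`` for one event code ``k``.

    ``values[i]`` holds the sample at trial index ``ν = offset + i``; for the
    plain indicator ``d`` the offset is 1, for the padded input signal ``g``
    it is ``1 - pad`` (pad samples at ν ≤ 0 carry the uniform prior 1/K).
    """

    values: np.ndarray
    kind: str
    k: int
    offset: int = 1

    def __post_init__(self):
        if self.kind not in ("d", "g"):
            raise ValueError("kind must be 'd' or 'g'")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _validate_k(seq: StimulusSequence, k: int) -> None:
    if not (1 <= k <= seq.K):
        raise ValueError(f"event code k={k} out of range 1..{seq.K}")


def generate_sequence(K: int, N: int, probs, seed: int) -> StimulusSequence:
    """Draw an i.i.d. stimulus sequence of length ``N`` from ``probs``.

    Identical ``seed`` yields identical sequences.  ``probs`` must be a
    length-``K`` probability vector (sum 1 within 1e-9).
    """
    if K < 2:
        raise ValueError(f"alphabet size K must be >= 2, got {K}")
    if N < 1:
        raise ValueError("N must be >= 1")
    p = np.asarray(probs, dtype=float)
    if p.size != K:
        raise ValueError("probs must have length K")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError("probs must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    events = rng.choice(np.arange(1, K + 1), size=N, p=p / p.sum())
    return StimulusSequence(events=events, K=K, probs=tuple(p), seed=int(seed))


def indicator_d(seq: StimulusSequence, k: int) -> IndicatorSignal:
    """Occurrence indicator ``d_k(ν) = 1`` iff ``s(ν) = k``, for ν = 1..N."""
    _validate_k(seq, k)
    values = (seq.events == k).astype(float)
    return IndicatorSignal(values=values, kind="d", k=k, offset=1)


def input_signal_g(seq: StimulusSequence, k: int, pad: int = 0) -> IndicatorSignal:
    """Model-exciting input ``g_k``: uniform prior 1/K for ν ≤ 0, else ``d_k``.

    The signal is conceptually infinite toward ν = −∞; ``pad`` materializes
    that many ν ≤ 0 samples (used by the direct-sum filter forms; the
    recursive filters realize the prefix through their 1/K initialization,
    so pad defaults to 0).
    """
    _validate_k(seq, k)
    if pad < 0:
        raise ValueError("pad must be >= 0")
    d = (seq.events == k).astype(float)
    values = np.concatenate([np.full(pad, 1.0 / seq.K), d])
    return IndicatorSignal(values=values, kind="g", k=k, offset=1 - pad)


def write_sequence_csv(seq: StimulusSequence, path) -> None:
    """Write ``trial,event`` CSV (1-based trials, codes 1..K) plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"trial": np.arange(1, seq.N + 1), "event": seq.events}
    ).to_csv(path, index=False)
    meta = {"K": seq.K, "probs": seq.probs, "seed": seq.seed, "N": seq.N,
            "note": "event codes are 1-based (1..K)"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_sequence_csv(path) -> StimulusSequence:
    """Read a sequence written by :func:`write_sequence_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        K = int(meta["K"])
        probs = tuple(meta["probs"]) if meta.get("probs") else None
        seed = meta.get("seed")
    else:
        K = int(df["event"].max())
        probs, seed = None, None
    return StimulusSequence(events=df["event"].to_numpy(), K=K, probs=probs,
                            seed=seed)
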