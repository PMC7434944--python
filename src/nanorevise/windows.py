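"""Fixed-size training/inference windows over base-level events.

One window per event, stride 1, centred on the event. Per position the
feature vector is: one-hot called base (4) + event mean + stdv + relative
dwell length (3), plus a one-hot methylation channel (3) when enabled.
Positions beyond the read ends are all-zero PAD vectors. The signal input is
the concatenation of the member events' normalized samples, each event
padded or truncated (from the tail) to a fixed per-event cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BASES, METHYL_TYPES, Event, RawSignal

FEATURES_PER_POSITION = 7
FEATURES_PER_POSITION_METHYL = 10


@dataclass
class WindowSet:
    """Batched window examples for one or more reads."""

    signal: np.ndarray    # (n, window * sig_cap) float32
    features: np.ndarray  # (n, window, F) float32
    labels1: np.ndarray | None = None  # (n,) int — error-type class index
    labels2: np.ndarray | None = None  # (n,) int — true-base class index
    trainable: np.ndarray | None = None  # (n,) bool — False for clipped events
    read_ids: list[str] | None = None
    window: int = 13
    sig_cap: int = 40

    def __len__(self) -> int:
        return int(self.signal.shape[0])

    @property
    def feature_dim(self) -> int:
        return int(self.features.shape[2])


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    if not sets:
        raise ValueError("no window sets to concatenate")
    first = sets[0]

    def cat(attr):
        vals = [getattr(s, attr) for s in sets]
        return None if vals[0] is None else np.concatenate(vals, axis=0)

    read_ids = None
    if first.read_ids is not None:
        read_ids = [r for s in sets for r in (s.read_ids or [])]
    return WindowSet(
        signal=cat("signal"), features=cat("features"),
        labels1=cat("labels1"), labels2=cat("labels2"),
        trainable=cat("trainable"), read_ids=read_ids,
        window=first.window, sig_cap=first.sig_cap)


def event_feature_matrix(events: list[Event], methyl: list[str] | None = None
                         ) -> np.ndarray:
    """Per-event feature vectors (n_events, 7 or 10)."""
    n = len(events)
    with_methyl = methyl is not None
    dim = FEATURES_PER_POSITION_METHYL if with_methyl else FEATURES_PER_POSITION
    out = np.zeros((n, dim), dtype=np.float32)
    mean_len = float(np.mean([ev.length for ev in events])) if n else 1.0
    for i, ev in enumerate(events):
        out[i, BASES.index(ev.base)] = 1.0
        out[i, 4] = ev.mean
        out[i, 5] = ev.stdv
        out[i, 6] = ev.length / mean_len
        if with_methyl and methyl[i] in METHYL_TYPES:
            out[i, 7 + METHYL_TYPES.index(methyl[i])] = 1.0
    return out


def windows_from_events(events: list[Event], raw_norm: RawSignal,
                        window: int = 13, sig_cap: int = 40,
                        methyl: list[str] | None = None,
                        read_id: str = "") -> WindowSet:
    """Build one window per event from base-level events over a normalized
    signal. ``raw_norm`` must be the signal the events index into."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    n = len(events)
    if window > 2 * n + 1:
        raise ValueError(
            f"window {window} too large for a read of {n} events")
    feats = event_feature_matrix(events, methyl)
    dim = feats.shape[1]
    half = window // 2

    # per-event signal blocks, tail-truncated / zero-padded to sig_cap
    blocks = np.zeros((n, sig_cap), dtype=np.float32)
    for i, ev in enumerate(events):
        seg = raw_norm.samples[ev.start : ev.start + min(ev.length, sig_cap)]
        blocks[i, : seg.size] = seg

    features = np.zeros((n, window, dim), dtype=np.float32)
    signal = np.zeros((n, window * sig_cap), dtype=np.float32)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        features[i, lo - (i - half) : hi - (i - half), :] = feats[lo:hi]
        signal[i, (lo - (i - half)) * sig_cap : (hi - (i - half)) * sig_cap] = \
            blocks[lo:hi].reshape(-1)
    return WindowSet(signal=signal, features=features,
                     read_ids=[read_id] * n, window=window, sig_cap=sig_cap)
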