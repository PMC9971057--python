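"""Evaluation statistics for sessions and model predictions.

Class-selection accuracy uses the Jaccard index J(X, Y) = |X n Y| / |X u Y|
between class sets (truth vs participant, truth vs model, participant vs
model, and the per-episode selection/rejection deltas s_t, r_t). Sampling
behaviour is summarised by fixation maps (normalised click-frequency
distributions) compared with KL divergence, Pearson correlation (CC) and
histogram intersection (SIM), plus confusion (|c_t|/n), samples-to-
recognition, observed image area and within-class scanpath correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baseline import SessionPrediction
from .stimuli import STIMULUS_SHAPE
from .task_env import Location, Session, TaskConfig, observed_area_fraction

#: image centre used as the polar origin for scanpath direction (0-based)
IMAGE_CENTER = ((STIMULUS_SHAPE[0] - 1) // 2, (STIMULUS_SHAPE[1] - 1) // 2)


@dataclass
class FixationMap:
    """Normalised distribution of sampled locations over the image."""

    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        if np.any(self.dist < 0):
            raise ValueError("fixation map entries must be non-negative")
        if abs(self.dist.sum() - 1.0) > 1e-9:
            raise ValueError("fixation map must sum to 1")


def jaccard(X: Iterable, Y: Iterable) -> float:
    """|X n Y| / |X u Y|; undefined (error) when both sets are empty."""
    xs, ys = set(X), set(Y)
    union = xs | ys
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(xs & ys) / len(union)


def selection_rejection(
    c_prev: Iterable[int], c_curr: Iterable[int]
) -> tuple[frozenset[int], frozenset[int]]:
    """Per-episode deltas: s_t = c_t - c_{t-1}, r_t = c_{t-1} - c_t."""
    prev, curr = set(c_prev), set(c_curr)
    if not curr:
        raise ValueError("current class set must be non-empty")
    return frozenset(curr - prev), frozenset(prev - curr)


def fixation_map(
    locations: Sequence[Location], shape: tuple[int, int] = STIMULUS_SHAPE
) -> FixationMap:
    """Click-frequency distribution: counts at each location, normalised."""
    if not locations:
        raise ValueError("cannot build a fixation map from zero locations")
    counts = np.zeros(shape, dtype=float)
    for r, c in locations:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"location {(r, c)} out of bounds for {shape}")
        counts[r, c] += 1.0
    return FixationMap(counts / counts.sum())


def kl_divergence(P: np.ndarray, Q: np.ndarray, delta: float = 1e-7) -> float:
    """Regularised pixelwise KL divergence, summed: sum P log(d + P/(Q+d))."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return float(np.sum(P * np.log(delta + P / (Q + delta))))


def compare_maps(
    P: FixationMap | np.ndarray,
    Q: FixationMap | np.ndarray,
    delta: float = 1e-7,
) -> tuple[float, float, float]:
    """(KL, CC, SIM) between two fixation maps.

    KL treats P as the reference distribution and is sensitive to zeros in
    Q; CC is the Pearson correlation of the flattened maps (undefined for
    a constant map); SIM is the histogram intersection sum_k min(P_k, Q_k).
    """
    p = (P.dist if isinstance(P, FixationMap) else np.asarray(P, float)).ravel()
    q = (Q.dist if isinstance(Q, FixationMap) else np.asarray(Q, float)).ravel()
    if p.shape != q.shape:
        raise ValueError("fixation maps must share a shape")
    kl = kl_divergence(p, q, delta)
    sp, sq = p.std(), q.std()
    if sp == 0.0 or sq == 0.0:
        raise ValueError("CC undefined: constant fixation map")
    cc = float(np.cov(p, q, bias=True)[0, 1] / (sp * sq))
    sim = float(np.minimum(p, q).sum())
    return kl, cc, sim


def confusion(c_t: Iterable[int], n: int) -> float:
    """Degree of confusion: selected classes as a fraction of all classes."""
    chosen = set(c_t)
    if not chosen:
        raise ValueError("class set must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    return len(chosen) / n


def samples_to_recognition(session: Session, sustained: bool = True) -> int | None:
    """Episodes needed to settle on the true class alone.

    With ``sustained=True`` (default): the smallest t from which the
    selection equals the true singleton at every later episode; with
    ``sustained=False``: the first t where it does, ignoring later lapses.
    None when the session never recognises the class.
    """
    target = frozenset({session.true_class})
    hits = [ep.classes == target for ep in session.episodes]
    if sustained:
        for t in range(len(hits), 0, -1):
            if not hits[t - 1]:
                return t + 1 if t < len(hits) else None
        return 1 if hits else None
    for t, hit in enumerate(hits, start=1):
        if hit:
            return t
    return None


def _scanpath_sequences(
    session: Session, center: Location
) -> tuple[np.ndarray, np.ndarray]:
    rows = np.array([e.row for e in session.episodes], dtype=float)
    cols = np.array([e.col for e in session.episodes], dtype=float)
    cr, cc = center
    dist = np.hypot(rows - cr, cols - cc)
    # rows grow downward, so "directly above centre" maps to +pi/2
    direction = np.arctan2(cr - rows, cols - cc)
    return dist, direction


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) < 3 or a.std() == 0.0 or b.std() == 0.0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SequenceCorrelations:
    """Average within-class scanpath agreement across session pairs."""

    dist_mean: float
    dist_std: float
    dir_mean: float
    dir_std: float
    n_pairs: int


def sequence_correlations(
    sessions: Sequence[Session], center: Location = IMAGE_CENTER
) -> SequenceCorrelations:
    """Pairwise Pearson correlation of distance and direction sequences.

    Each session's clicks become sequences of Euclidean distance and polar
    angle about the image centre; every unordered session pair is
    truncated to its common length (pairs shorter than 3, or with a
    constant sequence, are skipped) and the correlations are averaged.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    seqs = [_scanpath_sequences(s, center) for s in sessions]
    dist_rs, dir_rs = [], []
    for a in range(len(seqs)):
        for b in range(a + 1, len(seqs)):
            m = min(len(seqs[a][0]), len(seqs[b][0]))
            rd = _pearson(seqs[a][0][:m], seqs[b][0][:m])
            ra = _pearson(seqs[a][1][:m], seqs[b][1][:m])
            if rd is not None:
                dist_rs.append(rd)
            if ra is not None:
                dir_rs.append(ra)
    if not dist_rs and not dir_rs:
        raise ValueError("no usable session pairs (need length >= 3 and non-constant sequences)")
    return SequenceCorrelations(
        dist_mean=float(np.mean(dist_rs)) if dist_rs else float("nan"),
        dist_std=float(np.std(dist_rs)) if dist_rs else float("nan"),
        dir_mean=float(np.mean(dir_rs)) if dir_rs else float("nan"),
        dir_std=float(np.std(dir_rs)) if dir_rs else float("nan"),
        n_pairs=max(len(dist_rs), len(dir_rs)),
    )


def behavior_report(
    sessions: Sequence[Session],
    predictions: Sequence[SessionPrediction],
    n_classes: int,
    config: TaskConfig = TaskConfig(),
) -> pd.DataFrame:
    """Per-episode evaluation table (one row per episode index t).

    Columns are means (and std where informative) over sessions of:
    participant accuracy J(eta, c_t), model accuracy J(eta, chat_t),
    participant-model similarity J(c_t, chat_t), selection/rejection
    similarity (over the episodes where they are defined), location-hit
    rate, confusion and cumulative observed-area fraction.
    """
    if len(sessions) != len(predictions):
        raise ValueError("sessions and predictions are misaligned (lengths differ)")
    T = max(len(s.episodes) for s in sessions)
    per_t: dict[int, dict[str, list[float]]] = {
        t: {k: [] for k in (
            "j_true_participant", "j_true_model", "j_similarity",
            "j_selection", "j_rejection", "loc_hit", "confusion", "area",
        )}
        for t in range(1, T + 1)
    }
    for sess, pred in zip(sessions, predictions):
        if len(pred.pred_classes) != len(sess.episodes):
            raise ValueError(
                f"session {sess.stimulus_id}: prediction has "
                f"{len(pred.pred_classes)} episodes, session has {len(sess.episodes)}"
            )
        eta = frozenset({sess.true_class})
        prev: frozenset[int] = frozenset()
        for idx, ep in enumerate(sess.episodes):
            t = idx + 1
            chat = pred.pred_classes[idx]
            row = per_t[t]
            row["j_true_participant"].append(jaccard(eta, ep.classes))
            row["j_true_model"].append(jaccard(eta, chat))
            row["j_similarity"].append(jaccard(ep.classes, chat))
            s_t, r_t = selection_rejection(prev, ep.classes)
            s_hat = frozenset(chat - prev)
            r_hat = frozenset(prev - chat)
            if s_t:
                row["j_selection"].append(jaccard(s_t, s_hat))
            if r_t:
                row["j_rejection"].append(jaccard(r_t, r_hat))
            if pred.loc_hits[idx] is not None:
                row["loc_hit"].append(float(pred.loc_hits[idx]))
            row["confusion"].append(confusion(ep.classes, n_classes))
            row["area"].append(
                observed_area_fraction([e.location for e in sess.episodes[:t]], config)
            )
            prev = ep.classes
    records = []
    for t in range(1, T + 1):
        row = per_t[t]
        rec: dict[str, float] = {"t": t, "n_sessions": len(row["j_true_participant"])}
        for key, vals in row.items():
            rec[f"{key}_mean"] = float(np.mean(vals)) if vals else float("nan")
            rec[f"{key}_std"] = float(np.std(vals)) if vals else float("nan")
        records.append(rec)
    return pd.DataFrame.from_records(records)
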