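"""The sequential patch-reveal task environment.

A participant (or agent) sees a 270x250 canvas showing a low-intensity
context background (the mean of the currently entertained classes). At
each of up to T episodes they click one location; a 5x5 image-pixel patch
of the stimulus centred there is revealed and stays revealed. They then
select a non-empty set of candidate classes. Each episode is scored
1/|c_t| when the true class is among the selection, 0 otherwise, and the
session total h = sum_t P_t lies in [0, T].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stimuli import STIMULUS_SHAPE, ClassTemplate, Stimulus

Location = tuple[int, int]  # (row, col), 0-based, image space


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and budget of the sampling task.

    ``patch_half=2`` gives the 5x5 image-pixel patch (a 50x50 canvas patch
    at 10x upsampling). ``background_alpha`` scales the context background;
    ``time_limit_s`` is recorded metadata only.
    """

    T: int = 12
    patch_half: int = 2
    image_shape: tuple[int, int] = STIMULUS_SHAPE
    canvas_scale: int = 10
    background_alpha: float = 0.3
    time_limit_s: float = 360.0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.patch_half < 0:
            raise ValueError("patch_half must be >= 0")
        if self.canvas_scale < 1:
            raise ValueError("canvas_scale must be >= 1")
        if not 0.0 < self.background_alpha <= 1.0:
            raise ValueError("background_alpha must be in (0, 1]")


@dataclass
class Episode:
    """One sampling event: a click, a class selection, and its duration."""

    t: int
    row: int
    col: int
    classes: frozenset[int]
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.classes = frozenset(int(c) for c in self.classes)
        if not self.classes:
            raise ValueError("an episode must select at least one class")

    @property
    def location(self) -> Location:
        return (self.row, self.col)


@dataclass
class Session:
    """An ordered sequence of episodes for one stimulus."""

    stimulus_id: str
    dataset_tag: str
    true_class: int
    episodes: list[Episode]
    scores: list[float] = field(default_factory=list)
    h: float = 0.0

    @classmethod
    def from_episodes(
        cls,
        stimulus_id: str,
        dataset_tag: str,
        true_class: int,
        episodes: Sequence[Episode],
    ) -> "Session":
        scores = [score_episode(e.classes, true_class) for e in episodes]
        return cls(
            stimulus_id=stimulus_id,
            dataset_tag=dataset_tag,
            true_class=int(true_class),
            episodes=list(episodes),
            scores=scores,
            h=float(sum(scores)),
        )

    @property
    def locations(self) -> list[Location]:
        return [e.location for e in self.episodes]

    @property
    def class_sets(self) -> list[frozenset[int]]:
        return [e.classes for e in self.episodes]


def canvas_to_image(canvas_point: Location, config: TaskConfig) -> Location:
    """Map a canvas click (270x250 space) to image coordinates."""
    r, c = canvas_point
    loc = (int(r) // config.canvas_scale, int(c) // config.canvas_scale)
    _check_bounds(loc, config.image_shape)
    return loc


def _check_bounds(loc: Location, shape: tuple[int, int]) -> None:
    r, c = loc
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise ValueError(f"location {loc} out of bounds for image {shape}")


def patch_mask(
    locations: Iterable[Location],
    shape: tuple[int, int] = STIMULUS_SHAPE,
    patch_half: int = 2,
) -> np.ndarray:
    """Boolean union of square patch windows, clipped at image borders."""
    mask = np.zeros(shape, dtype=bool)
    for loc in locations:
        _check_bounds(loc, shape)
        r, c = loc
        mask[
            max(0, r - patch_half) : r + patch_half + 1,
            max(0, c - patch_half) : c + patch_half + 1,
        ] = True
    return mask


def reveal(
    stimulus: Stimulus | np.ndarray,
    locations: Sequence[Location],
    patch_half: int = 2,
) -> np.ndarray:
    """Compose the observation image I': stimulus pixels on the union of
    revealed patches, zero elsewhere."""
    pixels = stimulus.pixels if isinstance(stimulus, Stimulus) else np.asarray(stimulus, float)
    mask = patch_mask(locations, pixels.shape, patch_half)
    return np.where(mask, pixels, 0.0)


def background_image(
    selected_classes: Iterable[int],
    templates: Sequence[ClassTemplate],
    alpha: float = 0.3,
) -> np.ndarray:
    """Low-intensity context: alpha x mean template of the selected classes.

    Before the first episode the caller passes the set of all classes, so
    the background starts as the grand mean of the dataset.
    """
    selected = sorted(set(int(c) for c in selected_classes))
    if not selected:
        raise ValueError("selected class set must be non-empty")
    by_id = {t.class_id: t.mean_image for t in templates}
    missing = [c for c in selected if c not in by_id]
    if missing:
        raise ValueError(f"unknown class id(s): {missing}")
    return alpha * np.mean([by_id[c] for c in selected], axis=0)


def score_episode(c_t: Iterable[int], eta: int) -> float:
    """Episode score: 1/|c_t| when the true class is selected, else 0."""
    chosen = set(int(c) for c in c_t)
    if not chosen:
        raise ValueError("class selection must be non-empty")
    return 1.0 / len(chosen) if int(eta) in chosen else 0.0


def total_score(session: Session) -> float:
    """Session total h = sum of episode scores, bounded by [0, T]."""
    return float(sum(session.scores))


def filter_sessions(sessions: Sequence[Session], T: int) -> list[Session]:
    """Retain complete sessions whose final-episode score is positive.

    A session is discarded when it has fewer than T episodes (left
    incomplete) or when its T-th episode scored zero.
    """
    return [
        s
        for s in sessions
        if len(s.episodes) == T and s.scores and s.scores[-1] > 0.0
    ]


def observed_area_fraction(
    locations: Sequence[Location], config: TaskConfig = TaskConfig()
) -> float:
    """Fraction of image pixels inside the union of revealed patches."""
    if not locations:
        return 0.0
    mask = patch_mask(locations, config.image_shape, config.patch_half)
    return float(mask.sum()) / float(np.prod(config.image_shape))
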