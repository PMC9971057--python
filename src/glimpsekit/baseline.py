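"""Template-matching baseline for predicting sampling behaviour.

Two predictions per episode:

* **Class**: the belief over classes given the revealed pixels I' is the
  cosine similarity between I' and each class template I_i, normalised to
  sum to one; the model's class set is the k most probable classes with
  k equal to the participant's selection size.

* **Location**: for every ordered class pair (i, j) a discriminative
  saliency map D_ij = N(., sigma) * g(I_i, I_j) scores how strongly an
  observation at each pixel supports class i over class j, with g either
  a pixelwise KL term or a plain difference, smoothed by a 5x5 Gaussian
  kernel. Locations whose score exceeds theta = 0.5 * max over all maps,
  restricted to pairs touching the currently selected classes and not yet
  sampled, form the candidate set Gamma of (location, for-class,
  against-class) triples. A participant's next click counts as predicted
  when some triple lies within epsilon of it, its supported class is kept
  and its opposed class is dropped at the next episode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .stimuli import ClassTemplate, Stimulus
from .task_env import Location, Session, reveal

#: default regularizer for the pixelwise KL score
DEFAULT_DELTA = 1e-7
#: max centre-to-pixel Euclidean distance inside a 5x5 patch
DEFAULT_EPSILON = 2.0 * math.sqrt(2.0)


@dataclass
class Belief:
    """Probability vector over class ids."""

    class_ids: tuple[int, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.class_ids),):
            raise ValueError("probs length must match class_ids")
        if np.any(self.probs < 0):
            raise ValueError("belief entries must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("belief must sum to 1")

    @classmethod
    def uniform(cls, class_ids: Sequence[int]) -> "Belief":
        ids = tuple(int(c) for c in class_ids)
        return cls(ids, np.full(len(ids), 1.0 / len(ids)))


class SalientTriple(NamedTuple):
    """A candidate next sample: where, which class it supports, against which."""

    location: Location
    for_class: int
    against_class: int


def class_posterior(observed: np.ndarray, templates: Sequence[ClassTemplate]) -> Belief:
    """Belief over classes: cosine match of I' with each template, normalised.

    Invariant to positive rescaling of the observation. Raises on an
    all-zero observation (no evidence yet — use ``Belief.uniform``).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    norm = np.linalg.norm(obs)
    if norm == 0.0:
        raise ValueError("observation is all-zero; belief is undefined before any evidence")
    obs = obs / norm
    sims = np.empty(len(templates))
    for k, tpl in enumerate(templates):
        tv = tpl.mean_image.ravel()
        tn = np.linalg.norm(tv)
        if tn == 0.0:
            raise ValueError(f"template for class {tpl.class_id} is all-zero")
        sims[k] = obs @ (tv / tn)
    total = sims.sum()
    if total <= 0.0:
        raise ValueError("all template similarities are zero")
    return Belief(tuple(t.class_id for t in templates), sims / total)


def top_k_classes(belief: Belief, k: int) -> frozenset[int]:
    """The k most probable classes; ties break toward the smaller class id."""
    n = len(belief.class_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    ranked = sorted(zip(belief.class_ids, belief.probs), key=lambda cp: (-cp[1], cp[0]))
    return frozenset(cid for cid, _ in ranked[:k])


def pairwise_score(
    template_i: np.ndarray,
    template_j: np.ndarray,
    mode: str = "diff",
    delta: float = DEFAULT_DELTA,
) -> np.ndarray:
    """Unsmoothed discriminative score g(I_i, I_j), pixelwise.

    ``"kl"``: I_i * log(delta + I_i / (I_j + delta)) — the information lost
    when I_j stands in for I_i. ``"diff"``: I_i - I_j. Both are asymmetric
    in (i, j) and vanish where the templates agree.
    """
    a = np.asarray(template_i, dtype=float)
    b = np.asarray(template_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("templates must share a shape")
    mode = mode.lower()
    if mode == "diff":
        return a - b
    if mode == "kl":
        if delta <= 0:
            raise ValueError("delta must be positive in KL mode")
        return a * np.log(delta + a / (b + delta))
    raise ValueError(f"unknown saliency mode {mode!r}")


def gaussian_kernel(size: int = 5, sigma: float = 6.0) -> np.ndarray:
    """Truncated 2-D Gaussian kernel, renormalised to sum to one.

    With sigma=6 over a 5x5 support the kernel is nearly uniform; it is
    built exactly as specified (truncate, renormalise).
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and positive")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


@dataclass
class SaliencySet:
    """All pairwise saliency maps D_ij for one stimulus set, plus theta.

    ``maps[(i, j)]`` scores locations supporting class i against class j;
    ``theta`` is half the global maximum over every map in the set.
    """

    maps: dict[tuple[int, int], np.ndarray]
    theta: float
    mode: str
    sigma: float = 6.0
    kernel_size: int = 5
    delta: float = DEFAULT_DELTA

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(sorted({i for i, _ in self.maps}))

    def restricted(self, c_t: Iterable[int]) -> dict[tuple[int, int], np.ndarray]:
        """Maps D' whose ordered pair touches the selected class set."""
        chosen = set(int(c) for c in c_t)
        return {
            (i, j): m for (i, j), m in self.maps.items() if i in chosen or j in chosen
        }


def build_saliency(
    templates: Sequence[ClassTemplate],
    mode: str = "diff",
    sigma: float = 6.0,
    kernel_size: int = 5,
    delta: float = DEFAULT_DELTA,
) -> SaliencySet:
    """Smooth every ordered-pair score with the Gaussian kernel.

    Convolution uses reflect padding and same-size output. theta is
    0.5 x the maximum entry over the whole family of maps.
    """
    if len(templates) < 2:
        raise ValueError("need at least two class templates")
    kernel = gaussian_kernel(kernel_size, sigma)
    maps: dict[tuple[int, int], np.ndarray] = {}
    for ti in templates:
        for tj in templates:
            if ti.class_id == tj.class_id:
                continue
            score = pairwise_score(ti.mean_image, tj.mean_image, mode=mode, delta=delta)
            maps[(ti.class_id, tj.class_id)] = ndimage.convolve(
                score, kernel, mode="reflect"
            )
    theta = 0.5 * max(float(m.max()) for m in maps.values())
    return SaliencySet(
        maps=maps, theta=theta, mode=mode, sigma=sigma,
        kernel_size=kernel_size, delta=delta,
    )


def candidate_locations(
    sal: SaliencySet,
    c_t: Iterable[int],
    visited: Sequence[Location],
) -> set[SalientTriple]:
    """The Gamma set of above-threshold, unvisited salient triples."""
    chosen = set(int(c) for c in c_t)
    if not chosen:
        raise ValueError("selected class set must be non-empty")
    seen = {tuple(v) for v in visited}
    gamma: set[SalientTriple] = set()
    for (i, j), m in sal.restricted(chosen).items():
        for r, c in np.argwhere(m > sal.theta):
            loc = (int(r), int(c))
            if loc not in seen:
                gamma.add(SalientTriple(loc, i, j))
    return gamma


def location_hit(
    gamma: Iterable[SalientTriple],
    l_next: Location,
    c_next: Iterable[int],
    epsilon: float = DEFAULT_EPSILON,
) -> bool:
    """Was the next click predicted?

    True iff some triple lies strictly within epsilon of the click, its
    supported class is in the next selection and its opposed class is not.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    nxt = set(int(c) for c in c_next)
    lr, lc = l_next
    for (r, c), i, j in gamma:
        if i in nxt and j not in nxt and math.hypot(r - lr, c - lc) < epsilon:
            return True
    return False


@dataclass
class SessionPrediction:
    """Baseline outputs aligned with one session.

    ``pred_classes[t-1]`` is the model's class set at episode t;
    ``loc_hits[t-1]`` says whether the participant's episode-(t+1) click was
    predicted from episode t's state (None at the final episode, which has
    no next click).
    """

    stimulus_id: str
    pred_classes: list[frozenset[int]]
    loc_hits: list[bool | None]
    gamma_sizes: list[int] = field(default_factory=list)


def predict_session(
    session: Session,
    stimulus: Stimulus,
    templates: Sequence[ClassTemplate],
    sal: SaliencySet,
    epsilon: float = DEFAULT_EPSILON,
    patch_half: int = 2,
) -> SessionPrediction:
    """Run the baseline along one recorded session.

    At each episode t the model sees exactly what the participant saw
    (the union of revealed patches), predicts the class set of the same
    size as the participant's, and builds Gamma from the participant's
    selection to predict the next click.
    """
    class_ids = [t.class_id for t in templates]
    pred_classes: list[frozenset[int]] = []
    loc_hits: list[bool | None] = []
    gamma_sizes: list[int] = []
    episodes = session.episodes
    for idx, ep in enumerate(episodes):
        visited = [e.location for e in episodes[: idx + 1]]
        observed = reveal(stimulus, visited, patch_half)
        if observed.any():
            belief = class_posterior(observed, templates)
        else:
            belief = Belief.uniform(class_ids)
        pred_classes.append(top_k_classes(belief, len(ep.classes)))
        gamma = candidate_locations(sal, ep.classes, visited)
        gamma_sizes.append(len(gamma))
        if idx + 1 < len(episodes):
            nxt = episodes[idx + 1]
            loc_hits.append(location_hit(gamma, nxt.location, nxt.classes, epsilon))
        else:
            loc_hits.append(None)
    return SessionPrediction(
        stimulus_id=session.stimulus_id,
        pred_classes=pred_classes,
        loc_hits=loc_hits,
        gamma_sizes=gamma_sizes,
    )
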