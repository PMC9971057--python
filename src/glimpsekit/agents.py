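"""Simulated participants for the patch-reveal task.

Two built-in policies generate complete sessions with the statistical
structure the analyses assume: a greedy saliency agent that always clicks
the most discriminative unvisited location for the classes it currently
entertains, and a uniform-random null agent. Both select classes by
thresholding the template-matching belief at its mean probability.
Episode durations follow a confusion-dependent model (longer deliberation
when more classes are entertained), so simulated data reproduce the
positive confusion-duration association seen in human sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .baseline import Belief, SaliencySet, class_posterior
from .metrics import confusion
from .stimuli import ClassTemplate, Stimulus
from .task_env import Episode, Location, Session, TaskConfig, patch_mask, reveal


@dataclass
class DurationModel:
    """duration_t = base + gain * confusion_t + N(0, noise_sd), floored at 0 s."""

    base_s: float = 2.0
    gain_s: float = 20.0
    noise_sd: float = 1.0

    def draw(self, conf: float, rng: np.random.Generator) -> float:
        return max(0.0, self.base_s + self.gain_s * conf + rng.normal(0.0, self.noise_sd))


@dataclass
class EnvState:
    """What an agent may condition on at the start of an episode."""

    stimulus: Stimulus
    templates: Sequence[ClassTemplate]
    visited: list[Location]
    observed: np.ndarray
    belief: Belief
    prev_classes: frozenset[int]
    t: int
    rng: np.random.Generator


def mean_threshold_classes(belief: Belief) -> frozenset[int]:
    """Classes with probability above the mean probability.

    The rule can come up empty on a flat belief, which the task forbids;
    the fallback is the single most probable class (smallest id on ties).
    """
    mean = float(belief.probs.mean())
    chosen = {cid for cid, p in zip(belief.class_ids, belief.probs) if p > mean}
    if not chosen:
        best = min(zip(belief.class_ids, belief.probs), key=lambda cp: (-cp[1], cp[0]))
        chosen = {best[0]}
    return frozenset(chosen)


class AgentPolicy:
    """Contract for a simulated participant (or an external model adapter)."""

    name: str = "abstract"

    def next_location(self, state: EnvState) -> Location:
        raise NotImplementedError

    def next_classes(self, state: EnvState) -> frozenset[int]:
        # with no ink revealed yet the agent entertains every class, like
        # a participant facing the all-classes context background
        if not state.observed.any():
            return frozenset(t.class_id for t in state.templates)
        return mean_threshold_classes(state.belief)


class GreedySaliencyAgent(AgentPolicy):
    """Clicks the most salient unrevealed location among maps touching the
    currently entertained classes (ties: smallest row, then column) — the
    uncertainty-reducing sampling principle.

    While some unrevealed location is still salient (above theta), the
    whole already-revealed patch union is excluded, not just the exact
    click pixels: re-sampling revealed ink cannot change the belief, so a
    goal-directed sampler never returns there. Once nothing salient
    remains unrevealed the agent clicks the best unvisited pixel even
    inside the revealed area, deliberately gaining nothing — the forced
    click of a participant who has already made up their mind.
    """

    name = "greedy"

    def __init__(self, sal: SaliencySet, patch_half: int = 2):
        self.sal = sal
        self.patch_half = patch_half

    def next_location(self, state: EnvState) -> Location:
        maps = self.sal.restricted(state.prev_classes)
        stacked = np.max(np.stack(list(maps.values())), axis=0)
        unrevealed = stacked.copy()
        if state.visited:
            unrevealed[
                patch_mask(state.visited, stacked.shape, self.patch_half)
            ] = -np.inf
        if np.isfinite(unrevealed).any() and unrevealed.max() > self.sal.theta:
            flat = int(np.argmax(unrevealed))  # row-major: smallest row, then col
            return (flat // stacked.shape[1], flat % stacked.shape[1])
        for r, c in state.visited:
            stacked[r, c] = -np.inf
        if not np.isfinite(stacked).any():
            raise RuntimeError("every location has been visited")
        flat = int(np.argmax(stacked))
        return (flat // stacked.shape[1], flat % stacked.shape[1])


class RandomAgent(AgentPolicy):
    """Null baseline: uniform over unvisited locations."""

    name = "random"

    def next_location(self, state: EnvState) -> Location:
        shape = state.stimulus.pixels.shape
        visited = set(state.visited)
        free = [
            (r, c)
            for r in range(shape[0])
            for c in range(shape[1])
            if (r, c) not in visited
        ]
        if not free:
            raise RuntimeError("every location has been visited")
        return free[int(state.rng.integers(len(free)))]


AGENT_REGISTRY: dict[str, Callable[..., AgentPolicy]] = {
    "greedy": GreedySaliencyAgent,
    "random": lambda sal=None: RandomAgent(),
}


def make_agent(name: str, sal: SaliencySet | None = None) -> AgentPolicy:
    if name not in AGENT_REGISTRY:
        raise ValueError(f"unknown agent {name!r}; available: {sorted(AGENT_REGISTRY)}")
    if name == "greedy":
        if sal is None:
            raise ValueError("the greedy agent needs a SaliencySet")
        return GreedySaliencyAgent(sal)
    return AGENT_REGISTRY[name]()


def cumulative_reward(scores: Sequence[float]) -> list[float]:
    """Running sum of episode scores — the reward exposed to learning agents."""
    return list(np.cumsum(scores))


def simulate(
    agent: AgentPolicy,
    stimuli: Sequence[Stimulus],
    templates: Sequence[ClassTemplate],
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
    durations: DurationModel = DurationModel(),
) -> list[Session]:
    """Run one complete T-episode session per stimulus.

    Deterministic for a fixed seed: each session gets its own generator
    derived from (seed, stimulus index). The belief presented to the
    agent is the template-matching posterior over the pixels revealed so
    far (uniform while the observation is still all-zero).
    """
    class_ids = [t.class_id for t in templates]
    n = len(class_ids)
    sessions: list[Session] = []
    for k, stim in enumerate(stimuli):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(k)]))
        state = EnvState(
            stimulus=stim,
            templates=templates,
            visited=[],
            observed=np.zeros(config.image_shape),
            belief=Belief.uniform(class_ids),
            prev_classes=frozenset(class_ids),
            t=1,
            rng=rng,
        )
        episodes: list[Episode] = []
        for t in range(1, config.T + 1):
            state.t = t
            loc = agent.next_location(state)
            state.visited.append(loc)
            state.observed = reveal(stim, state.visited, config.patch_half)
            if state.observed.any():
                state.belief = class_posterior(state.observed, templates)
            else:
                state.belief = Belief.uniform(class_ids)
            classes = agent.next_classes(state)
            conf = confusion(classes, n)
            episodes.append(
                Episode(
                    t=t,
                    row=loc[0],
                    col=loc[1],
                    classes=classes,
                    duration_s=durations.draw(conf, rng),
                )
            )
            state.prev_classes = classes
        sessions.append(
            Session.from_episodes(
                stimulus_id=f"{stim.dataset_tag}:{stim.class_id}:{k}",
                dataset_tag=stim.dataset_tag,
                true_class=stim.class_id,
                episodes=episodes,
            )
        )
    return sessions
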