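"""Economic choice task environments.

Five trial-based tasks (standard, risky, bundles, ternary, sequential) in
which an agent holds fixation through a fixation and a rule-cue epoch,
observes one or more offers, and reports a choice during a response window.
Each offer consists of a good with an intrinsic value rho, a quantity q and
a reward probability p; its value is rho*q*p.  Rewards are delivered as a
Bernoulli draw of rho*q with probability p (componentwise for bundles).

Environments are stateful step-based objects advancing in 20 ms increments.
Observations are 16-channel vectors: one fixation cue, five one-hot rule
cues, five quantity channels and five probability channels (one per good
A-E), each normalized to [0, 1] plus a 0.2 baseline and Gaussian input
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DT_MS = 20
N_INPUTS = 16
BASELINE = 0.2
RESPONSE_MS = 1000

#: Intrinsic (dimensionless) values of the five goods. rho_E = 1 is the
#: reference; the ordering rho_A > ... > rho_E is required by the tasks.
DEFAULT_RHO = {"A": 3.0, "B": 2.5, "C": 2.0, "D": 1.5, "E": 1.0}

GOOD_ORDER = ("A", "B", "C", "D", "E")
TASK_NAMES = ("standard", "risky", "bundles", "ternary", "sequential")

# input channel layout
CH_FIX = 0
CH_RULE = {name: 1 + i for i, name in enumerate(TASK_NAMES)}
CH_QUANT = {g: 6 + i for i, g in enumerate(GOOD_ORDER)}
CH_PROB = {g: 11 + i for i, g in enumerate(GOOD_ORDER)}

ACT_FIXATE = 0
N_ACTIONS = 4  # fixate + three choice slots (slot 3 inert outside ternary)


@dataclass(frozen=True)
class Good:
    """A consumable good with a fixed intrinsic value rho > 0."""

    id: str
    intrinsic_value: float

    def __post_init__(self):
        if self.intrinsic_value <= 0:
            raise ValueError("intrinsic value must be positive")

    @property
    def max_quantity(self) -> float:
        # quantities are drawn from [0, 10/rho] so every good spans the
        # same value range [0, 10]
        return 10.0 / self.intrinsic_value


@dataclass(frozen=True)
class Offer:
    """A single-good offer: quantity, probability and resulting value."""

    good: Good
    quantity: float
    probability: float

    @property
    def value(self) -> float:
        return self.good.intrinsic_value * self.quantity * self.probability


@dataclass(frozen=True)
class TaskSpec:
    """Static description of one task: which goods in which choice slots."""

    name: str
    slots: tuple  # tuple of tuples of good ids, one inner tuple per slot
    deterministic: bool
    sequential: bool = False

    @property
    def n_choices(self) -> int:
        return len(self.slots)


def make_tasks(rho: dict | None = None, enforce_order: bool = True) -> dict:
    """Build the five canonical task specs for a given rho assignment.

    ``enforce_order`` checks the canonical ranking rho_A > ... > rho_E;
    experiments that deliberately re-assign a single good's value (the
    value-weight cohort varies rho_C from 1 to 5) disable it.
    """
    rho = dict(DEFAULT_RHO if rho is None else rho)
    vals = [rho[g] for g in GOOD_ORDER if g in rho]
    if enforce_order and sorted(vals, reverse=True) != vals:
        raise ValueError("intrinsic values must be ordered rho_A > ... > rho_E")
    return {
        "standard": TaskSpec("standard", (("C",), ("E",)), deterministic=True),
        "risky": TaskSpec("risky", (("C",), ("E",)), deterministic=False),
        "bundles": TaskSpec("bundles", (("B", "C"), ("D", "E")), deterministic=False),
        "ternary": TaskSpec("ternary", (("A",), ("C",), ("E",)), deterministic=False),
        "sequential": TaskSpec(
            "sequential", (("C",), ("E",)), deterministic=False, sequential=True
        ),
    }


@dataclass(frozen=True)
class TrialTimeline:
    """Epoch schedule of one trial; all durations in ms, multiples of 20."""

    epochs: tuple  # tuple of (name, duration_ms)

    def __post_init__(self):
        for name, dur in self.epochs:
            if dur <= 0 or dur % DT_MS:
                raise ValueError(f"epoch {name}: duration must be a positive multiple of {DT_MS} ms")

    @property
    def total_ms(self) -> int:
        return sum(d for _, d in self.epochs)

    @property
    def n_steps(self) -> int:
        return self.total_ms // DT_MS

    def phase_at(self, t: int) -> str:
        """Epoch label at integer step t (0-based)."""
        ms = t * DT_MS
        acc = 0
        for name, dur in self.epochs:
            acc += dur
            if ms < acc:
                return name
        return "done"

    def onset_step(self, name: str) -> int:
        acc = 0
        for n, dur in self.epochs:
            if n == name:
                return acc // DT_MS
            acc += dur
        raise KeyError(name)


def _draw_ms(rng: np.random.Generator, lo: int = 500, hi: int = 1500) -> int:
    """Duration uniform over [lo, hi] ms, quantized to the 20 ms grid."""
    return int(rng.integers(lo // DT_MS, hi // DT_MS + 1)) * DT_MS


def sample_offer(
    good: Good,
    deterministic: bool,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> Offer:
    """Draw (q, p) uniformly, resampling until the offer value is >= 1.

    Quantity ~ U(0, 10/rho); probability ~ U(0, 1), or exactly 1 for
    deterministic offers.  Offers with value rho*q*p < 1 are redrawn so that
    every presented offer is non-trivial.
    """
    for _ in range(max_attempts):
        q = rng.uniform(0.0, good.max_quantity)
        p = 1.0 if deterministic else rng.uniform(0.0, 1.0)
        if good.intrinsic_value * q * p >= 1.0:
            return Offer(good, q, p)
    raise RuntimeError(
        f"could not draw an offer of value >= 1 for good {good.id} "
        f"(rho={good.intrinsic_value}) in {max_attempts} attempts"
    )


def sample_constrained_risky(
    goods: dict,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list:
    """Constrained 'cross-shaped' offer set for the generalization study.

    With probability 0.5 both goods' probabilities are fixed at 0.5 while
    quantities span their full ranges; otherwise quantities are fixed at
    half their maxima (q_C = 2.5, q_E = 5 for the default rho) while
    probabilities span [0, 1].  The value >= 1 resampling rule still holds.
    """
    fixed_prob = rng.random() < 0.5
    offers = []
    for gid in ("C", "E"):
        good = goods[gid]
        for _ in range(max_attempts):
            if fixed_prob:
                q = rng.uniform(0.0, good.max_quantity)
                p = 0.5
            else:
                q = good.max_quantity / 2.0
                p = rng.uniform(0.0, 1.0)
            if good.intrinsic_value * q * p >= 1.0:
                offers.append(Offer(good, q, p))
                break
        else:
            raise RuntimeError("constrained offer resampling failed")
    return offers


def build_trial(
    spec: TaskSpec,
    rng: np.random.Generator,
    fixed_epochs: bool = False,
    rho: dict | None = None,
    offer_sampler=None,
):
    """Draw one trial: epoch schedule, per-slot offers and sequential order.

    Epoch durations are uniform over 500-1500 ms (midpoints, i.e. 1000 ms,
    when ``fixed_epochs`` -- used for neural-analysis trials where activity
    must be temporally aligned across trials).  For the sequential task the
    presentation order of the two goods is randomized; ``order`` is +1 when
    good C is presented second, -1 when first, 0 otherwise.

    Returns ``(timeline, offers, order)`` where offers is a list (one entry
    per slot) of lists of Offer.
    """
    rho = dict(DEFAULT_RHO if rho is None else rho)
    goods = {g: Good(g, r) for g, r in rho.items()}
    dur = (lambda: 1000) if fixed_epochs else (lambda: _draw_ms(rng))
    if spec.sequential:
        epochs = (
            ("fixation", dur()),
            ("rule", dur()),
            ("offer1", dur()),
            ("delay", dur()),
            ("offer2", dur()),
            ("response", RESPONSE_MS),
        )
    else:
        epochs = (
            ("fixation", dur()),
            ("rule", dur()),
            ("offer", dur()),
            ("response", RESPONSE_MS),
        )
    timeline = TrialTimeline(epochs)
    if offer_sampler is not None:
        offers = [[o] for o in offer_sampler(goods, rng)]
    else:
        offers = [
            [sample_offer(goods[g], spec.deterministic, rng) for g in slot]
            for slot in spec.slots
        ]
    order = 0
    if spec.sequential:
        order = +1 if rng.random() < 0.5 else -1  # +1: C second
    return timeline, offers, order


@dataclass
class EnvState:
    timeline: TrialTimeline
    offers: list
    order: int
    t: int = 0
    done: bool = False
    outcome: float = 0.0


class ChoiceEnv:
    """Stateful single-trial environment for one task.

    The agent emits one of four actions per 20 ms step: fixate or choose
    slot 1-3.  Breaking fixation before the response window aborts the
    trial with reward -1; failing to respond within the 1000 ms window ends
    the trial unrewarded and incomplete; a choice during the window yields
    a Bernoulli-realized terminal reward.
    """

    def __init__(
        self,
        spec: TaskSpec,
        rho: dict | None = None,
        rng: np.random.Generator | None = None,
        fixed_epochs: bool = False,
        sigma_in: float = 0.01,
        tau_ms: float = 100.0,
        offer_sampler=None,
        timeout_reward: float = -1.0,
    ):
        self.spec = spec
        self.rho = dict(DEFAULT_RHO if rho is None else rho)
        self.goods = {g: Good(g, r) for g, r in self.rho.items()}
        self.rng = rng if rng is not None else np.random.default_rng()
        self.fixed_epochs = fixed_epochs
        self.offer_sampler = offer_sampler
        # failing to respond aborts the trial; penalized like a fixation
        # break so that indefinite fixation is never a reward-neutral policy
        self.timeout_reward = timeout_reward
        alpha = DT_MS / tau_ms
        # discretized amplitude of the continuous sqrt(2*tau)*sigma noise
        self.noise_std = sigma_in * np.sqrt(2.0 / alpha)
        self.state: EnvState | None = None

    # -- trial construction ------------------------------------------------

    def reset(self) -> np.ndarray:
        timeline, offers, order = build_trial(
            self.spec, self.rng, fixed_epochs=self.fixed_epochs,
            rho=self.rho, offer_sampler=self.offer_sampler,
        )
        self.state = EnvState(timeline, offers, order)
        self._phase_cache = {}
        return self.observe()

    # -- observations ------------------------------------------------------

    def _offer_channels_visible(self, phase: str) -> list:
        """Slots whose offers are on-screen during ``phase``."""
        if self.spec.sequential:
            # slot 0 holds good C, slot 1 good E; order=+1 means C second
            first, second = (1, 0) if self.state.order == +1 else (0, 1)
            if phase == "offer1":
                return [first]
            if phase == "offer2":
                return [second]
            return []
        if phase in ("offer", "response"):
            return [0, 1, 2][: self.spec.n_choices]
        return []

    def observe(self, noise: bool = True) -> np.ndarray:
        """16-channel observation for the current step."""
        s = self.state
        phase = s.timeline.phase_at(s.t)
        base = self._phase_cache.get(phase)
        if base is None:
            u = np.zeros(N_INPUTS)
            if phase != "response":
                u[CH_FIX] = 1.0
            if phase != "fixation":
                u[CH_RULE[self.spec.name]] = 1.0
            for slot in self._offer_channels_visible(phase):
                for off in s.offers[slot]:
                    g = off.good
                    u[CH_QUANT[g.id]] = off.quantity / g.max_quantity
                    u[CH_PROB[g.id]] = off.probability
            base = u + BASELINE
            self._phase_cache[phase] = base
        if noise:
            return base + self.rng.normal(0.0, self.noise_std, size=N_INPUTS)
        return base.copy()

    # -- stepping ----------------------------------------------------------

    def _realize_reward(self, slot: int) -> float:
        r = 0.0
        for off in self.state.offers[slot]:
            if off.probability >= 1.0 or self.rng.random() < off.probability:
                r += off.good.intrinsic_value * off.quantity
        return r

    def slot_values(self) -> np.ndarray:
        """Expected value (rho*q*p, summed over bundle components) per slot."""
        return np.array([sum(o.value for o in slot) for slot in self.state.offers])

    def step(self, action: int):
        """Advance one 20 ms step.  Returns (obs, reward, done, info)."""
        if not 0 <= action < N_ACTIONS:
            raise ValueError(f"invalid action {action}")
        s = self.state
        if s.done:
            raise RuntimeError("step() called on a finished trial")
        phase = s.timeline.phase_at(s.t)
        info = {}
        reward = 0.0
        if phase != "response":
            if action != ACT_FIXATE:
                s.done = True
                reward = -1.0
                info = self._end_info(completed=False, aborted=True)
        else:
            if action == ACT_FIXATE:
                if s.t + 1 >= s.timeline.n_steps:  # response window elapsed
                    s.done = True
                    reward = self.timeout_reward
                    info = self._end_info(completed=False, aborted=False)
            elif action - 1 < self.spec.n_choices:
                slot = action - 1
                reward = self._realize_reward(slot)
                s.done = True
                rt = (s.t + 1 - s.timeline.onset_step("response")) * DT_MS
                info = self._end_info(completed=True, aborted=False,
                                      choice=slot, rt_ms=rt)
            else:  # inert slot: trial ends unrewarded, not completed
                s.done = True
                info = self._end_info(completed=False, aborted=False)
        s.outcome = reward
        if not s.done:
            s.t += 1
        obs = self.observe() if not s.done else np.full(N_INPUTS, BASELINE)
        return obs, reward, s.done, info

    def _end_info(self, completed, aborted, choice=None, rt_ms=None):
        vals = self.slot_values()
        return {
            "completed": completed,
            "aborted": aborted,
            "choice": choice,
            "rt_ms": rt_ms,
            "slot_values": vals,
            "best_slot": int(np.argmax(vals)),
            "correct": (choice == int(np.argmax(vals))) if choice is not None else False,
            "order": self.state.order,
            "offers": self.state.offers,
            "task": self.spec.name,
        }


def constrained_offer_sampler(goods: dict, rng: np.random.Generator) -> list:
    """Adapter of :func:`sample_constrained_risky` to the env's sampler hook."""
    return sample_constrained_risky(goods, rng)


# -- trial logs -----------------------------------------------------------

LOG_COLUMNS = [
    "task", "trial", "completed", "aborted", "choice", "best_slot", "correct",
    "reward", "rt_ms", "order",
]


def trial_log_row(task: str, trial: int, info: dict, reward: float) -> dict:
    """Flatten one finished trial into a tidy log row."""
    row = {
        "task": task, "trial": trial,
        "completed": info["completed"], "aborted": info["aborted"],
        "choice": info["choice"], "best_slot": info["best_slot"],
        "correct": info["correct"], "reward": reward,
        "rt_ms": info["rt_ms"], "order": info["order"],
    }
    for si, slot in enumerate(info["offers"]):
        for off in slot:
            g = off.good.id
            row[f"slot{si}_{g}_q"] = off.quantity
            row[f"slot{si}_{g}_p"] = off.probability
            row[f"slot{si}_{g}_rho"] = off.good.intrinsic_value
        row[f"slot{si}_value"] = info["slot_values"][si]
    return row


def logs_to_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows)
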