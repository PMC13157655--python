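"""Proximal policy optimization of the recurrent actor-critic network.

The total objective (to be maximized) is

    L(theta) = E[ L_PPO - c1 * L_VF + c2 * S ]

with the clipped surrogate L_PPO = min(rho_t A_t, clip(rho_t, 1-eps, 1+eps) A_t),
rho_t the new/old probability ratio, A_t = R_t - V(s_t) the advantage,
R_t the bootstrapped discounted return, L_VF = 0.5 (V - R)^2 and S the
policy entropy.  Experience is collected from 20 parallel task environments
for T = 128 twenty-millisecond steps per rollout; parameters are updated by
Adam (lr 2.5e-4) with the gradient norm clipped at 1.0, backpropagating
through time within each rollout.  Dale's law is maintained after every
update through the magnitude reparameterization of the weights.

Gradients are computed analytically (the backward recursion through the
rate dynamics is written out by hand) and are validated against finite
differences in the test suite.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, taskenv
from .network import NetworkConfig, NetworkParams, enforce_dale, init_params
from .taskenv import ChoiceEnv, TaskSpec, trial_log_row


@dataclass
class PPOConfig:
    gamma: float = 0.99
    clip_eps: float = 0.1
    c1: float = 0.5            # value-loss coefficient
    c2: float = 0.01           # entropy coefficient
    lr: float = 2.5e-4
    grad_clip: float = 1.0
    n_envs: int = 20
    T: int = 128               # steps per rollout
    n_epochs: int = 4          # optimization epochs per rollout
    n_minibatches: int = 4     # minibatches of whole sequences
    normalize_advantage: bool = True
    value_huber_delta: float = 1.0  # bounds critic gradients through the trunk
    # generalized advantage estimation; the default lambda = 1 is exactly
    # the plain bootstrapped-return advantage A_t = R_t - V(s_t), which
    # also trains more reliably here than lambda < 1
    gae_lambda: float = 1.0
    target_kl: float = 0.02        # stop a rollout's epochs when exceeded
    c2_init: float | None = None   # optional higher entropy weight early on,
    c2_anneal_steps: int = 1_000_000  # decayed linearly to c2
    # decoupled weight decay on the actor head: bounds the softmax logit
    # gaps, giving a recovery path out of saturated (zero-entropy) policies
    # where the entropy-bonus gradient itself has vanished.  The strong
    # rescue value caps fixation reliability at ~95%, so once the behavior
    # policy completes most trials the decay is relaxed to the trained
    # value and restored whenever completion degrades again.
    actor_weight_decay: float = 0.3
    actor_weight_decay_trained: float = 0.02
    # hysteresis: relax the decay when recent completion crosses the upper
    # bound, restore it only when completion falls below the lower bound
    wd_relax_completion: float = 0.9
    wd_restore_completion: float = 0.8
    # optional epsilon-floor mixture on the behavior policy during training
    # rollouts (never at evaluation), applied only at steps where the
    # fixation cue is off.  Off by default: PPO's importance ratio nulls
    # the gradient of actions the current policy has fully suppressed, so
    # forced samples cannot rescue a saturated policy anyway.
    explore_eps: float = 0.0
    max_env_steps: int = 20_000_000
    eval_every_steps: int = 100_000
    eval_trials_per_task: int = 400
    test_set_size: int = 25_000   # held-out trials for the final criteria
    completion_criterion: float = 0.99
    accuracy_criterion: float = 0.90
    # training stops only when the criteria hold with this margin, so the
    # delivered network clears them under independent re-evaluation noise
    stop_margin_completion: float = 0.006
    stop_margin_accuracy: float = 0.015

    def __post_init__(self):
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.clip_eps <= 0:
            raise ValueError("clip_eps must be positive")


# -- returns and advantages ----------------------------------------------

def bootstrapped_return(
    rewards: np.ndarray, dones: np.ndarray, bootstrap_value: np.ndarray, gamma: float
) -> np.ndarray:
    """Discounted returns R_t = sum_k gamma^k r_{t+k} + gamma^{T-t} V(s_T).

    ``rewards``/``dones`` are (B, T); ``bootstrap_value`` is (B,).  The
    accumulation truncates at episode boundaries: a ``done`` flag at step t
    zeroes the contribution of everything after t, including the bootstrap.
    """
    B, T = rewards.shape
    R = np.zeros((B, T))
    nxt = bootstrap_value.astype(float).copy()
    for t in range(T - 1, -1, -1):
        nxt = rewards[:, t] + gamma * nxt * (1.0 - dones[:, t])
        R[:, t] = nxt
    return R


def advantage(returns: np.ndarray, values: np.ndarray) -> np.ndarray:
    """A_t = R_t - V(s_t)."""
    return returns - values


def gae_advantage(rewards, dones, values, bootstrap_value, gamma, lam):
    """Generalized advantage estimate with episode-boundary truncation.

    A_t = sum_k (gamma*lam)^k delta_{t+k} with
    delta_t = r_t + gamma V(s_{t+1}) (1 - done_t) - V(s_t).
    At lam = 1 this equals bootstrapped_return(...) - values exactly.
    """
    B, T = rewards.shape
    adv = np.zeros((B, T))
    next_v = bootstrap_value.astype(float)
    carry = np.zeros(B)
    for t in range(T - 1, -1, -1):
        nd = 1.0 - dones[:, t]
        delta = rewards[:, t] + gamma * next_v * nd - values[:, t]
        carry = delta + gamma * lam * nd * carry
        adv[:, t] = carry
        next_v = values[:, t]
    return adv


# -- forward / backward through the unrolled network ----------------------

def forward_segment(params: NetworkParams, eff, h0, obs, noise, prev_done):
    """Unroll the network over a stored rollout segment.

    h0: (B, N) hidden state at segment start; obs: (B, T, n_in) observations
    (input noise already included); noise: (B, T, N) stored recurrent noise
    for exact replay; prev_done: (B, T) flag that the *previous* step ended
    a trial, i.e. the hidden state is reset to zero before step t.

    Returns dict with rates (B, T, N), pre-activation sign masks, logits,
    log-probabilities, values.
    """
    cfg = params.cfg
    alpha = cfg.alpha
    B, T, N = noise.shape
    W, U = eff["W_rec"], eff["W_in"]
    A, c = eff["W_out_actor"], eff["W_out_critic"]
    if _kernels.HAVE_NUMBA:
        rates, pos = _kernels.fwd_segment(
            alpha, W, U, eff["b"], np.ascontiguousarray(h0),
            np.ascontiguousarray(obs), np.ascontiguousarray(noise),
            np.ascontiguousarray(prev_done))
    else:
        rates = np.empty((B, T, N))
        pos = np.empty((B, T, N), dtype=bool)
        h = h0
        for t in range(T):
            h = np.where(prev_done[:, t, None], 0.0, h)
            pre = (1.0 - alpha) * h + alpha * (
                h @ W.T + obs[:, t] @ U.T + eff["b"] + noise[:, t]
            )
            h = np.maximum(pre, 0.0)
            rates[:, t] = h
            pos[:, t] = pre > 0.0
    logits = rates @ A.T + eff["b_actor"]
    z = logits - logits.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logprobs = z - logZ
    values = rates @ c.T[:, 0] + eff["b_critic"][0]
    return {"rates": rates, "pos": pos, "logits": logits,
            "logprobs": logprobs, "values": values}


def backward_segment(params, eff, fw, h0, obs, noise, prev_done, dlogits, dvalues):
    """Backpropagate through time; returns grads w.r.t. the free parameters.

    ``dlogits`` (B, T, A) and ``dvalues`` (B, T) are the loss gradients at
    the readouts.  The recursion mirrors the forward unroll; gradient flow
    is cut across trial boundaries (where the hidden state was reset).
    """
    cfg = params.cfg
    alpha = cfg.alpha
    rates, pos = fw["rates"], fw["pos"]
    B, T, N = rates.shape
    W, U = eff["W_rec"], eff["W_in"]
    A, c = eff["W_out_actor"], eff["W_out_critic"]

    gA = np.zeros_like(A)
    gba = np.zeros(A.shape[0])
    gc = np.zeros_like(c)
    gbc = np.zeros(1)

    if _kernels.HAVE_NUMBA:
        gW, gU, gb = _kernels.bwd_segment(
            alpha, W, U, A, c, rates, pos, np.ascontiguousarray(h0),
            np.ascontiguousarray(obs), np.ascontiguousarray(prev_done),
            np.ascontiguousarray(dlogits), np.ascontiguousarray(dvalues))
    else:
        gW = np.zeros_like(W)
        gU = np.zeros_like(U)
        gb = np.zeros(N)
        carry = np.zeros((B, N))
        for t in range(T - 1, -1, -1):
            dh = dlogits[:, t] @ A + dvalues[:, t, None] * c[0][None, :] + carry
            dpre = dh * pos[:, t]
            h_prev = rates[:, t - 1] if t > 0 else h0
            h_prev = np.where(prev_done[:, t, None], 0.0, h_prev)
            gW += alpha * dpre.T @ h_prev
            gU += alpha * dpre.T @ obs[:, t]
            gb += alpha * dpre.sum(axis=0)
            carry = (1.0 - alpha) * dpre + alpha * (dpre @ W)
            carry = np.where(prev_done[:, t, None], 0.0, carry)  # cut at reset
    # readout grads
    flat_r = rates.reshape(B * T, N)
    gA += dlogits.reshape(B * T, -1).T @ flat_r
    gba += dlogits.sum(axis=(0, 1))
    gc[0] += dvalues.reshape(-1) @ flat_r
    gbc[0] += dvalues.sum()

    # chain through the magnitude reparameterization
    dale = params.dale_sign
    grads = {
        "W_rec": gW * dale[None, :] * np.sign(params.W_rec),
        "W_in": gU * np.sign(params.W_in),
        "W_out_actor": gA * np.sign(params.W_out_actor),
        "W_out_critic": gc * np.sign(params.W_out_critic),
        "b": gb,
        "b_actor": gba,
        "b_critic": gbc,
    }
    return grads


# -- PPO loss -------------------------------------------------------------

def ppo_total_loss(logp_old, actions, returns, advantages, fw, cfg: PPOConfig):
    """Scalar loss (to minimize) and its gradients at the readouts.

    Returns (loss, dlogits, dvalues, stats).  Gradient descent on this loss
    performs gradient ascent on the PPO objective.
    """
    logprobs, values = fw["logprobs"], fw["values"]
    B, T, nA = logprobs.shape
    M = B * T
    onehot = np.eye(nA)[actions]
    logp_new = np.take_along_axis(logprobs, actions[..., None], axis=-1)[..., 0]
    ratio = np.exp(logp_new - logp_old)
    adv = advantages
    if cfg.normalize_advantage:
        # center: a lagging critic otherwise gives every step of an
        # improving policy a positive advantage, inflating the logit of
        # whichever action dominates the batch (fixation) without bound.
        # scale down (never up): amplifying a reward-sparse batch's noise
        # would drown the entropy bonus and freeze exploration.
        adv = adv - adv.mean()
        adv = adv / max(1.0, adv.std())
    unclipped = ratio * adv
    clipped = np.clip(ratio, 1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps) * adv
    surr = np.minimum(unclipped, clipped)
    # gradient flows through the unclipped branch only where it attains the min
    gate = (unclipped <= clipped).astype(float)
    probs = np.exp(logprobs)
    entropy = -(probs * logprobs).sum(axis=-1)
    v_err = values - returns
    delta = cfg.value_huber_delta
    if delta is not None:
        # Huber: quadratic within +-delta, linear outside
        v_sq = np.where(np.abs(v_err) <= delta, 0.5 * v_err ** 2,
                        delta * (np.abs(v_err) - 0.5 * delta))
        dv_err = np.clip(v_err, -delta, delta)
    else:
        v_sq = 0.5 * v_err ** 2
        dv_err = v_err

    policy_loss = -surr.mean()
    value_loss = v_sq.mean()
    entropy_mean = entropy.mean()
    loss = policy_loss + cfg.c1 * value_loss - cfg.c2 * entropy_mean

    dlogits = (-gate * adv * ratio)[..., None] * (onehot - probs) / M
    dlogits += cfg.c2 * probs * (logprobs + entropy[..., None]) / M
    dvalues = cfg.c1 * dv_err / M
    stats = {
        "loss": float(loss), "policy_loss": float(policy_loss),
        "value_loss": float(value_loss), "entropy": float(entropy_mean),
        "clip_frac": float((unclipped > clipped).mean()),
        "approx_kl": float((ratio - 1.0 - np.log(ratio)).mean()),
    }
    return loss, dlogits, dvalues, stats


# -- Adam -----------------------------------------------------------------

class Adam:
    def __init__(self, params: NetworkParams, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(params, k)) for k in params.TRAINABLE}
        self.v = {k: np.zeros_like(getattr(params, k)) for k in params.TRAINABLE}

    def step(self, params: NetworkParams, grads: dict, grad_clip: float | None,
             weight_decay: dict | None = None):
        if weight_decay:
            for k, wd in weight_decay.items():
                arr = getattr(params, k)
                arr *= 1.0 - self.lr * wd
        if grad_clip is not None:
            norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if norm > grad_clip:
                grads = {k: g * (grad_clip / norm) for k, g in grads.items()}
        self.t += 1
        for k in params.TRAINABLE:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            arr = getattr(params, k)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return params


# -- rollout collection ---------------------------------------------------

class RolloutCollector:
    """Drives n parallel environments and the network, storing everything
    needed to replay the trajectories exactly during optimization."""

    def __init__(self, params: NetworkParams, specs: list, cfg: PPOConfig,
                 rng: np.random.Generator, rho: dict | None = None,
                 offer_sampler=None, task_probs=None):
        self.params = params
        self.specs = list(specs)
        self.cfg = cfg
        self.rng = rng
        self.rho = rho
        self.offer_sampler = offer_sampler
        self.task_probs = task_probs
        ncfg = params.cfg
        self.envs = [self._new_env() for _ in range(cfg.n_envs)]
        self.last_obs = np.stack([e.reset() for e in self.envs])
        self.h = np.zeros((cfg.n_envs, ncfg.n_neurons))
        self.prev_done = np.ones(cfg.n_envs, dtype=bool)  # fresh trials
        self.total_steps = 0
        self.total_trials = 0
        # recent finished trials only; full logs come from run_trials
        self.trial_rows = deque(maxlen=20_000)
        self._recent_completed = deque(maxlen=400)

    def recent_completion(self) -> float:
        """Completion rate of the behavior policy's recent finished trials."""
        if not self._recent_completed:
            return 0.0
        return float(np.mean(self._recent_completed))

    def _new_env(self) -> ChoiceEnv:
        spec = self.specs[self.rng.choice(len(self.specs), p=self.task_probs)]
        ncfg = self.params.cfg
        return ChoiceEnv(spec, rho=self.rho, rng=self.rng,
                         sigma_in=ncfg.sigma_in, tau_ms=ncfg.tau_ms,
                         offer_sampler=self.offer_sampler if spec.name == "risky" else None)

    def collect(self):
        """Run one rollout of cfg.T steps; returns the stored batch."""
        cfg, params = self.cfg, self.params
        ncfg = params.cfg
        eff = params.effective()
        B, T, N = cfg.n_envs, cfg.T, ncfg.n_neurons
        obs = np.empty((B, T, ncfg.n_in))
        noise = np.empty((B, T, N))
        actions = np.empty((B, T), dtype=int)
        logp = np.empty((B, T))
        values = np.empty((B, T))
        rewards = np.empty((B, T))
        dones = np.empty((B, T))
        prev_done = np.empty((B, T), dtype=bool)
        h0 = self.h.copy()
        alpha = ncfg.alpha
        W, U = eff["W_rec"], eff["W_in"]
        for t in range(T):
            prev_done[:, t] = self.prev_done
            obs[:, t] = self.last_obs
            noise[:, t] = self.rng.normal(0.0, ncfg.noise_std_rec, size=(B, N))
            h = np.where(self.prev_done[:, None], 0.0, self.h)
            pre = (1 - alpha) * h + alpha * (
                h @ W.T + obs[:, t] @ U.T + eff["b"] + noise[:, t])
            self.h = np.maximum(pre, 0.0)
            logits = self.h @ eff["W_out_actor"].T + eff["b_actor"]
            z = logits - logits.max(axis=-1, keepdims=True)
            ez = np.exp(z)
            probs = ez / ez.sum(axis=-1, keepdims=True)
            values[:, t] = self.h @ eff["W_out_critic"].T[:, 0] + eff["b_critic"][0]
            if cfg.explore_eps:
                nA = probs.shape[-1]
                # the fixation cue (channel 0) carries signal 1 until the
                # response phase; baseline alone is 0.2
                go = obs[:, t, 0] < 0.7
                mixed = (1.0 - cfg.explore_eps) * probs + cfg.explore_eps / nA
                probs = np.where(go[:, None], mixed, probs)
            # vectorized categorical sampling
            cdf = probs.cumsum(axis=-1)
            u = self.rng.random((B, 1))
            a = (u > cdf).sum(axis=-1)
            actions[:, t] = a
            logp[:, t] = np.log(probs[np.arange(B), a] + 1e-12)
            for i, env in enumerate(self.envs):
                o, r, d, info = env.step(int(a[i]))
                rewards[i, t] = r
                dones[i, t] = d
                if d:
                    self.total_trials += 1
                    self.trial_rows.append(
                        trial_log_row(env.spec.name, self.total_trials, info, r))
                    self._recent_completed.append(info["completed"])
                    env2 = self._new_env()
                    self.envs[i] = env2
                    o = env2.reset()
                self.last_obs[i] = o
            self.prev_done = dones[:, t].astype(bool)
        self.total_steps += B * T
        # bootstrap value at s_T (next obs, without advancing the envs)
        hb = np.where(self.prev_done[:, None], 0.0, self.h)
        nb = self.rng.normal(0.0, ncfg.noise_std_rec, size=(B, N))
        pre = (1 - alpha) * hb + alpha * (
            hb @ W.T + self.last_obs @ U.T + eff["b"] + nb)
        hb = np.maximum(pre, 0.0)
        vboot = hb @ eff["W_out_critic"].T[:, 0] + eff["b_critic"][0]
        return {
            "h0": h0, "obs": obs, "noise": noise, "actions": actions,
            "logp_old": logp, "values": values, "rewards": rewards,
            "dones": dones, "prev_done": prev_done, "v_boot": vboot,
        }


def effective_c2(cfg: PPOConfig, env_steps: int) -> float:
    """Entropy coefficient at a given point in training (linear anneal)."""
    if cfg.c2_init is None or env_steps >= cfg.c2_anneal_steps:
        return cfg.c2
    frac = env_steps / cfg.c2_anneal_steps
    return cfg.c2_init + frac * (cfg.c2 - cfg.c2_init)


def ppo_update(params: NetworkParams, opt: Adam, batch: dict, cfg: PPOConfig,
               rng: np.random.Generator):
    """Run the PPO optimization epochs on one rollout batch."""
    if cfg.gae_lambda < 1.0:
        adv = gae_advantage(batch["rewards"], batch["dones"], batch["values"],
                            batch["v_boot"], cfg.gamma, cfg.gae_lambda)
        returns = adv + batch["values"]  # value targets
    else:
        returns = bootstrapped_return(batch["rewards"], batch["dones"],
                                      batch["v_boot"], cfg.gamma)
        adv = advantage(returns, batch["values"])
    B = cfg.n_envs
    stats = {}
    stop = False
    for _ in range(cfg.n_epochs):
        if stop:
            break
        perm = rng.permutation(B)
        for mb in np.array_split(perm, min(cfg.n_minibatches, B)):
            eff = params.effective()
            fw = forward_segment(params, eff, batch["h0"][mb], batch["obs"][mb],
                                 batch["noise"][mb], batch["prev_done"][mb])
            loss, dlogits, dvalues, stats = ppo_total_loss(
                batch["logp_old"][mb], batch["actions"][mb], returns[mb],
                adv[mb], fw, cfg)
            grads = backward_segment(params, eff, fw, batch["h0"][mb],
                                     batch["obs"][mb], batch["noise"][mb],
                                     batch["prev_done"][mb], dlogits, dvalues)
            opt.step(params, grads, cfg.grad_clip,
                     weight_decay={"W_out_actor": cfg.actor_weight_decay,
                                   "b_actor": cfg.actor_weight_decay})
            enforce_dale(params)
            if cfg.target_kl is not None and stats["approx_kl"] > cfg.target_kl:
                stop = True
                break
    return stats


# -- evaluation -----------------------------------------------------------

def run_trials(params: NetworkParams, spec: TaskSpec, n_trials: int,
               rng: np.random.Generator, rho: dict | None = None,
               fixed_epochs: bool = False, offer_sampler=None,
               record_rates: bool = False, lesion=None, n_envs: int = 50,
               greedy: bool = False):
    """Simulate complete trials with frozen weights.

    Returns ``(log_frame, rate_trials)`` where ``rate_trials`` is a list of
    (T_i, N) rate arrays per completed trial (None unless ``record_rates``).
    Actions are sampled from the policy (or argmax when ``greedy``).
    """
    from .network import apply_lesion, Lesion

    clamp = None
    if lesion is not None:
        params, clamp = apply_lesion(params, lesion)
    eff = params.effective()
    ncfg = params.cfg
    alpha = ncfg.alpha
    n_envs = min(n_envs, n_trials)
    envs = [ChoiceEnv(spec, rho=rho, rng=rng, sigma_in=ncfg.sigma_in,
                      tau_ms=ncfg.tau_ms, fixed_epochs=fixed_epochs,
                      offer_sampler=offer_sampler)
            for _ in range(n_envs)]
    obs = np.stack([e.reset() for e in envs])
    h = np.zeros((n_envs, ncfg.n_neurons))
    active = np.ones(n_envs, dtype=bool)
    rows = []
    rate_buf = [[] for _ in range(n_envs)] if record_rates else None
    rate_trials = [] if record_rates else None
    done_count = 0
    launched = n_envs
    W, U = eff["W_rec"], eff["W_in"]
    while done_count < n_trials:
        noise = rng.normal(0.0, ncfg.noise_std_rec, size=h.shape)
        pre = (1 - alpha) * h + alpha * (h @ W.T + obs @ U.T + eff["b"] + noise)
        h = np.maximum(pre, 0.0)
        if clamp is not None:
            h = np.where(clamp[None, :], 0.0, h)
        logits = h @ eff["W_out_actor"].T + eff["b_actor"]
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=-1, keepdims=True)
        if greedy:
            a = probs.argmax(axis=-1)
        else:
            cdf = probs.cumsum(axis=-1)
            a = (rng.random((len(envs), 1)) > cdf).sum(axis=-1)
        for i, env in enumerate(envs):
            if not active[i]:
                continue
            if record_rates:
                rate_buf[i].append(h[i].copy())
            o, r, d, info = env.step(int(a[i]))
            if d:
                done_count += 1
                rows.append(trial_log_row(spec.name, done_count, info, r))
                if record_rates:
                    rate_trials.append((np.array(rate_buf[i]), info))
                    rate_buf[i] = []
                if launched < n_trials:
                    launched += 1
                    o = env.reset()
                    h[i] = 0.0
                else:
                    active[i] = False
            obs[i] = o
        if not active.any():
            break
    frame = pd.DataFrame(rows)
    return frame, rate_trials


def evaluate_criteria(frame: pd.DataFrame):
    """(completion rate, accuracy on completed trials) from a trial log."""
    if len(frame) == 0:
        return 0.0, 0.0
    completion = float(frame["completed"].mean())
    comp = frame[frame["completed"]]
    accuracy = float(comp["correct"].mean()) if len(comp) else 0.0
    return completion, accuracy


def evaluate(params: NetworkParams, specs: list, n_trials_per_task: int,
             seed: int, rho: dict | None = None, offer_sampler=None):
    """Held-out evaluation on a seeded test set; no weight updates.

    Returns a per-task dict of (completion, accuracy) plus the pooled pair.
    """
    per_task = {}
    frames = []
    for k, spec in enumerate(specs):
        rng = np.random.default_rng((seed, k))
        frame, _ = run_trials(
            params, spec, n_trials_per_task, rng, rho=rho,
            offer_sampler=offer_sampler if spec.name == "risky" else None)
        per_task[spec.name] = evaluate_criteria(frame)
        frames.append(frame)
    pooled = pd.concat(frames, ignore_index=True)
    return per_task, evaluate_criteria(pooled), pooled


# -- training loops -------------------------------------------------------

def train(params: NetworkParams, specs: list, cfg: PPOConfig,
          rng: np.random.Generator, rho: dict | None = None,
          offer_sampler=None, eval_seed: int = 10_000,
          verbose: bool = False, callback=None):
    """PPO training until both performance criteria hold or budget runs out.

    Criteria: completion >= cfg.completion_criterion on a seeded held-out
    set and accuracy >= cfg.accuracy_criterion on its completed trials.
    Returns ``(params, history)``; history rows carry per-task completion
    and accuracy, cumulative steps/trials and ``criteria_met``.
    """
    collector = RolloutCollector(params, specs, cfg, rng, rho=rho,
                                 offer_sampler=offer_sampler)
    opt = Adam(params, cfg.lr)
    history = []
    next_eval = cfg.eval_every_steps
    criteria_met = False
    relaxed = False
    while collector.total_steps < cfg.max_env_steps:
        batch = collector.collect()
        rc = collector.recent_completion()
        if relaxed and rc < cfg.wd_restore_completion:
            relaxed = False
        elif not relaxed and rc >= cfg.wd_relax_completion:
            relaxed = True
        wd = cfg.actor_weight_decay_trained if relaxed else cfg.actor_weight_decay
        step_cfg = replace(cfg, c2=effective_c2(cfg, collector.total_steps),
                           actor_weight_decay=wd)
        stats = ppo_update(params, opt, batch, step_cfg, rng)
        if collector.total_steps >= next_eval:
            next_eval += cfg.eval_every_steps
            per_task, (comp, acc), _ = evaluate(
                params, specs, cfg.eval_trials_per_task, eval_seed,
                rho=rho, offer_sampler=offer_sampler)
            criteria_met = (comp >= cfg.completion_criterion
                            and acc >= cfg.accuracy_criterion)
            stop_now = (comp >= cfg.completion_criterion + cfg.stop_margin_completion
                        and acc >= cfg.accuracy_criterion + cfg.stop_margin_accuracy)
            row = {
                "env_steps": collector.total_steps,
                "trials": collector.total_trials,
                "completion": comp, "accuracy": acc,
                "criteria_met": criteria_met, **stats,
            }
            for name, (c, a) in per_task.items():
                row[f"completion_{name}"] = c
                row[f"accuracy_{name}"] = a
            history.append(row)
            if verbose:
                print(f"steps={collector.total_steps} trials={collector.total_trials} "
                      f"completion={comp:.3f} accuracy={acc:.3f}")
            if callback is not None:
                callback(row)
            if stop_now:
                break
    report = pd.DataFrame(history)
    report.attrs["criteria_met"] = criteria_met
    report.attrs["total_trials"] = collector.total_trials
    report.attrs["total_steps"] = collector.total_steps
    return params, report


def curriculum_train(params: NetworkParams, target: TaskSpec, curriculum: list,
                     cfg: PPOConfig, rng: np.random.Generator,
                     rho: dict | None = None, **kw):
    """Train through ``curriculum`` stages, then the target task.

    Each stage is trained to criterion before advancing.  Returns
    ``(params, trials_final_stage, reports)`` where the trial count covers
    only the final (target) stage.
    """
    reports = []
    for stage in curriculum:
        params, rep = train(params, [stage], cfg, rng, rho=rho, **kw)
        reports.append(rep)
        if not rep.attrs.get("criteria_met", False):
            raise RuntimeError(f"curriculum stage {stage.name} did not reach criterion")
    params, rep = train(params, [target], cfg, rng, rho=rho, **kw)
    reports.append(rep)
    return params, rep.attrs["total_trials"], reports


def normalize_trial_counts(counts_by_condition: dict) -> dict:
    """Normalize per-network trial counts by the maximum across conditions."""
    mx = max(max(v) for v in counts_by_condition.values())
    return {k: [c / mx for c in v] for k, v in counts_by_condition.items()}


def zero_shot_eval(params: NetworkParams, specs: list, n_trials: int,
                   seed: int, rho: dict | None = None) -> pd.DataFrame:
    """Evaluate a trained network on every task without weight updates."""
    rows = []
    per_task, _, _ = evaluate(params, specs, n_trials, seed, rho=rho)
    for name, (comp, acc) in per_task.items():
        rows.append({"target": name, "completion": comp, "accuracy": acc})
    return pd.DataFrame(rows)
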