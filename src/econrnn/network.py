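"""Continuous-time excitatory-inhibitory rate network with actor-critic readouts.

The firing-rate vector r(t) of N neurons (80% excitatory, 20% inhibitory)
evolves under

    tau dr/dt = -r + W_rec r + W_in u + b + sqrt(2 tau) sigma_rec xi(t),

rectified to non-negative rates, integrated by the Euler method with
dt = 20 ms (alpha = dt/tau = 0.2).  Dale's law is enforced by a magnitude
reparameterization: free parameters are stored unsigned and the effective
recurrent weight is |w| times the presynaptic sign (+1 excitatory,
-1 inhibitory); the long-range input and output matrices are constrained
non-negative the same way.  Two linear readouts share the population: a
softmax policy over four actions (the actor) and a scalar value estimate
(the critic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np


@dataclass(frozen=True)
class NetworkConfig:
    n_neurons: int = 256
    frac_exc: float = 0.8
    tau_ms: float = 100.0
    dt_ms: float = 20.0
    sigma_rec: float = 0.15
    sigma_in: float = 0.01
    n_in: int = 16
    n_actions: int = 4
    spectral_radius: float = 1.5

    def __post_init__(self):
        if not 0 < self.dt_ms <= self.tau_ms:
            raise ValueError("require 0 < dt <= tau")
        if not 0 < self.frac_exc < 1:
            raise ValueError("frac_exc must be in (0, 1)")

    @property
    def alpha(self) -> float:
        return self.dt_ms / self.tau_ms

    @property
    def n_exc(self) -> int:
        return round(self.frac_exc * self.n_neurons)

    @property
    def noise_std_rec(self) -> float:
        """Per-step std of the discretized recurrent noise (inside the bracket)."""
        return self.sigma_rec * np.sqrt(2.0 / self.alpha)


@dataclass
class NetworkParams:
    """Free (unsigned) parameters plus the fixed Dale sign vector.

    ``W_rec`` etc. hold the free magnitudes; use :meth:`effective` to obtain
    the signed weight matrices that enter the dynamics.
    """

    cfg: NetworkConfig
    W_rec: np.ndarray        # (N, N) free magnitudes
    W_in: np.ndarray         # (N, n_in)
    W_out_actor: np.ndarray  # (n_actions, N)
    W_out_critic: np.ndarray  # (1, N)
    b: np.ndarray            # (N,)
    b_actor: np.ndarray      # (n_actions,)
    b_critic: np.ndarray     # (1,)
    dale_sign: np.ndarray    # (N,), +1 excitatory, -1 inhibitory

    TRAINABLE = ("W_rec", "W_in", "W_out_actor", "W_out_critic",
                 "b", "b_actor", "b_critic")

    def effective(self) -> dict:
        """Signed weights obeying Dale's law and non-negative projections."""
        return {
            "W_rec": np.abs(self.W_rec) * self.dale_sign[None, :],
            "W_in": np.abs(self.W_in),
            "W_out_actor": np.abs(self.W_out_actor),
            "W_out_critic": np.abs(self.W_out_critic),
            "b": self.b,
            "b_actor": self.b_actor,
            "b_critic": self.b_critic,
        }

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.cfg, *(getattr(self, k).copy() for k in self.TRAINABLE),
            self.dale_sign.copy(),
        )


def init_params(cfg: NetworkConfig, rng: np.random.Generator) -> NetworkParams:
    """Initialize parameters.

    Recurrent magnitudes are Gamma(shape=4, scale=4) rescaled so the
    spectral radius of the (pre-sign) matrix is ``cfg.spectral_radius``;
    the Dale sign mask is applied afterwards through the reparameterization.
    Input weights are U(0, 1/n_in); both readouts U(0, 0.4/N); biases zero.
    """
    N = cfg.n_neurons
    W = rng.gamma(shape=4.0, scale=4.0, size=(N, N))
    radius = np.max(np.abs(np.linalg.eigvals(W)))
    W *= cfg.spectral_radius / radius
    dale = np.ones(N)
    dale[cfg.n_exc:] = -1.0
    return NetworkParams(
        cfg=cfg,
        W_rec=W,
        W_in=rng.uniform(0.0, 1.0 / cfg.n_in, size=(N, cfg.n_in)),
        W_out_actor=rng.uniform(0.0, 0.4 / N, size=(cfg.n_actions, N)),
        W_out_critic=rng.uniform(0.0, 0.4 / N, size=(1, N)),
        b=np.zeros(N),
        b_actor=np.zeros(cfg.n_actions),
        b_critic=np.zeros(1),
        dale_sign=dale,
    )


def spectral_radius(W: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(W))))


def step_dynamics(
    params: NetworkParams,
    rates: np.ndarray,
    obs: np.ndarray,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    eff: dict | None = None,
    clamp_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler step of the rate dynamics.

    r <- [(1 - alpha) r + alpha (W_rec r + W_in u + b + noise)]_+

    ``rates``/``obs`` may be batched (leading batch dimension).  ``noise``
    (per-step Gaussian with std sigma_rec*sqrt(2/alpha)) can be passed
    explicitly for replay; otherwise it is drawn from ``rng`` (or omitted
    when both are None).  ``clamp_mask`` forces the listed neurons to zero
    rate (lesion clamp).
    """
    cfg = params.cfg
    e = eff if eff is not None else params.effective()
    alpha = cfg.alpha
    drive = rates @ e["W_rec"].T + obs @ e["W_in"].T + e["b"]
    if noise is None and rng is not None:
        noise = rng.normal(0.0, cfg.noise_std_rec, size=rates.shape)
    if noise is not None:
        drive = drive + noise
    new = (1.0 - alpha) * rates + alpha * drive
    new = np.maximum(new, 0.0)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("network rates diverged (non-finite values)")
    if clamp_mask is not None:
        new = np.where(clamp_mask, 0.0, new)
    return new


def readout(params: NetworkParams, rates: np.ndarray, eff: dict | None = None):
    """Actor softmax probabilities and critic value from the current rates."""
    e = eff if eff is not None else params.effective()
    logits = rates @ e["W_out_actor"].T + e["b_actor"]
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    value = rates @ e["W_out_critic"].T + e["b_critic"]
    return probs, value[..., 0]


def enforce_dale(params: NetworkParams) -> NetworkParams:
    """Project free parameters onto the constraint set (idempotent).

    Under the magnitude reparameterization the stored free weights are made
    non-negative in place; the effective weights are unchanged by this
    projection, so it is a pure canonicalization.
    """
    params.W_rec = np.abs(params.W_rec)
    params.W_in = np.abs(params.W_in)
    params.W_out_actor = np.abs(params.W_out_actor)
    params.W_out_critic = np.abs(params.W_out_critic)
    return params


@dataclass(frozen=True)
class Lesion:
    """Lesion specification: remove recurrence and/or clamp neurons to zero."""

    recurrent_removal: bool = False
    clamp_neurons: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "clamp_neurons", tuple(self.clamp_neurons))


def apply_lesion(params: NetworkParams, lesion: Lesion):
    """Return ``(lesioned_params, clamp_mask)`` leaving the originals intact.

    ``recurrent_removal`` zeroes W_rec (isolating the feedforward pathway);
    ``clamp_neurons`` lists neurons whose rates are forced to zero at every
    step of the simulation.
    """
    lp = params.copy()
    if lesion.recurrent_removal:
        lp.W_rec = np.zeros_like(lp.W_rec)
    mask = None
    if lesion.clamp_neurons:
        idx = np.asarray(lesion.clamp_neurons, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= params.cfg.n_neurons):
            raise IndexError("clamp neuron index out of range")
        mask = np.zeros(params.cfg.n_neurons, dtype=bool)
        mask[idx] = True
    return lp, mask


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path, params: NetworkParams, extra: dict | None = None):
    cfg = params.cfg
    with h5py.File(path, "w") as f:
        for k in params.TRAINABLE:
            f.create_dataset(k, data=getattr(params, k))
        f.create_dataset("dale_sign", data=params.dale_sign)
        for k, v in vars(cfg).items():
            f.attrs[k] = v
        if extra:
            for k, v in extra.items():
                f.attrs[f"extra_{k}"] = v


def load_checkpoint(path) -> NetworkParams:
    with h5py.File(path, "r") as f:
        cfg = NetworkConfig(
            n_neurons=int(f.attrs["n_neurons"]), frac_exc=float(f.attrs["frac_exc"]),
            tau_ms=float(f.attrs["tau_ms"]), dt_ms=float(f.attrs["dt_ms"]),
            sigma_rec=float(f.attrs["sigma_rec"]), sigma_in=float(f.attrs["sigma_in"]),
            n_in=int(f.attrs["n_in"]), n_actions=int(f.attrs["n_actions"]),
            spectral_radius=float(f.attrs["spectral_radius"]),
        )
        arrays = {k: f[k][()] for k in NetworkParams.TRAINABLE}
        dale = f["dale_sign"][()]
    return NetworkParams(cfg=cfg, dale_sign=dale, **arrays)
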