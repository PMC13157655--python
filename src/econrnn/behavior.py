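"""Logistic and multinomial choice models with MLE fitting.

Choices are modeled through powered offer values V_X = rho_X q_X p_X^gamma:
for binary tasks P(choose slot 1) is a logistic function of
eta * ln(V_1 / V_2) (plus an order-bias term eta*eps'*Order in the
sequential task, Order = +1 when good C was presented second), and the
ternary task uses a softmax over V_X^eta.  Free parameters are the relative
values rho_X (rho_E = 1 is the reference), the risk attitude gamma (fit
only for probabilistic tasks; gamma > 1 is risk averse), the choice
consistency eta > 0 and the sequential order bias eps'.

Fitting maximizes the log-likelihood with L-BFGS on log-transformed
positive parameters, from several starting points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

ETA_CAP = 1e3  # consistency cap flagging perfectly separable data

#: free rho parameters per task (rho_E == 1 always)
TASK_RHO_PARAMS = {
    "standard": ("C",),
    "risky": ("C",),
    "bundles": ("B", "C", "D"),
    "ternary": ("A", "C"),
    "sequential": ("C",),
}
PROBABILISTIC = {"risky", "bundles", "ternary", "sequential"}


@dataclass
class BehavioralFit:
    task: str
    rho_hat: dict                 # per non-reference good; rho_E fixed at 1
    gamma_hat: float
    eta_hat: float
    eps_hat: float                # sequential order bias (0 otherwise)
    log_likelihood: float
    n_trials: int
    separable: bool = False       # eta hit its cap
    converged: bool = True

    def params_vector(self):
        return {**{f"rho_{g}": v for g, v in self.rho_hat.items()},
                "gamma": self.gamma_hat, "eta": self.eta_hat, "eps": self.eps_hat}


def _powered_values(frame: pd.DataFrame, task: str, rho: dict, gamma: float):
    """Per-slot powered value V = sum_goods rho_g q p^gamma, shape (n, n_slots)."""
    n_slots = 3 if task == "ternary" else 2
    V = np.zeros((len(frame), n_slots))
    for si in range(n_slots):
        for col in frame.columns:
            if col.startswith(f"slot{si}_") and col.endswith("_q"):
                g = col.split("_")[1]
                q = frame[col].to_numpy(float)
                p = frame[f"slot{si}_{g}_p"].to_numpy(float)
                r = 1.0 if g == "E" else rho.get(g, 1.0)
                V[:, si] += r * q * np.power(p, gamma)
    return V


def choice_probability(frame: pd.DataFrame, task: str, rho: dict,
                       gamma: float, eta: float, eps: float = 0.0) -> np.ndarray:
    """Model probability of choosing slot 0 (binary) or each slot (ternary).

    ``frame`` is a trial log with slot{i}_{good}_{q,p} columns (and
    ``order`` for the sequential task).
    """
    V = _powered_values(frame, task, rho, gamma)
    if task == "ternary":
        logw = eta * np.log(np.maximum(V, 1e-300))
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        return w / w.sum(axis=1, keepdims=True)
    z = eta * np.log(np.maximum(V[:, 0], 1e-300) / np.maximum(V[:, 1], 1e-300))
    if task == "sequential":
        order = frame["order"].to_numpy(float)
        z = z + eta * eps * order
    return 1.0 / (1.0 + np.exp(-z))


def log_likelihood(frame: pd.DataFrame, task: str, rho: dict, gamma: float,
                   eta: float, eps: float = 0.0) -> float:
    choice = frame["choice"].to_numpy(int)
    P = choice_probability(frame, task, rho, gamma, eta, eps)
    if task == "ternary":
        p = P[np.arange(len(frame)), choice]
    else:
        p = np.where(choice == 0, P, 1.0 - P)
    return float(np.log(np.clip(p, 1e-300, None)).sum())


def fit_behavior(frame: pd.DataFrame, task: str, n_starts: int = 5,
                 seed: int = 0) -> BehavioralFit:
    """Maximum-likelihood fit of the task's choice model.

    Only completed trials enter the likelihood.  gamma is fixed at 1 for
    the deterministic standard task.  Positive parameters (rho, gamma, eta)
    are log-transformed; eta is capped at 1e3 and the fit flagged separable
    when the cap binds.
    """
    data = frame[frame["completed"]].reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no completed trials to fit")
    rho_names = TASK_RHO_PARAMS[task]
    fit_gamma = task in PROBABILISTIC
    fit_eps = task == "sequential"

    def unpack(x):
        # box the log-parameters: rho in [e^-5, e^5], gamma in [e^-2, e^2],
        # eta in (0, ETA_CAP]; keeps separable/value-blind data from
        # running the optimizer to infinity
        i = len(rho_names)
        rho = {g: np.exp(np.clip(x[j], -5, 5)) for j, g in enumerate(rho_names)}
        gamma = np.exp(np.clip(x[i], -2, 2)) if fit_gamma else 1.0
        i += fit_gamma
        eta = np.exp(np.clip(x[i], -12, np.log(ETA_CAP)))
        i += 1
        eps = np.clip(x[i], -20, 20) if fit_eps else 0.0
        return rho, gamma, eta, eps

    def nll(x):
        rho, gamma, eta, eps = unpack(x)
        if eta > ETA_CAP:
            eta = ETA_CAP
        return -log_likelihood(data, task, rho, gamma, eta, eps)

    rng = np.random.default_rng(seed)
    ndim = len(rho_names) + int(fit_gamma) + 1 + int(fit_eps)
    best = None
    for s in range(n_starts):
        x0 = np.zeros(ndim)
        if s > 0:
            x0 = rng.normal(0.0, 0.5, size=ndim)
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    rho, gamma, eta, eps = unpack(best.x)
    separable = eta >= ETA_CAP
    eta = min(eta, ETA_CAP)
    return BehavioralFit(
        task=task, rho_hat=rho, gamma_hat=gamma, eta_hat=eta, eps_hat=eps,
        log_likelihood=-best.fun, n_trials=len(data),
        separable=separable, converged=bool(best.success or best.fun < np.inf),
    )


def fit_standard_errors(fit: BehavioralFit, frame: pd.DataFrame) -> dict:
    """Asymptotic standard errors from the observed information matrix.

    The Hessian of the negative log-likelihood at the MLE is computed by
    central finite differences in the natural (untransformed) parameter
    space; its inverse diagonal gives the squared standard errors.
    """
    data = frame[frame["completed"]].reset_index(drop=True)
    names = list(fit.rho_hat) + (["gamma"] if fit.task in PROBABILISTIC else []) \
        + ["eta"] + (["eps"] if fit.task == "sequential" else [])

    def nll_at(vec):
        rho = {g: vec[i] for i, g in enumerate(fit.rho_hat)}
        i = len(fit.rho_hat)
        gamma = vec[i] if fit.task in PROBABILISTIC else 1.0
        i += fit.task in PROBABILISTIC
        eta = vec[i]
        i += 1
        eps = vec[i] if fit.task == "sequential" else 0.0
        return -log_likelihood(data, fit.task, rho, gamma, eta, eps)

    x0 = np.array(list(fit.rho_hat.values())
                  + ([fit.gamma_hat] if fit.task in PROBABILISTIC else [])
                  + [fit.eta_hat]
                  + ([fit.eps_hat] if fit.task == "sequential" else []))
    n = len(x0)
    H = np.zeros((n, n))
    h = np.maximum(1e-4, 1e-4 * np.abs(x0))
    f0 = nll_at(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (nll_at(xpp) - nll_at(xpm) - nll_at(xmp)
                                 + nll_at(xmm)) / (4 * h[i] * h[j])
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return dict(zip(names, se))


def simulate_choices(task: str, frame: pd.DataFrame, rho: dict, gamma: float,
                     eta: float, eps: float, rng: np.random.Generator) -> pd.DataFrame:
    """Draw choices from the model itself (generator for recovery tests)."""
    out = frame.copy()
    P = choice_probability(frame, task, rho, gamma, eta, eps)
    if task == "ternary":
        cdf = P.cumsum(axis=1)
        out["choice"] = (rng.random((len(frame), 1)) > cdf).sum(axis=1)
    else:
        out["choice"] = np.where(rng.random(len(frame)) < P, 0, 1)
    out["completed"] = True
    return out


def compare_fits(train_fit: BehavioralFit, test_fit: BehavioralFit,
                 train_accuracy: float | None = None,
                 test_accuracy: float | None = None) -> pd.DataFrame:
    """Paired train/test table of the key behavioral parameters."""
    if train_fit.task != test_fit.task:
        raise ValueError("fits come from different tasks")
    rows = []
    for name in sorted(set(train_fit.rho_hat) | set(test_fit.rho_hat)):
        rows.append({"parameter": f"rho_{name}",
                     "train": train_fit.rho_hat.get(name),
                     "test": test_fit.rho_hat.get(name)})
    rows.append({"parameter": "gamma", "train": train_fit.gamma_hat,
                 "test": test_fit.gamma_hat})
    rows.append({"parameter": "eta", "train": train_fit.eta_hat,
                 "test": test_fit.eta_hat})
    if train_accuracy is not None:
        rows.append({"parameter": "accuracy", "train": train_accuracy,
                     "test": test_accuracy})
    return pd.DataFrame(rows)
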