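"""Connectivity-level analyses and causal circuit experiments.

Covers the input-weight structure of trained networks (feature-correlation
matrix, per-neuron selectivity index), the value-weight cohort experiment,
the reduced pool-by-pool connectivity matrix and competitive-recurrent-
inhibition (CRI) score, the SVD spectrum of the recurrent matrix, lesion
batteries (recurrent removal, negatively tuned neurons, functional pools,
task clusters), output-dynamics regressions, the feedforward
multiplicative-vs-additive test on lesioned networks, and a toy
feedforward model showing how ReLU ramps approximate multiplication and
how mixed-selective wiring rotates the value representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from . import taskenv
from .network import Lesion, NetworkParams
from .taskenv import CH_PROB, CH_QUANT, GOOD_ORDER


# -- input weights --------------------------------------------------------

def selectivity_index(w_qC: np.ndarray, w_qE: np.ndarray) -> np.ndarray:
    """SI = (w_qC - w_qE) / (w_qC + w_qE) in [-1, 1]; zero-sum entries NaN.

    +1 marks a neuron exclusively driven by good C's quantity input, -1 by
    good E's, 0 balanced input from both.
    """
    w_qC = np.asarray(w_qC, float)
    w_qE = np.asarray(w_qE, float)
    denom = w_qC + w_qE
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.where(denom > 0, (w_qC - w_qE) / denom, np.nan)
    return si


def network_si(params: NetworkParams) -> np.ndarray:
    W = params.effective()["W_in"]
    return selectivity_index(W[:, CH_QUANT["C"]], W[:, CH_QUANT["E"]])


def input_weight_structure(params: NetworkParams,
                           goods=("C", "E")) -> pd.DataFrame:
    """Pearson correlations between input-weight columns of offer features."""
    W = params.effective()["W_in"]
    cols = {}
    for g in goods:
        cols[f"q_{g}"] = W[:, CH_QUANT[g]]
        cols[f"p_{g}"] = W[:, CH_PROB[g]]
    names = list(cols)
    M = pd.DataFrame(np.corrcoef(np.stack([cols[n] for n in names])),
                     index=names, columns=names)
    return M


def rule_weight_correlations(params_list) -> pd.DataFrame:
    """Rule-cue input-weight correlation matrix, averaged across networks."""
    mats = []
    for params in params_list:
        W = params.effective()["W_in"]
        vecs = np.stack([W[:, taskenv.CH_RULE[t]] for t in taskenv.TASK_NAMES])
        mats.append(np.corrcoef(vecs))
    return pd.DataFrame(np.mean(mats, axis=0), index=taskenv.TASK_NAMES,
                        columns=taskenv.TASK_NAMES)


def mean_nonzero_qc_weight(params: NetworkParams, zero_tol: float = 1e-12,
                           exc_only: bool = True) -> float:
    """Mean of the non-zero (excitatory) input weights for good C's quantity."""
    w = params.effective()["W_in"][:, CH_QUANT["C"]]
    if exc_only:
        w = w[params.dale_sign > 0]
    nz = w[w > zero_tol]
    return float(nz.mean()) if nz.size else 0.0


def value_weight_regression(pairs: list):
    """Linear regression of mean q_C input weight on inferred rho_C.

    ``pairs`` is a list of (rho_hat_C, mean_weight) per network.  Returns
    (slope, intercept, R2, p).
    """
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), float(res.pvalue)


# -- recurrent connectivity -----------------------------------------------

@dataclass(frozen=True)
class FunctionalPoolLabel:
    cell_type: str    # "E" or "I"
    selectivity: str  # e.g. "OVC", "CV", "CHC", "CHE", "none"

    def __str__(self):
        return f"{self.selectivity}_{self.cell_type}"


def assign_pools(params: NetworkParams, profile, window: slice) -> list:
    """Classify each neuron into a functional pool for one task.

    Uses the selectivity labels at the time of peak population selectivity
    within ``window`` (offer period).  Choice-selective neurons are split
    by preferred option via the sign of the CH slope (CHC: prefers slot 0).
    """
    lab = profile.labels[window]
    t_rel = int(np.argmax((lab >= 0).sum(axis=1)))
    labels_at = lab[t_rel]
    ch_slope = profile.slope["CH"][window][t_rel]
    out = []
    for j in range(labels_at.shape[0]):
        cell = "E" if params.dale_sign[j] > 0 else "I"
        li = labels_at[j]
        if li < 0:
            sel = "none"
        else:
            sel = profile.variables[li]
            if sel == "CH":
                sel = "CHC" if ch_slope[j] > 0 else "CHE"
        out.append(FunctionalPoolLabel(cell, sel))
    return out


def reduced_connectivity(params: NetworkParams, pools: list,
                         pool_order=None) -> pd.DataFrame:
    """Mean synaptic weight between every pair of functional pools.

    Entry (row=post, col=pre) is the mean effective weight over all
    (post, pre) neuron pairs; empty pools give NaN rows/columns.
    """
    W = params.effective()["W_rec"]
    names = [str(p) for p in pools]
    if pool_order is None:
        pool_order = sorted(set(names))
    M = pd.DataFrame(np.nan, index=pool_order, columns=pool_order)
    idx = {p: [i for i, n in enumerate(names) if n == p] for p in pool_order}
    for post in pool_order:
        for pre in pool_order:
            if idx[post] and idx[pre]:
                M.loc[post, pre] = float(W[np.ix_(idx[post], idx[pre])].mean())
    return M


def cri_score(reduced: pd.DataFrame) -> float:
    """Competitive-recurrent-inhibition score.

    Mean magnitude of cross-choice I->E weights (CHC_I -> CHE_E and
    CHE_I -> CHC_E) minus same-choice I->E magnitude; positive values mean
    inhibition preferentially targets the competing choice's excitatory
    pool.
    """
    pairs_cross = [("CHE_E", "CHC_I"), ("CHC_E", "CHE_I")]
    pairs_same = [("CHC_E", "CHC_I"), ("CHE_E", "CHE_I")]

    def mean_mag(pairs):
        vals = [abs(reduced.loc[post, pre]) for post, pre in pairs
                if post in reduced.index and pre in reduced.columns
                and np.isfinite(reduced.loc[post, pre])]
        return np.mean(vals) if vals else np.nan

    return float(mean_mag(pairs_cross) - mean_mag(pairs_same))


def svd_spectrum(W_rec: np.ndarray):
    """Singular values (decreasing) and their participation-ratio rank."""
    sv = np.linalg.svd(W_rec, compute_uv=False)
    lam = sv ** 2
    eff_rank = float(lam.sum() ** 2 / (lam ** 2).sum())
    return sv, eff_rank


# -- lesions --------------------------------------------------------------

def negatively_tuned_neurons(profile, window: slice,
                             variables=("OVC", "OVE", "CV")) -> np.ndarray:
    """Neurons with significant negative slope for OV or CV in the offer
    period (per-bin significance pooled by majority vote over the window)."""
    hits = []
    for v in variables:
        sl = profile.slope[v][window]
        p = profile.p[v][window]
        neg = (sl < 0) & (p < 0.05)
        hits.append(neg.mean(axis=0) > 0.5)
    return np.where(np.any(hits, axis=0))[0]


def lesion_battery(params: NetworkParams, specs: list, targets: dict,
                   n_trials: int, seed: int, rho=None) -> pd.DataFrame:
    """Paired intact-vs-lesion evaluation over tasks.

    ``targets`` maps a lesion name to a Lesion spec.  Each lesion is
    evaluated on the same seeded trial stream as the intact control;
    reported values are percentage changes in completion and accuracy.
    """
    from .ppo import evaluate_criteria, run_trials
    from .utils import derive_rng

    rows = []
    for spec in specs:
        base_frame, _ = run_trials(params, spec, n_trials,
                                   derive_rng(seed, spec.name, "base"), rho=rho)
        c0, a0 = evaluate_criteria(base_frame)
        for name, lesion in targets.items():
            frame, _ = run_trials(params, spec, n_trials,
                                  derive_rng(seed, spec.name, "base"),
                                  rho=rho, lesion=lesion)
            c1, a1 = evaluate_criteria(frame)
            rows.append({
                "task": spec.name, "lesion": name,
                "completion_intact": c0, "completion_lesion": c1,
                "accuracy_intact": a0, "accuracy_lesion": a1,
                "completion_change_pct": 100.0 * (c1 - c0) / c0 if c0 else np.nan,
                "accuracy_change_pct": 100.0 * (a1 - a0) / a0 if a0 else np.nan,
                "n_clamped": len(lesion.clamp_neurons),
            })
    return pd.DataFrame(rows)


# -- output dynamics ------------------------------------------------------

def output_dynamics_regression(outputs: np.ndarray, variables: pd.DataFrame,
                               node_names=None) -> pd.DataFrame:
    """R2 heatmap of each output node against each decision variable.

    ``outputs`` is (trials, nodes): one summary activity per trial per
    output node (e.g. mean over the last 200 ms of the offer period).
    Winner-take-all coding appears as a choice output predicted by its own
    conjunctive chosen-value variable but not the competitor's.
    """
    n_nodes = outputs.shape[1]
    if node_names is None:
        node_names = [f"node{i}" for i in range(n_nodes)]
    rows = []
    for i, name in enumerate(node_names):
        y = outputs[:, i]
        row = {"node": name}
        for var in variables.columns:
            x = variables[var].to_numpy(float)
            if np.var(x) == 0 or np.var(y) == 0:
                row[var] = 0.0
            else:
                row[var] = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")


def collect_output_activity(params: NetworkParams, spec, n_trials, rng,
                            rho=None, last_ms: float = 200.0):
    """Per-trial actor probabilities and critic value averaged over the
    last ``last_ms`` of the offer period; returns (outputs, trial frame)."""
    from .network import readout
    from .ppo import run_trials

    frame, rate_trials = run_trials(params, spec, n_trials, rng, rho=rho,
                                    fixed_epochs=True, record_rates=True)
    steps = int(round(last_ms / taskenv.DT_MS))
    offer_end = 3 * 50  # fixed 1000 ms epochs
    outs, keep = [], []
    for i, (rates, info) in enumerate(rate_trials):
        if not info["completed"] or rates.shape[0] < offer_end:
            continue
        w = rates[offer_end - steps:offer_end]
        probs, value = readout(params, w)
        outs.append(np.concatenate([probs.mean(axis=0), [value.mean()]]))
        keep.append(i)
    completed = frame[frame["completed"]].reset_index(drop=True)
    return np.array(outs), completed


# -- toy feedforward model ------------------------------------------------

@dataclass
class ToyModelConfig:
    n_units: int = 200
    alpha: float | np.ndarray = 1.0   # input gain(s), shared or per unit
    beta: float | np.ndarray = 1.0    # bias scale(s)
    e_qp: float = 0.25                # E[q*p] over the offer distribution


def toy_activity(cfg: ToyModelConfig, q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """ReLU ramp units r_i = [alpha_i (q + p) - beta_i E[qp]]_+ over offers.

    Returns (n_offers, n_units).  With alpha_i, beta_i varying across the
    population the ramps tile the (q, p) plane and a linear readout can
    approximate the product q*p.
    """
    alpha = np.broadcast_to(np.asarray(cfg.alpha, float), (cfg.n_units,))
    beta = np.broadcast_to(np.asarray(cfg.beta, float), (cfg.n_units,))
    drive = alpha[None, :] * (q[:, None] + p[:, None]) - beta[None, :] * cfg.e_qp
    return np.maximum(drive, 0.0)


def _r2_of_fit(X: np.ndarray, y: np.ndarray) -> float:
    """R2 of the least-squares linear fit y ~ X (with intercept)."""
    A = np.column_stack([X, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid ** 2).sum() / ss) if ss > 0 else 0.0


def toy_mult_vs_add(cfg: ToyModelConfig, n_grid: int = 21) -> dict:
    """Multiplicative vs additive account of the toy population's top PCs.

    Over a (q, p) in [0,1]^2 grid, computes PCA of the population activity
    and the R2 of PC1 regressed on the product q*p versus the sum q+p.
    """
    g = np.linspace(0.0, 1.0, n_grid)
    qq, pp = np.meshgrid(g, g)
    q, p = qq.ravel(), pp.ravel()
    act = toy_activity(cfg, q, p)
    if act.std() == 0:
        return {"r2_mult": 0.0, "r2_add": 0.0, "advantage": 0.0}
    pc1 = PCA(n_components=1).fit_transform(act - act.mean(axis=0))[:, 0]
    r2_mult = _r2_of_fit((q * p)[:, None], pc1)
    r2_add = _r2_of_fit((q + p)[:, None], pc1)
    return {"r2_mult": r2_mult, "r2_add": r2_add, "advantage": r2_mult - r2_add}


def toy_parameter_sweep(alphas=None, betas=None, n_units: int = 200,
                        e_qp: float = 0.25) -> pd.DataFrame:
    """Sweep shared (alpha, beta); returns tidy frame with the R2 advantage."""
    if alphas is None:
        alphas = np.logspace(-2, 1, 25)
    if betas is None:
        betas = np.logspace(-2, 1, 25)
    rows = []
    for a in alphas:
        for b in betas:
            res = toy_mult_vs_add(ToyModelConfig(n_units=n_units, alpha=a,
                                                 beta=b, e_qp=e_qp))
            rows.append({"alpha": a, "beta": b, **res})
    return pd.DataFrame(rows)


def toy_geometry(variant: str, rng: np.random.Generator, n_units: int = 100,
                 n_offers: int = 2000) -> pd.DataFrame:
    """PCA geometry of segregated vs mixed-selective toy populations.

    Two populations each encode one offer's value (OVC, OVE) through
    diverse ReLU ramps of that offer's (q, p); the mixed variant adds a
    third population receiving the summed inputs of both offers.  Returns
    the R2 of PC1/PC2 projections against OVC, OVE, their sum and
    difference.
    """
    if variant not in ("segregated", "mixed"):
        raise ValueError(variant)
    qC = rng.uniform(0, 1, n_offers)
    pC = rng.uniform(0, 1, n_offers)
    qE = rng.uniform(0, 1, n_offers)
    pE = rng.uniform(0, 1, n_offers)
    alphas = np.linspace(0.2, 2.0, n_units)
    betas = np.linspace(0.2, 2.0, n_units)
    e_qp = 0.25

    def pop(q, p):
        drive = alphas[None, :] * (q[:, None] + p[:, None]) - betas[None, :] * e_qp
        return np.maximum(drive, 0.0)

    pops = [pop(qC, pC), pop(qE, pE)]
    if variant == "mixed":
        pops.append(pop(0.5 * (qC + qE), 0.5 * (pC + pE)))
    act = np.concatenate(pops, axis=1)
    proj = PCA(n_components=2).fit_transform(act - act.mean(axis=0))
    ovc, ove = qC * pC, qE * pE
    variables = {"OVC": ovc, "OVE": ove, "sum": ovc + ove, "diff": ovc - ove}
    rows = []
    for k in range(2):
        row = {"pc": k + 1}
        for name, x in variables.items():
            row[name] = float(np.corrcoef(x, proj[:, k])[0, 1] ** 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pc")


def feedforward_mult_test(params: NetworkParams, spec, n_trials, rng,
                          rho=None) -> pd.DataFrame:
    """Product-vs-sum account of the lesioned network's top two PCs.

    Applies the recurrent-removal lesion, collects last-200-ms offer-period
    activity over risky trials, and regresses PC1/PC2 on the multiplicative
    offer values (OVC, OVE) versus the additive (q + p) features.
    """
    from .neuro import collect_rate_tensor, decision_variables

    tensor = collect_rate_tensor(params, spec, n_trials, rng, rho=rho,
                                 lesion=Lesion(recurrent_removal=True))
    w = tensor.window("offer", last_ms=200.0)
    n_tr, n_t, n_n = w.shape
    act = w.reshape(n_tr * n_t, n_n)
    trial_idx = np.repeat(np.arange(n_tr), n_t)
    dv = decision_variables(tensor.trials)
    qC = tensor.trials["slot0_C_q"].to_numpy(float)
    pC = tensor.trials["slot0_C_p"].to_numpy(float)
    qE = tensor.trials["slot1_E_q"].to_numpy(float)
    pE = tensor.trials["slot1_E_p"].to_numpy(float)
    Xprod = np.column_stack([dv["OVC"], dv["OVE"]])[trial_idx]
    Xsum = np.column_stack([qC + pC, qE + pE])[trial_idx]
    proj = PCA(n_components=2).fit_transform(act - act.mean(axis=0))
    rows = []
    for k in range(2):
        rows.append({"pc": k + 1,
                     "r2_product": _r2_of_fit(Xprod, proj[:, k]),
                     "r2_sum": _r2_of_fit(Xsum, proj[:, k])})
    return pd.DataFrame(rows).set_index("pc")


def estimate_e_qp(rho: float, rng: np.random.Generator, n: int = 100_000) -> float:
    """Monte-Carlo E[q*p] under uniform sampling with the value >= 1 rule."""
    qmax = 10.0 / rho
    q = rng.uniform(0, qmax, n)
    p = rng.uniform(0, 1, n)
    keep = rho * q * p >= 1.0
    return float((q[keep] * p[keep]).mean())
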