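"""Single-neuron and population analyses of firing-rate tensors.

Rate tensors are (trials, time, neurons) arrays collected on trials with
fixed epoch durations so that time bins align across trials (sequential
trials are aligned to second-stimulus onset by construction).  The module
provides per-neuron per-time selectivity regressions against decision
variables, the temporal stability index, delta-R2 categorical/mixed coding
analysis, participation-ratio dimensionality, principal-component
regression, principal angles between task subspaces, orthogonal Procrustes
alignment across networks, task-variance clustering, fractional task
variance, reaction-time analysis, and a planted-tuning synthetic fixture
generator used to validate all of the above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes, subspace_angles
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

P_THRESH = 0.05
R2_THRESH = 0.005

#: canonical variable order; also the deterministic tie-break order
CANONICAL_VARIABLES = ("OVC", "OVE", "CV", "CH", "sum", "diff", "CVC", "CVE")


@dataclass
class RateTensor:
    """rates[trial, time, neuron] with epoch annotations."""

    rates: np.ndarray
    epochs: dict            # epoch name -> (start_step, end_step)
    trials: pd.DataFrame    # per-trial variables / log rows
    dt_ms: float = 20.0

    def window(self, epoch: str, last_ms: float | None = None) -> np.ndarray:
        """Rates restricted to an epoch (optionally its last ``last_ms``)."""
        s, e = self.epochs[epoch]
        if last_ms is not None:
            s = max(s, e - int(round(last_ms / self.dt_ms)))
        return self.rates[:, s:e, :]


def decision_variables(frame: pd.DataFrame) -> pd.DataFrame:
    """Standard decision variables from a (binary-task) trial log.

    OVC/OVE are the slot values, CV the chosen slot's value, CH the choice
    (+1 for slot 0, -1 for slot 1), sum/diff the offer-value sum and
    difference, and CVC/CVE the conjunctive chosen values (value of the
    slot when chosen, zero otherwise).
    """
    ovc = frame["slot0_value"].to_numpy(float)
    ove = frame["slot1_value"].to_numpy(float)
    ch = np.where(frame["choice"].to_numpy() == 0, 1.0, -1.0)
    cv = np.where(ch > 0, ovc, ove)
    return pd.DataFrame({
        "OVC": ovc, "OVE": ove, "CV": cv, "CH": ch,
        "sum": ovc + ove, "diff": ovc - ove,
        "CVC": np.where(ch > 0, ovc, 0.0), "CVE": np.where(ch < 0, ove, 0.0),
    })


# -- per-neuron regressions ----------------------------------------------

def regress_neuron(rates_t: np.ndarray, x: np.ndarray):
    """OLS of one neuron's rates (at one time) on one variable.

    Returns (slope, R2, two-sided p for the slope).
    """
    if len(rates_t) < 3:
        raise ValueError("need at least 3 trials")
    if np.var(x) == 0:
        raise ValueError("degenerate regressor (zero variance)")
    res = stats.linregress(x, rates_t)
    return res.slope, res.rvalue ** 2, res.pvalue


def regress_all(rates: np.ndarray, variables: pd.DataFrame):
    """Vectorized OLS of every (neuron, time) against every variable.

    ``rates``: (trials, time, neurons).  Returns dict variable -> dict of
    (time, neurons) arrays ``slope``, ``r2``, ``p``.
    """
    n_tr, n_t, n_n = rates.shape
    Y = rates.reshape(n_tr, n_t * n_n)
    Yc = Y - Y.mean(axis=0)
    ss_y = (Yc ** 2).sum(axis=0)
    out = {}
    df = n_tr - 2
    for var in variables.columns:
        x = variables[var].to_numpy(float)
        xc = x - x.mean()
        ss_x = (xc ** 2).sum()
        sxy = xc @ Yc
        slope = sxy / ss_x
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_y > 0, sxy ** 2 / (ss_x * ss_y), 0.0)
            r2 = np.clip(r2, 0.0, 1.0)
            tstat = np.sqrt(df) * np.sqrt(r2 / np.maximum(1e-300, 1.0 - r2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        out[var] = {
            "slope": slope.reshape(n_t, n_n),
            "r2": r2.reshape(n_t, n_n),
            "p": p.reshape(n_t, n_n),
        }
    return out


@dataclass
class SelectivityProfile:
    variables: tuple
    labels: np.ndarray   # (time, neurons) int index into variables, -1 none
    r2: dict             # variable -> (time, neurons)
    slope: dict
    p: dict

    def fraction_selective(self, neuron_idx=None) -> pd.DataFrame:
        """Per-variable fraction of selective neurons at each time bin."""
        lab = self.labels if neuron_idx is None else self.labels[:, neuron_idx]
        n = lab.shape[1]
        return pd.DataFrame(
            {v: (lab == i).sum(axis=1) / n for i, v in enumerate(self.variables)}
        )


def classify_selectivity(regs: dict, variables=None) -> SelectivityProfile:
    """Best-variable label per neuron-time by maximum R2 among variables
    passing the two-step criterion (p < 0.05 and R2 >= 0.005)."""
    if variables is None:
        variables = tuple(v for v in CANONICAL_VARIABLES if v in regs) or tuple(regs)
    r2 = np.stack([regs[v]["r2"] for v in variables])     # (V, time, neurons)
    p = np.stack([regs[v]["p"] for v in variables])
    ok = (p < P_THRESH) & (r2 >= R2_THRESH)
    masked = np.where(ok, r2, -np.inf)
    labels = masked.argmax(axis=0)
    labels[~ok.any(axis=0)] = -1
    return SelectivityProfile(
        variables=tuple(variables), labels=labels,
        r2={v: regs[v]["r2"] for v in variables},
        slope={v: regs[v]["slope"] for v in variables},
        p={v: regs[v]["p"] for v in variables},
    )


def temporal_stability_index(labels_per_time: np.ndarray) -> float:
    """TSI of one neuron: primary-variable count / selective count.

    ``labels_per_time`` is the neuron's label sequence (-1 = not selective).
    The primary variable is the modal label; ties break to the lowest index
    (the canonical variable order).  Raises on never-selective neurons.
    """
    sel = labels_per_time[labels_per_time >= 0]
    if sel.size == 0:
        raise ValueError("neuron is never selective; TSI undefined")
    counts = np.bincount(sel)
    primary = int(np.argmax(counts))  # argmax takes the lowest index on ties
    return counts[primary] / sel.size


def tsi_distribution(profile: SelectivityProfile) -> np.ndarray:
    """TSI for every neuron selective at >= 1 time point."""
    out = []
    for j in range(profile.labels.shape[1]):
        lab = profile.labels[:, j]
        if (lab >= 0).any():
            out.append(temporal_stability_index(lab))
    return np.array(out)


def delta_r2(regs: dict, var_pair: tuple, mode: str = "strict",
             strict_thresh: float = 0.5) -> np.ndarray:
    """Distribution of R2_var1 - R2_var2 over included neuron-time points.

    strict: at least one of the pair has R2 >= 0.5 (categorical coding in
    highly selective cells); lenient: at least one passes (p < 0.05 and
    R2 >= 0.005) (mixed selectivity in the general population).
    """
    v1, v2 = var_pair
    r1, r2_ = regs[v1]["r2"], regs[v2]["r2"]
    if mode == "strict":
        inc = (r1 >= strict_thresh) | (r2_ >= strict_thresh)
    elif mode == "lenient":
        ok1 = (regs[v1]["p"] < P_THRESH) & (r1 >= R2_THRESH)
        ok2 = (regs[v2]["p"] < P_THRESH) & (r2_ >= R2_THRESH)
        inc = ok1 | ok2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (r1 - r2_)[inc]


# -- population geometry --------------------------------------------------

def participation_ratio(activity: np.ndarray) -> float:
    """PR = (sum lambda)^2 / sum lambda^2 over covariance eigenvalues.

    ``activity`` is (samples, neurons); samples are typically the last
    200 ms of the offer period concatenated across trials.
    """
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = activity - activity.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    lam = sv ** 2
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    return float(total ** 2 / (lam ** 2).sum())


def offer_window_activity(tensor: RateTensor, epoch: str = "offer",
                          last_ms: float = 200.0) -> np.ndarray:
    """(samples, neurons) activity from the last ``last_ms`` of an epoch."""
    w = tensor.window(epoch, last_ms=last_ms)
    return w.reshape(-1, w.shape[-1])


def pc_regression(activity: np.ndarray, variables: pd.DataFrame,
                  trial_index: np.ndarray | None = None,
                  n_pcs: int = 3) -> pd.DataFrame:
    """R2 of each top PC's projection against each decision variable.

    ``activity`` is (samples, neurons); when the samples pool several time
    bins per trial, ``trial_index`` maps each sample to its trial row in
    ``variables``.  Per-neuron means are subtracted before PCA; no variance
    scaling (rates share units).
    """
    pca = PCA(n_components=n_pcs)
    proj = pca.fit_transform(activity - activity.mean(axis=0))
    if trial_index is None:
        trial_index = np.arange(len(variables))
    rows = []
    for k in range(n_pcs):
        y = proj[:, k]
        row = {"pc": k + 1, "explained_var": float(pca.explained_variance_ratio_[k])}
        for var in variables.columns:
            x = variables[var].to_numpy(float)[trial_index]
            if np.var(x) == 0:
                row[var] = 0.0
                continue
            r = np.corrcoef(x, y)[0, 1]
            row[var] = float(r ** 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pc")


def principal_angles(activity_by_task: dict, angle: str = "largest") -> pd.DataFrame:
    """Pairwise principal angles (degrees) between task subspaces.

    Each task's subspace is spanned by its top round(PR) principal
    components of the (samples, neurons) activity.  ``angle`` selects the
    largest (default, most conservative) or mean canonical angle.
    """
    bases = {}
    for name, act in activity_by_task.items():
        X = act - act.mean(axis=0)
        pr = participation_ratio(act)
        k = max(1, int(round(pr)))
        pca = PCA(n_components=k).fit(X)
        bases[name] = pca.components_.T  # (neurons, k)
    names = list(bases)
    M = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ang = np.degrees(subspace_angles(bases[a], bases[b]))
            val = float(ang.max() if angle == "largest" else ang.mean())
            M.loc[a, b] = M.loc[b, a] = val
    return M


def procrustes_align(points: np.ndarray, reference: np.ndarray):
    """Orthogonal R minimizing ||points @ R - reference||_F.

    ``points``/``reference`` are (n_tasks, dims) mean task representations.
    Returns (aligned points, R, residual).  Rank-deficient configurations
    are flagged with a warning field in the residual tuple.
    """
    if points.shape != reference.shape:
        raise ValueError("shape mismatch")
    R, _ = orthogonal_procrustes(points, reference)
    aligned = points @ R
    residual = float(((aligned - reference) ** 2).sum())
    return aligned, R, residual


# -- clustering and task variance -----------------------------------------

def task_variance_profiles(tensors_by_task: dict, epoch: str = "offer") -> np.ndarray:
    """Per-neuron stimulus-phase variance per task, max-normalized per neuron.

    Returns (neurons, n_tasks) profiles; rows with zero variance everywhere
    come out as all-zero (callers exclude them).
    """
    names = list(tensors_by_task)
    tv = []
    for name in names:
        t = tensors_by_task[name]
        ep = epoch if epoch in t.epochs else ("offer2" if "offer2" in t.epochs else epoch)
        w = t.window(ep)
        tv.append(w.reshape(-1, w.shape[-1]).var(axis=0))
    tv = np.stack(tv, axis=1)
    mx = tv.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(mx > 0, tv / mx, 0.0)
    return prof


def task_variance_clusters(profiles: np.ndarray, k_range=range(2, 21),
                           seed: int = 0, n_init: int = 20):
    """k-means over task-variance profiles, k chosen by max silhouette.

    Returns (labels, centroids, k, silhouette).  Neurons whose profile is
    all-zero must be excluded by the caller.  Degenerate (near-identical)
    profiles fall back to k = 2 with a flag.
    """
    best = None
    n = profiles.shape[0]
    for k in k_range:
        if k >= n:
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(profiles)
        if len(np.unique(km.labels_)) < 2:
            continue
        try:
            sil = silhouette_score(profiles, km.labels_)
        except ValueError:
            continue
        if best is None or sil > best[3]:
            best = (km.labels_, km.cluster_centers_, k, sil)
    if best is None:
        km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(profiles)
        return km.labels_, km.cluster_centers_, 2, float("nan")
    return best


def fractional_task_variance(tv1: np.ndarray, tv2: np.ndarray) -> np.ndarray:
    """(TV1 - TV2) / (TV1 + TV2) per neuron, in [-1, 1]; zero-sum excluded."""
    s = tv1 + tv2
    keep = s > 0
    return (tv1[keep] - tv2[keep]) / s[keep]


# -- reaction times -------------------------------------------------------

def reaction_times(frame: pd.DataFrame):
    """RT distribution and RT-vs-|value difference| regression.

    Uses completed trials only; RT runs from response-phase onset to the
    step of the choice.  Returns (rts_ms, slope, p).
    """
    comp = frame[frame["completed"]]
    rts = comp["rt_ms"].to_numpy(float)
    dv = np.abs(comp["slot0_value"].to_numpy(float) - comp["slot1_value"].to_numpy(float))
    if len(rts) < 3 or np.var(dv) == 0 or np.var(rts) == 0:
        return rts, 0.0, 1.0
    res = stats.linregress(dv, rts)
    return rts, float(res.slope), float(res.pvalue)


# -- synthetic planted-tuning fixture -------------------------------------

@dataclass
class PlantedGroup:
    """A group of neurons sharing one planted linear tuning."""

    n_neurons: int
    variable: str        # column of the trial-variable frame; "none" = untuned
    slope: float = 1.0
    conjunctive_gate: str | None = None  # zero rates where this column <= 0


def synthetic_rate_fixture(groups: list, n_trials: int, rng: np.random.Generator,
                           noise_sigma: float = 0.1, baseline: float = 1.0,
                           epoch_steps: int = 50):
    """Rate tensor with planted linear tuning plus Gaussian noise.

    Trials carry the standard binary-task variables (OVC, OVE drawn like
    risky-task offer values, CV/CH from the better offer).  Each planted
    group's neurons respond, during the offer epoch, as
    baseline + slope * variable (+ noise); tuning is zero in earlier
    epochs.  Epoch structure matches the fixed-duration task timeline
    (fixation / rule / offer, ``epoch_steps`` bins each).

    Returns (RateTensor, ground_truth_labels list).
    """
    ovc = rng.uniform(1.0, 10.0, size=n_trials)
    ove = rng.uniform(1.0, 10.0, size=n_trials)
    ch = np.where(ovc >= ove, 1.0, -1.0)
    cv = np.maximum(ovc, ove)
    trials = pd.DataFrame({
        "OVC": ovc, "OVE": ove, "CV": cv, "CH": ch,
        "sum": ovc + ove, "diff": ovc - ove,
        "CVC": np.where(ch > 0, ovc, 0.0), "CVE": np.where(ch < 0, ove, 0.0),
        "choice": np.where(ch > 0, 0, 1),
        "slot0_value": ovc, "slot1_value": ove, "completed": True,
    })
    n_neurons = sum(g.n_neurons for g in groups)
    T = 3 * epoch_steps
    rates = np.zeros((n_trials, T, n_neurons))
    labels = []
    j = 0
    offer_slice = slice(2 * epoch_steps, 3 * epoch_steps)
    for g in groups:
        for _ in range(g.n_neurons):
            labels.append(g.variable)
            sig = np.zeros(n_trials)
            if g.variable != "none":
                sig = g.slope * trials[g.variable].to_numpy(float)
            if g.conjunctive_gate is not None:
                sig = np.where(trials[g.conjunctive_gate].to_numpy(float) > 0, sig, 0.0)
            rates[:, offer_slice, j] = baseline + sig[:, None]
            j += 1
    rates[:, :2 * epoch_steps, :] = baseline
    if noise_sigma > 0:
        rates += rng.normal(0.0, noise_sigma, size=rates.shape)
    rates = np.maximum(rates, 0.0)
    epochs = {"fixation": (0, epoch_steps), "rule": (epoch_steps, 2 * epoch_steps),
              "offer": (2 * epoch_steps, 3 * epoch_steps)}
    return RateTensor(rates=rates, epochs=epochs, trials=trials), labels


def save_rate_tensor(path, tensor: RateTensor):
    """Write a RateTensor to HDF5 (rates, trial table, epoch boundaries)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=tensor.rates)
        f.attrs["dt_ms"] = tensor.dt_ms
        g = f.create_group("epochs")
        for name, (s, e) in tensor.epochs.items():
            g.attrs[name] = (s, e)
        tcols = f.create_group("trials")
        for col in tensor.trials.columns:
            vals = tensor.trials[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            tcols.create_dataset(col, data=vals)


def load_rate_tensor(path) -> RateTensor:
    import h5py

    with h5py.File(path, "r") as f:
        rates = f["rates"][()]
        dt = float(f.attrs["dt_ms"])
        epochs = {k: tuple(int(x) for x in v) for k, v in f["epochs"].attrs.items()}
        cols = {}
        for col in f["trials"]:
            v = f["trials"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
    return RateTensor(rates=rates, epochs=epochs,
                      trials=pd.DataFrame(cols), dt_ms=dt)


# -- collecting rate tensors from trained networks ------------------------

def collect_rate_tensor(params, spec, n_trials, rng, rho=None, lesion=None,
                        offer_sampler=None) -> RateTensor:
    """Run fixed-epoch trials and assemble an aligned RateTensor.

    Only completed trials are kept.  Trials are truncated to the shortest
    recorded length (responses end trials at different steps within the
    response window); for the sequential task the fixed epochs align the
    second-stimulus onset across trials by construction.
    """
    from .ppo import run_trials

    frame, rate_trials = run_trials(
        params, spec, n_trials, rng, rho=rho, fixed_epochs=True,
        record_rates=True, lesion=lesion, offer_sampler=offer_sampler)
    kept = [(r, info) for r, info in rate_trials if info["completed"]]
    if not kept:
        raise RuntimeError("no completed trials; cannot build a rate tensor")
    tmin = min(r.shape[0] for r, _ in kept)
    rates = np.stack([r[:tmin] for r, _ in kept])
    rows = pd.DataFrame([trial_info_row(spec.name, i, info)
                         for i, (_, info) in enumerate(kept)])
    steps = 50  # 1000 ms fixed epochs at 20 ms
    if spec.sequential:
        epochs = {"fixation": (0, steps), "rule": (steps, 2 * steps),
                  "offer1": (2 * steps, 3 * steps), "delay": (3 * steps, 4 * steps),
                  "offer2": (4 * steps, 5 * steps), "response": (5 * steps, tmin)}
    else:
        epochs = {"fixation": (0, steps), "rule": (steps, 2 * steps),
                  "offer": (2 * steps, 3 * steps), "response": (3 * steps, tmin)}
    return RateTensor(rates=rates, epochs=epochs, trials=rows)


def trial_info_row(task, i, info):
    from .taskenv import trial_log_row
    return trial_log_row(task, i, info, 0.0)
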