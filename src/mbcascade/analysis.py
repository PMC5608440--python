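"""Cascade statistics on reaction-coordinate trajectories or event tables.

From per-module chi time series this module extracts first-passage
transition events and turns ensembles of them into transition-order
probabilities (P-order), heuristic pair-rate constants k(b|a), bootstrap
confidence intervals, exact-binomial order p-values, scaled-time ensemble
averages, and Kolmogorov-Smirnov tests against the analytic null of two
independent exponential clocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ChiTrajectory

__all__ = [
    "TransitionEventTable",
    "OrderMap",
    "RateMap",
    "NullTestResult",
    "detect_transitions",
    "order_map",
    "pair_rates",
    "pair_rate_samples",
    "bootstrap_ci",
    "independent_null_pdf",
    "ks_critical_value",
    "ks_independence_test",
    "order_pvalue",
    "scaled_time_average",
    "compare_setups",
    "load_event_table",
    "save_event_table",
]

#: columns of an event table (one row per trajectory x module)
EVENT_COLUMNS = ["trajectory", "module", "tau", "censored", "t_end", "frame_steps"]

TransitionEventTable = pd.DataFrame  # alias documenting the tabular contract


def _detect_single(traj: ChiTrajectory, chi_threshold: float, persistence: int,
                   traj_id) -> pd.DataFrame:
    if len(traj.steps) == 0:
        raise ValueError("empty trajectory")
    if chi_threshold < 0 or persistence < 1:
        raise ValueError("chi_threshold must be >= 0 and persistence >= 1")
    target_sign = 1 if traj.direction == "power" else -1
    start_state = -target_sign
    frame_steps = int(traj.steps[1] - traj.steps[0]) if len(traj.steps) > 1 else 1
    rows = []
    for m, name in enumerate(traj.module_names):
        x = traj.chi[:, m]
        state = start_state
        run_hi = run_lo = 0
        tau, censored = None, True
        for f in range(len(x)):
            run_hi = run_hi + 1 if x[f] > chi_threshold else 0
            run_lo = run_lo + 1 if x[f] < -chi_threshold else 0
            new_state = state
            if run_hi >= persistence:
                new_state = 1
            elif run_lo >= persistence:
                new_state = -1
            if new_state != state:
                state = new_state
                if state == target_sign and censored:
                    # entry time = first frame of the persistent excursion
                    tau = int(traj.steps[f - persistence + 1])
                    censored = False
                    break
        rows.append({
            "trajectory": traj_id, "module": name,
            "tau": tau if tau is not None else np.nan,
            "censored": censored, "t_end": traj.t_end,
            "frame_steps": frame_steps,
        })
    return pd.DataFrame(rows)


def detect_transitions(trajectories, chi_threshold: float = 1.0,
                       persistence: int = 2) -> TransitionEventTable:
    """First-passage times to the run's target state, with hysteresis.

    A module flips to the post state after ``persistence`` consecutive saved
    frames with chi > +chi_threshold, and to pre likewise below
    -chi_threshold; sub-threshold excursions do not count.  ``tau`` is the
    time of first entry into the target state (post for power strokes, pre
    for recovery strokes); modules that never arrive are censored.  Accepts
    one trajectory or a list.
    """
    if isinstance(trajectories, ChiTrajectory):
        trajectories = [trajectories]
    tables = []
    for idx, traj in enumerate(trajectories):
        tid = traj.seed if traj.seed is not None else idx
        tables.append(_detect_single(traj, chi_threshold, persistence, tid))
    return pd.concat(tables, ignore_index=True)


def _module_order(events: pd.DataFrame) -> list[str]:
    seen = []
    for m in events["module"]:
        if m not in seen:
            seen.append(m)
    return seen


@dataclass
class OrderMap:
    """Pairwise transition-order probabilities and their significance.

    ``p_order[a, b]`` is the fraction of trajectories in which module ``a``
    transited strictly before module ``b`` with both observed, over all n
    trajectories; censoring makes ``p_order[a, b] + p_order[b, a] < 1``
    possible.  ``p_scores[a]`` sums row ``a``; sorting by descending score
    gives the average transition order.
    """

    modules: list[str]
    p_order: np.ndarray          # (K, K), diagonal NaN
    n_first: np.ndarray          # decided counts: a before b
    n_trajectories: int
    p_raw: np.ndarray
    p_corrected: np.ndarray
    correction: str

    @property
    def p_scores(self) -> np.ndarray:
        return np.nansum(self.p_order, axis=1)

    @property
    def sorted_modules(self) -> list[str]:
        order = np.argsort(-self.p_scores, kind="stable")
        return [self.modules[i] for i in order]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_order, index=self.modules, columns=self.modules)


def order_map(events: TransitionEventTable, correction: str = "bonferroni") -> OrderMap:
    """P-order matrix over an ensemble of event tables.

    Only pairs observed in the same trajectory with both modules uncensored
    and strictly distinct first-passage times are decided; ties and
    censored partners leave the trajectory out of both numerators while the
    denominator stays the ensemble size.  Raw pair p-values come from a
    two-sided exact binomial test on the decided trajectories; the
    correction (Bonferroni or Holm) spans the K(K-1)/2 tested pairs.
    """
    modules = _module_order(events)
    K = len(modules)
    trajs = events["trajectory"].unique()
    n = len(trajs)
    tau = {(r.trajectory, r.module): (r.tau, r.censored)
           for r in events.itertuples()}
    n_first = np.zeros((K, K), dtype=int)
    for t in trajs:
        for a in range(K):
            ta, ca = tau[(t, modules[a])]
            if ca:
                continue
            for b in range(K):
                if a == b:
                    continue
                tb, cb = tau[(t, modules[b])]
                if not cb and ta < tb:
                    n_first[a, b] += 1
    p_order = n_first / n
    np.fill_diagonal(p_order, np.nan)

    p_raw = np.full((K, K), np.nan)
    pairs, pvals = [], []
    for a in range(K):
        for b in range(a + 1, K):
            if n_first[a, b] + n_first[b, a] >= 1:
                res = order_pvalue(n_first[a, b], n_first[b, a], K,
                                   method=None)
                p_raw[a, b] = p_raw[b, a] = res["raw"]
                pairs.append((a, b))
                pvals.append(res["raw"])
    p_corr = np.full((K, K), np.nan)
    if pvals:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "holm": "holm"}[correction]
        n_tests = K * (K - 1) // 2  # correct over all tested pairs
        if correction == "bonferroni":
            adj = np.minimum(np.asarray(pvals) * n_tests, 1.0)
        else:
            adj = multipletests(pvals, method=method)[1]
        for (a, b), p in zip(pairs, adj):
            p_corr[a, b] = p_corr[b, a] = p
    return OrderMap(modules, p_order, n_first, n, p_raw, p_corr, correction)


@dataclass
class RateMap:
    """Average pair-rate constants k(b|a) in 1/10^4 MD steps.

    ``k[a, b]`` estimates how quickly module ``b`` follows module ``a``;
    cells with fewer than ``mask_threshold`` contributing trajectories are
    masked (NaN).  This reciprocal-interval average is a heuristic coupling
    score, not a true rate.
    """

    modules: list[str]
    k: np.ndarray
    n: np.ndarray
    mask_threshold: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.k, index=self.modules, columns=self.modules)


def pair_rate_samples(events: TransitionEventTable, a: str, b: str) -> np.ndarray:
    """Per-trajectory reciprocal waiting times 1/dt(b after a), unit 1/10^4 steps.

    Includes trajectories where ``a`` transited and ``b`` transited later or
    never (a censored ``b`` contributes the interval to the end of the run).
    ``dt`` is floored at one saved-frame duration so the reciprocal stays
    finite.
    """
    ev = events.set_index(["trajectory", "module"])
    out = []
    for t in events["trajectory"].unique():
        ra = ev.loc[(t, a)]
        rb = ev.loc[(t, b)]
        if ra["censored"]:
            continue
        tb = rb["t_end"] if rb["censored"] else rb["tau"]
        if rb["censored"] or tb > ra["tau"]:
            dt = max(float(tb - ra["tau"]), float(ra["frame_steps"]))
            out.append(1e4 / dt)
    return np.asarray(out)


def pair_rates(events: TransitionEventTable, mask_threshold: int = 7,
               with_bootstrap: bool = False, n_boot: int = 2000,
               level: float = 0.95, seed: int = 0) -> RateMap:
    """k(b|a) = mean over qualifying trajectories of 1/dt_ab, per ordered pair."""
    modules = _module_order(events)
    K = len(modules)
    k = np.full((K, K), np.nan)
    n = np.zeros((K, K), dtype=int)
    lo = np.full((K, K), np.nan) if with_bootstrap else None
    hi = np.full((K, K), np.nan) if with_bootstrap else None
    for ai, a in enumerate(modules):
        for bi, b in enumerate(modules):
            if ai == bi:
                continue
            vals = pair_rate_samples(events, a, b)
            n[ai, bi] = len(vals)
            if len(vals) >= mask_threshold:
                k[ai, bi] = float(np.mean(vals))
                if with_bootstrap:
                    lo[ai, bi], hi[ai, bi] = bootstrap_ci(
                        vals, n_boot=n_boot, level=level,
                        seed=seed + 1000 * ai + bi)
    return RateMap(modules, k, n, mask_threshold, lo, hi)


def bootstrap_ci(values, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean (resampling with replacement)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    a = 0.5 * (1.0 - level)
    return float(np.quantile(means, a)), float(np.quantile(means, 1.0 - a))


def independent_null_pdf(k_a: float, k_b: float):
    """Analytic density/CDF of dt = tau_b - tau_a for independent exponentials.

    f(dt) = k_a k_b / (k_a + k_b) * exp(-k_b dt) for dt >= 0 and
    * exp(+k_a dt) for dt < 0.  Returns ``(pdf, cdf)`` as vectorized
    callables; rates must be positive and share the unit of 1/dt.
    """
    if k_a <= 0 or k_b <= 0:
        raise ValueError("rates must be positive")
    pref = k_a * k_b / (k_a + k_b)

    def pdf(x):
        x = np.asarray(x, dtype=float)
        pos = pref * np.exp(-k_b * np.maximum(x, 0.0))
        neg = pref * np.exp(k_a * np.minimum(x, 0.0))
        return np.where(x >= 0, pos, neg)

    def cdf(x):
        x = np.asarray(x, dtype=float)
        neg = (k_b / (k_a + k_b)) * np.exp(k_a * np.minimum(x, 0.0))
        pos = 1.0 - (k_a / (k_a + k_b)) * np.exp(-k_b * np.maximum(x, 0.0))
        return np.where(x < 0, neg, pos)

    return pdf, cdf


def ks_critical_value(n: int, alpha: float = 0.05) -> float:
    """Exact one-sample two-sided KS critical value at sample size n."""
    return float(stats.kstwo.ppf(1.0 - alpha, n))


@dataclass
class NullTestResult:
    """One-sample KS comparison of dt samples against the independence null."""

    k_a: float
    k_b: float
    statistic: float
    n: int
    alpha: float
    critical_value: float
    reject: bool
    pvalue: float


def ks_independence_test(dt_samples, k_a: float, k_b: float,
                         alpha: float = 0.05) -> NullTestResult:
    """Test observed transition-time differences against perfect independence.

    D is the maximum deviation between the empirical CDF of ``dt_samples``
    and the closed-form difference-of-exponentials CDF; the null is rejected
    when D exceeds the exact critical value at (n, alpha).
    """
    dt_samples = np.asarray(dt_samples, dtype=float)
    if len(dt_samples) == 0:
        raise ValueError("empty sample")
    if len(dt_samples) < 5:
        raise ValueError("KS independence test needs at least 5 samples")
    _, cdf = independent_null_pdf(k_a, k_b)
    res = stats.kstest(dt_samples, cdf)
    crit = ks_critical_value(len(dt_samples), alpha)
    return NullTestResult(k_a, k_b, float(res.statistic), len(dt_samples),
                          alpha, crit, bool(res.statistic > crit),
                          float(res.pvalue))


def estimate_rate(events: TransitionEventTable, module: str) -> float:
    """Single-exponential rate 1/mean(tau) from uncensored first-passage times,
    in 1/10^4 steps."""
    sel = events[(events["module"] == module) & (~events["censored"])]
    if len(sel) == 0:
        raise ValueError(f"module {module}: no uncensored transitions")
    return 1e4 / float(sel["tau"].mean())


def order_pvalue(n_ab: int, n_ba: int, K: int, method: str | None = "bonferroni"):
    """Two-sided exact binomial p-value for one pair's transition order.

    The null is a coin flip (p = 0.5) over the decided trajectories.  With
    ``method="bonferroni"`` the corrected value multiplies by the K(K-1)/2
    tested pairs (capped at 1); ``method=None`` returns only the raw value.
    """
    if n_ab + n_ba < 1:
        raise ValueError("need at least one decided trajectory")
    raw = float(stats.binomtest(n_ab, n_ab + n_ba, 0.5).pvalue)
    out = {"raw": raw}
    if method == "bonferroni":
        out["corrected"] = min(1.0, raw * K * (K - 1) / 2)
    elif method is not None:
        raise ValueError(f"unknown correction {method!r}")
    return out


def scaled_time_average(
    trajectories: list[ChiTrajectory],
    anchor_first: str,
    anchor_second: str,
    target: str,
    s_grid: np.ndarray | None = None,
    chi_threshold: float = 1.0,
    persistence: int = 2,
) -> pd.DataFrame:
    """Ensemble-average chi of ``target`` on the two-anchor scaled clock.

    Per trajectory, time is mapped to s = (t - tau_first)/(tau_second -
    tau_first) so the two anchor transitions land at s = 0 and s = 1; the
    target's chi is interpolated onto a common s grid and averaged over the
    trajectories in which both anchors transited.
    """
    if s_grid is None:
        s_grid = np.linspace(-0.5, 1.5, 101)
    curves = []
    for traj in trajectories:
        ev = detect_transitions(traj, chi_threshold, persistence)
        ev = ev.set_index("module")
        if ev.loc[anchor_first, "censored"] or ev.loc[anchor_second, "censored"]:
            continue
        t1 = ev.loc[anchor_first, "tau"]
        t2 = ev.loc[anchor_second, "tau"]
        if t2 == t1:
            continue
        s = (traj.steps - t1) / (t2 - t1)
        x = traj.chi[:, traj.module_names.index(target)]
        curves.append(np.interp(s_grid, s, x))
    if not curves:
        raise ValueError("no trajectory has both anchors uncensored")
    mean = np.mean(curves, axis=0)
    return pd.DataFrame({"s": s_grid, "chi_mean": mean,
                         "n_included": len(curves)})


def compare_setups(reference: dict, perturbed: dict[str, dict]) -> pd.DataFrame:
    """Tabulate P-order and k(b|a) changes of perturbed setups vs a reference.

    Each report is ``{"order": OrderMap, "rates": RateMap}``.  Rows hold one
    ordered module pair per setup with the reference and delta values; a
    module-set mismatch raises.
    """
    ref_om, ref_rm = reference["order"], reference["rates"]
    rows = []
    for label, rep in perturbed.items():
        om, rm = rep["order"], rep["rates"]
        if om.modules != ref_om.modules:
            raise ValueError(f"setup {label}: module set differs from reference")
        K = len(om.modules)
        for a in range(K):
            for b in range(K):
                if a == b:
                    continue
                rows.append({
                    "setup": label,
                    "first": om.modules[a], "second": om.modules[b],
                    "p_order_ref": ref_om.p_order[a, b],
                    "p_order": om.p_order[a, b],
                    "delta_p_order": om.p_order[a, b] - ref_om.p_order[a, b],
                    "k_ref": ref_rm.k[a, b], "k": rm.k[a, b],
                    "delta_k": rm.k[a, b] - ref_rm.k[a, b],
                })
    return pd.DataFrame(rows)


def plot_order_map(om: OrderMap, ax=None, sort: bool = False):
    """Heatmap of P-order(column precedes row); optionally in sorted order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    modules = om.sorted_modules if sort else om.modules
    idx = [om.modules.index(m) for m in modules]
    mat = om.p_order[np.ix_(idx, idx)].T  # column transits first
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="Greys", origin="upper")
    ax.set_xticks(range(len(modules)), modules, rotation=90)
    ax.set_yticks(range(len(modules)), modules)
    ax.set_xlabel("earlier module")
    ax.set_ylabel("later module")
    ax.figure.colorbar(im, ax=ax, label="P-order")
    return ax


def plot_rate_map(rm: RateMap, ax=None):
    """Heatmap of the pair-rate constants k(row | column), masked cells blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    mat = np.ma.masked_invalid(rm.k.T)
    im = ax.imshow(mat, cmap="Greys", origin="upper")
    ax.set_xticks(range(len(rm.modules)), rm.modules, rotation=90)
    ax.set_yticks(range(len(rm.modules)), rm.modules)
    ax.set_xlabel("module a (first)")
    ax.set_ylabel("module b (follows)")
    ax.figure.colorbar(im, ax=ax, label="k(b|a)  [1/10$^4$ steps]")
    return ax


def save_event_table(events: TransitionEventTable, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def load_event_table(path) -> TransitionEventTable:
    df = pd.read_csv(path)
    if "frame_steps" not in df.columns:
        df["frame_steps"] = 1
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df[EVENT_COLUMNS]
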