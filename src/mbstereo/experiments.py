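"""Seeded in-silico experiments on the PN -> KC -> MBON network.

Every runner draws one independent child random stream per iteration from
the master seed (``numpy.random.SeedSequence(seed).spawn``), so a run is
bit-reproducible and any single iteration can be regenerated in isolation.
Results come back as :class:`StereotypyReport` objects holding per-iteration
metric values, aggregate statistics (mean, sd, one-sample t-test against 0)
and auxiliary per-iteration quantities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .circuit import (NetworkParams, batch_forward, calibrate_linear_gain,
                      mbon_weights, sample_individual_pair,
                      sample_pn_responses)
from .metrics import _mean_pred_fast, pairwise_pred_values

__all__ = [
    "StereotypyReport",
    "HillFit",
    "run_simulation",
    "run_learning",
    "run_fixed_drive",
    "run_parameter_sweep",
    "drive_difference_analysis",
    "run_convergence_randomness_grid",
    "fit_hill",
    "hill_curve",
    "partition_spikes",
    "apply_learning_event",
    "iteration_rngs",
    "CONTROLS",
    "FIXED_DRIVE_VARIANTS",
    "SWEEPABLE_PARAMETERS",
]

CONTROLS = ("none", "identical_connectivity", "nonstereotypic_pns")
FIXED_DRIVE_VARIANTS = ("base", "range_one_odor", "range_both_odors",
                        "nactive_one_odor", "nactive_both_odors",
                        "linear_range", "linear_nactive", "shuffled_labels")
SWEEPABLE_PARAMETERS = ("pn_mean_rate", "n_kcs", "pn_kc_prob", "kc_threshold",
                        "n_pns", "pn_response_prob")


def iteration_rngs(seed: int, n: int) -> list:
    """One independent child generator per iteration from a master seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class StereotypyReport:
    """Per-iteration metric values plus recomputable aggregates."""

    per_iteration: pd.DataFrame  # iteration, quantity, metric, value
    aggregates: pd.DataFrame     # quantity, metric, mean, sd, n, t, p
    auxiliaries: pd.DataFrame    # iteration, n_active_kcs, mean_active_rate, ...
    kc_pool: pd.DataFrame | None = None  # iteration, metric, value_sum, n_kcs
    params: NetworkParams | None = None
    meta: dict = field(default_factory=dict)

    def mean(self, quantity: str, metric: str = "pred") -> float:
        sel = self.aggregates
        row = sel[(sel["quantity"] == quantity) & (sel["metric"] == metric)]
        if row.empty:
            raise KeyError(f"no aggregate for ({quantity}, {metric})")
        return float(row["mean"].iloc[0])

    def pooled_kc_mean(self, metric: str) -> float:
        """Mean over all qualifying KCs pooled across iterations."""
        if self.kc_pool is None:
            raise ValueError("per-KC metrics were not computed for this run")
        sub = self.kc_pool[self.kc_pool["metric"] == metric]
        n = sub["n_kcs"].sum()
        return float(sub["value_sum"].sum() / n) if n else float("nan")


@dataclass(frozen=True)
class HillFit:
    """Hill-equation fit S = r^a / (b + r^a) of stereotypy vs a ratio."""

    a: float
    b: float
    r_squared: float
    n_points: int
    degenerate: bool = False


def _aggregate(per_iteration: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (quantity, metric), grp in per_iteration.groupby(
            ["quantity", "metric"], sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mean = float(vals.mean()) if n else float("nan")
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        if n > 1 and np.ptp(vals) > 1e-12 * max(1.0, abs(mean)):
            res = stats.ttest_1samp(vals, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        else:
            t, p = float("nan"), float("nan")
        rows.append((quantity, metric, mean, sd, n, t, p))
    return pd.DataFrame(rows, columns=["quantity", "metric", "mean", "sd",
                                       "n", "t_statistic", "p_value"])


def _pairwise_corr_mean(values: np.ndarray) -> float:
    """Mean Pearson r over individual pairs; NaN pairs excluded."""
    rs = []
    for ia, ib in itertools.combinations(range(values.shape[0]), 2):
        x, y = values[ia], values[ib]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def _per_kc_metrics(r1: np.ndarray, r2: np.ndarray, chunk: int = 256):
    """Per-KC correlation and mean-PRED for KCs active in both individuals.

    ``r1``/``r2`` are (odors, n_kcs) response matrices of the two
    individuals.  A KC qualifies if it responded to at least one odor in
    both individuals; correlations that are undefined (constant vector in
    either individual) are dropped from the correlation pool.
    Returns (corr_sum, corr_n, pred_sum, pred_n).
    """
    active_both = (r1 > 0).any(axis=0) & (r2 > 0).any(axis=0)
    idx = np.flatnonzero(active_both)
    if idx.size == 0:
        return 0.0, 0, 0.0, 0
    x = r1[:, idx].T  # (n_sel, odors)
    y = r2[:, idx].T
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    ok = denom > 0
    corr = (xc * yc).sum(axis=1)[ok] / denom[ok]
    pred_sum, pred_n = 0.0, 0
    for start in range(0, idx.size, chunk):
        preds = pairwise_pred_values(x[start:start + chunk],
                                     y[start:start + chunk])
        pred_sum += float(preds.mean(axis=1).sum())
        pred_n += preds.shape[0]
    return float(corr.sum()), int(ok.sum()), pred_sum, pred_n


def _drive_difference(total_per_odor: np.ndarray) -> float:
    """|difference in total PN output| for two-odor panels, else NaN."""
    if total_per_odor.size == 2:
        return float(abs(total_per_odor[0] - total_per_odor[1]))
    return float("nan")


def _iteration_tables(params: NetworkParams, rng, control: str,
                      normalize_mbon_weights: bool):
    """One network iteration: spike draw, wiring draw, forward passes.

    Returns (quantity -> (n_individuals, n_odors) array, aux dict,
    per-individual KC response matrices).
    """
    if control not in CONTROLS:
        raise ValueError(f"unknown control {control!r}; choose from {CONTROLS}")
    if control == "nonstereotypic_pns":
        spike_sets = [sample_pn_responses(params, rng).spikes
                      for _ in range(params.n_individuals)]
    else:
        shared = sample_pn_responses(params, rng).spikes
        spike_sets = [shared] * params.n_individuals
    pair_params = params
    if control == "identical_connectivity":
        pair_params = params.with_(randomness_fraction=0.0)
    pair = sample_individual_pair(pair_params, rng)
    w = mbon_weights(pair.kc_mbon_mask, normalize_mbon_weights)
    quantities = {q: np.empty((params.n_individuals, params.n_odors))
                  for q in ("mbon", "total_kc_response", "total_kc_input")}
    kc_responses = []
    n_active_acc, rate_acc = [], []
    for ind in range(params.n_individuals):
        k, r = batch_forward(spike_sets[ind], pair.pn_kc[ind],
                             params.kc_threshold, params.noise_sd, rng)
        quantities["mbon"][ind] = np.maximum(0.0, r @ w - params.mbon_t)
        quantities["total_kc_response"][ind] = r.sum(axis=1)
        quantities["total_kc_input"][ind] = k.sum(axis=1)
        n_active = (r > 0).sum(axis=1)
        n_active_acc.append(n_active)
        with np.errstate(invalid="ignore"):
            rates = np.where(n_active > 0, r.sum(axis=1) / np.maximum(n_active, 1),
                             0.0)
        rate_acc.append(rates)
        kc_responses.append(r)
    aux = {
        "n_active_kcs": float(np.mean(n_active_acc)),
        "mean_active_rate": float(np.mean(rate_acc)),
        "active_fraction": float(np.mean(n_active_acc) / params.n_kcs),
        "drive_diff": _drive_difference(spike_sets[0].sum(axis=1)),
    }
    return quantities, aux, kc_responses


def run_simulation(params: NetworkParams, n_iterations: int = 100,
                   control: str = "none",
                   normalize_mbon_weights: bool = False,
                   compute_kc_metrics: bool | None = None,
                   seed: int | None = None) -> StereotypyReport:
    """Reference experiment: repeated paired-network simulations.

    Per iteration a fresh odor panel and fresh per-individual wiring are
    drawn, both networks are run on all odors, and both stereotypy metrics
    are computed on the MBON response, the total KC response and the total
    KC input.  ``control`` selects the positive control (identical PN-KC
    wiring in the two individuals) or the negative control (independent,
    non-stereotypic PN responses per individual).  Per-KC stereotypy is
    collected for two-individual runs unless disabled.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if compute_kc_metrics is None:
        compute_kc_metrics = params.n_individuals == 2
    seed = params.seed if seed is None else seed
    rows, aux_rows, pool_rows = [], [], []
    for it, rng in enumerate(iteration_rngs(seed, n_iterations)):
        quantities, aux, kc_resp = _iteration_tables(
            params, rng, control, normalize_mbon_weights)
        for qname, vals in quantities.items():
            rows.append((it, qname, "pred", _mean_pred_fast(vals)))
            rows.append((it, qname, "correlation", _pairwise_corr_mean(vals)))
        if compute_kc_metrics and params.n_individuals == 2:
            c_sum, c_n, p_sum, p_n = _per_kc_metrics(kc_resp[0], kc_resp[1])
            pool_rows.append((it, "correlation", c_sum, c_n))
            pool_rows.append((it, "pred", p_sum, p_n))
            rows.append((it, "individual_kc", "correlation",
                         c_sum / c_n if c_n else float("nan")))
            rows.append((it, "individual_kc", "pred",
                         p_sum / p_n if p_n else float("nan")))
        aux_rows.append({"iteration": it, **aux})
    per_it = pd.DataFrame(rows, columns=["iteration", "quantity", "metric",
                                         "value"])
    kc_pool = (pd.DataFrame(pool_rows, columns=["iteration", "metric",
                                                "value_sum", "n_kcs"])
               if pool_rows else None)
    return StereotypyReport(
        per_iteration=per_it, aggregates=_aggregate(per_it),
        auxiliaries=pd.DataFrame(aux_rows), kc_pool=kc_pool, params=params,
        meta={"experiment": "simulate", "control": control,
              "normalize_mbon_weights": normalize_mbon_weights,
              "n_iterations": n_iterations, "seed": seed})


def run_learning(params: NetworkParams, n_iterations: int = 100,
                 learning_rate: float = 0.5,
                 seed: int | None = None) -> StereotypyReport:
    """Sequential synaptic learning at the KC -> MBON layer.

    Per individual, a random half of the odor panel is learned in random
    order.  Each event, with probability 1/2, either connects a fraction
    ``learning_rate`` of the KCs activated by that odor that are currently
    unconnected to the MBON, or disconnects the same fraction of the
    activated, connected KCs (nearest-integer counts, uniform choice
    without replacement).  MBON responses are recomputed after all events
    and MBON stereotypy is reported.
    """
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError("learning_rate must be in [0, 1]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    seed = params.seed if seed is None else seed
    rows, aux_rows = [], []
    for it, rng in enumerate(iteration_rngs(seed, n_iterations)):
        quantities, aux, kc_resp = _iteration_tables(params, rng, "none", False)
        n_learned = params.n_odors // 2
        mask0 = np.zeros(params.n_kcs, dtype=bool)
        mask0[:int(np.ceil(params.kc_mbon_prob * params.n_kcs))] = True
        mbon = np.empty((params.n_individuals, params.n_odors))
        for ind in range(params.n_individuals):
            connected = mask0.copy()
            learned = rng.permutation(params.n_odors)[:n_learned]
            for odor in learned:
                active = kc_resp[ind][odor] > 0
                increase = rng.random() < 0.5
                apply_learning_event(connected, active, increase,
                                     learning_rate, rng)
            mbon[ind] = np.maximum(
                0.0, kc_resp[ind] @ connected.astype(float) - params.mbon_t)
        rows.append((it, "mbon", "pred", _mean_pred_fast(mbon)))
        rows.append((it, "mbon", "correlation", _pairwise_corr_mean(mbon)))
        aux_rows.append({"iteration": it, **aux})
    per_it = pd.DataFrame(rows, columns=["iteration", "quantity", "metric",
                                         "value"])
    return StereotypyReport(
        per_iteration=per_it, aggregates=_aggregate(per_it),
        auxiliaries=pd.DataFrame(aux_rows), params=params,
        meta={"experiment": "learn", "learning_rate": learning_rate,
              "n_iterations": n_iterations, "seed": seed})


def apply_learning_event(connected: np.ndarray, active: np.ndarray,
                         increase: bool, learning_rate: float, rng) -> int:
    """One learning event on the KC -> MBON connection vector, in place.

    If ``increase``, a fraction ``learning_rate`` of the KCs that are
    active and unconnected become connected; otherwise the same fraction
    of the active, connected KCs are disconnected.  The count is rounded
    to the nearest integer and the subset drawn uniformly without
    replacement (a full permutation is consumed so the stream advances
    identically for every learning rate).  Returns the number of synapses
    changed.
    """
    eligible = np.flatnonzero(active & (~connected if increase else connected))
    order = rng.permutation(eligible)
    k = int(math.floor(learning_rate * eligible.size + 0.5))
    if k:
        connected[order[:k]] = increase
    return k


def partition_spikes(total: int, n_parts: int, low: int, high: int,
                     rng) -> np.ndarray:
    """Randomly split ``total`` spikes into ``n_parts`` counts in [low, high].

    Sequential bounded sampling: part j is uniform on the interval that
    keeps the remaining total feasible, followed by a random permutation to
    remove order bias.  Raises before sampling when no partition exists.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    if not (n_parts * low <= total <= n_parts * high):
        raise ValueError(
            f"cannot split {total} spikes into {n_parts} parts in "
            f"[{low}, {high}]")
    parts = np.empty(n_parts, dtype=int)
    rem = total
    for j in range(n_parts):
        left = n_parts - j - 1
        lo_j = max(low, rem - left * high)
        hi_j = min(high, rem - left * low)
        parts[j] = rng.integers(lo_j, hi_j + 1)
        rem -= parts[j]
    return rng.permutation(parts)


def _fixed_drive_specs(params: NetworkParams, variant: str, variant_args: dict,
                       total: int, rng):
    """Per-odor (n_active, low, high) for the two odors of one iteration."""
    lo, hi = params.spike_low, params.spike_high
    half = params.n_pns // 2
    args = variant_args or {}
    if variant in ("range_one_odor", "linear_range"):
        lo2, hi2 = args["spike_range"]
        return [(half, lo, hi), (half, lo2, hi2)]
    if variant == "range_both_odors":
        lo2, hi2 = args["spike_range"]
        return [(half, lo2, hi2), (half, lo2, hi2)]
    if variant in ("nactive_one_odor", "linear_nactive"):
        return [(half, lo, hi), (int(args["n_active"]), lo, hi)]
    if variant == "nactive_both_odors":
        n2 = int(args["n_active"])
        return [(n2, lo, hi), (n2, lo, hi)]
    # base: both odors use half the PNs at the default range, the fully
    # matched condition (equal drive, equal active count, equal range)
    # under which stereotypy is expected to vanish
    if variant == "base":
        return [(half, lo, hi), (half, lo, hi)]
    if variant == "shuffled_labels":
        return [(half, lo, hi), None]
    raise ValueError(f"unknown fixed-drive variant {variant!r}; "
                     f"choose from {FIXED_DRIVE_VARIANTS}")


def run_fixed_drive(params: NetworkParams, n_iterations: int = 100,
                    variant: str = "base", variant_args: dict | None = None,
                    seed: int | None = None) -> StereotypyReport:
    """Simulations with the total PN drive fixed for both odors.

    The total PN spike count is pinned to mean rate x (response probability
    x number of PNs) — 500 at the defaults — and distributed over the
    active PNs, isolating the contributions of the active-PN count and the
    spiking-rate range.  ``variant`` manipulates one or both odors' range
    or active count, routes through a calibrated linear KC transfer
    (``linear_*``), or builds odor 2 by shuffling odor 1's PN labels.
    Reports PRED of the total KC input and total KC response.
    """
    if variant not in FIXED_DRIVE_VARIANTS:
        raise ValueError(f"unknown fixed-drive variant {variant!r}; "
                         f"choose from {FIXED_DRIVE_VARIANTS}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    seed = params.seed if seed is None else seed
    total = int(round(params.mean_spike_rate * params.n_pns
                      * params.pn_response_prob))
    # validate the per-odor specs up front so infeasible settings fail fast
    probe = _fixed_drive_specs(params, variant, variant_args, total,
                               np.random.default_rng(0))
    for spec in probe:
        if spec is None:
            continue
        n_active, lo, hi = spec
        if not (n_active * lo <= total <= n_active * hi):
            raise ValueError(
                f"infeasible partition: {total} spikes over {n_active} "
                f"PNs in [{lo}, {hi}]")
    linear = variant.startswith("linear_")
    params2 = params.with_(n_odors=2, n_individuals=2)
    rows, aux_rows = [], []
    for it, rng in enumerate(iteration_rngs(seed, n_iterations)):
        specs = _fixed_drive_specs(params2, variant, variant_args, total, rng)
        spikes = np.zeros((2, params2.n_pns), dtype=int)
        for o, spec in enumerate(specs):
            if spec is None:  # shuffled_labels odor 2
                spikes[o] = spikes[0][rng.permutation(params2.n_pns)]
                continue
            n_active, lo, hi = spec
            active = rng.choice(params2.n_pns, size=n_active, replace=False)
            spikes[o, active] = partition_spikes(total, n_active, lo, hi, rng)
        pair = sample_individual_pair(params2, rng)
        k_all = np.empty((2, 2, params2.n_kcs))  # (individual, odor, kc)
        for ind in range(2):
            k_all[ind] = spikes.astype(float) @ pair.pn_kc[ind]
        t = params2.kc_threshold
        if linear:
            m = calibrate_linear_gain(k_all.reshape(-1, params2.n_kcs), t)
            r_all = m * k_all - t
        else:
            r_all = np.maximum(0.0, k_all - t)
        tot_in = k_all.sum(axis=2)    # (individual, odor)
        tot_resp = r_all.sum(axis=2)
        rows.append((it, "total_kc_input", "pred", _mean_pred_fast(tot_in)))
        rows.append((it, "total_kc_response", "pred",
                     _mean_pred_fast(tot_resp)))
        n_active_kcs = (r_all > 0).sum(axis=2)
        aux_rows.append({
            "iteration": it,
            "n_active_kcs": float(n_active_kcs.mean()),
            "mean_active_rate": float(
                np.mean(np.where(n_active_kcs > 0,
                                 r_all.sum(axis=2) / np.maximum(n_active_kcs, 1),
                                 0.0))),
            "drive_diff": _drive_difference(spikes.sum(axis=1)),
        })
    per_it = pd.DataFrame(rows, columns=["iteration", "quantity", "metric",
                                         "value"])
    return StereotypyReport(
        per_iteration=per_it, aggregates=_aggregate(per_it),
        auxiliaries=pd.DataFrame(aux_rows), params=params2,
        meta={"experiment": "fixed-drive", "variant": variant,
              "variant_args": variant_args or {}, "total_drive": total,
              "n_iterations": n_iterations, "seed": seed})


def _apply_swept(params: NetworkParams, name: str, value) -> NetworkParams:
    if name == "pn_mean_rate":
        mean = int(round(value))
        return params.with_(spike_low=mean - 10, spike_high=mean + 10)
    if name in ("n_kcs", "n_pns"):
        return params.with_(**{name: int(value)})
    if name in ("pn_kc_prob", "kc_threshold", "pn_response_prob"):
        return params.with_(**{name: float(value)})
    raise ValueError(f"unknown swept parameter {name!r}; "
                     f"choose from {SWEEPABLE_PARAMETERS}")


def run_parameter_sweep(params: NetworkParams, n_iterations: int,
                        swept_parameter: str, values,
                        seed: int | None = None) -> pd.DataFrame:
    """Sparseness sweeps: rerun the reference experiment per parameter value.

    Each value yields a full :func:`run_simulation` (two odors and two
    individuals in the standard configuration) and one row of aggregate
    stereotypy plus the mean active-KC count and mean active-KC rate, so
    stereotypy can be plotted against sparseness.
    """
    seed = params.seed if seed is None else seed
    rows = []
    for value in values:
        p2 = _apply_swept(params, swept_parameter, value)
        rep = run_simulation(p2, n_iterations, seed=seed,
                             compute_kc_metrics=False)
        agg = rep.aggregates.set_index(["quantity", "metric"])
        rows.append({
            "parameter": swept_parameter,
            "value": value,
            "pred_total_kc_response": agg.loc[("total_kc_response", "pred"),
                                              "mean"],
            "pred_total_kc_input": agg.loc[("total_kc_input", "pred"), "mean"],
            "pred_mbon": agg.loc[("mbon", "pred"), "mean"],
            "p_total_kc_response": agg.loc[("total_kc_response", "pred"),
                                           "p_value"],
            "n_active_kcs": rep.auxiliaries["n_active_kcs"].mean(),
            "mean_active_rate": rep.auxiliaries["mean_active_rate"].mean(),
            "active_fraction": rep.auxiliaries["active_fraction"].mean(),
        })
    return pd.DataFrame(rows)


def drive_difference_analysis(params: NetworkParams, n_iterations: int = 100,
                              seed: int | None = None):
    """Stereotypy vs |difference in total PN output| over 2-odor iterations.

    Returns ``(per_iteration_table, r_input, r_response)`` where the r's
    are Pearson correlations of the per-iteration PRED of total KC input /
    total KC response against the absolute drive difference (NaN when the
    drive difference is constant across iterations).
    """
    rep = run_simulation(params.with_(n_odors=2, n_individuals=2),
                         n_iterations, seed=seed, compute_kc_metrics=False)
    piv = rep.per_iteration[rep.per_iteration["metric"] == "pred"].pivot(
        index="iteration", columns="quantity", values="value")
    table = pd.DataFrame({
        "iteration": piv.index,
        "drive_diff": rep.auxiliaries.set_index("iteration")["drive_diff"],
        "pred_total_kc_input": piv["total_kc_input"],
        "pred_total_kc_response": piv["total_kc_response"],
    }).reset_index(drop=True)

    def _corr(col):
        x = table["drive_diff"].to_numpy()
        y = table[col].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y).statistic)

    return table, _corr("pred_total_kc_input"), _corr("pred_total_kc_response")


def _pred_two_odors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-odor PRED: a, b are (..., 2) response pairs."""
    s1 = (a[..., 0] - b[..., 0]) ** 2
    s2 = (a[..., 1] - b[..., 1]) ** 2
    c1 = (a[..., 0] - b[..., 1]) ** 2
    c2 = (a[..., 1] - b[..., 0]) ** 2
    d1, d2 = s1 + s2, c1 + c2
    top = np.max(np.stack([s1, s2, c1, c2]), axis=0)
    denom = d1 + d2
    return np.where(denom > 1e-12 * np.maximum(top, 1e-300),
                    (d2 - d1) / np.where(denom == 0, 1.0, denom), 0.0)


def run_convergence_randomness_grid(params: NetworkParams,
                                    n_iterations: int = 100,
                                    grid_size: int = 21,
                                    value_range=(0.01, 1.0),
                                    seed: int | None = None) -> pd.DataFrame:
    """Mean MBON PRED over a log grid of convergence x randomness.

    Convergence c is the KC-MBON connection probability (Bernoulli mask
    shared by both individuals); randomness f is the fraction of PN-KC
    entries set independently in individual 2.  Two odors, two individuals
    per iteration; all iterations of a grid point run as one batched
    computation.  Rows carry the ratio r = c / f for the Hill fit.
    """
    lo, hi = value_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("grid values must lie in (0, 1]")
    seed = params.seed if seed is None else seed
    values = np.logspace(np.log10(lo), np.log10(hi), grid_size)
    children = np.random.SeedSequence(seed).spawn(grid_size * grid_size)
    n_pns, n_kcs = params.n_pns, params.n_kcs
    t = params.kc_threshold
    rows = []
    for idx, (c, f) in enumerate(itertools.product(values, values)):
        rng = np.random.default_rng(children[idx])
        b = n_iterations
        responding = rng.random((b, 2, n_pns)) < params.pn_response_prob
        counts = rng.integers(params.spike_low, params.spike_high + 1,
                              size=(b, 2, n_pns))
        spikes = np.where(responding, counts, 0).astype(np.float32)
        conn_a = rng.random((b, n_pns, n_kcs)) < params.pn_kc_prob
        redraw = rng.random((b, n_pns, n_kcs)) < f
        fresh = rng.random((b, n_pns, n_kcs)) < params.pn_kc_prob
        conn_b = np.where(redraw, fresh, conn_a)
        mask = (rng.random((b, n_kcs)) < c).astype(np.float32)
        mbon = np.empty((2, b, 2))  # (individual, iteration, odor)
        for ind, conn in enumerate((conn_a, conn_b)):
            k = np.einsum("bop,bpk->bok", spikes, conn.astype(np.float32))
            r = np.maximum(np.float32(0.0), k - np.float32(t))
            mbon[ind] = np.maximum(
                0.0, np.einsum("bok,bk->bo", r, mask) - params.mbon_t)
        preds = _pred_two_odors(mbon[0].astype(float), mbon[1].astype(float))
        rows.append({"convergence": c, "randomness": f, "ratio": c / f,
                     "mean_pred": float(preds.mean()),
                     "n_iterations": n_iterations})
    return pd.DataFrame(rows)


def hill_curve(r, a: float, b: float):
    """Hill equation S = r^a / (b + r^a)."""
    ra = np.power(r, a)
    return ra / (b + ra)


def fit_hill(ratios, stereotypies) -> HillFit:
    """Nonlinear least-squares Hill fit of stereotypy against a ratio.

    Initial guess (a, b) = (1, 1), bounds a in (0, 10], b in (0, 100];
    R^2 = 1 - SS_res / SS_tot on the provided points.  Constant stereotypy
    values give a degenerate fit flagged with R^2 = 0.
    """
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(stereotypies, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 points for a Hill fit")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    if np.ptp(s) == 0:
        return HillFit(a=float("nan"), b=float("nan"), r_squared=0.0,
                       n_points=int(r.size), degenerate=True)
    try:
        popt, _ = optimize.curve_fit(
            hill_curve, r, s, p0=(1.0, 1.0),
            bounds=((1e-12, 1e-12), (10.0, 100.0)),
            xtol=1e-10, ftol=1e-10, maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Hill fit did not converge from (a, b) = (1, 1); "
            f"residual sd of data = {s.std():.4g}") from err
    a, b = (float(v) for v in popt)
    resid = s - hill_curve(r, a, b)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((s - s.mean()) ** 2).sum())
    return HillFit(a=a, b=b, r_squared=1.0 - ss_res / ss_tot,
                   n_points=int(r.size))
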