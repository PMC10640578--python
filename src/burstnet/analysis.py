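"""Statistical analysis of constructed or observed temporal networks.

Extraction of inter-event and inter-communication gaps, maximum-
likelihood fits of the discrete waiting-time families, burstiness and
autocorrelation summaries, and time-aggregated weighted networks with
the node-strength normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .construction import TemporalNetwork
from .errors import EstimationError, ParameterError

__all__ = [
    "IntervalSample",
    "FitResult",
    "BurstinessSummary",
    "AggregatedNetwork",
    "extract_intervals",
    "pooled",
    "fit_discrete_power_law",
    "fit_discrete_exponential",
    "burstiness_and_memory",
    "aggregate_and_strengths",
    "normalized_strength_survival",
]

_MODES = ("node_iet", "link_iet", "node_ict")


@dataclass
class IntervalSample:
    """Waiting-time gaps of one unit (or of all units pooled).

    ``windows``, when present, holds the observation-window length the
    unit was watched for (per gap) — used by the censoring-aware fits.
    """

    unit: object
    mode: str
    gaps: np.ndarray
    windows: np.ndarray | None = None

    def __post_init__(self):
        self.gaps = np.asarray(self.gaps, dtype=np.int64)
        if self.mode not in _MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if len(self.gaps) and self.gaps.min() < 1:
            raise ParameterError("gaps must be >= 1")
        if self.windows is not None:
            self.windows = np.asarray(self.windows, dtype=np.int64)
            if self.windows.shape != self.gaps.shape:
                raise ParameterError("windows must align with gaps")


def _gaps_from_series(series: np.ndarray) -> np.ndarray:
    """Differences of consecutive active times; the censored final open
    interval carries no gap."""
    times = np.flatnonzero(series)
    return np.diff(times)


def extract_intervals(net: TemporalNetwork, mode: str,
                      scope: str = "per_unit"):
    """Collect waiting-time gaps from a constructed network.

    ``node_iet`` — gaps between consecutive active states of each node;
    ``link_iet`` — likewise for each link (branch states derived from
    the endpoints); ``node_ict`` — gaps between consecutive times a node
    has at least one active incident link, which is what contact data
    record.  ``scope="aggregated"`` pools all units into one sample.
    """
    if net.node_states.shape[0] < 2:
        raise ParameterError("need at least 2 time steps")
    if mode == "node_iet":
        samples = []
        for i in net.node_ids:
            gaps = _gaps_from_series(net.node_series(i))
            win = net.t_tol - int(net.birth[net.columns[i]])
            samples.append(IntervalSample(
                i, mode, gaps, windows=np.full(len(gaps), win)))
    elif mode == "link_iet":
        samples = [IntervalSample(e, mode,
                                  _gaps_from_series(net.link_series(*e)))
                   for e in sorted(net.all_edges())]
    elif mode == "node_ict":
        samples = []
        for i in net.node_ids:
            nbrs = [j for j in net.graph.adj[i]]
            if not nbrs:
                samples.append(IntervalSample(i, mode, np.zeros(0, int)))
                continue
            any_link = np.zeros(net.node_states.shape[0], dtype=bool)
            for j in nbrs:
                any_link |= net.link_series(i, j)
            samples.append(IntervalSample(i, mode,
                                          _gaps_from_series(any_link)))
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    if scope == "per_unit":
        return samples
    if scope == "aggregated":
        return pooled(samples)
    raise ParameterError(f"unknown scope {scope!r}")


def intervals_from_contacts(events, mode: str):
    """Per-unit gap samples straight from a contact-event stream.

    ``node_ict`` — gaps between consecutive steps at which a node
    appears in any contact; ``link_iet`` — gaps between consecutive
    contacts of each pair.  This is what empirical contact data support
    (node IETs are not observable there).
    """
    if mode not in ("node_ict", "link_iet"):
        raise ParameterError(f"mode {mode!r} not derivable from contacts")
    times = {}
    for ev in events:
        if mode == "node_ict":
            times.setdefault(ev.i, set()).add(ev.t)
            times.setdefault(ev.j, set()).add(ev.t)
        else:
            times.setdefault((ev.i, ev.j), set()).add(ev.t)
    return [IntervalSample(unit, mode, np.diff(sorted(ts)))
            for unit, ts in sorted(times.items(), key=lambda kv: str(kv[0]))]


def pooled(samples) -> IntervalSample:
    """Concatenate per-unit samples into one aggregated sample."""
    if not samples:
        raise ParameterError("no samples to pool")
    gaps = np.concatenate([s.gaps for s in samples])
    windows = None
    if all(s.windows is not None for s in samples):
        windows = np.concatenate([s.windows for s in samples])
    return IntervalSample("pooled", samples[0].mode, gaps, windows=windows)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    family: str
    exponent_hat: float
    xmin: int
    n_samples: int
    ks_distance: float
    se: float = float("nan")
    boundary: bool = False


def _as_gaps(sample) -> np.ndarray:
    gaps = sample.gaps if isinstance(sample, IntervalSample) \
        else np.asarray(sample, dtype=np.int64)
    if len(gaps) and gaps.min() < 1:
        raise ParameterError("gaps must be >= 1")
    return gaps


def fit_discrete_power_law(sample, xmin: int = 1, min_samples: int = 50,
                           scan_xmin: bool = False,
                           window: int | None = None) -> FitResult:
    """Discrete power-law MLE, ``pmf(g) = g**-a / zeta(a, xmin)``.

    The exponent maximizes the Hurwitz-zeta-normalized likelihood over
    gaps >= xmin.  With ``scan_xmin`` the cutoff is chosen by the usual
    KS minimization over candidate cutoffs; by default the full range
    (xmin = 1) is fit.  Standard error from observed Fisher information.

    ``window=T`` switches to the completed-interval likelihood for gaps
    harvested from a horizon of T steps, ``q(g) ∝ g**-a * (T - g + 1)``:
    long gaps are under-observed because they cannot complete inside the
    window, which biases the plain MLE upward by ~(a-1)/T-level terms.
    ``window`` may also be an array of per-gap window lengths (units
    observed for different durations, e.g. on growing topologies).
    """
    gaps = _as_gaps(sample)
    win_arr = None
    if window is not None and np.ndim(window) != 0:
        win_arr = np.asarray(window, dtype=np.int64)
        if win_arr.shape != gaps.shape:
            raise ParameterError("per-gap windows must align with gaps")
        win_arr = win_arr[gaps >= xmin]
        window = None if len(win_arr) == 0 else win_arr
    if scan_xmin:
        if win_arr is not None:
            raise ParameterError("scan_xmin with per-gap windows is not "
                                 "supported")
        candidates = np.unique(gaps)
        candidates = candidates[candidates <= np.quantile(gaps, 0.9)]
        best = None
        for xm in candidates:
            if np.count_nonzero(gaps >= xm) < min_samples:
                break
            r = fit_discrete_power_law(gaps, xmin=int(xm),
                                       min_samples=min_samples,
                                       window=window)
            if best is None or r.ks_distance < best.ks_distance:
                best = r
        if best is None:
            raise EstimationError("no viable xmin candidate")
        return best

    gaps = gaps[gaps >= xmin]
    n = len(gaps)
    if n < min_samples:
        raise EstimationError(f"need >= {min_samples} gaps, got {n}")
    if gaps.min() == gaps.max():
        raise EstimationError("degenerate sample: all gaps equal")
    slog = float(np.log(gaps).sum())

    if window is None:
        def log_norm(a):
            return math.log(special.zeta(a, xmin))
    elif win_arr is None:
        if gaps.max() > window:
            raise ParameterError("observed gap exceeds the window length")
        h = np.arange(xmin, window + 1, dtype=float)
        log_h, log_w = np.log(h), np.log(window - h + 1.0)

        def log_norm(a):
            x = -a * log_h + log_w
            m = x.max()
            return float(m + np.log(np.exp(x - m).sum()))
    else:
        if np.any(gaps > win_arr):
            raise ParameterError("observed gap exceeds its window length")
        t_vals, t_counts = np.unique(win_arr, return_counts=True)
        h = np.arange(xmin, int(t_vals.max()) + 1, dtype=float)
        idx = (t_vals - xmin).astype(np.int64)

        def log_norm(a):
            # S(a, T) = sum_{h<=T} h^-a (T - h + 1)
            #         = (T + 1) A(T) - B(T) via two cumulative sums
            A = np.cumsum(h ** (-a))
            B = np.cumsum(h ** (1.0 - a))
            S = (t_vals + 1.0) * A[idx] - B[idx]
            return float(t_counts @ np.log(S)) / n

    def nll(a):
        return a * slog + n * log_norm(a)

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-9, 25.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    a_hat = float(res.x)
    # observed information per sample = (log normalizer)''(a_hat)
    eps = 1e-5
    lz = [log_norm(a_hat + d) for d in (-eps, 0.0, eps)]
    info = (lz[0] - 2 * lz[1] + lz[2]) / eps ** 2
    se = 1.0 / math.sqrt(n * info) if info > 0 else float("nan")
    gmax = int(gaps.max())
    if window is None:
        cdf = _power_law_cdf(a_hat, xmin, gmax)
    elif win_arr is None:
        q = h ** (-a_hat) * (window - h + 1.0)
        cdf = np.cumsum(q / q.sum())[:gmax - xmin + 1]
    else:
        # mixture of per-window laws, weighted by gap counts
        g = np.arange(xmin, gmax + 1, dtype=float)
        A = np.cumsum(h ** (-a_hat))
        B = np.cumsum(h ** (1.0 - a_hat))
        S = (t_vals + 1.0) * A[idx] - B[idx]
        W = np.clip(t_vals[:, None] - g[None, :] + 1.0, 0.0, None) \
            * g[None, :] ** (-a_hat) / S[:, None]
        cdf = np.cumsum((t_counts / n) @ W)
    ks = _ks_distance(gaps, cdf, xmin)
    return FitResult(family="power_law", exponent_hat=a_hat, xmin=int(xmin),
                     n_samples=n, ks_distance=ks, se=se)


def fit_discrete_exponential(sample, min_samples: int = 50) -> FitResult:
    """Closed-form MLE of the discrete-exponential (geometric) rate.

    The geometric pmf ``(1 - q) q**(g - 1)`` has MLE ``q = 1 - 1/mean``;
    the rate is ``alpha = -log(q)``.  A sample with all gaps equal to 1
    pushes the rate to infinity and is flagged as a boundary fit.
    """
    gaps = _as_gaps(sample)
    n = len(gaps)
    if n < min_samples:
        raise EstimationError(f"need >= {min_samples} gaps, got {n}")
    mean = float(gaps.mean())
    if mean <= 1.0:
        return FitResult(family="discrete_exponential",
                         exponent_hat=float("inf"), xmin=1, n_samples=n,
                         ks_distance=float("nan"), boundary=True)
    q = 1.0 - 1.0 / mean
    a_hat = -math.log(q)
    # delta method through the sample mean
    d_dm = 1.0 / (mean * (mean - 1.0))
    se = d_dm * float(gaps.std(ddof=1)) / math.sqrt(n)
    gmax = int(gaps.max())
    cdf = 1.0 - q ** np.arange(1, gmax + 1, dtype=float)
    ks = _ks_distance(gaps, cdf, 1)
    return FitResult(family="discrete_exponential", exponent_hat=a_hat,
                     xmin=1, n_samples=n, ks_distance=ks, se=se)


def _power_law_cdf(a, xmin, gmax):
    g = np.arange(xmin, gmax + 1, dtype=float)
    pmf = g ** (-a) / special.zeta(a, xmin)
    return np.cumsum(pmf)


def _ks_distance(gaps, model_cdf, xmin):
    gmax = len(model_cdf) + xmin - 1
    counts = np.bincount(gaps, minlength=gmax + 1)[xmin:]
    ecdf = np.cumsum(counts) / len(gaps)
    return float(np.max(np.abs(ecdf - model_cdf)))


# ---------------------------------------------------------------------------
# burstiness and memory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstinessSummary:
    B: float
    autocorrelation: dict = field(default_factory=dict)


def burstiness_and_memory(sample, activity_series=None,
                          max_lag: int = 20) -> BurstinessSummary:
    """Burstiness ``B = (sigma - mu)/(sigma + mu)`` of the gaps, plus the
    autocorrelation of a binary activity series (mean-centered, biased
    normalization) up to ``max_lag``."""
    gaps = _as_gaps(sample)
    if len(gaps) < 2:
        raise ParameterError("need >= 2 gaps")
    mu = float(gaps.mean())
    sigma = float(gaps.std())
    if sigma + mu == 0:
        raise ParameterError("degenerate gaps: zero mean and variance")
    B = (sigma - mu) / (sigma + mu)
    acf = {}
    if activity_series is not None:
        x = np.asarray(activity_series, dtype=float)
        x = x - x.mean()
        denom = float(x @ x)
        if denom == 0:
            raise ParameterError("constant activity series")
        for lag in range(0, max_lag + 1):
            acf[lag] = float(x[:len(x) - lag] @ x[lag:]) / denom if lag \
                else 1.0
    return BurstinessSummary(B=B, autocorrelation=acf)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregatedNetwork:
    """Weighted graph of per-edge activation counts over [1, t_agg]."""

    t_agg: int
    t_base: int
    edge_weights: dict
    node_strengths: dict


def aggregate_and_strengths(net: TemporalNetwork, t_agg: int,
                            t_base: int | None = None) -> AggregatedNetwork:
    """Aggregate link activations from t = 1 to ``t_agg``.

    Edge weights count active-link events; node strengths sum incident
    weights.  ``t_base`` (default ``t_agg``) is the baseline used by the
    strength normalization ``t_base / t_agg``.
    """
    t_base = t_agg if t_base is None else t_base
    if not (1 <= t_base <= t_agg <= net.t_tol):
        raise ParameterError("need 1 <= t_base <= t_agg <= t_tol")
    edges = sorted(net.all_edges())
    S = net.node_states[1:t_agg + 1]
    ci = np.array([net.columns[e[0]] for e in edges], dtype=np.int64)
    cj = np.array([net.columns[e[1]] for e in edges], dtype=np.int64)
    co = (S[:, ci] & S[:, cj])
    if net.edge_intervals:
        for k, e in enumerate(edges):
            mask = np.zeros(t_agg, dtype=bool)
            for a, b in net.edge_intervals.get(e, [(net.edge_birth.get(e, 0),
                                                    net.t_tol + 1)]):
                mask[max(a - 1, 0):b - 1] = True
            co[:, k] &= mask
    elif net.edge_birth:
        for k, e in enumerate(edges):
            b = net.edge_birth.get(e, 0)
            if b > 0:
                co[:b - 1, k] = False
    weights = co.sum(axis=0)
    edge_weights = {e: int(w) for e, w in zip(edges, weights)}
    strengths = {i: 0 for i in net.node_ids}
    for e, w in edge_weights.items():
        strengths[e[0]] += int(w)
        strengths[e[1]] += int(w)
    return AggregatedNetwork(t_agg=t_agg, t_base=t_base,
                             edge_weights=edge_weights,
                             node_strengths=strengths)


def normalized_strength_survival(agg: AggregatedNetwork):
    """Survival function of node strengths scaled by ``t_base / t_agg``.

    Returns ``(values, survival)`` where ``survival[k] = P(strength >
    values[k])`` over nodes, evaluated at the sorted scaled strengths.
    """
    scale = agg.t_base / agg.t_agg
    vals = np.sort(np.array(list(agg.node_strengths.values()), dtype=float)
                   * scale)
    n = len(vals)
    surv = 1.0 - np.arange(1, n + 1) / n
    return vals, surv
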