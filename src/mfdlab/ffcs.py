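"""Species-filtered fluorescence correlation spectroscopy (fFCS).

Builds species filters from reference TCSPC decay patterns (statistical
unmixing with an unbiasedness constraint), applies them photon-by-photon
to compute species auto- (sACF) and cross-correlation (sCCF) functions
on a quasi-logarithmic multi-tau lag grid, and fits
diffusion × relaxation models.  Anticorrelated sCCF terms report the
interconversion kinetics between the species — the route by which
exchange faster than the diffusion time becomes measurable.

The correlator counts photon pairs directly (no binning of the time
axis), normalised so an uncorrelated Poisson stream gives G = 1 at all
lags; statistical weights follow from the spread over trace segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simkit import PhotonStream

__all__ = [
    "FilterSet", "CorrelationCurve", "RelaxationFit",
    "decay_pattern", "build_filters", "photon_weights",
    "make_lag_grid", "correlate", "fit_relaxations",
]

N_CHANNELS = 4


@dataclass
class FilterSet:
    """Per-species photon weights over (channel, micro-time bin)."""

    labels: tuple
    weights: np.ndarray          # (n_species, n_channels * n_micro_bins)
    micro_edges: np.ndarray      # ns
    patterns: np.ndarray         # normalised reference patterns, same layout

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def unbiasedness_error(self) -> float:
        """max |F·Dᵀ − I|; < 1e-6 by construction for valid inputs."""
        gram = self.weights @ self.patterns.T
        return float(np.max(np.abs(gram - np.eye(self.n_species))))


@dataclass
class CorrelationCurve:
    lag: np.ndarray              # s, strictly increasing
    G: np.ndarray
    sd: np.ndarray               # standard error over segments
    kind: str                    # "sACF", "sCCF" or "ACF"
    species: tuple               # (label_1, label_2)


@dataclass
class RelaxationFit:
    diffusion_time: float        # ms
    relaxation_times: np.ndarray  # s, ascending
    amplitudes: np.ndarray       # matching order; negative = anticorrelation
    anticorrelated: np.ndarray   # bool flags
    amplitude: float             # overall correlation amplitude (≈1/N)
    offset: float
    chi2_r: float
    converged: bool


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def decay_pattern(stream: PhotonStream, micro_edges) -> np.ndarray:
    """Counts over (channel, micro-time bin), flattened channel-major."""
    micro_edges = np.asarray(micro_edges, float)
    nb = micro_edges.size - 1
    out = np.zeros((N_CHANNELS, nb))
    for c in range(N_CHANNELS):
        sel = stream.channels == c
        h, _ = np.histogram(stream.micro_times[sel], bins=micro_edges)
        out[c] = h
    return out.ravel()


def build_filters(reference_decays: dict, micro_edges,
                  mixture_pattern=None, cond_limit: float = 1e10) -> FilterSet:
    """Solve the constrained unmixing problem for species filters.

    ``reference_decays`` maps species label → raw decay pattern
    (flattened (channel, micro-bin) counts, as from
    :func:`decay_pattern`).  Filters F minimise the photon-count
    variance subject to F·Dᵀ = I (applied to a pure normalised species
    pattern, the filter returns 1 for that species, 0 for others):

        F = (D W Dᵀ)⁻¹ D W,   W = diag(1/M),

    with M the mixture pattern (sum of references unless given).
    Raises on (near-)collinear patterns, reporting the condition number.
    """
    labels = tuple(reference_decays)
    if len(labels) < 2:
        raise ValueError("need at least 2 reference decay patterns")
    D = np.array([np.asarray(reference_decays[k], float) for k in labels])
    if np.any(D.sum(axis=1) <= 0):
        raise ValueError("reference pattern with no counts")
    D = D / D.sum(axis=1, keepdims=True)
    M = np.asarray(mixture_pattern, float) if mixture_pattern is not None \
        else np.array([np.asarray(reference_decays[k], float) for k in labels]).sum(axis=0)
    M = M / M.sum()
    w = np.where(M > 0, 1.0 / np.maximum(M, 1e-12), 0.0)
    DW = D * w
    gram = DW @ D.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(
            f"reference decay patterns are (near-)collinear: condition "
            f"number {cond:.3g} exceeds {cond_limit:.3g}")
    F = np.linalg.solve(gram, DW)
    return FilterSet(labels=labels, weights=F,
                     micro_edges=np.asarray(micro_edges, float), patterns=D)


def photon_weights(stream: PhotonStream, filters: FilterSet) -> np.ndarray:
    """Per-photon species weights, shape (n_species, n_photons)."""
    nb = filters.micro_edges.size - 1
    b = np.clip(np.searchsorted(filters.micro_edges, stream.micro_times,
                                side="right") - 1, 0, nb - 1)
    idx = stream.channels.astype(int) * nb + b
    return filters.weights[:, idx]


# ---------------------------------------------------------------------------
# Correlator
# ---------------------------------------------------------------------------

def make_lag_grid(min_lag: float = 2e-7, max_lag: float = 0.05,
                  n_per_cascade: int = 16) -> np.ndarray:
    """Quasi-logarithmic multi-tau lag-bin edges (seconds).

    The first cascade is linear with spacing ``min_lag``; each further
    cascade doubles the spacing and adds ``n_per_cascade // 2`` edges.
    """
    edges = list(min_lag * np.arange(1, n_per_cascade + 1))
    delta = min_lag
    while edges[-1] < max_lag:
        delta *= 2.0
        for _ in range(n_per_cascade // 2):
            edges.append(edges[-1] + delta)
            if edges[-1] >= max_lag:
                break
    return np.asarray(edges)


def _segment_pair_sums(t, W, edges, T):
    """G per lag bin for every ordered weight-vector pair.

    The (shared) photon-pair index windows per lag bin are computed
    once; each species pair then only needs cumulative-weight sums.
    Returns an array of shape (n_species, n_species, n_bins).
    """
    ns = W.shape[0]
    cums = np.concatenate([np.zeros((ns, 1)), np.cumsum(W, axis=1)], axis=1)
    rates = cums[:, -1] / T
    G = np.full((ns, ns, edges.size - 1), np.nan)
    for b in range(edges.size - 1):
        lo, hi = edges[b], edges[b + 1]
        # restrict left photons so the full lag window fits in the trace
        imax = np.searchsorted(t, T - hi, side="right")
        if imax == 0:
            continue
        ts = t[:imax]
        left = np.searchsorted(t, ts + lo, side="left")
        right = np.searchsorted(t, ts + hi, side="left")
        span = cums[:, right] - cums[:, left]          # (ns, imax)
        S = W[:, :imax] @ span.T                        # (ns_i, ns_j)
        W1_eff = cums[:, imax]
        denom = np.outer(W1_eff, rates) * (hi - lo)
        with np.errstate(invalid="ignore", divide="ignore"):
            G[..., b] = np.where(denom > 0, S / denom, np.nan)
    return G


def correlate(stream: PhotonStream, filters: FilterSet | None = None,
              min_lag: float = 2e-7, max_lag: float = 0.05,
              n_per_cascade: int = 16, n_segments: int = 8) -> list:
    """Species correlation curves on a multi-tau grid.

    With ``filters=None`` returns the ordinary intensity ACF (all
    weights 1).  Otherwise returns the sACF of every species and the
    sCCF of every ordered species pair.  Curves carry the standard
    error over ``n_segments`` trace segments (Wohland-style weights).
    """
    n = len(stream)
    if n < 1e4:
        warnings.warn(f"only {n} photons: correlation will be noisy",
                      stacklevel=2)
    T_total = stream.duration
    if T_total <= max_lag * n_segments:
        raise ValueError("stream too short for the requested lag range")
    edges = make_lag_grid(min_lag, max_lag, n_per_cascade)
    t = stream.macro_times
    if filters is None:
        W = np.ones((1, n))
        labels = ("all",)
    else:
        W = photon_weights(stream, filters)
        labels = filters.labels
    ns = W.shape[0]
    pairs = [(i, j) for i in range(ns) for j in range(ns)]

    seg_edges = np.linspace(0.0, T_total, n_segments + 1)
    seg_G = []
    for s in range(n_segments):
        a = np.searchsorted(t, seg_edges[s], side="left")
        b = np.searchsorted(t, seg_edges[s + 1], side="left")
        if b - a < 2:
            continue
        ts = t[a:b] - seg_edges[s]
        Tseg = seg_edges[s + 1] - seg_edges[s]
        seg_G.append(_segment_pair_sums(ts, W[:, a:b], edges, Tseg))

    lag = np.sqrt(edges[:-1] * edges[1:])
    curves = []
    for (i, j) in pairs:
        arr = np.array([g[i, j] for g in seg_G])
        if arr.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            G = np.nanmean(arr, axis=0)
            nseg_eff = np.sum(np.isfinite(arr), axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(nseg_eff, 1))
        if filters is None:
            kind = "ACF"
        else:
            kind = "sACF" if i == j else "sCCF"
        curves.append(CorrelationCurve(lag=lag, G=G, sd=sd, kind=kind,
                                       species=(labels[i], labels[j])))
    return curves


# ---------------------------------------------------------------------------
# Relaxation fitting
# ---------------------------------------------------------------------------

def _diffusion_term(tau, t_diff_s, model, aspect):
    if model == "exponential":
        return np.exp(-tau / t_diff_s)
    if model == "gaussian3d":
        return 1.0 / ((1.0 + tau / t_diff_s)
                      * np.sqrt(1.0 + tau / (aspect ** 2 * t_diff_s)))
    raise ValueError("diffusion model must be 'exponential' or 'gaussian3d'")


def fit_relaxations(curve: CorrelationCurve, n_components: int,
                    diffusion: str = "exponential", aspect: float = 4.0,
                    seed: int = 0, n_starts: int = 8,
                    t_diff_fixed: float | None = None) -> RelaxationFit:
    """Fit G(τ) = 1 + a·diff(τ)·(1 + Σ A_i·exp(−τ/t_i)).

    ``diffusion`` selects the transit term: ``"exponential"`` for a
    top-hat detection volume (exponential dwell) or ``"gaussian3d"`` for
    the 3D-Gaussian profile.  Negative fitted A_i flag anticorrelated
    (exchange) terms.  ``t_diff_fixed`` (ms) pins the diffusion time —
    the usual practice for species curves, where it is taken from the
    unfiltered intensity ACF of the same measurement.  Deterministic
    given bounds and the multi-start seed; a non-convergent fit is
    returned flagged, not raised.
    """
    ok = np.isfinite(curve.G) & np.isfinite(curve.lag)
    tau = curve.lag[ok]
    G = curve.G[ok]
    sd = curve.sd[ok] if curve.sd is not None else np.ones_like(G)
    good_sd = np.isfinite(sd) & (sd > 0)
    if good_sd.any():
        # bins estimated from a single trace segment carry no spread
        # estimate: weight them like the noisiest well-estimated bin
        sd = np.where(good_sd, sd, sd[good_sd].max())
        floor = max(1e-4, 0.05 * np.median(sd[good_sd]))
    else:
        sd = np.ones_like(G)
        floor = 1e-3
    w = 1.0 / np.maximum(sd, floor)
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    nc = n_components

    amp0 = max(G[0] - G[-1], 1e-3)
    # crude diffusion-time guess: lag where the decay passes half amplitude
    if t_diff_fixed is not None:
        td0 = t_diff_fixed * 1e-3
    else:
        below = np.flatnonzero(G < 1.0 + amp0 / 2.0)
        td0 = tau[below[0]] if below.size else tau[tau.size // 2]
    td0 = max(td0, tau[0] * 20.0)

    def model_fn(p):
        a, td = p[0], p[1]
        out = np.ones_like(tau) * p[2]
        relax = np.ones_like(tau)
        for i in range(nc):
            A, ti = p[3 + 2 * i], p[4 + 2 * i]
            relax = relax + A * np.exp(-tau / ti)
        return out + a * _diffusion_term(tau, td, diffusion, aspect) * relax

    def resid(p):
        return (model_fn(p) - G) * w

    # relaxation terms slower than the transit decay are masked by the
    # diffusion envelope and degenerate with its amplitude: cap t_i
    t_hi = min(tau[-1], 2.0 * td0)
    if t_diff_fixed is not None:
        td_s = t_diff_fixed * 1e-3
        lo = [0.0, td_s * (1 - 1e-9), 0.5] + [-5.0, tau[0]] * nc
        hi = [np.inf, td_s * (1 + 1e-9), 1.5] + [5.0, t_hi] * nc
    else:
        lo = [0.0, tau[0], 0.5] + [-5.0, tau[0]] * nc
        hi = [np.inf, 10.0, 1.5] + [5.0, t_hi] * nc
    rng = np.random.default_rng(seed)
    starts = []
    base_times = np.geomspace(max(tau[0] * 3, 1e-7), td0, max(nc, 1))
    first = [amp0, td0, 1.0]
    for i in range(nc):
        first += [-0.3 if curve.kind == "sCCF" else 0.3, base_times[i]]
    starts.append(np.array(first))
    for _ in range(max(0, n_starts - 1)):
        p = [amp0 * rng.uniform(0.3, 3.0), td0 * rng.uniform(0.3, 3.0), 1.0]
        for i in range(nc):
            p += [rng.uniform(-1.0, 1.0),
                  float(np.exp(rng.uniform(np.log(tau[0] * 2), np.log(td0))))]
        starts.append(np.array(p))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, np.asarray(lo) + 1e-12, np.asarray(hi) - 1e-12)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        cost = float(np.sum(sol.fun ** 2))
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        return RelaxationFit(np.nan, np.empty(0), np.empty(0),
                             np.empty(0, bool), np.nan, np.nan, np.nan, False)
    cost, sol = best
    p = sol.x
    times = np.array([p[4 + 2 * i] for i in range(nc)])
    amps = np.array([p[3 + 2 * i] for i in range(nc)])
    order = np.argsort(times)
    dof = max(tau.size - p.size, 1)
    return RelaxationFit(
        diffusion_time=float(p[1] * 1e3),
        relaxation_times=times[order],
        amplitudes=amps[order],
        anticorrelated=amps[order] < 0,
        amplitude=float(p[0]),
        offset=float(p[2]),
        chi2_r=cost / dof,
        converged=bool(sol.success),
    )


def fit_relaxations_global(curves, n_components: int,
                           diffusion: str = "exponential",
                           aspect: float = 4.0, seed: int = 0,
                           n_starts: int = 8,
                           t_diff_fixed: float | None = None):
    """Globally fit several species curves with shared relaxation times.

    The relaxation times t_i are common to all curves (they reflect the
    same exchange kinetics); the correlation amplitude, baseline and
    term amplitudes A_i are free per curve.  This is the standard way
    to analyse the sACF/sCCF set of one measurement and is markedly
    more precise than averaging independent single-curve fits when the
    per-curve pair statistics are thin.  Returns (times, fits): the
    shared times (s, ascending) and one :class:`RelaxationFit` per
    curve holding that curve's amplitudes against the shared times.
    """
    if not curves:
        raise ValueError("need at least one curve")
    nc = n_components
    if nc < 1:
        raise ValueError("the global fit needs n_components >= 1")
    data = []
    for c in curves:
        ok = np.isfinite(c.G) & np.isfinite(c.lag)
        tau = c.lag[ok]
        G = c.G[ok]
        sd = c.sd[ok]
        good = np.isfinite(sd) & (sd > 0)
        if good.any():
            sd = np.where(good, sd, sd[good].max())
            floor = max(1e-4, 0.05 * np.median(sd[good]))
        else:
            sd = np.ones_like(G)
            floor = 1e-3
        data.append((tau, G, 1.0 / np.maximum(sd, floor), c.kind))

    tau0 = min(d[0][0] for d in data)
    tau_last = max(d[0][-1] for d in data)
    if t_diff_fixed is not None:
        td0 = t_diff_fixed * 1e-3
    else:
        td0 = tau_last / 10.0
    td0 = max(td0, tau0 * 20.0)
    t_hi = min(tau_last, 2.0 * td0)

    m = len(data)
    # layout: [log t_1..t_nc] + per curve [a, offset, td, A_1..A_nc]
    per = 3 + nc

    def unpack(p):
        times = np.exp(p[:nc])
        rest = p[nc:].reshape(m, per)
        return times, rest

    def resid(p):
        times, rest = unpack(p)
        out = []
        for (tau, G, w, _), row in zip(data, rest):
            a, off, td = row[0], row[1], row[2]
            relax = np.ones_like(tau)
            for i in range(nc):
                relax = relax + row[3 + i] * np.exp(-tau / times[i])
            model = off + a * _diffusion_term(tau, td, diffusion,
                                              aspect) * relax
            out.append((model - G) * w)
        return np.concatenate(out)

    lo_t = [np.log(tau0)] * nc
    hi_t = [np.log(t_hi)] * nc
    if t_diff_fixed is not None:
        td_s = t_diff_fixed * 1e-3
        lo_c = [0.0, 0.5, td_s * (1 - 1e-9)] + [-5.0] * nc
        hi_c = [np.inf, 1.5, td_s * (1 + 1e-9)] + [5.0] * nc
    else:
        lo_c = [0.0, 0.5, tau0] + [-5.0] * nc
        hi_c = [np.inf, 1.5, 10.0] + [5.0] * nc
    lo = np.array(lo_t + lo_c * m)
    hi = np.array(hi_t + hi_c * m)

    rng = np.random.default_rng(seed)
    starts = []
    base_times = np.geomspace(max(tau0 * 5, 1e-7), td0 / 2, max(nc, 1))
    first = list(np.log(base_times))
    for (tau, G, w, kind) in data:
        amp0 = max(G[0] - G[-1], 1e-3)
        first += [amp0, 1.0, td0] + \
            [-0.3 if kind == "sCCF" else 0.3] * nc
    starts.append(np.array(first))
    for _ in range(max(0, n_starts - 1)):
        p = list(rng.uniform(np.log(tau0 * 5), np.log(t_hi * 0.8), nc))
        for (tau, G, w, kind) in data:
            amp0 = max(G[0] - G[-1], 1e-3)
            p += [amp0 * rng.uniform(0.3, 3.0), 1.0,
                  td0 * rng.uniform(0.5, 2.0)]
            p += list(rng.uniform(-1.0, 1.0, nc))
        starts.append(np.array(p))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                max_nfev=4000)
        except Exception:
            continue
        cost = float(np.sum(sol.fun ** 2))
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise RuntimeError("global relaxation fit failed to converge")
    cost, sol = best
    times, rest = unpack(sol.x)
    order = np.argsort(times)
    times = times[order]
    n_points = sum(d[0].size for d in data)
    chi2_r = cost / max(n_points - sol.x.size, 1)
    fits = []
    for (tau, G, w, kind), row in zip(data, rest):
        amps = row[3:][order]
        fits.append(RelaxationFit(
            diffusion_time=float(row[2] * 1e3),
            relaxation_times=times.copy(),
            amplitudes=amps,
            anticorrelated=amps < 0,
            amplitude=float(row[0]),
            offset=float(row[1]),
            chi2_r=chi2_r,
            converged=bool(sol.success),
        ))
    return times, fits
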