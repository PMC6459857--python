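"""Shot-noise-limited Probability Distribution Analysis (PDA).

PDA predicts the full histogram of a window-wise observable — the
FRET-averaged distance ⟨R_DA⟩_E or the anisotropy r_D — from a small
set of conformational states, by propagating each state's (Gaussian)
observable distribution through the binomial photon-partition noise of
the actual per-window photon counts.  Because the photon-count
distribution is taken from the data, the only free parameters are the
state means, half-widths and fractions; shot-noise broadening is
predicted, not fitted.  Fits are global over several time-window
lengths Δt, which pins long-lived states: a static species must show
Δt-independent fractions.

Conventions: state observable distributions are Gaussian in distance
(FRET) or anisotropy (smFA), truncated at physical bounds; window
observables are computed from raw counts with the same estimator used
in :mod:`mfdlab.bursts` (γ = 1 unless set on the model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .simkit import CH_G_PAR, CH_G_PERP, CH_R_PAR, CH_R_PERP

__all__ = [
    "PDAState", "PDAModel", "PDAData", "PDAFit", "PDAError",
    "pda_data_from_windows", "pda_predict", "pda_fit", "model_compare",
]


class PDAError(ValueError):
    pass


@dataclass(frozen=True)
class PDAState:
    """One shot-noise-limited state: Gaussian observable distribution."""

    kind: str                # "fret" or "anisotropy"
    mean: float              # Å (fret) or dimensionless (anisotropy)
    half_width: float        # same units (Gaussian sigma)
    fraction: float

    def __post_init__(self):
        if self.kind not in ("fret", "anisotropy"):
            raise ValueError("kind must be 'fret' or 'anisotropy'")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if self.kind == "fret" and self.mean <= 0:
            raise ValueError("FRET state mean distance must be > 0")


@dataclass(frozen=True)
class PDAModel:
    """A set of states plus nuisance parameters.

    ``acceptor_brightness_sd`` is the relative s.d. of a multiplicative
    Gaussian factor on the red detection efficiency, modelling
    molecule-to-molecule acceptor brightness variation.
    """

    states: tuple
    R0: float = 53.0
    gamma: float = 1.0
    acceptor_brightness_sd: float = 0.0

    def __post_init__(self):
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if not states:
            raise ValueError("need at least one state")
        tot = sum(s.fraction for s in states)
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"state fractions must sum to 1 (got {tot})")
        kinds = {s.kind for s in states}
        if len(kinds) != 1:
            raise ValueError("all states must share one observable kind")

    @property
    def kind(self) -> str:
        return self.states[0].kind


@dataclass
class PDAData:
    """One observed histogram with its photon-count distribution."""

    kind: str
    bin_edges: np.ndarray
    hist: np.ndarray            # windows per observable bin
    N_values: np.ndarray        # distinct window photon totals
    N_weights: np.ndarray       # windows per total
    label: str = ""
    n_censored: int = 0         # windows at the censoring bound (excluded)

    @property
    def n_windows(self) -> float:
        return float(self.N_weights.sum())


@dataclass
class PDAFit:
    model: PDAModel
    chi2_r: float
    uncertainties: dict
    fractions_per_dataset: list      # list of arrays, one per Δt dataset
    labels: list
    n_datasets: int
    data_checksum: tuple
    success: bool
    n_starts: int


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------

def pda_data_from_windows(windows, kind: str, bin_edges, R0: float = 53.0,
                          gamma: float = 1.0, label: str = "",
                          min_photons: int = 10,
                          censor_distance: float = 150.0) -> PDAData:
    """Build a :class:`PDAData` from time windows.

    FRET: observable = R0·(γ·G/R)^(1/6) from raw green/red totals;
    windows with zero red counts are censored (counted, excluded).
    Anisotropy: observable = (2P − N)/(2N − P) from green
    parallel/perpendicular counts.  Windows with fewer than
    ``min_photons`` in the relevant channels are dropped.
    """
    bin_edges = np.asarray(bin_edges, float)
    xs, Ns = [], []
    n_censored = 0
    for w in windows:
        c = w.counts
        if kind == "fret":
            G = int(c[CH_G_PAR] + c[CH_G_PERP])
            R = int(c[CH_R_PAR] + c[CH_R_PERP])
            N = G + R
            if N < min_photons:
                continue
            if R == 0 or G == 0:
                n_censored += 1
                continue
            x = R0 * (gamma * G / R) ** (1.0 / 6.0)
            if x >= censor_distance:
                n_censored += 1
                continue
        elif kind == "anisotropy":
            P = int(c[CH_G_PAR])
            S = int(c[CH_G_PERP])
            N = P + S
            if N < min_photons:
                continue
            x = (2.0 * P - N) / (2.0 * N - P)
        else:
            raise ValueError("kind must be 'fret' or 'anisotropy'")
        xs.append(x)
        Ns.append(N)
    xs = np.asarray(xs)
    Ns = np.asarray(Ns, int)
    hist, _ = np.histogram(xs, bins=bin_edges)
    Nv, Nw = np.unique(Ns, return_counts=True)
    return PDAData(kind, bin_edges, hist.astype(float), Nv,
                   Nw.astype(float), label=label, n_censored=n_censored)


def _compress_counts(N_values, N_weights, max_distinct: int = 40):
    """Reduce the count distribution to weighted quantile representatives."""
    if len(N_values) <= max_distinct:
        return np.asarray(N_values, int), np.asarray(N_weights, float)
    order = np.argsort(N_values)
    Nv = np.asarray(N_values)[order]
    Nw = np.asarray(N_weights, float)[order]
    cum = np.cumsum(Nw)
    edges = np.linspace(0, cum[-1], max_distinct + 1)
    idx = np.searchsorted(cum, edges[1:-1], side="left")
    groups = np.split(np.arange(len(Nv)), np.unique(idx))
    rep_N, rep_w = [], []
    for g in groups:
        if g.size == 0:
            continue
        w = Nw[g]
        rep_N.append(int(round(np.average(Nv[g], weights=w))))
        rep_w.append(w.sum())
    return np.asarray(rep_N, int), np.asarray(rep_w, float)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

_GH_NODES = 21
_gh_x, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
_gh_x = _gh_x * math.sqrt(2.0)
_gh_w = _gh_w / math.sqrt(math.pi)

_BRIGHT_NODES = 7


def _state_split_probabilities(model: PDAModel):
    """Quadrature nodes: per-node success probability and weight.

    FRET: probability that a photon is detected green.
    Anisotropy: probability that a green photon is parallel.
    """
    ps, ws = [], []
    for st in model.states:
        if st.half_width > 0:
            vals = st.mean + st.half_width * _gh_x
            wts = _gh_w * st.fraction
        else:
            vals = np.array([st.mean])
            wts = np.array([st.fraction])
        if model.kind == "fret":
            vals = np.maximum(vals, 1.0)              # truncate unphysical
            E = 1.0 / (1.0 + (vals / model.R0) ** 6)
            if model.acceptor_brightness_sd > 0:
                cx, cw = np.polynomial.hermite.hermgauss(_BRIGHT_NODES)
                c = np.maximum(1.0 + model.acceptor_brightness_sd
                               * cx * math.sqrt(2.0), 1e-3)
                cw = cw / math.sqrt(math.pi)
                E = (E[:, None] * c) / (E[:, None] * c + (1.0 - E[:, None]))
                wts = (wts[:, None] * cw).ravel()
                E = E.ravel()
            p_green = model.gamma * (1.0 - E) / (E + model.gamma * (1.0 - E))
            ps.append(p_green)
        else:
            vals = np.clip(vals, -0.199, 0.399)       # truncate at physical bounds
            p_par = (1.0 + 2.0 * vals) / (2.0 + vals)
            ps.append(p_par)
        ws.append(wts)
    return np.concatenate(ps), np.concatenate(ws)


def _binom_pmf_matrix(N: int, p: np.ndarray) -> np.ndarray:
    """Binomial pmf over k = 0..N for each p; shape (len(p), N+1)."""
    k = np.arange(N + 1)
    logc = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)
    p = np.clip(p[:, None], 1e-12, 1 - 1e-12)
    return np.exp(logc + k * np.log(p) + (N - k) * np.log1p(-p))


def pda_predict(model: PDAModel, N_values, N_weights, bin_edges,
                max_lost_mass: float = 0.02):
    """Expected observable histogram for a photon-count distribution.

    For each window total N the state mixture is propagated through the
    binomial counting distribution and the resulting discrete observable
    values are accumulated into ``bin_edges``.  The output is normalised
    to the number of windows (ΣN_weights); mass at the censoring bound
    (zero acceptor counts, FRET only) is returned separately, mirroring
    the exclusion of censored windows from the data histograms.

    Raises :class:`PDAError` when more than ``max_lost_mass`` of the
    non-censored probability falls outside the bins.
    """
    bin_edges = np.asarray(bin_edges, float)
    N_values = np.asarray(N_values, int)
    N_weights = np.asarray(N_weights, float)
    if N_values.size == 0:
        raise PDAError("empty photon-count distribution")
    if np.any(np.diff(bin_edges) <= 0):
        raise PDAError("bin edges must be strictly increasing")
    p_nodes, w_nodes = _state_split_probabilities(model)
    hist = np.zeros(bin_edges.size - 1)
    censored = 0.0
    lost = 0.0
    fret = model.kind == "fret"
    for N, wN in zip(N_values, N_weights):
        pmf = w_nodes @ _binom_pmf_matrix(int(N), p_nodes)   # over successes 0..N
        k = np.arange(N + 1)
        if fret:
            G, R = k, N - k
            with np.errstate(divide="ignore"):
                x = model.R0 * (model.gamma * G / np.maximum(R, 1e-300)) ** (1.0 / 6.0)
            cens = (R == 0) | (G == 0)
            censored += wN * pmf[cens].sum()
            pmf = pmf[~cens]
            x = x[~cens]
        else:
            P = k
            x = (2.0 * P - N) / (2.0 * N - P)
        idx = np.searchsorted(bin_edges, x, side="right") - 1
        ok = (idx >= 0) & (idx < hist.size) & (x < bin_edges[-1])
        np.add.at(hist, idx[ok], wN * pmf[ok])
        lost += wN * pmf[~ok].sum()
    total = N_weights.sum()
    if lost > max_lost_mass * total:
        raise PDAError(
            f"bins do not cover the predicted support: {lost / total:.3f} "
            f"of the probability mass lies outside the histogram range")
    return hist, censored, lost


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _unpack(params, k, n_datasets, shared, kind):
    means = np.array(params[:k])
    hws = np.array(params[k:2 * k])
    if shared == "global":
        fr = np.array(params[2 * k:2 * k + (k - 1)])
        fracs = [np.r_[fr, 1.0 - fr.sum()]] * n_datasets
    else:
        fracs = []
        for d in range(n_datasets):
            fr = np.array(params[2 * k + d * (k - 1): 2 * k + (d + 1) * (k - 1)])
            fracs.append(np.r_[fr, 1.0 - fr.sum()])
    return means, hws, fracs


def _model_from(means, hws, fracs, kind, R0, gamma, absd):
    fr = np.clip(fracs, 0.0, 1.0)
    tot = fr.sum()
    fr = fr / tot if tot > 0 else np.full_like(fr, 1.0 / len(fr))
    states = tuple(PDAState(kind, float(m), float(h), float(f))
                   for m, h, f in zip(means, hws, fr))
    return PDAModel(states, R0=R0, gamma=gamma, acceptor_brightness_sd=absd)


def pda_fit(datasets, k_states: int, shared: str = "global",
            R0: float = 53.0, gamma: float = 1.0,
            acceptor_brightness_sd: float = 0.0,
            n_starts: int = 8, seed: int = 0,
            max_distinct_counts: int = 40) -> PDAFit:
    """Fit a k-state PDA model globally across time-window datasets.

    Means and half-widths are always shared across the Δt datasets;
    fractions are shared too when ``shared="global"`` (default) or free
    per dataset with ``shared="per_window"``.  The reduced chi-square
    over Poisson-weighted histogram residuals is minimised by bounded
    trust-region least squares with ``n_starts`` seeded restarts;
    the best result by chi2_r wins.
    """
    if not datasets:
        raise PDAError("need at least one dataset")
    if k_states < 1:
        raise PDAError("k_states must be >= 1")
    if shared not in ("global", "per_window"):
        raise ValueError("shared must be 'global' or 'per_window'")
    kind = datasets[0].kind
    if any(d.kind != kind for d in datasets):
        raise PDAError("datasets mix observable kinds")
    nd = len(datasets)
    k = k_states

    compressed = [_compress_counts(d.N_values, d.N_weights, max_distinct_counts)
                  for d in datasets]

    def residuals(params):
        means, hws, fracs = _unpack(params, k, nd, shared, kind)
        res = []
        for di, (d, (Nv, Nw)) in enumerate(zip(datasets, compressed)):
            model = _model_from(means, hws, fracs[di], kind,
                                R0, gamma, acceptor_brightness_sd)
            try:
                pred, cens, _ = pda_predict(model, Nv, Nw, d.bin_edges,
                                            max_lost_mass=1.0)
            except PDAError:
                res.append(np.full(d.hist.size, 1e3))
                continue
            # rescale to the uncensored window count actually histogrammed
            tot_pred = pred.sum()
            if tot_pred > 0:
                pred = pred * (d.hist.sum() / tot_pred)
            res.append((pred - d.hist) / np.sqrt(np.maximum(pred, 1.0)))
        return np.concatenate(res)

    # bounds and starts
    if kind == "fret":
        mean_lo, mean_hi, hw_hi = 10.0, 140.0, 30.0
        supports = [d.bin_edges[np.r_[np.flatnonzero(d.hist > 0),
                                      np.flatnonzero(d.hist > 0) + 1]]
                    for d in datasets if d.hist.sum() > 0]
        data_lo = min(float(s.min()) for s in supports)
        data_hi = max(float(s.max()) for s in supports)
    else:
        mean_lo, mean_hi, hw_hi = -0.1, 0.4, 0.2
        supports = [d.bin_edges[np.r_[np.flatnonzero(d.hist > 0),
                                      np.flatnonzero(d.hist > 0) + 1]]
                    for d in datasets if d.hist.sum() > 0]
        data_lo = min(float(s.min()) for s in supports)
        data_hi = max(float(s.max()) for s in supports)

    n_frac = (k - 1) * (1 if shared == "global" else nd)
    lo = np.r_[np.full(k, mean_lo), np.zeros(k), np.zeros(n_frac)]
    hi = np.r_[np.full(k, mean_hi), np.full(k, hw_hi), np.ones(n_frac)]

    rng = np.random.default_rng(seed)
    starts = []
    # deterministic first start: spread means over the data quantile range
    q = np.linspace(0.25, 0.75, k)
    m0 = data_lo + q * (data_hi - data_lo)
    hw0 = np.full(k, 0.05 * (data_hi - data_lo))
    starts.append(np.r_[m0, hw0, np.full(n_frac, 1.0 / k)])
    for _ in range(max(0, n_starts - 1)):
        m = np.sort(rng.uniform(data_lo, data_hi, k))
        h = rng.uniform(0.0, 0.1 * (data_hi - data_lo), k)
        f = rng.dirichlet(np.ones(k))[:k - 1]
        f_rep = np.tile(f, 1 if shared == "global" else nd)
        starts.append(np.r_[m, h, f_rep])

    n_params = 2 * k + n_frac

    def reduced_chi2(params):
        # evaluated over informative bins (predicted count >= 1), where
        # the Poisson-weighted residual has unit expected variance
        means, hws, fracs = _unpack(params, k, nd, shared, kind)
        chi2, n_used = 0.0, 0
        for di, (d, (Nv, Nw)) in enumerate(zip(datasets, compressed)):
            model = _model_from(means, hws, fracs[di], kind, R0, gamma,
                                acceptor_brightness_sd)
            pred, _, _ = pda_predict(model, Nv, Nw, d.bin_edges,
                                     max_lost_mass=1.0)
            if pred.sum() > 0:
                pred = pred * (d.hist.sum() / pred.sum())
            use = pred >= 1.0
            chi2 += float(np.sum((pred[use] - d.hist[use]) ** 2 / pred[use]))
            n_used += int(use.sum())
        return chi2 / max(n_used - n_params, 1)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-8, ftol=1e-8, max_nfev=400)
        except Exception:
            continue
        cost = float(np.sum(sol.fun ** 2))
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise PDAError("all fit starts failed")
    _, sol = best
    chi2_r = float(reduced_chi2(sol.x))

    means, hws, fracs = _unpack(sol.x, k, nd, shared, kind)
    order = np.argsort(means)
    means = means[order]
    hws = hws[order]
    fracs = [np.clip(f[order], 0, 1) for f in fracs]
    fracs = [f / f.sum() for f in fracs]

    # uncertainties from the Jacobian at the optimum
    try:
        J = sol.jac
        cov = np.linalg.pinv(J.T @ J) * max(chi2_r, 1.0)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        perr = np.full(sol.x.size, np.inf)
    unc = {
        "means": perr[:k][order],
        "half_widths": perr[k:2 * k][order],
        "fractions": perr[2 * k:],
    }
    if k >= 3 and chi2_r > 10:
        warnings.warn("possible over-parameterisation: inspect parameter "
                      "correlations", stacklevel=2)

    model = _model_from(means, hws, fracs[0], kind, R0, gamma,
                        acceptor_brightness_sd)
    checksum = tuple((int(d.hist.sum()), float(d.N_weights.sum()))
                     for d in datasets)
    return PDAFit(model=model, chi2_r=chi2_r, uncertainties=unc,
                  fractions_per_dataset=fracs,
                  labels=[d.label for d in datasets],
                  n_datasets=nd, data_checksum=checksum,
                  success=bool(sol.success), n_starts=len(starts))


def model_compare(fits, improvement_threshold: float = 0.10):
    """Rank PDA fits of the same data with a parsimony rule.

    A model with more states is preferred only when its chi2_r improves
    on the best simpler model by more than ``improvement_threshold``
    (relative).  Returns (selected_fit, report) where the report lists
    (n_states, chi2_r, selected) in ranked order.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    checksums = {f.data_checksum for f in fits}
    if len(checksums) != 1:
        raise ValueError("fits are not of the same data")
    by_k = sorted(fits, key=lambda f: (len(f.model.states), f.chi2_r))
    selected = by_k[0]
    for f in by_k[1:]:
        if f.chi2_r < selected.chi2_r * (1.0 - improvement_threshold):
            selected = f
    report = [{"n_states": len(f.model.states), "chi2_r": f.chi2_r,
               "selected": f is selected}
              for f in sorted(fits, key=lambda f: f.chi2_r)]
    return selected, report
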