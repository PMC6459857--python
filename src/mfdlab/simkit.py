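"""Synthetic single-molecule photon streams and ITC titrations.

The generator emulates a confocal multiparameter fluorescence detection
(MFD) experiment on freely diffusing molecules: molecules enter the
detection volume as a Poisson process, dwell for an exponentially
distributed transit (top-hat volume approximation; an optional
3D-Gaussian intensity-profile mode serves the FCS-facing calibration
path), interconvert between conformational states as a continuous-time
Markov chain, and emit photons whose colour follows the Förster
efficiency of the current state, whose polarisation follows the
Perrin steady-state anisotropy, and whose TCSPC micro time is a
mono-exponential decay convolved with a Gaussian instrument response.

Every stochastic element is driven by a single ``numpy`` generator
seeded from the required ``seed`` argument, so identical seeds give
bit-identical streams.

Units: macro times s, micro times ns, rates in the rate matrix s⁻¹,
diffusion time ms, brightness and background kHz, distances Å.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CH_G_PAR", "CH_G_PERP", "CH_R_PAR", "CH_R_PERP",
    "GREEN_CHANNELS", "RED_CHANNELS",
    "DyeState", "ExchangeModel", "ConfocalModel", "PhotonStream",
    "ITCSimParams",
    "simulate_photon_stream", "simulate_itc_titrations",
    "write_stream", "read_stream", "StreamFormatError",
]

# Detection channels: colour (Green donor / Red acceptor) x polarisation.
CH_G_PAR, CH_G_PERP, CH_R_PAR, CH_R_PERP = 0, 1, 2, 3
GREEN_CHANNELS = (CH_G_PAR, CH_G_PERP)
RED_CHANNELS = (CH_R_PAR, CH_R_PERP)

#: TCSPC excitation period for a 64 MHz pulsed laser, ns.
DEFAULT_PERIOD_NS = 15.625

#: FRET-sensitised acceptor fluorescence lifetime, ns (typical red dye).
DEFAULT_ACCEPTOR_TAU_NS = 1.7

#: Fundamental anisotropy of FRET-sensitised acceptor emission; transfer
#: itself depolarises, so this is far below the donor r0.
TRANSFER_R0 = 0.1


class StreamFormatError(ValueError):
    """A photon container is missing a required field or is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyeState:
    """One conformational state as seen by the dye pair.

    ``R_DA`` may be ``inf`` for a donor-only construct (no FRET), which
    is how single-label anisotropy experiments are represented.
    ``sigma_DA`` is the Gaussian half-width (standard deviation) of the
    quasi-static distance distribution sampled once per state visit.
    """

    label: str
    R_DA: float          # Å
    sigma_DA: float      # Å
    tau_D: float         # donor-only fluorescence lifetime, ns
    rho: float           # rotational correlation time, ns
    r0: float = 0.38     # fundamental anisotropy

    def __post_init__(self):
        if not self.R_DA > 0:
            raise ValueError("R_DA must be > 0")
        if self.sigma_DA < 0:
            raise ValueError("sigma_DA must be >= 0")
        if not self.tau_D > 0 or not self.rho > 0:
            raise ValueError("tau_D and rho must be > 0")
        if not 0 < self.r0 <= 0.4:
            raise ValueError("r0 must lie in (0, 0.4]")


@dataclass(frozen=True)
class ExchangeModel:
    """k-state conformational exchange with first-order kinetics.

    ``rates[i, j]`` (i ≠ j) is the i→j rate in s⁻¹; diagonals are set so
    each row sums to zero.  The model must be ergodic (single
    communicating class) unless it has one state.
    """

    states: tuple
    rates: np.ndarray    # k x k, s^-1
    R0: float = 53.0     # Å

    def __post_init__(self):
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        k = len(states)
        Q = np.array(self.rates, dtype=float).reshape(k, k).copy()
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        object.__setattr__(self, "rates", Q)
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")
        if k > 1 and not _is_ergodic(Q):
            raise ValueError("rate matrix is not ergodic (unreachable states)")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def stationary_distribution(self) -> np.ndarray:
        """Equilibrium occupancies π with πQ = 0, Σπ = 1."""
        k = self.n_states
        if k == 1:
            return np.ones(1)
        A = np.vstack([self.rates.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


def _is_ergodic(Q: np.ndarray) -> bool:
    adj = Q > 0
    np.fill_diagonal(adj, True)
    reach = adj.copy()
    for _ in range(Q.shape[0]):
        reach = reach | (reach @ adj)
    return bool(reach.all())


@dataclass(frozen=True)
class ConfocalModel:
    """Detection-volume and instrument parameters.

    ``brightness`` is the peak detected photon rate per molecule summed
    over all channels.  ``background`` is the per-channel Poisson rate
    (scalar applied to all four channels, or a length-4 sequence).
    """

    t_diff: float = 1.7              # ms
    mean_occupancy: float = 0.002    # molecules in volume (~1 burst/s)
    brightness: float = 100.0        # kHz per molecule
    background: object = 0.3         # kHz per channel
    g_factor: float = 1.0
    det_ratio_gr: float = 1.0
    irf_mu: float = 1.0              # IRF centre, ns
    irf_sigma: float = 0.25          # IRF width, ns
    period_ns: float = DEFAULT_PERIOD_NS
    acceptor_tau: float = DEFAULT_ACCEPTOR_TAU_NS

    def __post_init__(self):
        bg = np.broadcast_to(np.asarray(self.background, float), (4,)).copy()
        object.__setattr__(self, "background", bg)
        if self.t_diff <= 0:
            raise ValueError("t_diff must be > 0")
        if self.brightness < 0 or np.any(bg < 0):
            raise ValueError("rates must be >= 0")
        if self.mean_occupancy > 0.1:
            warnings.warn(
                "mean occupancy above 0.1: bursts will frequently overlap; "
                "not single-molecule conditions", stacklevel=2)


@dataclass
class PhotonStream:
    """Time-ordered photon records from a 4-channel MFD registration."""

    macro_times: np.ndarray   # s, nondecreasing
    micro_times: np.ndarray   # ns, within [0, period)
    channels: np.ndarray      # uint8 in {0, 1, 2, 3}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.macro_times)
        if not (len(self.micro_times) == n and len(self.channels) == n):
            raise ValueError("photon arrays must have equal length")
        if n and np.any(np.diff(self.macro_times) < 0):
            raise ValueError("macro times must be nondecreasing")

    def __len__(self):
        return len(self.macro_times)

    @property
    def duration(self) -> float:
        return float(self.metadata.get("duration", self.macro_times[-1] if len(self) else 0.0))

    def counts_per_channel(self) -> np.ndarray:
        return np.bincount(self.channels, minlength=4)


# ---------------------------------------------------------------------------
# Photon-stream simulation
# ---------------------------------------------------------------------------

def _polarization_split(r: np.ndarray) -> np.ndarray:
    """P(parallel detection) for steady-state anisotropy r (g = 1)."""
    return (1.0 + 2.0 * r) / (2.0 + r)


def _ctmc_trajectory(Q, pi, duration, rng):
    """Jump times and states of a CTMC over [0, duration).

    Returns (times, states): ``states[i]`` holds on
    [times[i], times[i+1]); times[0] == 0.
    """
    k = Q.shape[0]
    s0 = int(rng.choice(k, p=pi))
    if k == 1:
        return np.array([0.0]), np.array([s0])
    exit_rates = -np.diag(Q)
    if k == 2:
        # vectorised alternating two-state chain
        n_guess = max(8, int(duration * exit_rates.mean() * 1.5 + 10))
        times = [0.0]
        states = [s0]
        t, s = 0.0, s0
        while t < duration:
            n = n_guess
            # dwell blocks alternate between the two exit rates
            dwells = rng.exponential(
                1.0 / exit_rates[(s + np.arange(n)) % 2])
            ts = t + np.cumsum(dwells)
            keep = ts < duration
            times.extend(ts[keep].tolist())
            states.extend(((s + 1 + np.arange(n)) % 2)[keep].tolist())
            if not keep.all():
                break
            t = ts[-1]
            s = (s + n) % 2
        return np.asarray(times), np.asarray(states, dtype=int)
    # general k: sequential
    times = [0.0]
    states = [s0]
    t, s = 0.0, s0
    P = Q.copy()
    np.fill_diagonal(P, 0.0)
    P = P / P.sum(axis=1, keepdims=True)
    while True:
        t += rng.exponential(1.0 / exit_rates[s])
        if t >= duration:
            break
        s = int(rng.choice(k, p=P[s]))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=int)


def _visit_efficiency(model, confocal, state_idx, rng):
    """Per-visit quasi-static efficiency and donor lifetime draws."""
    st = model.states
    R = np.array([st[s].R_DA for s in state_idx])
    sig = np.array([st[s].sigma_DA for s in state_idx])
    tau0 = np.array([st[s].tau_D for s in state_idx])
    finite = np.isfinite(R)
    Rd = R.copy()
    if finite.any():
        Rd[finite] = np.maximum(
            R[finite] + sig[finite] * rng.standard_normal(finite.sum()), 1.0)
    E = np.zeros_like(Rd)
    E[finite] = 1.0 / (1.0 + (Rd[finite] / model.R0) ** 6)
    # red detection-efficiency imbalance
    gr = confocal.det_ratio_gr
    p_red = E / (E + gr * (1.0 - E))
    tau_vis = tau0 * (1.0 - E)
    return p_red, tau_vis


def _emit_photons(model, confocal, n, visit_idx, p_red, tau_vis, rho_vis,
                  r0_vis, rng):
    """Colour, polarisation and micro time for ``n`` photons.

    ``visit_idx`` maps each photon to its state visit (arrays of per-visit
    quantities are indexed by it).
    """
    pr = p_red[visit_idx]
    tau = tau_vis[visit_idx]
    rho = rho_vis[visit_idx]
    r0 = r0_vis[visit_idx]
    is_red = rng.random(n) < pr
    # micro time: IRF + donor dwell (+ acceptor dwell for red photons)
    micro = (confocal.irf_mu
             + confocal.irf_sigma * rng.standard_normal(n)
             + rng.exponential(np.maximum(tau, 1e-6)))
    micro[is_red] += rng.exponential(confocal.acceptor_tau, is_red.sum())
    micro %= confocal.period_ns
    # polarisation: steady-state Perrin anisotropy of the emitting dye
    r_green = r0 / (1.0 + tau / rho)
    r_red = TRANSFER_R0 / (1.0 + confocal.acceptor_tau / rho)
    r_eff = np.where(is_red, r_red, r_green)
    p_par = _polarization_split(r_eff)
    if confocal.g_factor != 1.0:
        g = confocal.g_factor
        p_par = g * p_par / (g * p_par + (1.0 - p_par))
    is_par = rng.random(n) < p_par
    channels = np.where(is_red,
                        np.where(is_par, CH_R_PAR, CH_R_PERP),
                        np.where(is_par, CH_G_PAR, CH_G_PERP)).astype(np.uint8)
    return channels, micro


def simulate_photon_stream(model: ExchangeModel, confocal: ConfocalModel,
                           duration: float, seed: int,
                           profile: str = "tophat",
                           aspect: float = 4.0) -> PhotonStream:
    """Simulate an MFD photon stream of ``duration`` seconds.

    ``profile="tophat"`` (default) draws exponential transit dwell times
    in a uniform-intensity volume, which preserves burst-duration
    statistics for burst/PDA work at low cost.  ``profile="gaussian3d"``
    runs Brownian paths through a 3D-Gaussian detection profile (single
    state only) for FCS-shape calibration.

    The ground-truth transit intervals are stored in
    ``metadata["transits"]`` as an (n, 2) [start, stop] array.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    if profile == "gaussian3d":
        return _simulate_gaussian3d(model, confocal, duration, rng,
                                    aspect=aspect)
    if profile != "tophat":
        raise ValueError(f"unknown profile {profile!r}")

    pi = model.stationary_distribution()
    t_diff_s = confocal.t_diff * 1e-3
    transit_rate = confocal.mean_occupancy / t_diff_s          # s^-1
    n_transits = rng.poisson(transit_rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, n_transits))
    dwells = rng.exponential(t_diff_s, n_transits)
    stops = np.minimum(starts + dwells, duration)

    rho_states = np.array([s.rho for s in model.states])
    r0_states = np.array([s.r0 for s in model.states])
    brightness_sps = confocal.brightness * 1e3                  # photons/s

    mt_parts, micro_parts, ch_parts = [], [], []
    for t0, t1 in zip(starts, stops):
        T = t1 - t0
        n_phot = rng.poisson(brightness_sps * T)
        if n_phot == 0:
            continue
        jt, js = _ctmc_trajectory(model.rates, pi, T, rng)
        p_red, tau_vis = _visit_efficiency(model, confocal, js, rng)
        ptimes = np.sort(rng.uniform(0.0, T, n_phot))
        vidx = np.searchsorted(jt, ptimes, side="right") - 1
        ch, micro = _emit_photons(model, confocal, n_phot, vidx, p_red,
                                  tau_vis, rho_states[js], r0_states[js], rng)
        mt_parts.append(t0 + ptimes)
        micro_parts.append(micro)
        ch_parts.append(ch)

    # Poisson background, uniform micro times
    for c in range(4):
        nb = rng.poisson(confocal.background[c] * 1e3 * duration)
        if nb == 0:
            continue
        mt_parts.append(rng.uniform(0.0, duration, nb))
        micro_parts.append(rng.uniform(0.0, confocal.period_ns, nb))
        ch_parts.append(np.full(nb, c, dtype=np.uint8))

    if mt_parts:
        mt = np.concatenate(mt_parts)
        order = np.argsort(mt, kind="stable")
        mt = mt[order]
        micro = np.concatenate(micro_parts)[order]
        ch = np.concatenate(ch_parts)[order]
    else:
        mt = np.empty(0)
        micro = np.empty(0)
        ch = np.empty(0, dtype=np.uint8)

    meta = {
        "duration": float(duration),
        "seed": int(seed),
        "profile": profile,
        "period_ns": confocal.period_ns,
        "irf_mu": confocal.irf_mu,
        "irf_sigma": confocal.irf_sigma,
        "t_diff_ms": confocal.t_diff,
        "background_khz": confocal.background.tolist(),
        "R0": model.R0,
        "transits": np.column_stack([starts, stops]) if n_transits else np.empty((0, 2)),
        "states": [asdict(s) for s in model.states],
        "stationary": pi.tolist(),
    }
    return PhotonStream(mt, micro, ch, meta)


def _simulate_gaussian3d(model, confocal, duration, rng,
                         aspect: float = 4.0, box_w: float = 6.0):
    """Brownian molecules through a 3D-Gaussian profile (one state)."""
    if model.n_states != 1:
        raise ValueError("gaussian3d profile supports single-state models")
    w = 0.5                                     # lateral 1/e^2 waist, µm
    z0 = aspect * w
    t_diff_s = confocal.t_diff * 1e-3
    D = w ** 2 / (4.0 * t_diff_s)               # µm^2/s
    half = np.array([box_w * w, box_w * w, box_w * z0])
    v_box = np.prod(2 * half)
    v_eff = np.pi ** 1.5 * w ** 2 * z0
    n_mol = max(1, int(round(confocal.mean_occupancy * v_box / v_eff)))
    dt = t_diff_s / 100.0
    n_steps = int(np.ceil(duration / dt))
    brightness_sps = confocal.brightness * 1e3

    state = model.states[0]
    p_red, tau_vis = _visit_efficiency(model, confocal, np.array([0]), rng)
    rho_vis = np.array([state.rho])
    r0_vis = np.array([state.r0])

    pos = rng.uniform(-half, half, size=(n_mol, 3))
    sigma_step = math.sqrt(2.0 * D * dt)
    chunk = 20000
    mt_parts, micro_parts, ch_parts = [], [], []
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        steps = sigma_step * rng.standard_normal((m, n_mol, 3))
        path = pos[None] + np.cumsum(steps, axis=0)
        # periodic box keeps concentration constant
        path = (path + half) % (2 * half) - half
        pos = path[-1]
        lam = brightness_sps * np.exp(
            -2.0 * (path[..., 0] ** 2 + path[..., 1] ** 2) / w ** 2
            - 2.0 * path[..., 2] ** 2 / z0 ** 2)
        counts = rng.poisson(lam * dt)
        tot = int(counts.sum())
        if tot == 0:
            continue
        step_idx = np.repeat(np.arange(m), counts.sum(axis=1))
        t = (start + step_idx) * dt + rng.uniform(0.0, dt, tot)
        ch, micro = _emit_photons(model, confocal, tot,
                                  np.zeros(tot, dtype=int), p_red, tau_vis,
                                  rho_vis, r0_vis, rng)
        mt_parts.append(t)
        micro_parts.append(micro)
        ch_parts.append(ch)

    for c in range(4):
        nb = rng.poisson(confocal.background[c] * 1e3 * duration)
        if nb:
            mt_parts.append(rng.uniform(0.0, duration, nb))
            micro_parts.append(rng.uniform(0.0, confocal.period_ns, nb))
            ch_parts.append(np.full(nb, c, dtype=np.uint8))

    mt = np.concatenate(mt_parts) if mt_parts else np.empty(0)
    order = np.argsort(mt, kind="stable")
    micro = np.concatenate(micro_parts)[order] if mt_parts else np.empty(0)
    ch = np.concatenate(ch_parts)[order] if mt_parts else np.empty(0, dtype=np.uint8)
    meta = {
        "duration": float(duration),
        "profile": "gaussian3d",
        "period_ns": confocal.period_ns,
        "irf_mu": confocal.irf_mu,
        "irf_sigma": confocal.irf_sigma,
        "t_diff_ms": confocal.t_diff,
        "aspect": aspect,
        "background_khz": confocal.background.tolist(),
        "R0": model.R0,
        "transits": np.empty((0, 2)),
        "states": [asdict(s) for s in model.states],
        "stationary": [1.0],
    }
    return PhotonStream(mt[order], micro, ch, meta)


# ---------------------------------------------------------------------------
# ITC simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCSimParams:
    """Parameters of a simulated 1:1 titration (syringe titrant into cell)."""

    K_D: float                   # M
    dH: float                    # kcal/mol at `temperature`
    n_sites: float = 1.0
    cell_conc: float = 1e-6      # M
    syringe_conc: float = 10e-6  # M
    injection_volumes: tuple = (0.5,) + (3.1,) * 15   # µL
    cell_volume: float = 200.0   # µL
    temperature: float = 298.15  # K
    noise_sd: float = 0.0        # µcal per injection

    def __post_init__(self):
        if self.K_D <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("K_D and concentrations must be > 0")
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("volumes must be > 0")
        if self.syringe_conc < self.cell_conc:
            warnings.warn("syringe concentration below cell concentration: "
                          "titration will not reach saturation", stacklevel=2)


def itc_injection_heats(K_D, dH, n_sites, cell_conc, syringe_conc,
                        injection_volumes, cell_volume):
    """Exact 1:1 isotherm heats (µcal) with per-injection dilution.

    Displacement bookkeeping: each injection of volume v dilutes the
    existing cell contents by (1 − v/V0) before adding titrant.  The
    heat of injection i is V0·ΔH·(B_i − B_{i−1}·(1 − v_i/V0)) with B the
    molar complex concentration solved from the binding quadratic.
    """
    V0 = cell_volume
    M = n_sites * cell_conc          # binding-site concentration
    X = 0.0
    B_prev = 0.0
    heats = np.empty(len(injection_volumes))
    for i, v in enumerate(injection_volumes):
        d = 1.0 - v / V0
        M *= d
        X = X * d + syringe_conc * (v / V0)
        s = M + X + K_D
        B = (s - math.sqrt(s * s - 4.0 * M * X)) / 2.0
        # kcal/mol * mol/L * L -> kcal; 1 kcal = 1e9 µcal
        heats[i] = dH * (B - B_prev * d) * (V0 * 1e-6) * 1e9
        B_prev = B
    return heats


def simulate_itc_titrations(params: ITCSimParams, temperatures, seed: int,
                            dCp: float = 0.0) -> list:
    """Simulate titration tables over a temperature series.

    ΔH varies linearly with temperature at slope ``dCp``
    (cal mol⁻¹ K⁻¹) around ``params.temperature``; K_D is held fixed.
    Returns one DataFrame per temperature with columns
    injection_index, volume_uL, heat_ucal, temperature_K.
    """
    temperatures = list(temperatures)
    if not temperatures:
        raise ValueError("need at least one temperature")
    rng = np.random.default_rng(seed)
    tables = []
    for T in temperatures:
        dH_T = params.dH + dCp * 1e-3 * (T - params.temperature)
        q = itc_injection_heats(params.K_D, dH_T, params.n_sites,
                                params.cell_conc, params.syringe_conc,
                                params.injection_volumes, params.cell_volume)
        if params.noise_sd > 0:
            q = q + rng.normal(0.0, params.noise_sd, q.size)
        tables.append(pd.DataFrame({
            "injection_index": np.arange(1, q.size + 1),
            "volume_uL": np.asarray(params.injection_volumes, float),
            "heat_ucal": q,
            "temperature_K": float(T),
        }))
    return tables


# ---------------------------------------------------------------------------
# Photon container I/O (Photon-HDF5-style layout)
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("macro_times", "micro_times", "channels")


def write_stream(stream: PhotonStream, path) -> None:
    """Write a stream to an HDF5 container.

    Layout: group ``/photon_data`` with datasets ``macro_times`` (s),
    ``micro_times`` (ns) and ``channels`` (uint8), plus a JSON-encoded
    ``/metadata`` scalar dataset.
    """
    meta = dict(stream.metadata)
    transits = meta.pop("transits", None)
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("macro_times", data=np.asarray(stream.macro_times, float))
        g.create_dataset("micro_times", data=np.asarray(stream.micro_times, float))
        g.create_dataset("channels", data=np.asarray(stream.channels, np.uint8))
        if transits is not None:
            f.create_dataset("ground_truth/transits", data=np.asarray(transits, float))
        f.create_dataset("metadata", data=json.dumps(meta, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_stream(path) -> PhotonStream:
    """Read a container written by :func:`write_stream` (lossless)."""
    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise StreamFormatError("missing group 'photon_data'")
        g = f["photon_data"]
        for name in _REQUIRED_FIELDS:
            if name not in g:
                raise StreamFormatError(f"missing field 'photon_data/{name}'")
        mt = g["macro_times"][...]
        micro = g["micro_times"][...]
        ch = g["channels"][...]
        meta = {}
        if "metadata" in f:
            raw = f["metadata"][()]
            meta = json.loads(raw.decode() if isinstance(raw, bytes) else raw)
        if "ground_truth/transits" in f:
            meta["transits"] = f["ground_truth/transits"][...]
    return PhotonStream(mt, micro, ch.astype(np.uint8), meta)
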