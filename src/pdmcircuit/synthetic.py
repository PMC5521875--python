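"""Synthetic circuits, spike trains and multi-session studies.

The generator emulates the statistical structure the analysis assumes so that
every downstream stage can be tested by parameter recovery:

* theta-modulated (4-7 Hz) Bernoulli input trains at hippocampal rates;
* causal feedforward filters shaped like an EPSP with an optional delayed
  inhibitory lobe (feedforward-inhibition motif), spectrally peaked in the
  high-theta range;
* feedback filters with a ~40 ms refractory trough followed by a rebound
  that produces a low-theta (~3.5 Hz) resonance;
* sparse CA3->CA1 connectivity; and
* session-level behavioral performance tied to per-session programmed
  effect magnitudes ("drug" scenarios).

Ground-truth filters are built *inside* the span of the Laguerre basis used
for fitting (their Laguerre coefficients are stored), so noise-free recovery
is exact by construction; ``off_basis_component`` injects out-of-span energy
for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ParameterError
from .io import SpikeTrain
from .laguerre import (DEFAULT_ALPHA, DEFAULT_BIN_WIDTH, DEFAULT_L, DEFAULT_M,
                       Filter, LaguerreBasis, laguerre_basis,
                       reconstruct_filter)


# --------------------------------------------------------------------------
# filter shape specification and construction
# --------------------------------------------------------------------------

@dataclass
class FilterShapeSpec:
    """Shape parameters for ground-truth filters (lags in bins, 4 ms each).

    Feedforward: Gaussian excitatory bump at ``ff_peak_lag`` plus an optional
    delayed inhibitory lobe; the lobe delay is tuned so the filter spectrum
    peaks at ``ff_resonance_hz``.  Feedback: exponential-plus-Gaussian
    refractory trough covering roughly the first 40 ms, then a rebound bump
    placed so the spectrum peaks at ``fb_resonance_hz``.
    """

    ff_peak_lag: float = 3.0
    ff_peak_width: float = 2.5
    ff_inhib_frac: float = 0.4      # inhibitory lobe amplitude / peak (0 = none)
    ff_inhib_width: float = 3.0
    ff_resonance_hz: float = 8.5
    ff_amp: float = 0.12            # peak |value|, probability per input spike

    fb_trough_tau: float = 6.0      # bins; exponential refractory decay
    fb_trough2_width: float = 4.0   # early Gaussian deepening the trough
    fb_rebound_frac: float = 0.5    # rebound amplitude / trough depth
    fb_rebound_width: float = 8.0
    fb_resonance_hz: float = 3.5
    fb_amp: float = 0.04            # trough depth, probability units

    excit_lag: float = 70.0         # slow excitatory component (EI shift target)
    excit_width: float = 25.0

    off_basis_component: float = 0.0  # relative out-of-span energy to inject


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _spectral_peak(values: np.ndarray, bin_width: float) -> float:
    power = np.abs(np.fft.rfft(values, 4096)) ** 2
    freqs = np.fft.rfftfreq(4096, bin_width)
    return float(freqs[np.argmax(power)])


def _tune_lag(build, lag_grid: np.ndarray, target_hz: float,
              basis: LaguerreBasis, bin_width: float) -> float:
    """Pick the lag parameter whose basis-projected shape peaks nearest the
    requested resonance frequency."""
    best_lag, best_err = lag_grid[0], np.inf
    for lag in lag_grid:
        proj = basis.B @ basis.project(build(lag))
        err = abs(_spectral_peak(proj, bin_width) - target_hz)
        if err < best_err:
            best_lag, best_err = lag, err
    return float(best_lag)


def _ff_coeffs(spec: FilterShapeSpec, basis: LaguerreBasis,
               bin_width: float) -> np.ndarray:
    lags = np.arange(basis.M + 1, dtype=float)

    def build(inhib_lag: float) -> np.ndarray:
        t = _gauss(lags, spec.ff_peak_lag, spec.ff_peak_width)
        if spec.ff_inhib_frac > 0:
            t = t - spec.ff_inhib_frac * _gauss(lags, inhib_lag,
                                                spec.ff_inhib_width)
        return t

    if spec.ff_inhib_frac > 0:
        grid = np.arange(6, 31, dtype=float)
        lag = _tune_lag(build, grid, spec.ff_resonance_hz, basis, bin_width)
    else:
        lag = 0.0
    coeffs = basis.project(build(lag))
    values = basis.B @ coeffs
    return coeffs * (spec.ff_amp / np.abs(values).max())


def _fb_component_coeffs(spec: FilterShapeSpec, basis: LaguerreBasis,
                         bin_width: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Laguerre coefficients of the three feedback components: refractory
    trough, oscillatory rebound, and slow excitatory shift (all unit-depth)."""
    tau = np.arange(basis.M + 1, dtype=float) + 1.0  # feedback lags 1..M+1
    trough = -(np.exp(-tau / spec.fb_trough_tau)
               + 0.4 * _gauss(tau, 6.0, spec.fb_trough2_width))
    c_trough = basis.project(trough / np.abs(trough).max())

    def build(lag: float) -> np.ndarray:
        t = trough / np.abs(trough).max()
        return t + spec.fb_rebound_frac * _gauss(tau, lag, spec.fb_rebound_width)

    grid = np.arange(18, 61, 2, dtype=float)
    lag = _tune_lag(build, grid, spec.fb_resonance_hz, basis, bin_width)
    c_osc = basis.project(spec.fb_rebound_frac * _gauss(tau, lag,
                                                        spec.fb_rebound_width))
    c_excit = basis.project(_gauss(tau, spec.excit_lag, spec.excit_width))
    return c_trough, c_osc, c_excit


def make_ground_truth_filters(
    alpha: float = DEFAULT_ALPHA,
    L: int = DEFAULT_L,
    M: int = DEFAULT_M,
    spec: FilterShapeSpec | None = None,
    seed: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[Filter, Filter]:
    """Build one feedforward and one feedback ground-truth filter.

    Both are Laguerre-coefficient mixtures of the (alpha, L, M) basis, so the
    estimation stage can recover them exactly in the noise-free limit.  The
    optional seed jitters amplitudes mildly (for population variability);
    with ``seed=None`` the construction is deterministic.
    """
    spec = spec or FilterShapeSpec()
    nyquist = 0.5 / bin_width
    for f_req in (spec.ff_resonance_hz, spec.fb_resonance_hz):
        if f_req is not None and f_req >= nyquist:
            raise ParameterError(
                f"requested oscillation frequency {f_req} Hz is at or above "
                f"Nyquist ({nyquist} Hz)")
    basis = laguerre_basis(alpha, L, M)
    c_ff = _ff_coeffs(spec, basis, bin_width)
    c_tr, c_osc, c_ex = _fb_component_coeffs(spec, basis, bin_width)
    c_fb = (c_tr + c_osc) * spec.fb_amp

    if seed is not None:
        rng = np.random.default_rng(seed)
        c_ff = c_ff * rng.uniform(0.85, 1.15)
        c_fb = c_fb * rng.uniform(0.85, 1.15)

    ff = reconstruct_filter(c_ff, basis, "feedforward", bin_width)
    fb = reconstruct_filter(c_fb, basis, "feedback", bin_width)
    if spec.off_basis_component > 0:
        rng = np.random.default_rng(0 if seed is None else seed + 1)
        for filt in (ff, fb):
            bump = rng.standard_normal(filt.values.size)
            bump -= basis.B @ basis.project(bump)  # orthogonal to the span
            scale = spec.off_basis_component * np.linalg.norm(filt.values) \
                / max(np.linalg.norm(bump), 1e-12)
            filt.values = filt.values + scale * bump
            filt.coeffs = None
    return ff, fb


# --------------------------------------------------------------------------
# circuits
# --------------------------------------------------------------------------

@dataclass
class GroundTruthCircuit:
    """A known CA3->CA1 circuit: who connects to whom, with which filters."""

    n_ca3: int
    n_ca1: int
    connectivity: np.ndarray              # (n_ca3, n_ca1) in {0,1}
    ff_coeffs: dict                       # (i, j) -> Laguerre coeffs
    fb_trough: list[np.ndarray]           # per CA1 unit, coeff components
    fb_osc: list[np.ndarray]
    fb_excit: np.ndarray                  # shared slow excitatory component
    fb_theta_gain: np.ndarray             # per CA1 multiplier on fb_osc
    fb_ei_shift: np.ndarray               # per CA1 additive excit weight
    offsets: np.ndarray                   # baseline probability per bin
    input_rate: float                     # Hz per CA3 unit
    theta_freq: float
    theta_depth: float
    basis: LaguerreBasis
    bin_width: float = DEFAULT_BIN_WIDTH

    def fb_coeffs(self, j: int) -> np.ndarray:
        return (self.fb_trough[j] + self.fb_theta_gain[j] * self.fb_osc[j]
                + self.fb_ei_shift[j] * self.fb_excit)

    def feedforward_filter(self, i: int, j: int) -> Filter:
        return reconstruct_filter(self.ff_coeffs[(i, j)], self.basis,
                                  "feedforward", self.bin_width)

    def feedback_filter(self, j: int) -> Filter:
        return reconstruct_filter(self.fb_coeffs(j), self.basis, "feedback",
                                  self.bin_width)

    def true_edges(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.n_ca3) for j in range(self.n_ca1)
                if self.connectivity[i, j]]


def make_circuit(
    n_ca3: int = 4,
    n_ca1: int = 6,
    connect_prob: float = 0.5,
    spec: FilterShapeSpec | None = None,
    offset: float = 0.012,
    input_rate: float = 8.0,
    theta_freq: float = 6.0,
    theta_depth: float = 0.6,
    alpha: float = DEFAULT_ALPHA,
    L: int = DEFAULT_L,
    M: int = DEFAULT_M,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int | None = None,
) -> GroundTruthCircuit:
    """Draw a random ground-truth circuit at the study's default scale
    (4 CA3 x 6 CA1 per session, roughly half the pairs connected)."""
    spec = spec or FilterShapeSpec()
    rng = np.random.default_rng(seed)
    basis = laguerre_basis(alpha, L, M)
    base_ff = _ff_coeffs(spec, basis, bin_width)
    c_tr, c_osc, c_ex = _fb_component_coeffs(spec, basis, bin_width)

    conn = (rng.random((n_ca3, n_ca1)) < connect_prob).astype(int)
    ff_coeffs = {}
    for i in range(n_ca3):
        for j in range(n_ca1):
            if conn[i, j]:
                ff_coeffs[(i, j)] = base_ff * rng.uniform(0.8, 1.25)
    fb_trough, fb_osc = [], []
    for j in range(n_ca1):
        amp = spec.fb_amp * rng.uniform(0.8, 1.25)
        fb_trough.append(c_tr * amp)
        fb_osc.append(c_osc * amp)
    offsets = offset * rng.uniform(0.8, 1.25, size=n_ca1)
    return GroundTruthCircuit(
        n_ca3=n_ca3, n_ca1=n_ca1, connectivity=conn, ff_coeffs=ff_coeffs,
        fb_trough=fb_trough, fb_osc=fb_osc, fb_excit=c_ex * spec.fb_amp,
        fb_theta_gain=np.ones(n_ca1), fb_ei_shift=np.zeros(n_ca1),
        offsets=offsets, input_rate=input_rate, theta_freq=theta_freq,
        theta_depth=theta_depth, basis=basis, bin_width=bin_width)


# --------------------------------------------------------------------------
# spike-train generation
# --------------------------------------------------------------------------

def make_theta_inputs(
    n_units: int,
    duration: float,
    rate: float = 8.0,
    theta_freq: float = 6.0,
    theta_depth: float = 0.6,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int | None = None,
    events: np.ndarray | None = None,
    event_gain: float = 1.0,
    event_window: float = 1.5,
    unit_prefix: str = "ca3",
    region: str = "CA3",
) -> list[SpikeTrain]:
    """Theta-modulated Bernoulli spike trains.

    Per-bin spike probability ``p(t) = rate*bin_width*(1 + depth*cos(2 pi f t))``,
    clipped to [0, 1]; independent units, reproducible under ``seed``.  When
    ``events`` are given, p(t) is multiplied by ``event_gain`` inside
    ``[event, event + event_window)`` (sample-presentation responsiveness).
    """
    if rate * bin_width >= 0.5:
        raise ParameterError("rate * bin_width must stay below 0.5")
    nyquist = 0.5 / bin_width
    if not 0.0 < theta_freq < nyquist:
        raise ParameterError("theta_freq must lie in (0, Nyquist)")
    if not 0.0 <= theta_depth <= 1.0:
        raise ParameterError("theta_depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration / bin_width))
    t = (np.arange(n_bins) + 0.5) * bin_width
    p = rate * bin_width * (1.0 + theta_depth * np.cos(2 * np.pi * theta_freq * t))
    if events is not None and event_gain != 1.0:
        mod = np.ones(n_bins)
        for e in np.asarray(events, float):
            a = int(np.ceil((e - 0.5 * bin_width) / bin_width))
            b = int(np.ceil((e + event_window - 0.5 * bin_width) / bin_width))
            mod[max(a, 0):min(b, n_bins)] = event_gain
        p = p * mod
    excess = p.max() - 1.0
    if excess > 0:
        warnings.warn(f"spike probability exceeded 1 before clipping "
                      f"(max excess {excess:.3g})")
        p = np.clip(p, 0.0, 1.0)
    trains = []
    for u in range(n_units):
        values = (rng.random(n_bins) < p).astype(np.int8)
        trains.append(SpikeTrain(unit_id=f"{unit_prefix}{u}", region=region,
                                 bin_width=bin_width, t_start=0.0,
                                 values=values))
    return trains


def simulate_ca1(
    inputs: list[SpikeTrain],
    circuit: GroundTruthCircuit,
    seed: int | None = None,
    spike_output: bool = True,
    unit_prefix: str = "ca1",
) -> list:
    """Generate CA1 activity from the circuit's linear drive.

    The drive of unit j at bin t is ``offset_j + sum_i k_ij * x_i + k_AR * y_j``
    (feedforward lags 0..M on the inputs, feedback lags 1..M+1 on the unit's
    own past output).  With ``spike_output`` the spike at t is Bernoulli with
    probability clip(drive, 0, 1) using previously *generated* spikes in the
    feedback term; otherwise the continuous unclipped drive itself feeds back
    (the deterministic, exactly linear regime) and float arrays are returned.
    """
    if not inputs:
        raise ParameterError("need at least one input train")
    n_bins = inputs[0].n_bins
    bw = inputs[0].bin_width
    for tr in inputs:
        if tr.n_bins != n_bins or tr.bin_width != bw:
            raise ParameterError("inputs must share bin width and extent")
    if len(inputs) != circuit.n_ca3:
        raise ParameterError("number of inputs does not match the circuit")
    rng = np.random.default_rng(seed)
    M = circuit.basis.M
    B = circuit.basis.B

    nfft = 1
    while nfft < n_bins + M:
        nfft <<= 1
    in_fft = [np.fft.rfft(tr.values.astype(float), nfft) for tr in inputs]

    outputs = []
    n_clip_total = 0
    for j in range(circuit.n_ca1):
        base = np.full(n_bins, circuit.offsets[j])
        for i in range(circuit.n_ca3):
            if circuit.connectivity[i, j]:
                k = B @ circuit.ff_coeffs[(i, j)]
                kf = np.fft.rfft(k, nfft)
                base += np.fft.irfft(in_fft[i] * kf, nfft)[:n_bins]
        k_ar = B @ circuit.fb_coeffs(j)  # lags 1..M+1
        if not spike_output:
            a = np.concatenate(([1.0], -k_ar))
            outputs.append(lfilter([1.0], a, base))
            continue
        u = rng.random(n_bins)
        fb = np.zeros(n_bins + M + 2)
        y = np.zeros(n_bins, dtype=np.int8)
        n_clip = 0
        for t in range(n_bins):
            drive = base[t] + fb[t]
            if drive < 0.0 or drive > 1.0:
                n_clip += 1
                drive = 0.0 if drive < 0.0 else 1.0
            if u[t] < drive:
                y[t] = 1
                fb[t + 1:t + M + 2] += k_ar
        n_clip_total += n_clip
        outputs.append(SpikeTrain(unit_id=f"{unit_prefix}{j}", region="CA1",
                                  bin_width=bw, t_start=0.0, values=y))
    if n_clip_total:
        warnings.warn(f"simulate_ca1: drive clipped to [0,1] in "
                      f"{n_clip_total} bin(s)")
    return outputs


# --------------------------------------------------------------------------
# study scenarios
# --------------------------------------------------------------------------

@dataclass
class EffectScenario:
    """Programmed condition effects; all magnitudes scale with the per-session
    effect draw g ~ U[0.3, 1].  Gains are the value reached at g = 1."""

    condition: str = "control"
    ff_gain: float = 1.0        # multiplier on feedforward amplitude
    fb_theta_gain: float = 1.0  # multiplier on the oscillatory feedback part
    fb_ei_shift: float = 0.0    # additive slow-excitation weight (EI increase)
    connection_drop: float = 0.0  # probability a true connection is removed
    behavior_slope: float = 0.0   # percent-correct lost per unit magnitude
    behavior_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.connection_drop <= 1.0:
            raise ParameterError("connection_drop must lie in [0, 1]")
        if self.ff_gain < 0 or self.fb_theta_gain < 0:
            raise ParameterError("gains must be non-negative")


def control_scenario() -> EffectScenario:
    return EffectScenario(condition="control")


def thc_scenario() -> EffectScenario:
    """Drug scenario emulating the reported effect directions: weakened and
    sparser feedforward coupling, reduced feedback theta resonance, an
    excitatory shift of the feedback filter, and dose-linked behavioral loss
    (about a 12-point mean drop at the default magnitudes)."""
    return EffectScenario(condition="THC", ff_gain=0.6, fb_theta_gain=0.25,
                          fb_ei_shift=0.9, connection_drop=0.25,
                          behavior_slope=18.8, behavior_noise_sd=2.0)


def apply_scenario(circuit: GroundTruthCircuit, scenario: EffectScenario,
                   magnitude: float, rng: np.random.Generator
                   ) -> tuple[GroundTruthCircuit, list[tuple[int, int]]]:
    """Session-specific circuit under a scenario at effect magnitude g.

    Returns the modified circuit and the list of dropped connections.
    """
    g = float(magnitude)
    ff_gain = 1.0 - (1.0 - scenario.ff_gain) * g
    th_gain = 1.0 - (1.0 - scenario.fb_theta_gain) * g
    shift = scenario.fb_ei_shift * g
    conn = circuit.connectivity.copy()
    dropped = []
    for (i, j) in circuit.true_edges():
        if rng.random() < scenario.connection_drop * g:
            conn[i, j] = 0
            dropped.append((i, j))
    ff_coeffs = {k: v * ff_gain for k, v in circuit.ff_coeffs.items()
                 if conn[k[0], k[1]]}
    new = replace(circuit, connectivity=conn, ff_coeffs=ff_coeffs,
                  fb_theta_gain=np.full(circuit.n_ca1, th_gain),
                  fb_ei_shift=np.full(circuit.n_ca1, shift))
    return new, dropped


@dataclass
class StudyData:
    """One synthetic study: tabular data plus the full ground-truth record."""

    spikes: pd.DataFrame
    meta: pd.DataFrame
    events: pd.DataFrame
    ground_truth: dict


def make_study(
    n_animals: int = 6,
    sessions_per_condition: int = 2,
    duration: float = 600.0,
    circuit_kwargs: dict | None = None,
    scenarios: tuple[EffectScenario, EffectScenario] | None = None,
    event_interval: float = 20.0,
    sample_cell_frac: float = 0.3,
    sample_gain: float = 2.5,
    seed: int = 0,
) -> StudyData:
    """Generate a control-versus-drug study, a pure function of ``seed``.

    Each animal has its own ground-truth circuit shared by all its sessions;
    every drug session draws an effect magnitude g ~ U[0.3, 1] that scales all
    programmed effects, and its behavior is the animal's control mean minus
    ``behavior_slope * g`` plus Gaussian noise.  The ground-truth record holds
    per-session magnitudes, surviving/dropped edges and noiseless behavior,
    for recovery scoring.
    """
    scenarios = scenarios or (control_scenario(), thc_scenario())
    ctrl, drug = scenarios
    circuit_kwargs = dict(circuit_kwargs or {})
    root = np.random.default_rng(np.random.SeedSequence(seed))
    spike_rows, meta_rows, event_rows = [], [], []
    gt: dict = {"seed": seed, "sessions": {}, "animals": {}}

    for a in range(n_animals):
        animal = f"rat{a}"
        circuit = make_circuit(seed=int(root.integers(2 ** 31)),
                               **circuit_kwargs)
        base_perf = 70.0 + root.uniform(0.0, 10.0)
        n_sample_cells = int(round(sample_cell_frac * circuit.n_ca3))
        gt["animals"][animal] = {
            "base_performance": base_perf,
            "n_ca3": circuit.n_ca3, "n_ca1": circuit.n_ca1,
            "edges": circuit.true_edges(),
        }
        for cond_scenario, cond in ((ctrl, "control"), (drug, "THC")):
            for s in range(sessions_per_condition):
                sid = f"{animal}_{cond}_{s}"
                if cond == "control":
                    g = 0.0
                    sess_circ, dropped = circuit, []
                else:
                    g = float(root.uniform(0.3, 1.0))
                    sess_circ, dropped = apply_scenario(
                        circuit, cond_scenario, g, root)
                perf_clean = base_perf - cond_scenario.behavior_slope * g
                perf = float(np.clip(
                    perf_clean + root.normal(0.0, cond_scenario.behavior_noise_sd),
                    0.0, 100.0))

                n_events = int(duration // event_interval)
                events = (np.arange(n_events) * event_interval
                          + root.uniform(2.0, event_interval - 2.0, n_events))
                events = np.sort(events[events < duration - 2.0])

                seed_in = int(root.integers(2 ** 31))
                plain = make_theta_inputs(
                    circuit.n_ca3 - n_sample_cells, duration,
                    rate=circuit.input_rate, theta_freq=circuit.theta_freq,
                    theta_depth=circuit.theta_depth,
                    bin_width=circuit.bin_width, seed=seed_in)
                resp = make_theta_inputs(
                    n_sample_cells, duration, rate=circuit.input_rate,
                    theta_freq=circuit.theta_freq,
                    theta_depth=circuit.theta_depth,
                    bin_width=circuit.bin_width, seed=seed_in + 1,
                    events=events, event_gain=sample_gain)
                inputs = plain + resp
                for i, tr in enumerate(inputs):
                    tr.unit_id = f"{animal}_ca3_{i}"
                outputs = simulate_ca1(inputs, sess_circ,
                                       seed=int(root.integers(2 ** 31)))
                for j, tr in enumerate(outputs):
                    tr.unit_id = f"{animal}_ca1_{j}"

                for tr in inputs + outputs:
                    times = tr.spike_times()
                    spike_rows.append(pd.DataFrame({
                        "session_id": sid, "unit_id": tr.unit_id,
                        "region": tr.region, "spike_time": times}))
                meta_rows.append({"session_id": sid, "animal_id": animal,
                                  "condition": cond, "performance": perf})
                event_rows.append(pd.DataFrame({"session_id": sid,
                                                "event_time": events}))
                gt["sessions"][sid] = {
                    "animal_id": animal, "condition": cond,
                    "magnitude": g, "dropped_edges": dropped,
                    "true_edges": [(f"{animal}_ca3_{i}", f"{animal}_ca1_{j}")
                                   for (i, j) in sess_circ.true_edges()],
                    "performance_clean": perf_clean,
                    "performance": perf,
                }
    spikes = (pd.concat(spike_rows, ignore_index=True)
              .sort_values(["session_id", "unit_id", "spike_time"],
                           kind="mergesort").reset_index(drop=True))
    meta = (pd.DataFrame(meta_rows).sort_values("session_id", kind="mergesort")
            .reset_index(drop=True))
    events = (pd.concat(event_rows, ignore_index=True)
              .sort_values(["session_id", "event_time"], kind="mergesort")
              .reset_index(drop=True))
    return StudyData(spikes=spikes, meta=meta, events=events, ground_truth=gt)
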