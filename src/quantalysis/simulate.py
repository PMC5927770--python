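"""Synthetic recordings with binomial release statistics and known ground truth.

The generator produces the data the estimators assume: each stimulus releases
``Binomial(N, p)`` quanta, each quantum contributes a gamma-distributed
postsynaptic amplitude (mean ``q_mean``, coefficient of variation ``q_cv``),
release probability rises with extracellular Ca2+ along a Hill curve, and
high-frequency trains deplete a finite readily releasable pool that refills
at a constant rate.  Everything is seeded and bit-reproducible; scenario
generation writes a ground-truth sidecar so parameter recovery can be scored.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CURRENT_CLAMP, MODES, TEVC, TraceRecording, TrainResponse


# --------------------------------------------------------------------------
# ground-truth parameter models
# --------------------------------------------------------------------------

@dataclass
class ReleaseModel:
    """Binomial release parameters of one cell: N sites, p(Ca), quantal size Q.

    Quantal content is the product N * p * Q / Q = N * p quanta per stimulus;
    the mean evoked amplitude is N * p * q_mean.
    """

    n_sites: int = 150
    p_max: float = 0.85
    ca_half: float = 1.7      # mM at which p = p_max / 2
    hill: float = 2.2
    q_mean: float = 0.6       # nA (TEVC) or mV (current clamp)
    q_cv: float = 0.3

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.ca_half <= 0 or self.hill <= 0:
            raise ValueError("ca_half and hill must be positive")
        if self.q_mean <= 0:
            raise ValueError("q_mean must be positive")
        if self.q_cv < 0:
            raise ValueError("q_cv must be nonnegative")


@dataclass
class PoolModel:
    """Readily releasable pool: size, per-stimulus release fraction, refill rate."""

    pool_size: int = 600          # quanta
    release_fraction: float = 0.3  # per stimulus, of the currently available pool
    replenish_rate: float = 1800.0  # quanta / s toward pool_size

    def __post_init__(self):
        if self.pool_size < 0:
            raise ValueError("pool_size must be >= 0")
        if not 0 <= self.release_fraction <= 1:
            raise ValueError("release_fraction must be in [0, 1]")
        if self.replenish_rate < 0:
            raise ValueError("replenish_rate must be >= 0")


@dataclass
class RecordingConfig:
    """Acquisition parameters for trace synthesis."""

    sampling_rate: float = 10_000.0  # Hz
    duration: float = 30.0           # s
    kernel_rise: float = 0.002       # s
    kernel_decay: float = 0.015      # s
    noise_sd: float = 0.12           # amplitude units
    mini_rate: float = 2.0           # spontaneous events / s
    holding: float = -70.0           # mV, TEVC holding potential (metadata)
    mode: str = CURRENT_CLAMP

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if not self.kernel_decay > self.kernel_rise > 0:
            raise ValueError("require kernel_decay > kernel_rise > 0")
        if self.noise_sd < 0 or self.mini_rate < 0:
            raise ValueError("noise_sd and mini_rate must be nonnegative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class ScenarioConfig:
    """A simulated genotype: per-muscle ground truth plus protocol settings."""

    label: str
    muscles: dict  # muscle name -> (ReleaseModel, PoolModel)
    ca_levels: tuple = (0.5, 1.5, 3.0, 6.0)
    n_sweeps_per_level: int = 30
    train_ca: float = 3.0
    train_freq: float = 60.0
    train_n: int = 30
    baseline_ca: float = 0.4  # evoked/mini quantal-content condition
    # TEVC by default: the pool and variance-mean protocols are voltage clamp
    recording: RecordingConfig = field(
        default_factory=lambda: RecordingConfig(mode=TEVC))
    seed: int = 0

    def __post_init__(self):
        if not self.muscles:
            raise ValueError("at least one muscle required")
        for name, pair in self.muscles.items():
            if len(pair) != 2:
                raise ValueError(f"muscle {name!r} needs (ReleaseModel, PoolModel)")
        ca = np.asarray(self.ca_levels, dtype=float)
        if ca.size == 0 or np.any(np.diff(ca) <= 0):
            raise ValueError("ca_levels must be non-empty and strictly increasing")


# --------------------------------------------------------------------------
# seeding: one stream per scenario, named substreams per condition
# --------------------------------------------------------------------------

def substream(seed: int, *labels) -> np.random.Generator:
    """Deterministic named substream so conditions do not perturb each other."""
    keys = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


# --------------------------------------------------------------------------
# core draws
# --------------------------------------------------------------------------

def release_probability_at(model: ReleaseModel, ca: float) -> float:
    """Hill-form release probability p(Ca) = p_max * ca^h / (ca_half^h + ca^h)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca must be nonnegative")
    with np.errstate(divide="ignore"):
        x = np.where(ca > 0, ca ** model.hill, 0.0)
    p = model.p_max * x / (model.ca_half ** model.hill + x)
    return float(p) if p.ndim == 0 else p


def _summed_quanta(rng: np.random.Generator, counts, q_mean: float,
                   q_cv: float) -> np.ndarray:
    """Sum of ``counts`` i.i.d. gamma quanta per entry (closed under addition)."""
    counts = np.asarray(counts)
    if q_cv == 0:
        return counts * q_mean
    shape = 1.0 / q_cv**2
    scale = q_mean * q_cv**2
    return rng.gamma(counts * shape, scale)


def draw_quantal_sizes(rng: np.random.Generator, q_mean: float, q_cv: float,
                       size: int) -> np.ndarray:
    """Single-quantum amplitudes: gamma with mean q_mean and CV q_cv."""
    if q_cv == 0:
        return np.full(size, q_mean)
    return rng.gamma(1.0 / q_cv**2, q_mean * q_cv**2, size=size)


def draw_evoked_amplitudes(model: ReleaseModel, ca: float, n_sweeps: int,
                           seed=None, rng: np.random.Generator | None = None,
                           ) -> np.ndarray:
    """Per-sweep evoked amplitudes under binomial release at one Ca level.

    amplitude = sum over released sites of a gamma quantal draw, so
    E = N p Q and Var = N p (1-p) Q^2 + N p Q^2 q_cv^2.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    p = release_probability_at(model, ca)
    released = rng.binomial(model.n_sites, p, size=n_sweeps)
    return _summed_quanta(rng, released, model.q_mean, model.q_cv)


def simulate_train(model: ReleaseModel, pool: PoolModel, ca: float,
                   n_stim: int = 30, freq: float = 60.0, seed=None,
                   rng: np.random.Generator | None = None) -> TrainResponse:
    """Depleting pool: r_k ~ Binomial(available_k, f), refill at fixed rate.

    The available pool refills by ``replenish_rate / freq`` quanta between
    stimuli (capped at pool_size), giving a steady-state release near
    replenish_rate / freq quanta per stimulus — the linear cumulative phase
    the back-extrapolation estimator fits.
    """
    if n_stim < 2:
        raise ValueError("n_stim must be >= 2")
    if freq <= 0:
        raise ValueError("freq must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    refill = pool.replenish_rate / freq
    available = float(pool.pool_size)
    released = np.zeros(n_stim, dtype=int)
    for k in range(n_stim):
        r = rng.binomial(int(available), pool.release_fraction)
        released[k] = r
        available = min(float(pool.pool_size), available - r + refill)
    amplitudes = _summed_quanta(rng, released, model.q_mean, model.q_cv)
    train = TrainResponse(amplitudes=amplitudes, freq=freq, ca_mM=ca)
    train.released = released  # ground truth for conservation checks
    return train


def mean_train_trajectory(pool: PoolModel, n_stim: int, freq: float) -> np.ndarray:
    """Deterministic mean dynamics of the depletion model (released quanta/stim).

    Oracle for the stochastic train: a_{k+1} = min(pool, a_k(1-f) + R).
    """
    refill = pool.replenish_rate / freq
    a = float(pool.pool_size)
    out = np.zeros(n_stim)
    for k in range(n_stim):
        r = a * pool.release_fraction
        out[k] = r
        a = min(float(pool.pool_size), a - r + refill)
    return out


# --------------------------------------------------------------------------
# trace synthesis
# --------------------------------------------------------------------------

def psp_kernel(times: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials synaptic kernel, normalized to unit peak."""
    t = np.asarray(times, dtype=float)
    k = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


def kernel_peak_delay(rise: float, decay: float) -> float:
    return rise * decay / (decay - rise) * np.log(decay / rise)


def kernel_half_rise_delay(rise: float, decay: float) -> float:
    """Onset-to-half-peak delay of the kernel (the detector's timestamp)."""
    from scipy.optimize import brentq
    t_peak = kernel_peak_delay(rise, decay)
    k = lambda t: psp_kernel(np.array([t]), rise, decay)[0] - 0.5
    return brentq(k, 1e-12, t_peak)


def synthesize_trace(events, config: RecordingConfig, seed=None,
                     release_model: ReleaseModel | None = None,
                     rng: np.random.Generator | None = None,
                     stim_times=None, metadata: dict | None = None,
                     ) -> TraceRecording:
    """Render point events into a sampled sweep.

    Parameters
    ----------
    events : sequence of (time_s, amplitude)
        Evoked events; each contributes ``amplitude`` at the kernel peak.
    release_model : ReleaseModel, optional
        Supplies the quantal-size distribution for spontaneous minis when
        ``config.mini_rate > 0``.

    The trace is baseline + sum of unit-peak kernels + Gaussian noise;
    TEVC traces deflect negative.  Ground-truth mini times/amplitudes are
    recorded in ``metadata["truth"]``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    events = [(float(t), float(a)) for t, a in events]
    for t, _ in events:
        if not 0 <= t <= config.duration:
            raise ValueError(f"event time {t} outside [0, {config.duration}]")

    n = int(round(config.duration * config.sampling_rate))
    fs = config.sampling_rate
    impulses = np.zeros(n)

    mini_times: list[float] = []
    mini_amps: list[float] = []
    if config.mini_rate > 0:
        if release_model is None:
            raise ValueError("mini_rate > 0 requires a release_model for "
                             "quantal-size draws")
        n_minis = rng.poisson(config.mini_rate * config.duration)
        times = np.sort(rng.uniform(0, config.duration, size=n_minis))
        amps = draw_quantal_sizes(rng, release_model.q_mean,
                                  release_model.q_cv, n_minis)
        mini_times, mini_amps = list(times), list(amps)

    for t, a in events + list(zip(mini_times, mini_amps)):
        idx = int(round(t * fs))
        if idx < n:
            impulses[idx] += a

    kernel_len = int(round((config.kernel_decay * 8 + config.kernel_rise) * fs))
    kt = np.arange(kernel_len) / fs
    kernel = psp_kernel(kt, config.kernel_rise, config.kernel_decay)
    trace = np.convolve(impulses, kernel)[:n]
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, size=n)

    baseline = config.holding if config.mode == TEVC else 0.0
    sign = -1.0 if config.mode == TEVC else 1.0
    samples = baseline + sign * trace

    meta = dict(metadata or {})
    meta["truth"] = {
        "mini_times": [round(float(t), 9) for t in mini_times],
        "mini_amps": [round(float(a), 9) for a in mini_amps],
        "event_times": [t for t, _ in events],
        "event_amps": [a for _, a in events],
    }
    return TraceRecording(
        samples=samples, sampling_rate=fs,
        stim_times=np.asarray(stim_times if stim_times is not None else [],
                              dtype=float),
        mode=config.mode, metadata=meta)


# --------------------------------------------------------------------------
# scenario templates and dataset generation
# --------------------------------------------------------------------------

WT_RELEASE = dict(n_sites=150, p_max=0.85, ca_half=1.7, hill=2.2,
                  q_mean=0.6, q_cv=0.3)
WT_POOL = dict(pool_size=600, release_fraction=0.3, replenish_rate=1800.0)

# Chronic GluRIIA knockdown on the manipulated muscle: quantal size halved,
# functional site number doubled (quantal content doubled, so evoked
# amplitude is homeostatically maintained), readily releasable pool +65%.
KD_Q_FACTOR = 0.5
KD_N_FACTOR = 2.0
KD_POOL_FACTOR = 1.65


def _wt_pair(mode=TEVC):
    return (ReleaseModel(**WT_RELEASE), PoolModel(**WT_POOL))


def _kd_pair(mode=TEVC):
    rel = dict(WT_RELEASE)
    rel["q_mean"] = rel["q_mean"] * KD_Q_FACTOR
    rel["n_sites"] = int(round(rel["n_sites"] * KD_N_FACTOR))
    pool = dict(WT_POOL)
    pool["pool_size"] = int(round(pool["pool_size"] * KD_POOL_FACTOR))
    return (ReleaseModel(**rel), PoolModel(**pool))


def wild_type_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Both muscles share wild-type ground truth."""
    return ScenarioConfig(label="wild_type",
                          muscles={"m6": _wt_pair(), "m7": _wt_pair()},
                          seed=seed, **overrides)


def knockdown_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Muscle-6-restricted GluRIIA knockdown; muscle 7 stays wild type."""
    return ScenarioConfig(label="m6_gluriia_rnai",
                          muscles={"m6": _kd_pair(), "m7": _wt_pair()},
                          seed=seed, **overrides)


def phtx_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Acute receptor blockade: quantal size reduced on both muscles, with
    homeostatic doubling of functional sites (global acute potentiation)."""
    return ScenarioConfig(label="phtx",
                          muscles={"m6": _kd_pair(), "m7": _kd_pair()},
                          seed=seed, **overrides)


SCENARIO_TEMPLATES = {
    "wild_type": wild_type_scenario,
    "knockdown": knockdown_scenario,
    "phtx": phtx_scenario,
}


def generate_scenario(scenario: ScenarioConfig, out_dir, overwrite: bool = False,
                      fmt: str = "text") -> pd.DataFrame:
    """Write a full synthetic dataset: manifest, traces, ground-truth sidecar.

    Per muscle: one spontaneous sweep, ``n_sweeps_per_level`` evoked sweeps at
    each Ca level, and one high-frequency train.  Returns the manifest frame.
    """
    if fmt not in ("text", "hdf5"):
        raise ValueError("fmt must be 'text' or 'hdf5'")
    out = Path(out_dir)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if fmt == "text" else ".h5"
    writer = (lambda tr, p: tr.to_text(p)) if fmt == "text" else \
             (lambda tr, p: tr.to_hdf5(p))

    rows = []
    truth: dict = {"label": scenario.label, "seed": scenario.seed, "muscles": {}}
    cfg = scenario.recording

    for muscle, (model, pool) in sorted(scenario.muscles.items()):
        truth["muscles"][muscle] = {
            "release": vars(model).copy(),
            "pool": vars(pool).copy(),
            "p_ca": {str(ca): release_probability_at(model, ca)
                     for ca in list(scenario.ca_levels) + [scenario.baseline_ca]},
        }

        def add(trace, name, kind, ca):
            path = f"{scenario.label}_{muscle}_{name}{ext}"
            writer(trace, out / path)
            rows.append(dict(
                path=path, mode=trace.mode, muscle=muscle,
                genotype=scenario.label, ca_mM=ca, kind=kind,
                sampling_rate=trace.sampling_rate,
                stim_times=";".join(f"{t:.6f}" for t in trace.stim_times)))

        # spontaneous activity
        rng = substream(scenario.seed, muscle, "spont")
        spont = synthesize_trace([], cfg, rng=rng, release_model=model,
                                 metadata={"muscle": muscle,
                                           "genotype": scenario.label})
        add(spont, "spont", "spont", 0.0)

        # evoked sweeps per Ca level (short sweeps, one stimulus each)
        sweep_cfg = RecordingConfig(
            sampling_rate=cfg.sampling_rate, duration=0.3,
            kernel_rise=cfg.kernel_rise, kernel_decay=cfg.kernel_decay,
            noise_sd=cfg.noise_sd, mini_rate=0.0, holding=cfg.holding,
            mode=cfg.mode)
        stim_t = 0.05
        levels = [(scenario.baseline_ca, "baseline")] + [
            (ca, "evoked") for ca in scenario.ca_levels]
        for ca, kind in levels:
            rng = substream(scenario.seed, muscle, kind, ca)
            amps = draw_evoked_amplitudes(model, ca, scenario.n_sweeps_per_level,
                                          rng=rng)
            for j, a in enumerate(amps):
                sweep = synthesize_trace([(stim_t, a)], sweep_cfg, rng=rng,
                                         stim_times=[stim_t],
                                         metadata={"muscle": muscle,
                                                   "genotype": scenario.label,
                                                   "sweep": j})
                add(sweep, f"{kind}_ca{ca:g}_{j:02d}", kind, ca)

        # high-frequency train
        rng = substream(scenario.seed, muscle, "train")
        train = simulate_train(model, pool, scenario.train_ca,
                               n_stim=scenario.train_n,
                               freq=scenario.train_freq, rng=rng)
        t0 = 0.1
        stim_times = t0 + train.stimulus_times
        train_cfg = RecordingConfig(
            sampling_rate=cfg.sampling_rate,
            duration=t0 + scenario.train_n / scenario.train_freq + 0.3,
            kernel_rise=cfg.kernel_rise, kernel_decay=cfg.kernel_decay,
            noise_sd=cfg.noise_sd, mini_rate=0.0, holding=cfg.holding,
            mode=cfg.mode)
        trace = synthesize_trace(list(zip(stim_times, train.amplitudes)),
                                 train_cfg, rng=rng, stim_times=stim_times,
                                 metadata={"muscle": muscle,
                                           "genotype": scenario.label})
        add(trace, "train", "train", scenario.train_ca)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
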