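"""Synthetic multi-channel 2-AFC contrast-discrimination sessions.

Emulates the trial and population structure of a chronic multi-electrode
contrast-categorization experiment: each trial presents a fixed 30% sample
grating followed by a test grating at one of 14 contrasts (10-60%), and the
subject reports whether the test was higher or lower in contrast.  Each
recording "channel" (a small multi-unit cluster) is contrast-tuned via a
Naka-Rushton CRF whose C50 drifts toward the 30% boundary and whose
exponent steepens over training days (perceptual learning), and spike
counts carry the two noise structures the downstream analyses probe:

* a *shared within-trial gain*: one lognormal factor per trial multiplies
  the expected sample- and test-epoch counts of every channel, emulating
  slow excitability fluctuations;
* *cross-channel noise correlations*: a latent Gaussian correlation matrix
  blending a uniform component with the tuning-similarity matrix (signal
  correlations of the generating CRFs), so similarly tuned channels share
  more noise and noise correlations grow with signal correlations.  The
  blend scale is calibrated per day so the mean pairwise count correlation
  follows a configured early-to-late schedule, and the tuning-similarity
  share fades with training (the noise-vs-signal correlation slope
  flattens with learning, while overall correlations weaken).

Counts are latent-Gaussian with Poisson-like variance (variance = mean),
rounded and clipped at zero.  Choices come from a noisy linear readout of
test-epoch population activity against a fixed criterion; the criterion
noise shrinks over training, so neuronal activity becomes increasingly
predictive of the upcoming choice (rising choice probability).

Everything is driven by a single integer seed: identical configs produce
bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tuning import BOUNDARY_CONTRAST, CRFParams

__all__ = [
    "CONTRAST_LEVELS",
    "HARD_CONTRASTS",
    "LearningTrajectory",
    "ReadoutConfig",
    "GeneratorConfig",
    "SessionData",
    "BinnedPopulation",
    "generate_population",
    "simulate_session",
    "simulate_choice",
    "generate_dataset",
    "simulate_binned_sessions",
    "write_sessions",
    "read_sessions",
]

#: The 14 test contrasts used throughout (% contrast).
CONTRAST_LEVELS = (10.0, 15.0, 20.0, 25.0, 27.0, 28.0, 29.0,
                   31.0, 32.0, 33.0, 35.0, 40.0, 50.0, 60.0)

#: The six most difficult test contrasts (closest to the 30% boundary).
HARD_CONTRASTS = (27.0, 28.0, 29.0, 31.0, 32.0, 33.0)


@dataclass(frozen=True)
class LearningTrajectory:
    """Per-day drift of CRF parameters with training.

    ``c50_step``: % contrast per day by which C50 moves toward the 30%
    boundary (clamped at the boundary).  ``exponent_growth``: multiplicative
    per-day factor on the Naka-Rushton exponent (capped at 10).  Setting
    both to the identity (0 and 1) freezes tuning across days.
    """

    c50_step: float = 0.4
    exponent_growth: float = 1.015

    @property
    def enabled(self) -> bool:
        return self.c50_step != 0.0 or self.exponent_growth != 1.0


@dataclass(frozen=True)
class ReadoutConfig:
    """Linear choice readout: weights, criterion and criterion noise.

    ``weights`` default to the day-1 CRF slopes at 30% (so reversed-tuned
    channels get negative weights).  The criterion is the weighted expected
    population count at the 30% sample contrast.  Criterion noise is
    expressed as a multiple of the trial-to-trial SD of the weighted
    sample-epoch activity, interpolated linearly from ``noise_early`` to
    ``noise_late`` across days (the readout improves with training).
    """

    weights: tuple | None = None
    noise_early: float = 3.5
    noise_late: float = 0.6


@dataclass(frozen=True)
class GeneratorConfig:
    n_channels: int = 24
    n_days: int = 22
    trials_per_contrast: int = 60
    contrast_levels: tuple = CONTRAST_LEVELS
    sample_contrast: float = BOUNDARY_CONTRAST
    crf_init: tuple | None = None          # per-channel CRFParams, or drawn
    trajectory: LearningTrajectory = field(default_factory=LearningTrajectory)
    gain_sigma: float = 0.05               # SD of log shared within-trial gain
    noise_corr_early: float = 0.12         # target mean pairwise correlation
    noise_corr_late: float = 0.06
    tuned_corr_early: float = 0.8          # tuning-similarity factor weight
    tuned_corr_late: float = 0.2           # (relative to the uniform factor)
    latent_loading: tuple | None = None    # per-channel relative loadings
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    reversed_fraction: float = 0.125
    adaptation: float = 0.92               # test-epoch attenuation (<=1)
    window_ms: float = 256.0               # sample/test analysis window
    spont_window_ms: float = 300.0         # spontaneous (pre-test) window
    seed: int = 0

    def __post_init__(self):
        levels = np.asarray(self.contrast_levels, dtype=float)
        if np.any(np.diff(levels) <= 0):
            raise ValueError("contrast_levels must be strictly increasing")
        if np.any((levels <= 0) | (levels > 100)):
            raise ValueError("contrast_levels must lie in (0, 100]")
        if self.gain_sigma < 0:
            raise ValueError("gain_sigma must be >= 0")
        if not 0.0 < self.adaptation <= 1.0:
            raise ValueError("adaptation must lie in (0, 1]")
        if not 0.0 <= self.reversed_fraction <= 1.0:
            raise ValueError("reversed_fraction must lie in [0, 1]")
        if self.n_channels < 2 or self.n_days < 1 or self.trials_per_contrast < 1:
            raise ValueError("population/session sizes must be positive")
        if self.crf_init is not None:
            for p in self.crf_init:
                if not p.flat and (p.rmax <= 0 or p.m < 0):
                    raise ValueError("crf_init requires Rmax>0 and M>=0")

    @property
    def n_reversed(self) -> int:
        return int(round(self.reversed_fraction * self.n_channels))


@dataclass
class SessionData:
    """One day's trials: counts (trials x channels x 3 epochs) plus labels.

    Epoch order is (spontaneous, sample, test).  ``ground_truth`` embeds the
    generating CRF parameters, per-trial gains and readout used, so every
    downstream estimator can be checked against what was injected.
    """

    day: int
    counts: np.ndarray
    test_contrast: np.ndarray
    choice: np.ndarray        # 'higher' / 'lower'
    correct: np.ndarray       # bool
    ground_truth: dict

    EPOCHS = ("spont", "sample", "test")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    def epoch(self, name: str) -> np.ndarray:
        return self.counts[:, :, self.EPOCHS.index(name)]


def _drifted_params(p: CRFParams, day: int, traj: LearningTrajectory
                    ) -> CRFParams:
    dist = abs(p.c50 - BOUNDARY_CONTRAST)
    dist_d = max(dist - traj.c50_step * (day - 1), 0.0)
    c50_d = BOUNDARY_CONTRAST + np.sign(p.c50 - BOUNDARY_CONTRAST) * dist_d
    n_d = min(p.n * traj.exponent_growth ** (day - 1), 10.0)
    if not (0.0 < c50_d < 100.0):
        raise ValueError(
            f"learning trajectory drove C50 to {c50_d} (outside (0,100))")
    return dataclasses.replace(p, c50=c50_d, n=n_d)


def _draw_initial_population(config: GeneratorConfig) -> list:
    rng = np.random.default_rng([config.seed, 101])
    n_rev = config.n_reversed
    params = []
    for i in range(config.n_channels):
        rmax = rng.uniform(30.0, 80.0)
        side = 1.0 if rng.random() < 0.7 else -1.0   # most start above 30%
        c50 = BOUNDARY_CONTRAST + side * rng.uniform(3.0, 10.0)
        n = rng.uniform(1.5, 3.0)
        m = rng.uniform(4.0, 12.0)
        params.append(CRFParams(rmax=rmax, c50=c50, n=n, m=m,
                                reversed_tuning=(i >= config.n_channels - n_rev)))
    return params


def generate_population(config: GeneratorConfig) -> list:
    """Day-indexed CRF schedule: schedule[d-1][i] is channel i's params on day d.

    With learning enabled, |C50(day) - 30| is non-increasing and the
    (rectified) slope at 30% non-decreasing across days; reversed channels
    keep a negative signed slope throughout.
    """
    init = (list(config.crf_init) if config.crf_init is not None
            else _draw_initial_population(config))
    if len(init) != config.n_channels:
        raise ValueError("crf_init length must equal n_channels")
    return [[_drifted_params(p, day, config.trajectory) for p in init]
            for day in range(1, config.n_days + 1)]


def _gain_variance(sigma: float) -> float:
    return float(np.exp(sigma**2) - 1.0)


def _latent_structure(uniform: np.ndarray, tuning_sim: np.ndarray,
                      ratio: float) -> np.ndarray:
    """Unit-scale latent correlation structure among channels.

    A blend of a uniform component (outer product of the relative
    loadings, default all ones) and the tuning-similarity matrix ``S``
    (signal correlations of the generating CRFs): Q = (1-ratio)*u u' +
    ratio*S.  Both terms are PSD, so lam*Q (off-diagonal) with lam in
    [0, 1] always yields a valid correlation matrix.
    """
    u = uniform / max(np.max(np.abs(uniform)), 1e-12)
    q = (1.0 - ratio) * np.outer(u, u) + ratio * tuning_sim
    return _nearest_psd_unit_diag(q)


def _nearest_psd_unit_diag(m: np.ndarray) -> np.ndarray:
    """Eigenvalue-floored projection to a valid correlation structure."""
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= 1e-9:
        return m
    m2 = (v * np.clip(w, 1e-9, None)) @ v.T
    d = np.sqrt(np.diag(m2))
    return m2 / np.outer(d, d)


def _mean_count_corr(lam: float, q: np.ndarray, means: np.ndarray,
                     gain_var: float) -> float:
    """Closed-form mean pairwise count correlation of the latent model.

    ``means``: (n_contrasts, n_channels) expected counts.  Per contrast,
    cov_ij = lam*Q_ij*sqrt(m_i m_j) + m_i m_j v and var_i = m_i + m_i^2 v.
    """
    iu = np.triu_indices(q.shape[0], k=1)
    rs = []
    for m in means:
        sd = np.sqrt(m + m**2 * gain_var)
        cov = lam * q * np.sqrt(np.outer(m, m)) + np.outer(m, m) * gain_var
        rs.append((cov / np.outer(sd, sd))[iu])
    return float(np.mean(rs))


def _solve_latent_scale(target: float, q: np.ndarray, means: np.ndarray,
                        gain_var: float) -> float:
    """Bisect lam in [0, 1] so the mean count correlation hits target."""
    lo, hi = 0.0, 1.0
    if _mean_count_corr(lo, q, means, gain_var) >= target:
        return lo
    if _mean_count_corr(hi, q, means, gain_var) <= target:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _mean_count_corr(mid, q, means, gain_var) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _latent_cholesky(lam: float, q: np.ndarray) -> np.ndarray:
    m = lam * q
    np.fill_diagonal(m, 1.0)
    # tiny jitter guards the factorization against numerically semidefinite
    # blends (e.g. identical tuning curves)
    return np.linalg.cholesky(m + 1e-9 * np.eye(m.shape[0]))


def _day_target_corr(config: GeneratorConfig, day: int) -> float:
    if config.n_days == 1:
        return config.noise_corr_early
    frac = (day - 1) / (config.n_days - 1)
    return (config.noise_corr_early
            + (config.noise_corr_late - config.noise_corr_early) * frac)


def _day_tuned_ratio(config: GeneratorConfig, day: int) -> float:
    if config.n_days == 1:
        return config.tuned_corr_early
    frac = (day - 1) / (config.n_days - 1)
    return (config.tuned_corr_early
            + (config.tuned_corr_late - config.tuned_corr_early) * frac)


def _latent_counts(mean: np.ndarray, chol: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Rounded, clipped latent-Gaussian counts with variance = mean and
    cross-channel correlation given by the Cholesky factor ``chol``."""
    eps = rng.standard_normal(mean.shape) @ chol.T
    x = mean + np.sqrt(mean) * eps
    return np.maximum(np.rint(x), 0.0).astype(np.int64)


def simulate_session(schedule, day: int, config: GeneratorConfig,
                     with_choices: bool = True) -> SessionData:
    """Simulate one day's session from the population schedule.

    A shared lognormal gain (mean exactly 1) is drawn once per trial and
    applied multiplicatively to both the sample- and test-epoch expected
    counts; cross-channel correlations come from a shared latent factor
    whose per-day loading scale is solved so the mean pairwise count
    correlation follows the configured early-to-late schedule.
    """
    if not 1 <= day <= len(schedule):
        raise ValueError(f"schedule does not cover day {day}")
    params = schedule[day - 1]
    rng = np.random.default_rng([config.seed, 11, day])

    levels = np.asarray(config.contrast_levels, dtype=float)
    contrasts = np.repeat(levels, config.trials_per_contrast)
    rng.shuffle(contrasts)
    n_trials = contrasts.size
    n_ch = config.n_channels
    win_s = config.window_ms / 1000.0
    spont_s = config.spont_window_ms / 1000.0

    # short-term contrast adaptation: the sample grating precedes the test
    # by <1 s and attenuates test-epoch responses by a fixed factor, which
    # places the point of neuronal equality above the 30% boundary
    rate_at = np.stack([p.rate(levels) for p in params], axis=1)  # (14, n_ch)
    mean_test_by_c = config.adaptation * win_s * rate_at          # counts
    sample_rate = np.array([float(p.rate(config.sample_contrast))
                            for p in params])
    spont_rate = np.array([p.m for p in params])

    uniform = (np.ones(n_ch) if config.latent_loading is None
               else np.asarray(config.latent_loading, dtype=float))
    # tuning-similarity component: similarly tuned channels share more
    # noise, so noise correlations grow with signal correlations; the
    # component's weight fades from early to late training.  Similarity is
    # taken on the Fisher-z scale (normalized), where the downstream
    # regression of noise on signal correlation operates -- monotone
    # contrast tuning compresses raw curve correlations near 1.
    with np.errstate(invalid="ignore"):
        tuning_sim = np.corrcoef(rate_at.T)
    tuning_sim = np.nan_to_num(tuning_sim, nan=0.0)
    tuning_sim = np.clip(
        np.arctanh(np.clip(tuning_sim, -0.999, 0.999)) / 3.0, -1.0, 1.0)
    np.fill_diagonal(tuning_sim, 1.0)
    ratio = _day_tuned_ratio(config, day)
    q = _latent_structure(uniform, tuning_sim, ratio)
    gain_var = _gain_variance(config.gain_sigma)
    lam = _solve_latent_scale(_day_target_corr(config, day), q,
                              mean_test_by_c, gain_var)
    chol = _latent_cholesky(lam, q)

    if config.gain_sigma > 0:
        gains = rng.lognormal(mean=-config.gain_sigma**2 / 2.0,
                              sigma=config.gain_sigma, size=n_trials)
    else:
        gains = np.ones(n_trials)

    idx = np.searchsorted(levels, contrasts)
    mean_test = gains[:, None] * mean_test_by_c[idx, :]
    mean_sample = gains[:, None] * (win_s * sample_rate)[None, :]
    mean_spont = np.broadcast_to(spont_s * spont_rate, (n_trials, n_ch))

    counts = np.empty((n_trials, n_ch, 3), dtype=np.int64)
    for e, mean in enumerate([mean_spont, mean_sample, mean_test]):
        counts[:, :, e] = _latent_counts(np.asarray(mean, dtype=float),
                                         chol, rng)

    session = SessionData(
        day=day,
        counts=counts,
        test_contrast=contrasts,
        choice=np.full(n_trials, "", dtype=object),
        correct=np.zeros(n_trials, dtype=bool),
        ground_truth={
            "params": params,
            "gains": gains,
            "latent_scale": lam,
            "tuned_ratio": ratio,
            "target_corr": _day_target_corr(config, day),
            "window_s": win_s,
            "spont_window_s": spont_s,
        },
    )
    if with_choices:
        simulate_choice(session, config, schedule)
    return session


def _readout_noise_sd_fraction(config: GeneratorConfig, day: int) -> float:
    ro = config.readout
    if config.n_days == 1:
        return ro.noise_early
    frac = (day - 1) / (config.n_days - 1)
    return ro.noise_early + (ro.noise_late - ro.noise_early) * frac


def simulate_choice(session: SessionData, config: GeneratorConfig,
                    schedule) -> SessionData:
    """Fill in choices from a noisy linear readout of test-epoch activity.

    choice = 'higher' iff w . test_counts + eps >= criterion, with the
    criterion set at the weighted expected sample-epoch (30% contrast)
    count and eps Gaussian; exact ties go to 'higher'.  Deterministic given
    the config seed.
    """
    ro = config.readout
    if ro.weights is not None:
        w = np.asarray(ro.weights, dtype=float)
    else:
        w = np.array([p.slope30 for p in schedule[0]])
    if np.all(w == 0.0):
        raise ValueError("readout weights must not be all zero")

    # criterion at the expected *test-epoch* activity of a boundary (30%)
    # stimulus, so the adapted readout is unbiased
    win_s = config.window_ms / 1000.0
    params = session.ground_truth["params"]
    criterion = float(np.sum(
        w * config.adaptation * win_s
        * np.array([float(p.rate(config.sample_contrast))
                    for p in params])))
    dv_sample = session.epoch("sample") @ w
    sd_base = float(np.std(dv_sample))
    noise_sd = _readout_noise_sd_fraction(config, session.day) * sd_base

    rng = np.random.default_rng([config.seed, 12, session.day])
    eps = (noise_sd * rng.standard_normal(session.n_trials)
           if noise_sd > 0 else np.zeros(session.n_trials))
    dv = session.epoch("test") @ w + eps
    higher = dv >= criterion
    session.choice = np.where(higher, "higher", "lower").astype(object)
    session.correct = higher == (session.test_contrast
                                 > config.sample_contrast)
    return session


def generate_dataset(config: GeneratorConfig) -> list:
    """All sessions for the configured training course (days 1..n_days)."""
    schedule = generate_population(config)
    return [simulate_session(schedule, day, config)
            for day in range(1, config.n_days + 1)]


# ---------------------------------------------------------------------------
# Time-binned population counts (analysis-window selection only)


@dataclass
class BinnedPopulation:
    """Channel-pooled per-bin counts for one session (window selection)."""

    bin_ms: float
    sample: np.ndarray        # (trials, n_bins)
    test: np.ndarray          # (trials, n_bins)
    test_contrast: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.sample.shape[1]


def _rate_profile(t_ms: np.ndarray, latency_ms: float) -> np.ndarray:
    """Onset transient (x1.8, tau 80 ms) decaying to a sustained plateau."""
    dt = t_ms - latency_ms
    env = np.where(dt >= 0.0, 1.0 + 0.8 * np.exp(-np.maximum(dt, 0.0) / 80.0),
                   0.0)
    return env


def simulate_binned_sessions(config: GeneratorConfig, n_sessions: int = 5,
                             n_trials: int = 200, latency_ms: float = 30.0,
                             bin_ms: float = 4.0, epoch_ms: float = 512.0,
                             ) -> list:
    """Per-bin Poisson counts pooled across channels, for window selection.

    The population rate follows the summed day-1 CRFs, gated by an onset
    latency and a transient-plus-sustained envelope; the test-epoch rate is
    contrast dependent, the sample epoch sits at the 30% sample contrast.
    """
    schedule = generate_population(config)
    levels = np.asarray(config.contrast_levels, dtype=float)
    pooled_rate = np.sum(np.stack([p.rate(levels) for p in schedule[0]],
                                  axis=1), axis=1)          # per contrast
    pooled_sample = float(sum(p.rate(config.sample_contrast)
                              for p in schedule[0]))
    edges = np.arange(0.0, epoch_ms + 0.5 * bin_ms, bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    env = _rate_profile(centers, latency_ms)
    bin_s = bin_ms / 1000.0

    out = []
    for s in range(n_sessions):
        rng = np.random.default_rng([config.seed, 21, s])
        contrasts = rng.choice(levels, size=n_trials)
        idx = np.searchsorted(levels, contrasts)
        lam_test = pooled_rate[idx][:, None] * env[None, :] * bin_s
        lam_sample = pooled_sample * env[None, :] * bin_s
        out.append(BinnedPopulation(
            bin_ms=bin_ms,
            sample=rng.poisson(np.broadcast_to(lam_sample,
                                               lam_test.shape)),
            test=rng.poisson(lam_test),
            test_contrast=contrasts,
        ))
    return out


# ---------------------------------------------------------------------------
# Delimited-table I/O


def _session_frame(session: SessionData) -> pd.DataFrame:
    n_ch = session.n_channels
    data = {
        "day": session.day,
        "trial": np.arange(session.n_trials),
        "test_contrast": session.test_contrast,
        "choice": session.choice,
        "correct": session.correct.astype(int),
    }
    for e, name in enumerate(["spont", "sample", "test"]):
        for k in range(n_ch):
            data[f"{name}_ch{k}"] = session.counts[:, k, e]
    return pd.DataFrame(data)


def write_sessions(sessions, outdir) -> None:
    """One delimited table per day plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {}
    for s in sessions:
        _session_frame(s).to_csv(outdir / f"session_day{s.day:02d}.csv",
                                 index=False)
        truth[str(s.day)] = {
            "params": [
                {"rmax": p.rmax, "c50": p.c50, "n": p.n, "m": p.m,
                 "reversed_tuning": p.reversed_tuning}
                for p in s.ground_truth["params"]],
            "gains": np.asarray(s.ground_truth["gains"]).tolist(),
            "latent_scale": float(s.ground_truth["latent_scale"]),
            "tuned_ratio": float(s.ground_truth["tuned_ratio"]),
            "target_corr": s.ground_truth["target_corr"],
            "window_s": s.ground_truth.get("window_s", 0.256),
            "spont_window_s": s.ground_truth.get("spont_window_s", 0.300),
        }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_sessions(indir) -> list:
    """Read back sessions written by :func:`write_sessions`."""
    indir = Path(indir)
    truth_path = indir / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    sessions = []
    for path in sorted(indir.glob("session_day*.csv")):
        df = pd.read_csv(path)
        day = int(df["day"].iloc[0])
        ch_cols = [c for c in df.columns if c.startswith("test_ch")]
        n_ch = len(ch_cols)
        counts = np.stack(
            [df[[f"{name}_ch{k}" for k in range(n_ch)]].to_numpy()
             for name in ["spont", "sample", "test"]], axis=2)
        gt = truth.get(str(day), {})
        if "params" in gt:
            gt = dict(gt)
            gt["params"] = [CRFParams(rmax=p["rmax"], c50=p["c50"], n=p["n"],
                                      m=p["m"],
                                      reversed_tuning=p["reversed_tuning"])
                            for p in gt["params"]]
        sessions.append(SessionData(
            day=day,
            counts=counts.astype(np.int64),
            test_contrast=df["test_contrast"].to_numpy(dtype=float),
            choice=df["choice"].to_numpy(dtype=object),
            correct=df["correct"].to_numpy(dtype=bool),
            ground_truth=gt,
        ))
    return sessions


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(config: GeneratorConfig, path) -> None:
    d = _listify(dataclasses.asdict(config))
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("trajectory"):
        d["trajectory"] = LearningTrajectory(**d["trajectory"])
    if d.get("readout"):
        ro = d["readout"]
        if ro.get("weights") is not None:
            ro["weights"] = tuple(ro["weights"])
        d["readout"] = ReadoutConfig(**ro)
    if d.get("crf_init") is not None:
        d["crf_init"] = tuple(
            CRFParams(**{k: v for k, v in p.items()
                         if k in ("rmax", "c50", "n", "m", "reversed_tuning")})
            for p in d["crf_init"])
    if d.get("contrast_levels") is not None:
        d["contrast_levels"] = tuple(d["contrast_levels"])
    if d.get("latent_loading") is not None:
        d["latent_loading"] = tuple(d["latent_loading"])
    return GeneratorConfig(**d)
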