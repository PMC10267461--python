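"""Synthetic cold-pressor studies with known ground truth.

The cold pressor test (CPT) — immersing a hand in ice water — triggers a
sympathetic response: blood pressure rises and peripheral vessels constrict,
which reshapes the pulse wave seen by PPG sensors.  This module emulates a
multi-site CPT recording session so the whole analysis chain can be tested
against known truth: per subject it produces contact-PPG beat trains for the
finger and earlobe (2000 Hz), low-rate head-site traces standing in for
video-derived iPPG (25 Hz, forehead and the "super" face ROI), optional
synthetic video frames that embed such a trace, and a beat-wise reference
series (systolic/diastolic pressure, heart rate).

Beats follow the two-kernel Gamma-Gaussian model, so the generated morphology
is exactly representable by the downstream decomposition.  Stimulus effects
are injected as multiplicative shifts on kernel parameters — amplitude-like
effects on the kernel scales (s1, a2), width effects on the Gamma rate and
Gaussian width (beta1, sigma2) — which keeps the ground-truth features
recomputable from the shifted parameters.  Default effect directions mirror
the physiology the pipeline is meant to resolve: a large vasoconstrictive
amplitude drop at the finger, small drops at the head sites, and a pulse
width (PWHA) that widens at the finger while narrowing at the head.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .beats import INTERVAL_DURATION, INTERVALS, interval_starts
from .pwd import KernelParams, MorphFeatures, extract_features, recompose
from .signals import SampledSignal

__all__ = [
    "StudyConfig",
    "StudyData",
    "SubjectData",
    "generate_beat",
    "generate_beat_train",
    "generate_video",
    "generate_reference_series",
    "generate_study",
    "steepest_ascent_offset",
]

CONTACT_SITES = ("finger", "earlobe")
HEAD_SITES = ("forehead", "super")
REF_PARAMS = ("SBP", "DBP", "HR")

# Site-typical resting beat shapes.  Scales are arbitrary signal units;
# timing parameters are seconds.  All satisfy the fit constraints
# (Gamma peak first and dominant).
BASE_PARAMS: dict[str, KernelParams] = {
    "finger": KernelParams(s1=0.40, alpha1=3.0, beta1=13.0,
                           a2=0.45, mu2=0.42, sigma2=0.09),
    "earlobe": KernelParams(s1=0.30, alpha1=2.8, beta1=14.0,
                            a2=0.35, mu2=0.38, sigma2=0.08),
    "forehead": KernelParams(s1=0.25, alpha1=2.6, beta1=15.0,
                             a2=0.30, mu2=0.36, sigma2=0.08),
    "super": KernelParams(s1=0.25, alpha1=2.6, beta1=15.0,
                          a2=0.30, mu2=0.36, sigma2=0.08),
}

# Multiplicative kernel-parameter shifts per site and stimulation interval.
# s1/a2 control amplitude, slope and area; beta1 (inverse width of the
# systolic kernel) and sigma2 (diastolic width) control PWHA.  Finger: large
# amplitude drop, widening pulse.  Head sites (earlobe, forehead, super):
# small amplitude drop, narrowing pulse; the iPPG sites drift back towards
# baseline by the second stimulation window.
_HEAD_ST = {"s1": 0.82, "a2": 0.82, "beta1": 1.05, "sigma2": 0.82}
DEFAULT_EFFECT_MAP: dict[str, dict[str, dict[str, float]]] = {
    "finger": {
        "ST1": {"s1": 0.50, "a2": 0.50, "beta1": 0.85, "sigma2": 1.25},
        "ST2": {"s1": 0.50, "a2": 0.50, "beta1": 0.85, "sigma2": 1.25},
    },
    "earlobe": {"ST1": dict(_HEAD_ST), "ST2": dict(_HEAD_ST)},
    "forehead": {
        "ST1": dict(_HEAD_ST),
        "ST2": {"s1": 0.95, "a2": 0.95, "beta1": 1.00, "sigma2": 0.95},
    },
    "super": {
        "ST1": dict(_HEAD_ST),
        "ST2": {"s1": 0.95, "a2": 0.95, "beta1": 1.00, "sigma2": 0.95},
    },
}

# Additive reference shifts (mmHg / bpm) per stimulation interval, in the
# range reported for cold-pressor blood-pressure responses.
DEFAULT_REF_SHIFTS = {
    "ST1": {"SBP": 8.0, "DBP": 5.0, "HR": 4.0},
    "ST2": {"SBP": 15.0, "DBP": 10.0, "HR": 3.0},
}
DEFAULT_REF_MEANS = {"SBP": 120.0, "DBP": 70.0, "HR": 70.0}


@dataclass
class StudyConfig:
    """Parameters of one synthetic CPT study.

    The defaults encode the emulated study conditions: 35 analyzable
    subjects, four recording sites, 2000 Hz contact PPG, 25 Hz video-rate
    iPPG, analysis windows of 10 s at ``t_cpt - 30``, ``+20`` and ``+40``
    seconds, ~0.85 s beat-to-beat intervals and site-dependent noise.
    """

    n_subjects: int = 35
    sites: tuple[str, ...] = CONTACT_SITES + HEAD_SITES
    fs_contact: float = 2000.0
    fps_video: float = 25.0
    t_cpt: float = 40.0
    record_duration: float = 95.0
    mean_bbi: float = 0.85
    bbi_sd: float = 0.04
    subject_bbi_sd: float = 0.07     # between-subject spread of the mean BBI
    subject_scale_sd: float = 0.30   # lognormal sd of per-subject amplitude
    subject_shape_sd: float = 0.05   # lognormal sd of timing/width params
    effect_sd: float = 0.30          # lognormal sd of per-subject effect depth
    noise_sd: dict = field(default_factory=lambda: {
        "finger": 0.02, "earlobe": 0.02, "forehead": 0.12, "super": 0.12})
    wander_amplitude: float = 0.3
    wander_frequency: float = 0.2    # Hz, below the 0.4 Hz high-pass corner
    effect_map: dict = field(
        default_factory=lambda: _copy_effect_map(DEFAULT_EFFECT_MAP))
    ref_means: dict = field(default_factory=lambda: dict(DEFAULT_REF_MEANS))
    ref_shifts: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_REF_SHIFTS.items()})
    ref_subject_sd: dict = field(default_factory=lambda: {
        "SBP": 8.0, "DBP": 6.0, "HR": 7.0})
    ref_beat_noise_sd: dict = field(default_factory=lambda: {
        "SBP": 3.0, "DBP": 2.5, "HR": 2.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.mean_bbi <= 0:
            raise ValueError("mean beat-to-beat interval must be positive")
        if self.bbi_sd < 0 or any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("standard deviations must be non-negative")
        starts = interval_starts(self.t_cpt)
        if starts["BL"] + INTERVAL_DURATION > self.t_cpt:
            raise ValueError("baseline window must end before immersion")
        for name, start in starts.items():
            if start < 0 or start + INTERVAL_DURATION > self.record_duration:
                raise ValueError(
                    f"interval {name} [{start}, {start + INTERVAL_DURATION}) s "
                    f"outside the {self.record_duration} s record")

    @property
    def interval_windows(self) -> dict[str, tuple[float, float]]:
        return {name: (start, start + INTERVAL_DURATION)
                for name, start in interval_starts(self.t_cpt).items()}

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(open(path).read()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sites" in raw:
            raw["sites"] = tuple(raw["sites"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sites"] = list(d["sites"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _copy_effect_map(m):
    return {site: {iv: dict(p) for iv, p in per_site.items()}
            for site, per_site in m.items()}


# ---------------------------------------------------------------------------
# Beat-level generation
# ---------------------------------------------------------------------------

def generate_beat(params: KernelParams, duration: float,
                  fs: float) -> SampledSignal:
    """Sample one noise-free beat of the two-kernel model on [0, duration)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    return SampledSignal(values=recompose(params, t), fs=fs, t0=0.0,
                         meta={"kind": "clean_beat"})


def steepest_ascent_offset(params: KernelParams, fs_dense: float = 20000.0,
                           horizon: float = 1.0) -> float:
    """Time from beat onset to the steepest ascent of the clean beat,
    located by dense-grid search of the first-difference maximum."""
    t = np.arange(int(horizon * fs_dense)) / fs_dense
    y = recompose(params, t)
    d = np.diff(y)
    return float(t[int(np.argmax(d))])


def _phase_of(t: float, config: StudyConfig) -> str | None:
    """Which stimulation phase a beat onset falls in.

    Parameters switch at immersion and midway between the two stimulation
    windows, so every beat inside an analysis window carries exactly that
    window's parameters and neighbouring beats transition smoothly.
    """
    if t < config.t_cpt:
        return None  # pre-immersion: baseline parameters
    windows = config.interval_windows
    boundary = 0.5 * (windows["ST1"][1] + windows["ST2"][0])
    return "ST1" if t < boundary else "ST2"


def params_for(site: str, interval: str | None, config: StudyConfig,
               base: KernelParams,
               subject_effects: dict | None = None) -> KernelParams:
    """Kernel parameters of a site in one phase (None or 'BL' = baseline)."""
    if interval in (None, "BL"):
        return base
    site_map = config.effect_map.get(site, {})
    factors = dict(site_map.get(interval, {}))
    if subject_effects is not None:
        factors = {k: subject_effects[site][interval].get(k, v)
                   for k, v in factors.items()}
    return base.scaled(factors) if factors else base


def generate_beat_train(params_by_phase: dict, record_duration: float,
                        config: StudyConfig, rng: np.random.Generator,
                        *, fs: float, noise_sd: float,
                        mean_bbi: float | None = None
                        ) -> tuple[SampledSignal, np.ndarray]:
    """Concatenate beats into a record with wander and noise.

    ``params_by_phase`` maps phase labels (``None``/"BL", "ST1", "ST2") to
    :class:`KernelParams`.  Beat onsets are spaced by a truncated-normal
    beat-to-beat interval; each beat's parameters follow the phase its onset
    falls in.  A sinusoidal baseline wander and white noise are added on
    top.  Returns the record and the true onset times.
    """
    if mean_bbi is None:
        mean_bbi = config.mean_bbi
    if mean_bbi <= 0:
        raise ValueError("mean beat-to-beat interval must be positive")
    windows = config.interval_windows
    last_needed = max(w[1] for w in windows.values())
    if record_duration < last_needed:
        raise ValueError("record does not cover the analysis windows")
    n = int(round(record_duration * fs))
    y = np.zeros(n)
    onsets = []
    t = float(rng.uniform(0, mean_bbi))
    horizon = 2.0  # s; both kernels are negligible beyond this
    n_h = int(horizon * fs)
    while t < record_duration:
        onsets.append(t)
        phase = _phase_of(t, config)
        key = phase if phase is not None else "BL"
        p = params_by_phase.get(key) or params_by_phase.get("BL") \
            or params_by_phase.get(None)
        if p is None:
            raise ValueError("params_by_phase must provide baseline params")
        i0 = int(round(t * fs))
        n_beat = min(n_h, n - i0)
        if n_beat > 0:
            tt = (np.arange(n_beat) + (i0 - t * fs)) / fs
            y[i0:i0 + n_beat] += recompose(p, np.maximum(tt, 0.0))
        bbi = mean_bbi + rng.normal(0.0, config.bbi_sd)
        t += max(bbi, 0.25 * mean_bbi)  # truncate pathological draws
    if config.wander_amplitude > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        tgrid = np.arange(n) / fs
        y += config.wander_amplitude * np.sin(
            2 * np.pi * config.wander_frequency * tgrid + phase0)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=n)
    sig = SampledSignal(values=y, fs=fs, t0=0.0, meta={"kind": "ppg"})
    return sig, np.asarray(onsets)


# ---------------------------------------------------------------------------
# Video generation
# ---------------------------------------------------------------------------

def generate_video(ippg_signal: SampledSignal, frame_shape: tuple[int, int],
                   polygon, pixel_noise_sd: float, fps: float,
                   rng: np.random.Generator, *, background: float = 1800.0,
                   offset: float = 2400.0, bit_depth: int = 12):
    """Render frames that embed a PPG trace inside an ROI.

    Each frame is a constant background; pixels inside the polygon carry
    ``offset - signal(t_frame)`` (the sign is flipped so the downstream
    inversion recovers the physiological polarity) plus i.i.d. pixel noise.
    Intensities are clipped to the sensor's bit range; quantisation is not
    emulated.
    """
    from .ippg import FrameSequence, rasterize  # local import: no cycle at load

    if fps <= 0:
        raise ValueError("fps must be positive")
    mask = rasterize(polygon, frame_shape)
    n_frames = int(np.floor(ippg_signal.duration * fps))
    if n_frames < 1:
        raise ValueError("signal shorter than one frame period")
    t_frames = ippg_signal.t0 + np.arange(n_frames) / fps
    values = np.interp(t_frames, ippg_signal.times, ippg_signal.values)
    frames = np.full((n_frames,) + tuple(frame_shape), background)
    frames[:, mask] = offset - values[:, None]
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, size=frames.shape)
    np.clip(frames, 0.0, 2**bit_depth - 1, out=frames)
    return FrameSequence(frames=frames, fps=fps, bit_depth=bit_depth,
                         t0=ippg_signal.t0)


# ---------------------------------------------------------------------------
# Reference series
# ---------------------------------------------------------------------------

def generate_reference_series(config: StudyConfig, rng: np.random.Generator,
                              onsets: np.ndarray,
                              subject_ref: dict) -> pd.DataFrame:
    """Beat-wise SBP/DBP/HR values aligned with beat onsets.

    Each beat's value is the phase mean (subject baseline plus the injected
    stimulation shift) plus i.i.d. measurement noise.  Pulse pressure is
    derived beat-wise downstream as SBP - DBP.
    """
    rows = {"t": onsets}
    for p in REF_PARAMS:
        base = subject_ref["means"][p]
        vals = np.empty(onsets.size)
        for i, t in enumerate(onsets):
            phase = _phase_of(float(t), config)
            shift = subject_ref["shifts"].get(phase, {}).get(p, 0.0) \
                if phase else 0.0
            vals[i] = base + shift
        noise = config.ref_beat_noise_sd.get(p, 0.0)
        if noise > 0:
            vals = vals + rng.normal(0.0, noise, size=vals.size)
        rows[p] = vals
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject: str
    signals: dict            # site -> SampledSignal (physiological polarity)
    onsets: dict             # site -> ndarray of true onset times, s
    reference: pd.DataFrame  # beat-wise t, SBP, DBP, HR
    params: dict             # (site, interval) -> true KernelParams


@dataclass
class StudyData:
    config: StudyConfig
    subjects: list
    ground_truth: pd.DataFrame  # long: subject, site, interval, params + features


def _jitter_params(base: KernelParams, rng: np.random.Generator,
                   scale_sd: float, shape_sd: float) -> KernelParams:
    """Per-subject beat shape: a shared lognormal perfusion factor on the
    two kernel scales and small lognormal jitter on timing parameters."""
    perfusion = float(np.exp(rng.normal(0.0, scale_sd)))
    f_shape = np.exp(rng.normal(0.0, shape_sd, size=4))
    return KernelParams(
        s1=base.s1 * perfusion,
        alpha1=base.alpha1 * float(np.exp(rng.normal(0.0, shape_sd / 2))),
        beta1=base.beta1 * float(f_shape[0]),
        a2=base.a2 * perfusion * float(f_shape[1]),
        mu2=base.mu2 * float(f_shape[2]),
        sigma2=base.sigma2 * float(f_shape[3]),
    )


def _jitter_effects(config: StudyConfig,
                    rng: np.random.Generator) -> dict:
    """Per-subject effect depths: each multiplicative shift m becomes
    1 + (m - 1) * L with L lognormal, preserving the effect direction while
    spreading its magnitude across subjects."""
    out = {}
    for site, per_site in config.effect_map.items():
        out[site] = {}
        for interval, factors in per_site.items():
            depth = float(np.exp(rng.normal(0.0, config.effect_sd)))
            # deep responders must not drive a multiplicative shift through
            # zero: floor well above it
            out[site][interval] = {
                k: max(1.0 + (m - 1.0) * depth, 0.1)
                for k, m in factors.items()}
    return out


def ground_truth_features(params: KernelParams, mean_bbi: float,
                          fs: float = 2000.0) -> MorphFeatures:
    """Features of the noise-free beat, evaluated over the same relative
    span the pipeline's templates cover (1.45 beat-to-beat intervals)."""
    beat = generate_beat(params, 1.45 * mean_bbi, fs)
    return extract_features(beat.values, fs)


def generate_subject(config: StudyConfig, subject_id: str,
                     rng: np.random.Generator) -> SubjectData:
    mean_bbi = float(np.clip(
        config.mean_bbi + rng.normal(0.0, config.subject_bbi_sd),
        0.6, 1.4))
    subject_effects = _jitter_effects(config, rng)
    ref_means = {p: config.ref_means[p] + rng.normal(0.0, config.ref_subject_sd[p])
                 for p in REF_PARAMS}
    ref_means["HR"] = 60.0 / mean_bbi + rng.normal(0.0, 2.0)
    depth = float(np.exp(rng.normal(0.0, config.effect_sd)))
    ref_shifts = {iv: {p: s * depth for p, s in shifts.items()}
                  for iv, shifts in config.ref_shifts.items()}

    signals, onsets_map, params_map = {}, {}, {}
    shared_onset_seed = int(rng.integers(2**31))
    for site_index, site in enumerate(config.sites):
        base = _jitter_params(BASE_PARAMS[site], rng,
                              config.subject_scale_sd, config.subject_shape_sd)
        by_phase = {"BL": base}
        for interval in ("ST1", "ST2"):
            p = params_for(site, interval, config, base, subject_effects)
            by_phase[interval] = p
            params_map[(site, interval)] = p
        params_map[(site, "BL")] = base
        fs = config.fs_contact if site in CONTACT_SITES else config.fps_video
        # one heart per subject: all sites share the onset sequence
        train_rng = np.random.default_rng(
            [shared_onset_seed, 1 + site_index])
        onset_rng = np.random.default_rng(shared_onset_seed)
        sig, ons = _train_with_shared_onsets(
            by_phase, config, fs=fs, noise_sd=config.noise_sd.get(site, 0.0),
            mean_bbi=mean_bbi, onset_rng=onset_rng, noise_rng=train_rng)
        signals[site] = sig
        onsets_map[site] = ons

    ref = generate_reference_series(
        config, rng, onsets_map[config.sites[0]],
        {"means": ref_means, "shifts": ref_shifts})
    return SubjectData(subject=subject_id, signals=signals,
                       onsets=onsets_map, reference=ref, params=params_map)


def _train_with_shared_onsets(params_by_phase, config, *, fs, noise_sd,
                              mean_bbi, onset_rng, noise_rng):
    """Beat train where onsets come from ``onset_rng`` (shared across sites)
    and noise from ``noise_rng`` (independent per site)."""
    record_duration = config.record_duration
    n = int(round(record_duration * fs))
    y = np.zeros(n)
    onsets = []
    t = float(onset_rng.uniform(0, mean_bbi))
    n_h = int(2.0 * fs)
    while t < record_duration:
        onsets.append(t)
        phase = _phase_of(t, config)
        p = params_by_phase[phase if phase is not None else "BL"]
        i0 = int(round(t * fs))
        n_beat = min(n_h, n - i0)
        if n_beat > 0:
            tt = (np.arange(n_beat) + (i0 - t * fs)) / fs
            y[i0:i0 + n_beat] += recompose(p, np.maximum(tt, 0.0))
        bbi = mean_bbi + onset_rng.normal(0.0, config.bbi_sd)
        t += max(bbi, 0.25 * mean_bbi)
    if config.wander_amplitude > 0:
        phase0 = noise_rng.uniform(0, 2 * np.pi)
        tgrid = np.arange(n) / fs
        y += config.wander_amplitude * np.sin(
            2 * np.pi * config.wander_frequency * tgrid + phase0)
    if noise_sd > 0:
        y += noise_rng.normal(0.0, noise_sd, size=n)
    sig = SampledSignal(values=y, fs=fs, t0=0.0, meta={"kind": "ppg"})
    return sig, np.asarray(onsets)


def generate_study(config: StudyConfig,
                   seed: int | None = None) -> StudyData:
    """Generate a full multi-subject study.

    Deterministic for a given (config, seed): the same inputs reproduce the
    study bit for bit.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    subjects = []
    gt_rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        sub_rng = np.random.default_rng([int(seed) % 2**31, i])
        sub = generate_subject(config, sid, sub_rng)
        subjects.append(sub)
        bbis = np.diff(sub.onsets[config.sites[0]])
        mean_bbi = float(np.median(bbis)) if bbis.size else config.mean_bbi
        for (site, interval), p in sub.params.items():
            feats = ground_truth_features(p, mean_bbi)
            gt_rows.append({
                "subject": sid, "site": site, "interval": interval,
                "s1": p.s1, "alpha1": p.alpha1, "beta1": p.beta1,
                "a2": p.a2, "mu2": p.mu2, "sigma2": p.sigma2,
                **feats.as_dict()})
    gt = pd.DataFrame(gt_rows)
    return StudyData(config=config, subjects=subjects, ground_truth=gt)
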