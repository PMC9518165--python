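"""Synthetic laugh data: feature-space MVN cohorts and waveform simulation.

Two generators make the analysis testable end to end:

* ``fit_cohort_model`` / ``sample_cohort`` implement feature-space cohort
  augmentation: per group (class x sex) the componentwise mean and
  variance of the real feature vectors define a diagonal-covariance
  multivariate normal from which arbitrarily many surrogate laughs are
  drawn.

* ``synthesize_laugh`` / ``make_synthetic_study`` produce laugh-like
  waveforms from a glottal-pulse-train source (per-cycle jitter and
  shimmer), two formant resonators, per-burst amplitude envelopes and an
  aspiration-noise floor. A scalar ``effect_size`` interpolates a
  healthy parameter set toward a dysarthria-like one: more jitter and
  shimmer, a higher breath-noise floor, broadened formant bandwidths
  (articulation smearing) and reduced slow F0 variability. The healthy
  set sits at effect_size = 0 exactly.

The waveform simulator is a test harness with controllable class
contrast, not a perceptually realistic laughter synthesizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio import AudioClip
from .errors import ConfigError, InputError
from .features import LaughFeatureVector

GroupKey = tuple[str, str]  # (class_label, sex)

# Perturbation-axis endpoints. The healthy endpoint mimics a clear voiced
# laugh; the affected endpoint raises cycle-level perturbation and noise
# and smears articulation while flattening slow pitch variability.
HEALTHY_PARAMS = {
    "f0_var": 0.15,
    "jitter": 0.010,
    "shimmer": 0.04,
    "breath_noise_db": -25.0,
    "formant_bw_scale": 1.0,
}
AFFECTED_PARAMS = {
    "f0_var": 0.06,
    "jitter": 0.050,
    "shimmer": 0.14,
    "breath_noise_db": -12.0,
    "formant_bw_scale": 1.9,
}
# Axes whose endpoints move F0 statistics; held at the healthy value in
# pitch-matched mode so class contrast is purely spectral.
PITCH_AXES = ("f0_var", "jitter")

F0_RANGE_BY_SEX = {"f": (240.0, 340.0), "m": (160.0, 260.0), "unknown": (200.0, 300.0)}

FORMANTS_HZ = (700.0, 1400.0)
FORMANT_BW_HZ = (90.0, 150.0)


@dataclass(frozen=True)
class CohortModel:
    """Diagonal-covariance normal fitted to one group's feature vectors."""

    group_key: GroupKey
    mean_vec: np.ndarray
    var_vec: np.ndarray
    names: tuple[str, ...]
    n_source_laughs: int
    cov: np.ndarray | None = None  # full covariance, only kept on request

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.var_vec) < 0):
            raise InputError("cohort model variances must be non-negative")
        if not (np.all(np.isfinite(self.mean_vec)) and np.all(np.isfinite(self.var_vec))):
            raise InputError("cohort model moments must be finite")


def fit_cohort_model(
    features: list[LaughFeatureVector],
    group_key: GroupKey,
    full_cov: bool = False,
) -> CohortModel:
    """Componentwise sample mean and variance (n-1 denominator) of a group."""
    if len(features) < 2:
        raise InputError(
            f"group {group_key} has {len(features)} vector(s); at least 2 are required"
        )
    names = features[0].names
    mat = np.vstack([v.values for v in features])
    return CohortModel(
        group_key=group_key,
        mean_vec=mat.mean(axis=0),
        var_vec=mat.var(axis=0, ddof=1),
        names=names,
        n_source_laughs=len(features),
        cov=np.cov(mat, rowvar=False) if full_cov else None,
    )


def sample_cohort(
    model: CohortModel,
    n: int,
    seed: int,
    full_cov: bool = False,
    block_size: int | None = None,
) -> list[LaughFeatureVector]:
    """Draw n surrogate feature vectors from the fitted normal.

    Sampled laughs have no subject of their own; by default they all
    carry the source group as subject_id. ``block_size`` instead labels
    consecutive draws into pseudo-subject blocks (block_size=1 gives one
    block per draw), which lets grouped CV run on a sampled cohort.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if full_cov:
        if model.cov is None:
            raise InputError("model was fitted without full_cov; refit with full_cov=True")
        draws = rng.multivariate_normal(model.mean_vec, model.cov, size=n)
    else:
        draws = model.mean_vec + rng.standard_normal((n, model.mean_vec.size)) * np.sqrt(
            model.var_vec
        )
    cls, sex = model.group_key
    return [
        LaughFeatureVector(
            values=draws[i],
            names=model.names,
            subject_id=(
                f"mvn-{cls}-{sex}" if block_size is None else f"mvn-{cls}-{sex}-b{i // block_size:05d}"
            ),
            class_label=cls,
            sex=sex,
            clip_id=f"mvn-{cls}-{sex}-{i:05d}",
        )
        for i in range(n)
    ]


def cohort_to_frame(model: CohortModel) -> pd.DataFrame:
    return pd.DataFrame(
        {"component": list(model.names), "mean": model.mean_vec, "variance": model.var_vec}
    )


def write_cohort(model: CohortModel, path: str | Path) -> None:
    cohort_to_frame(model).to_csv(path, index=False)


@dataclass(frozen=True)
class LaughSynthSpec:
    """Parameters of one synthesized laugh bout."""

    n_bursts: tuple[int, int] = (3, 6)
    burst_dur_ms: tuple[float, float] = (120.0, 260.0)
    f0_hz: tuple[float, float] = (240.0, 340.0)
    f0_var: float = HEALTHY_PARAMS["f0_var"]
    jitter: float = HEALTHY_PARAMS["jitter"]
    shimmer: float = HEALTHY_PARAMS["shimmer"]
    breath_noise_db: float = HEALTHY_PARAMS["breath_noise_db"]
    formant_bw_scale: float = HEALTHY_PARAMS["formant_bw_scale"]
    effect_size: float = 0.0
    seed: int = 0
    sample_rate: int = 16_000

    def __post_init__(self) -> None:
        if self.n_bursts[0] < 1 or self.n_bursts[1] < self.n_bursts[0]:
            raise ConfigError(f"invalid n_bursts range {self.n_bursts}")
        if self.burst_dur_ms[0] <= 0 or self.burst_dur_ms[1] < self.burst_dur_ms[0]:
            raise ConfigError(f"invalid burst_dur_ms range {self.burst_dur_ms}")
        if self.f0_hz[0] <= 0 or self.f0_hz[1] < self.f0_hz[0]:
            raise ConfigError(f"invalid f0_hz range {self.f0_hz}")
        if self.formant_bw_scale < 1.0:
            raise ConfigError("formant_bw_scale must be >= 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ConfigError("effect_size must lie in [0, 1]")

    @classmethod
    def for_condition(
        cls,
        effect_size: float,
        sex: str = "f",
        seed: int = 0,
        pitch_matched: bool = False,
        f0_hz: tuple[float, float] | None = None,
        subject_factors: dict[str, float] | None = None,
        **overrides,
    ) -> "LaughSynthSpec":
        """Interpolate the healthy -> affected parameter sets linearly.

        With ``pitch_matched`` the pitch-moving axes stay at the healthy
        values, leaving a purely spectral class contrast.
        ``subject_factors`` perturb the interpolated set per speaker:
        multiplicative for jitter/shimmer/f0_var, additive (dB or scale
        units) for breath noise and formant bandwidth.
        """
        params = {}
        for key, healthy in HEALTHY_PARAMS.items():
            if pitch_matched and key in PITCH_AXES:
                params[key] = healthy
            else:
                params[key] = healthy + effect_size * (AFFECTED_PARAMS[key] - healthy)
        for key, factor in (subject_factors or {}).items():
            if key in ("breath_noise_db", "formant_bw_scale"):
                params[key] = params[key] + factor
            else:
                params[key] = params[key] * factor
        params["formant_bw_scale"] = max(params["formant_bw_scale"], 1.0)
        params.update(overrides)
        return cls(
            f0_hz=f0_hz or F0_RANGE_BY_SEX.get(sex, F0_RANGE_BY_SEX["unknown"]),
            effect_size=effect_size,
            seed=seed,
            **params,
        )


def _resonator(x: np.ndarray, freq: float, bw: float, rate: int) -> np.ndarray:
    """Second-order all-pole resonance at freq with -3 dB bandwidth bw."""
    r = np.exp(-np.pi * bw / rate)
    theta = 2.0 * np.pi * freq / rate
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    return lfilter([1.0 - r], a, x)


def _voiced_burst(
    rng: np.random.Generator, spec: LaughSynthSpec, f0_center: float, n_samples: int
) -> np.ndarray:
    """Glottal pulse train with per-cycle jitter/shimmer through formants."""
    rate = spec.sample_rate
    pulses = np.zeros(n_samples)
    # slow intra-burst F0 declination, scaled by the (class-dependent) f0_var
    t_rel = np.linspace(0.0, 1.0, n_samples)
    pos = 0.0
    while pos < n_samples - 1:
        frac = t_rel[int(pos)]
        f0_now = f0_center * (1.0 - spec.f0_var * 0.6 * frac)
        f0_now *= 1.0 + spec.jitter * rng.standard_normal()
        f0_now = max(f0_now, 40.0)
        amp = max(1.0 + spec.shimmer * rng.standard_normal(), 0.05)
        pulses[int(pos)] = amp
        pos += rate / f0_now
    voiced = pulses
    for freq, bw in zip(FORMANTS_HZ, FORMANT_BW_HZ):
        voiced = _resonator(voiced, freq, bw * spec.formant_bw_scale, rate)
    return voiced * np.hanning(n_samples)


def synthesize_laugh(spec: LaughSynthSpec, **labels) -> AudioClip:
    """Render one laugh bout: voiced bursts with gaps plus breath noise."""
    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate
    n_bursts = int(rng.integers(spec.n_bursts[0], spec.n_bursts[1] + 1))
    f0_center = rng.uniform(*spec.f0_hz)
    pieces = []
    for b in range(n_bursts):
        dur = rng.uniform(*spec.burst_dur_ms) / 1000.0
        n = max(int(dur * rate), 64)
        # bout-level declination across bursts, again scaled by f0_var
        f0_b = f0_center * (1.0 - spec.f0_var * 0.8 * b / max(n_bursts - 1, 1))
        f0_b *= 1.0 + 0.3 * spec.f0_var * rng.standard_normal()
        pieces.append(_voiced_burst(rng, spec, max(f0_b, 60.0), n))
        if b < n_bursts - 1:
            gap = int(rng.uniform(0.08, 0.18) * rate)
            pieces.append(np.zeros(gap))
    voiced = np.concatenate(pieces)
    voiced_rms = np.sqrt(np.mean(voiced**2)) or 1.0
    noise = rng.standard_normal(voiced.size)
    for freq, bw in zip(FORMANTS_HZ, FORMANT_BW_HZ):
        noise = _resonator(noise, freq, 3.0 * bw * spec.formant_bw_scale, rate)
    noise_rms = np.sqrt(np.mean(noise**2)) or 1.0
    noise *= voiced_rms / noise_rms * 10.0 ** (spec.breath_noise_db / 20.0)
    signal = voiced + noise
    peak = np.max(np.abs(signal)) or 1.0
    return AudioClip(samples=0.9 * signal / peak, sample_rate=rate, **labels)


def make_synthetic_study(
    n_subjects_per_group: int,
    laughs_per_subject: int = 1,
    effect_size: float = 0.6,
    seed: int = 0,
    pitch_matched: bool = False,
) -> list[AudioClip]:
    """A balanced two-class, two-sex cohort of synthetic laugh clips.

    Each subject draws a base F0 and per-subject multiplicative offsets
    once, so laughs within a subject correlate and subject-wise
    cross-validation is a meaningful protocol on this data.

    With ``pitch_matched`` the class contrast is restricted to the
    non-pitch perturbation axes and, in addition, subject base F0s are
    paired across classes (subject i of each class shares the same
    draw), so per-clip pitch statistics are matched by construction and
    not merely in expectation.
    """
    if n_subjects_per_group < 1 or laughs_per_subject < 1:
        raise ConfigError("counts must be >= 1")
    root = np.random.SeedSequence(seed)
    clips: list[AudioClip] = []
    groups = [(c, s) for c in ("healthy", "pd") for s in ("f", "m")]
    # one F0 stream per sex, shared by both classes when pitch-matched
    f0_by_sex: dict[str, np.ndarray] = {}
    for sex, sex_seq in zip(("f", "m"), np.random.SeedSequence((seed, 1)).spawn(2)):
        sex_rng = np.random.default_rng(sex_seq)
        lo, hi = F0_RANGE_BY_SEX[sex]
        base = sex_rng.uniform(lo, hi, size=n_subjects_per_group)
        offset = 1.0 + 0.04 * sex_rng.standard_normal(n_subjects_per_group)
        f0_by_sex[sex] = np.clip(base * offset, lo * 0.85, hi * 1.15)
    for (cls, sex), group_seq in zip(groups, root.spawn(len(groups))):
        for subj_idx, subj_seq in enumerate(group_seq.spawn(n_subjects_per_group)):
            subj_rng = np.random.default_rng(subj_seq)
            subject_id = f"{cls}-{sex}-{subj_idx:03d}"
            lo, hi = F0_RANGE_BY_SEX[sex]
            if pitch_matched:
                f0_subj = float(f0_by_sex[sex][subj_idx])
            else:
                f0_base = subj_rng.uniform(lo, hi)
                f0_offset = 1.0 + 0.04 * subj_rng.standard_normal()
                f0_subj = float(np.clip(f0_base * f0_offset, lo * 0.85, hi * 1.15))
            es = effect_size if cls == "pd" else 0.0
            # subjects vary in voice quality within class, so the class
            # contrast is a shift of overlapping distributions rather
            # than a separation of point masses
            overrides = {
                "shimmer": float(np.exp(0.35 * subj_rng.standard_normal())),
                "breath_noise_db": float(3.5 * subj_rng.standard_normal()),
                "formant_bw_scale": float(0.18 * subj_rng.standard_normal()),
                "jitter": float(np.exp(0.35 * subj_rng.standard_normal())),
                "f0_var": float(np.exp(0.25 * subj_rng.standard_normal())),
            }
            if pitch_matched:
                for axis in PITCH_AXES:
                    overrides.pop(axis, None)
            for laugh_idx in range(laughs_per_subject):
                clip_seed = int(subj_rng.integers(0, 2**31 - 1))
                spec = LaughSynthSpec.for_condition(
                    es,
                    sex=sex,
                    seed=clip_seed,
                    pitch_matched=pitch_matched,
                    f0_hz=(f0_subj * 0.97, f0_subj * 1.03),
                    subject_factors=overrides,
                )
                clips.append(
                    replace(
                        synthesize_laugh(spec),
                        subject_id=subject_id,
                        class_label=cls,
                        sex=sex,
                        clip_id=f"{subject_id}-l{laugh_idx:02d}",
                    )
                )
    return clips
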