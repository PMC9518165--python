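"""Cepstral coefficients, their dynamics, and per-laugh moment pooling.

Each frame's M filter energies are cosine-transformed into 13 cepstral
coefficients

    c_n = sum_{m=1..M} log10(s(m)) * cos(pi * n * (m - 0.5) / M),  n = 1..13.

The n = 0 term (a pure log-energy sum) is excluded so the features are
invariant to global gain. First and second differences across frames
(delta = (c[t+1] - c[t-1]) / 2, applied twice for delta-delta, with edge
replication) capture dynamics. A laugh is then summarized by the mean,
standard deviation, skewness and kurtosis of each coefficient track over
its frames: 3 streams x 4 statistics x 13 coefficients = 156 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .audio import AudioClip, FramingConfig, preprocess
from .errors import ConfigError, InputError
from .filterbanks import FilterBank, apply_filterbank

N_COEFFS = 13
ENERGY_FLOOR = 1e-10

STREAMS = ("c", "delta", "delta2")
MOMENTS = ("mean", "sd", "skew", "kurt")


@dataclass(frozen=True)
class FeatureSelection:
    """Which coefficient streams and which pooled statistics to keep."""

    streams: tuple[str, ...] = STREAMS
    moments: tuple[str, ...] = MOMENTS

    def __post_init__(self) -> None:
        if not self.streams or not self.moments:
            raise ConfigError("FeatureSelection needs at least one stream and one moment")
        bad = set(self.streams) - set(STREAMS)
        if bad:
            raise ConfigError(f"unknown streams {sorted(bad)}; valid: {STREAMS}")
        bad = set(self.moments) - set(MOMENTS)
        if bad:
            raise ConfigError(f"unknown moments {sorted(bad)}; valid: {MOMENTS}")
        object.__setattr__(self, "streams", tuple(s for s in STREAMS if s in self.streams))
        object.__setattr__(self, "moments", tuple(m for m in MOMENTS if m in self.moments))

    @property
    def n_components(self) -> int:
        return N_COEFFS * len(self.streams) * len(self.moments)

    def component_names(self) -> list[str]:
        return [
            f"{s}.{m}.{i}"
            for s in self.streams
            for m in self.moments
            for i in range(1, N_COEFFS + 1)
        ]


@dataclass(frozen=True)
class CepstralTrack:
    """Per-frame cepstra plus first/second difference tracks."""

    c: np.ndarray  # (T, 13)
    delta: np.ndarray
    delta2: np.ndarray
    bank_kind: str

    @property
    def n_frames(self) -> int:
        return self.c.shape[0]


@dataclass(frozen=True)
class LaughFeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    subject_id: str = ""
    class_label: str = "unknown"
    sex: str = "unknown"
    clip_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.size != len(self.names):
            raise InputError(
                f"feature vector length {values.size} does not match {len(self.names)} names"
            )
        object.__setattr__(self, "values", values)


def cepstra_from_energies(energies: np.ndarray, n_coeffs: int = N_COEFFS) -> np.ndarray:
    """DCT of log10 filter energies; coefficients n = 1..n_coeffs."""
    energies = np.asarray(energies, dtype=np.float64)
    n_filters = energies.shape[1]
    if n_coeffs > n_filters:
        raise ConfigError(f"n_coeffs {n_coeffs} exceeds the filter count {n_filters}")
    log_e = np.log10(np.maximum(energies, ENERGY_FLOOR))
    m = np.arange(1, n_filters + 1)
    n = np.arange(1, n_coeffs + 1)
    basis = np.cos(np.pi * np.outer(n, m - 0.5) / n_filters)  # (n_coeffs, M)
    return log_e @ basis.T


def delta_track(c: np.ndarray) -> np.ndarray:
    """Central difference (c[t+1] - c[t-1]) / 2 with edge replication."""
    c = np.asarray(c, dtype=np.float64)
    prev = np.vstack([c[:1], c[:-1]])
    nxt = np.vstack([c[1:], c[-1:]])
    return (nxt - prev) / 2.0


def cepstral_track(energies: np.ndarray, bank_kind: str, n_coeffs: int = N_COEFFS) -> CepstralTrack:
    c = cepstra_from_energies(energies, n_coeffs)
    d = delta_track(c)
    return CepstralTrack(c=c, delta=d, delta2=delta_track(d), bank_kind=bank_kind)


def _column_moments(x: np.ndarray, moment: str) -> np.ndarray:
    """One pooled statistic per column; zero-variance columns give 0 skew/kurt."""
    if moment == "mean":
        return x.mean(axis=0)
    if moment == "sd":
        return x.std(axis=0, ddof=1)
    constant = x.std(axis=0) == 0
    with warnings.catch_warnings():
        # constant columns trigger a precision warning; they are mapped to 0
        warnings.simplefilter("ignore", RuntimeWarning)
        if moment == "skew":
            out = stats.skew(x, axis=0)
        else:  # non-excess kurtosis: normal -> 3
            out = stats.kurtosis(x, axis=0, fisher=False)
    return np.where(constant, 0.0, out)


def pool_moments(track: CepstralTrack, sel: FeatureSelection | None = None, **labels) -> LaughFeatureVector:
    """Collapse coefficient tracks into the per-laugh moment vector."""
    sel = sel or FeatureSelection()
    if track.n_frames < 2 and set(sel.moments) - {"mean"}:
        raise InputError(
            f"{track.n_frames} frame(s) cannot support SD/skew/kurt pooling;"
            " provide a longer clip or a mean-only selection"
        )
    streams = {"c": track.c, "delta": track.delta, "delta2": track.delta2}
    parts = [
        _column_moments(streams[s], m)
        for s in sel.streams
        for m in sel.moments
    ]
    return LaughFeatureVector(
        values=np.concatenate(parts),
        names=tuple(sel.component_names()),
        **labels,
    )


def extract_features(
    clip: AudioClip,
    bank: FilterBank,
    cfg: FramingConfig | None = None,
    sel: FeatureSelection | None = None,
) -> LaughFeatureVector:
    """Full pipeline for one clip: preprocess -> bank -> cepstra -> moments."""
    cfg = cfg or FramingConfig()
    spec = preprocess(clip, cfg)
    energies = apply_filterbank(spec, bank)
    track = cepstral_track(energies, bank.kind)
    return pool_moments(
        track,
        sel,
        subject_id=clip.subject_id,
        class_label=clip.class_label,
        sex=clip.sex,
        clip_id=clip.clip_id,
    )


META_COLUMNS = ("clip_id", "subject_id", "class_label", "sex")


def features_to_frame(vectors: list[LaughFeatureVector]) -> pd.DataFrame:
    """One row per laugh: metadata columns then the ordered components."""
    if not vectors:
        raise InputError("no feature vectors to tabulate")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise InputError("feature vectors have inconsistent layouts")
    data = {
        "clip_id": [v.clip_id for v in vectors],
        "subject_id": [v.subject_id for v in vectors],
        "class_label": [v.class_label for v in vectors],
        "sex": [v.sex for v in vectors],
    }
    mat = np.vstack([v.values for v in vectors])
    for j, name in enumerate(names):
        data[name] = mat[:, j]
    return pd.DataFrame(data)


def frame_to_features(df: pd.DataFrame) -> list[LaughFeatureVector]:
    names = tuple(c for c in df.columns if c not in META_COLUMNS)
    return [
        LaughFeatureVector(
            values=row[list(names)].to_numpy(dtype=np.float64),
            names=names,
            subject_id=str(row["subject_id"]),
            class_label=str(row["class_label"]),
            sex=str(row["sex"]),
            clip_id=str(row["clip_id"]),
        )
        for _, row in df.iterrows()
    ]


def write_features(vectors: list[LaughFeatureVector], path: str | Path) -> None:
    features_to_frame(vectors).to_csv(path, index=False)


def read_features(path: str | Path) -> list[LaughFeatureVector]:
    return frame_to_features(pd.read_csv(path))
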