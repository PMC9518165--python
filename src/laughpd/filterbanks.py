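"""Auditory-scale triangular filter banks (Mel, Human-Factor, Bark).

Three 26-filter banks cover 0–8 kHz. Mel centers are placed equally on
the Mel scale, unwarped, and snapped to DFT bins; the snapped center is
the bin carrying the maximum weight of the discretized triangle (for
asymmetric triangles this can differ by one bin from naive nearest-bin
rounding). Human-Factor (HFCC) banks reuse Mel-style center placement
but set each triangle's width from the equivalent rectangular bandwidth
(ERB) at its center, so low-frequency filters are narrower. Bark banks
space centers equally on the Bark scale.

For the default configuration (26 filters, 16 kHz, 512-point DFT,
0–8 kHz) the HFCC and Bark center frequencies come from a packaged
reference table; the constructive spacing rules above are used for any
other configuration and are approximations for those two scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .audio import SpectrogramFrames
from .errors import ConfigError

BankKind = str  # {"mel", "hfcc", "bfcc"}
N_FILTERS_DEFAULT = 26


def hz_to_mel(f):
    """Mel scale: 1125 * ln(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ConfigError("frequency must be non-negative")
    return 1125.0 * np.log1p(f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * np.expm1(m / 1125.0)


def hz_to_bark(f):
    """Bark scale: 13*atan(0.00076 f) + 3.5*atan((f/7500)^2)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ConfigError("frequency must be non-negative")
    return 13.0 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)


def bark_to_hz(b, f_max: float = 16_000.0):
    """Numeric inverse of the Bark map by bisection on [0, f_max]."""
    b = np.asarray(b, dtype=np.float64)
    lo = np.zeros_like(b)
    hi = np.full_like(b, f_max)
    for _ in range(60):  # 60 halvings -> sub-micro-Hz resolution
        mid = 0.5 * (lo + hi)
        below = hz_to_bark(mid) < b
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def erb_bandwidth(fc):
    """Equivalent rectangular bandwidth in Hz at center fc (Hz).

    Uses the Moore–Glasberg polynomial 6.23 fk^2 + 93.39 fk + 28.52 with
    the center expressed in kHz (the polynomial is meaningless with the
    center in Hz).
    """
    fc = np.asarray(fc, dtype=np.float64)
    if np.any(fc < 0):
        raise ConfigError("center frequency must be non-negative")
    fk = fc / 1000.0
    return 6.23 * fk**2 + 93.39 * fk + 28.52


@dataclass(frozen=True)
class FilterBank:
    kind: BankKind
    n_filters: int
    centers_hz: np.ndarray  # (M,)
    edges_hz: np.ndarray  # (M, 2) lower/upper triangle edge per filter
    weights: np.ndarray  # (M, dft_size//2 + 1)
    sample_rate: int
    dft_size: int

    @property
    def bin_width(self) -> float:
        return self.sample_rate / self.dft_size


def reference_centers() -> pd.DataFrame:
    """The packaged 26x3 table of center frequencies (Hz) per scale."""
    with resources.files("laughpd.data").joinpath("reference_centers.csv").open() as fh:
        return pd.read_csv(fh, index_col="filter")


def _triangle(bins: np.ndarray, lo: float, center: float, hi: float) -> np.ndarray:
    rise = (bins - lo) / max(center - lo, 1e-12)
    fall = (hi - bins) / max(hi - center, 1e-12)
    return np.clip(np.minimum(rise, fall), 0.0, None)


def _snap_to_peak_bin(lo: float, center: float, hi: float, bin_width: float, n_bins: int) -> float:
    """Snap a triangle center to the DFT bin with maximal triangle weight.

    Ties resolve to the lower bin (argmax returns the first maximum).
    """
    bins = np.arange(n_bins) * bin_width
    return float(bins[np.argmax(_triangle(bins, lo, center, hi))])


def _spaced_centers(scale, unscale, f_lo, f_hi, n_filters, bin_width, n_bins):
    pts = unscale(np.linspace(scale(f_lo), scale(f_hi), n_filters + 2))
    snapped = [
        _snap_to_peak_bin(pts[m - 1], pts[m], pts[m + 1], bin_width, n_bins)
        for m in range(1, n_filters + 1)
    ]
    return np.asarray(snapped)


def build_filterbank(
    kind: BankKind,
    n_filters: int = N_FILTERS_DEFAULT,
    sample_rate: int = 16_000,
    dft_size: int = 512,
    f_lo: float = 0.0,
    f_hi: float | None = None,
    erb_scale: float = 1.0,
    use_reference_centers: bool = True,
) -> FilterBank:
    """Construct a triangular bank and its DFT-bin weight matrix.

    Mel/Bark triangles span adjacent snapped centers (unit peak at the
    center); HFCC triangles extend center +/- erb_scale*ERB/2, clipped to
    [f_lo, f_hi]. At the default configuration the HFCC and Bark centers
    are taken from the packaged reference table unless
    ``use_reference_centers`` is disabled.
    """
    if kind not in ("mel", "hfcc", "bfcc"):
        raise ConfigError(f"unknown filter bank kind {kind!r}")
    if f_hi is None:
        f_hi = sample_rate / 2.0
    if not (0 <= f_lo < f_hi <= sample_rate / 2.0):
        raise ConfigError(f"invalid band [{f_lo}, {f_hi}] for rate {sample_rate}")
    if n_filters < 1:
        raise ConfigError("n_filters must be >= 1")

    bin_width = sample_rate / dft_size
    n_bins = dft_size // 2 + 1
    bins = np.arange(n_bins) * bin_width

    is_default = (
        n_filters == N_FILTERS_DEFAULT
        and sample_rate == 16_000
        and dft_size == 512
        and f_lo == 0.0
        and f_hi == 8000.0
    )
    if kind in ("hfcc", "bfcc") and use_reference_centers and is_default:
        centers = reference_centers()[kind].to_numpy(dtype=np.float64)
    elif kind == "bfcc":
        centers = _spaced_centers(hz_to_bark, bark_to_hz, f_lo, f_hi, n_filters, bin_width, n_bins)
    else:  # mel spacing for both mel and (constructive) hfcc
        centers = _spaced_centers(hz_to_mel, mel_to_hz, f_lo, f_hi, n_filters, bin_width, n_bins)

    if np.unique(centers).size != n_filters:
        raise ConfigError(
            f"{n_filters} filters collapse onto shared DFT bins at dft_size={dft_size};"
            " reduce n_filters or raise dft_size"
        )

    if kind == "hfcc":
        half = erb_scale * erb_bandwidth(centers) / 2.0
        lo_edges = np.clip(centers - half, f_lo, None)
        hi_edges = np.clip(centers + half, None, f_hi)
    else:
        padded = np.concatenate(([f_lo], centers, [f_hi]))
        lo_edges = padded[:-2]
        hi_edges = padded[2:]

    weights = np.vstack(
        [_triangle(bins, lo, c, hi) for lo, c, hi in zip(lo_edges, centers, hi_edges)]
    )
    return FilterBank(
        kind=kind,
        n_filters=n_filters,
        centers_hz=centers,
        edges_hz=np.column_stack([lo_edges, hi_edges]),
        weights=weights,
        sample_rate=sample_rate,
        dft_size=dft_size,
    )


def apply_filterbank(spec: SpectrogramFrames, bank: FilterBank) -> np.ndarray:
    """Per-frame filter energies: energies[t, m] = sum_j w[m, j] * power[t, j]."""
    if spec.dft_size != bank.dft_size or spec.power.shape[1] != bank.weights.shape[1]:
        raise ConfigError(
            f"spectrogram dft_size {spec.dft_size} does not match bank dft_size {bank.dft_size}"
        )
    return spec.power @ bank.weights.T


def export_weights(bank: FilterBank) -> pd.DataFrame:
    """Bank weights as a tidy table (one row per filter x bin), for plotting."""
    n_bins = bank.weights.shape[1]
    return pd.DataFrame(
        {
            "filter": np.repeat(np.arange(1, bank.n_filters + 1), n_bins),
            "bin_hz": np.tile(np.arange(n_bins) * bank.bin_width, bank.n_filters),
            "weight": bank.weights.ravel(),
        }
    )
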