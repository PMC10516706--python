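"""Ground-truth somatic allele-frequency spectra and tumour mutation burden.

Three spectrum families are supported: the subclonal spectrum of a neutrally
evolving tumour (cumulative count of mutations above frequency f
proportional to 1/f, optionally with a clonal point mass at f = 0.5 for a
pure diploid tumour), a low-frequency high-burden point mass, and a uniform
distribution over semi-centile frequency bins partitioning (0, 0.5].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

SEMI_CENTILE_EDGES = np.linspace(0.0, 0.5, 101)


def semi_centile_bins(n_bins: int = 100) -> list[tuple[float, float]]:
    """Half-open bins [lo, hi) with lo=(i-1)/(2 n), hi=i/(2 n), covering (0, 0.5]."""
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bins)]


@dataclass
class SpectrumSpec:
    """Parameters of a ground-truth somatic VAF spectrum.

    kind
        ``neutral`` (1/f subclonal spectrum plus optional clonal mass),
        ``point_mass`` (all variants at ``f0``) or ``uniform_bins``
        (per-bin uniform draws).
    purity
        Tumour purity; scales every frequency multiplicatively (all the
        reference simulations use purity 1).
    """

    kind: str
    n_total: int = 0
    f_min: float = 0.01
    f_max: float = 0.25
    clonal_f: float = 0.5
    n_clonal: int = 0
    f0: float = 0.035
    bins: list[tuple[float, float]] = field(default_factory=list)
    bin_counts: list[int] = field(default_factory=list)
    purity: float = 1.0

    def __post_init__(self):
        if self.kind not in ("neutral", "point_mass", "uniform_bins"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.n_total < 0 or self.n_clonal < 0:
            raise ValueError("counts must be non-negative")


def sample_neutral(
    n: int,
    f_min: float = 0.01,
    f_max: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw subclonal frequencies from the neutral 1/f spectrum.

    Inverse-CDF sampling: with u ~ Uniform(0,1),
    ``f = 1 / (1/f_min - u * (1/f_min - 1/f_max))``, so the CDF is
    ``(1/f_min - 1/f) / (1/f_min - 1/f_max)`` on [f_min, f_max].
    """
    if not (0.0 < f_min < f_max <= 1.0):
        raise ValueError("need 0 < f_min < f_max <= 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(rng)
    u = rng.random(n)
    return neutral_quantile(u, f_min, f_max)


def neutral_quantile(u, f_min: float, f_max: float) -> np.ndarray:
    """Inverse CDF of the neutral spectrum (u=0 -> f_min, u=1 -> f_max)."""
    u = np.asarray(u, dtype=float)
    return 1.0 / (1.0 / f_min - u * (1.0 / f_min - 1.0 / f_max))


def neutral_cdf(f, f_min: float, f_max: float) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    c = (1.0 / f_min - 1.0 / np.clip(f, f_min, f_max)) / (1.0 / f_min - 1.0 / f_max)
    return np.clip(c, 0.0, 1.0)


def neutral_mean(f_min: float, f_max: float) -> float:
    """Analytic mean of the neutral spectrum: ln(f_max/f_min)/(1/f_min - 1/f_max)."""
    return math.log(f_max / f_min) / (1.0 / f_min - 1.0 / f_max)


def make_burden(
    spec: SpectrumSpec, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Materialise the ground-truth frequency list for a spectrum spec."""
    rng = np.random.default_rng(rng)
    if spec.kind == "neutral":
        if spec.n_clonal > spec.n_total:
            raise ValueError("n_clonal cannot exceed n_total")
        sub = sample_neutral(spec.n_total - spec.n_clonal, spec.f_min, spec.f_max, rng)
        freqs = np.concatenate([sub, np.full(spec.n_clonal, spec.clonal_f)])
    elif spec.kind == "point_mass":
        freqs = np.full(spec.n_total, spec.f0, dtype=float)
    else:  # uniform_bins
        if len(spec.bins) != len(spec.bin_counts):
            raise ValueError("bins and bin_counts must have equal length")
        parts = []
        for (lo, hi), count in zip(spec.bins, spec.bin_counts):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"invalid bin [{lo},{hi})")
            parts.append(lo + (hi - lo) * rng.random(count))
        freqs = np.concatenate(parts) if parts else np.empty(0)
    return freqs * spec.purity


def round_display(value: float, ndigits: int = 1) -> float:
    """Half-up rounding for displayed summary numbers."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def true_tmb(
    frequencies, threshold: float = 0.05, target_size_mb: float = 76.0
) -> float:
    """Ground-truth tumour mutation burden in mutations per megabase.

    Counts true frequencies >= ``threshold`` and divides by the target size
    in Mb; displayed to one decimal (e.g. 645 qualifying variants on a
    76 Mb target give 8.5 mut/Mb).
    """
    if target_size_mb <= 0:
        raise ValueError("target size must be positive")
    freqs = np.asarray(list(frequencies), dtype=float)
    count = int(np.count_nonzero(freqs >= threshold))
    return round_display(count / target_size_mb, 1)
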