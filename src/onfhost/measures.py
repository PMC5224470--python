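"""The 11 pairwise ONF distance/dissimilarity measures.

Two families: measures on observed k-mer frequencies only (Eu, Ma, Ch, d2,
JS) and measures that correct for a sequence background (d2star, d2S, Hao,
Teeling, EuF, Willner). Every score is oriented so that SMALLER means MORE
similar; similarity-type statistics (cosine, correlation) are wrapped as
(1 - s) / 2.

Sums always run in lexicographic word order, so results are reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from onfhost.kmer_model import (
    CenteredProfile,
    KmerProfile,
    MarkovModel,
    center_profile,
    count_kmers,
    estimate_markov,
)
from onfhost.sequence_io import SequenceRecord

NO_BACKGROUND = ("Eu", "Ma", "Ch", "d2", "JS")
BACKGROUND = ("d2star", "d2S", "Hao", "Teeling", "EuF", "Willner")
MEASURE_IDS = NO_BACKGROUND + BACKGROUND


class DegenerateInputError(ValueError):
    """Raised when a measure is undefined for the given pair of profiles."""


class ConfigurationError(ValueError):
    """Raised for invalid (measure, k, order) combinations."""


@dataclass(frozen=True)
class MeasureConfig:
    """One (measure, k-mer length, background order) configuration."""

    measure_id: str
    k: int = 6
    order: int = 2

    def __post_init__(self) -> None:
        if self.measure_id not in MEASURE_IDS:
            raise ConfigurationError(
                f"unknown measure {self.measure_id!r}; choose from {MEASURE_IDS}"
            )
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.order < 0:
            raise ConfigurationError(f"order must be >= 0, got {self.order}")
        if self.measure_id == "Willner" and not 2 <= self.k <= 4:
            raise ConfigurationError(
                "the Willner measure is not defined for k-mer lengths > 4 "
                f"(and needs k >= 2); got k={self.k}"
            )
        if self.measure_id in ("Hao", "Teeling") and self.k < 3:
            raise ConfigurationError(
                f"{self.measure_id} needs k >= 3 (its expectation uses "
                f"(k-1)- and (k-2)-words); got k={self.k}"
            )
        if self.measure_id in ("d2star", "d2S", "EuF") and self.order > self.k - 1:
            raise ConfigurationError(
                f"background order must be <= k-1 = {self.k - 1}, got {self.order}"
            )


class GenomeFeatures:
    """Lazy per-genome cache of profiles, models and centered profiles.

    Building one of these per genome lets a whole dissimilarity-matrix row
    or column reuse the same counts and background model.
    """

    def __init__(self, record: SequenceRecord, strand_mode: str = "forward") -> None:
        self.record = record
        self.strand_mode = strand_mode
        self._profiles: dict[int, KmerProfile] = {}
        self._models: dict[int, MarkovModel] = {}
        self._centered: dict[tuple[int, int], CenteredProfile] = {}

    @property
    def id(self) -> str:
        return self.record.id

    def profile(self, k: int) -> KmerProfile:
        if k not in self._profiles:
            self._profiles[k] = count_kmers(self.record, k, self.strand_mode)
        return self._profiles[k]

    def model(self, order: int) -> MarkovModel:
        if order not in self._models:
            self._models[order] = estimate_markov(
                self.record, order, self.strand_mode
            )
        return self._models[order]

    def centered(self, k: int, order: int) -> CenteredProfile:
        key = (k, order)
        if key not in self._centered:
            self._centered[key] = center_profile(self.profile(k), self.model(order))
        return self._centered[key]


# --- measures without background correction ----------------------------------


def eu_ma_ch(X: KmerProfile, Y: KmerProfile, which: str) -> float:
    """Euclidean / Manhattan / Chebyshev distance on frequency vectors."""
    if X.k != Y.k:
        raise ConfigurationError(f"k mismatch: {X.k} vs {Y.k}")
    d = X.freqs - Y.freqs
    if which == "Eu":
        return float(np.sqrt(np.sum(d * d)))
    if which == "Ma":
        return float(np.sum(np.abs(d)))
    if which == "Ch":
        return float(np.max(np.abs(d)))
    raise ConfigurationError(f"unknown metric {which!r}")


def d2_cosine(X: KmerProfile, Y: KmerProfile) -> float:
    """d2 = (1 - cosine similarity of frequency vectors) / 2."""
    if X.k != Y.k:
        raise ConfigurationError(f"k mismatch: {X.k} vs {Y.k}")
    fx, fy = X.freqs, Y.freqs
    nx, ny = np.linalg.norm(fx), np.linalg.norm(fy)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("zero frequency vector")
    return float((1.0 - np.dot(fx, fy) / (nx * ny)) / 2.0)


def js_divergence(X: KmerProfile, Y: KmerProfile) -> float:
    """Jensen-Shannon divergence (base 2) between (r+1)-mer distributions.

    X and Y must be profiles at word length r+1 for background order r;
    the result does not depend on the configured k.
    """
    if X.k != Y.k:
        raise ConfigurationError(f"k mismatch: {X.k} vs {Y.k}")
    p, q = X.freqs, Y.freqs
    m = (p + q) / 2.0
    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


# --- background-corrected measures --------------------------------------------


def d2star(Xc: CenteredProfile, Yc: CenteredProfile) -> float:
    """Correlation-type dissimilarity on centered counts scaled by sqrt(E)."""
    if Xc.k != Yc.k:
        raise ConfigurationError(f"k mismatch: {Xc.k} vs {Yc.k}")
    mask = (Xc.expected > 0) & (Yc.expected > 0)
    xt, yt = Xc.centered[mask], Yc.centered[mask]
    ex, ey = Xc.expected[mask], Yc.expected[mask]
    num = np.sum(xt * yt / np.sqrt(ex * ey))
    dx = np.sqrt(np.sum(xt * xt / ex))
    dy = np.sqrt(np.sum(yt * yt / ey))
    if dx == 0 or dy == 0:
        which = Xc.profile.source_id if dx == 0 else Yc.profile.source_id
        raise DegenerateInputError(
            f"all-zero centered vector for {which!r}; sequence matches its "
            "own background exactly"
        )
    return float(0.5 * (1.0 - num / (dx * dy)))


def d2s(Xc: CenteredProfile, Yc: CenteredProfile) -> float:
    """Variant of d2star scaled by sqrt(X~^2 + Y~^2) per word."""
    if Xc.k != Yc.k:
        raise ConfigurationError(f"k mismatch: {Xc.k} vs {Yc.k}")
    xt, yt = Xc.centered, Yc.centered
    denom = np.sqrt(xt * xt + yt * yt)
    mask = denom > 0
    xt, yt, denom = xt[mask], yt[mask], denom[mask]
    num = np.sum(xt * yt / denom)
    dx = np.sqrt(np.sum(xt * xt / denom))
    dy = np.sqrt(np.sum(yt * yt / denom))
    if dx == 0 or dy == 0:
        which = Xc.profile.source_id if dx == 0 else Yc.profile.source_id
        raise DegenerateInputError(f"all-zero centered vector for {which!r}")
    return float(0.5 * (1.0 - num / (dx * dy)))


def _hao_vector(fk: np.ndarray, fk1: np.ndarray, fk2: np.ndarray, k: int) -> np.ndarray:
    """Relative deviation a_w of observed from (k-1)/(k-2)-mer predicted freq."""
    idx = np.arange(4**k)
    prefix = idx // 4
    suffix = idx % (4 ** (k - 1))
    middle = prefix % (4 ** (k - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        f0 = np.where(fk2[middle] > 0, fk1[prefix] * fk1[suffix] / fk2[middle], 0.0)
        a = np.where(f0 > 0, (fk - f0) / f0, 0.0)
    return a


def hao_cvtree(
    Xk: KmerProfile, Xk1: KmerProfile, Xk2: KmerProfile,
    Yk: KmerProfile, Yk1: KmerProfile, Yk2: KmerProfile,
) -> float:
    """Composition-vector dissimilarity: (1 - cos) / 2 of relative deviations."""
    k = Xk.k
    ax = _hao_vector(Xk.freqs, Xk1.freqs, Xk2.freqs, k)
    ay = _hao_vector(Yk.freqs, Yk1.freqs, Yk2.freqs, k)
    nx, ny = np.linalg.norm(ax), np.linalg.norm(ay)
    if nx == 0 or ny == 0:
        which = Xk.source_id if nx == 0 else Yk.source_id
        raise DegenerateInputError(f"zero composition vector for {which!r}")
    return float((1.0 - np.dot(ax, ay) / (nx * ny)) / 2.0)


def _teeling_z(Nk: np.ndarray, Nk1: np.ndarray, Nk2: np.ndarray, k: int):
    """Per-word z-scores against the maximal-order Markov expectation.

    Returns (z, defined-mask); a word is undefined when the (k-2)-mer
    denominator or the resulting expectation is zero.
    """
    idx = np.arange(4**k)
    prefix = idx // 4
    suffix = idx % (4 ** (k - 1))
    middle = prefix % (4 ** (k - 2))
    den = Nk2[middle].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(den > 0, Nk1[prefix] * Nk1[suffix] / den, 0.0)
        z = np.where(e > 0, (Nk - e) / np.sqrt(np.where(e > 0, e, 1.0)), 0.0)
    return z, e > 0


def teeling_zscore(
    Xk: KmerProfile, Xk1: KmerProfile, Xk2: KmerProfile,
    Yk: KmerProfile, Yk1: KmerProfile, Yk2: KmerProfile,
) -> float:
    """(1 - Pearson correlation of z-score vectors) / 2 over shared words."""
    k = Xk.k
    zx, mx = _teeling_z(Xk.counts, Xk1.counts, Xk2.counts, k)
    zy, my = _teeling_z(Yk.counts, Yk1.counts, Yk2.counts, k)
    both = mx & my
    if int(both.sum()) < 2:
        raise DegenerateInputError("fewer than 2 jointly defined words")
    zx, zy = zx[both], zy[both]
    sx, sy = np.std(zx), np.std(zy)
    if sx == 0 or sy == 0:
        which = Xk.source_id if sx == 0 else Yk.source_id
        raise DegenerateInputError(f"zero-variance z vector for {which!r}")
    rho = float(np.corrcoef(zx, zy)[0, 1])
    return (1.0 - rho) / 2.0


def euf(Xc: CenteredProfile, Yc: CenteredProfile) -> float:
    """Euclidean distance of relative deviations (N - E)/E from background."""
    if Xc.k != Yc.k:
        raise ConfigurationError(f"k mismatch: {Xc.k} vs {Yc.k}")
    mask = (Xc.expected > 0) & (Yc.expected > 0)
    dx = np.zeros_like(Xc.expected)
    dy = np.zeros_like(Yc.expected)
    dx[mask] = Xc.centered[mask] / Xc.expected[mask]
    dy[mask] = Yc.centered[mask] / Yc.expected[mask]
    return float(np.sqrt(np.sum((dx - dy) ** 2)))


def _willner_delta(fk: np.ndarray, f1: np.ndarray, k: int) -> np.ndarray:
    """Relative abundance f_w / prod of mononucleotide frequencies."""
    prod = np.array([1.0])
    for _ in range(k):
        prod = (prod[:, None] * f1[None, :]).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(prod > 0, fk / prod, 0.0)


def willner(
    Xk: KmerProfile, X1: KmerProfile, Yk: KmerProfile, Y1: KmerProfile
) -> float:
    """Mean absolute difference of mononucleotide-normalized k-mer ratios."""
    k = Xk.k
    if k > 4:
        raise ConfigurationError(
            "the Willner measure is not defined for k-mer lengths > 4"
        )
    dx = _willner_delta(Xk.freqs, X1.freqs, k)
    dy = _willner_delta(Yk.freqs, Y1.freqs, k)
    return float(np.mean(np.abs(dx - dy)))


# --- dispatch ------------------------------------------------------------------


def compute_score(
    xf: GenomeFeatures, yf: GenomeFeatures, config: MeasureConfig
) -> float:
    """Score one virus-host pair under a MeasureConfig (smaller = more similar)."""
    m, k, r = config.measure_id, config.k, config.order
    if m in ("Eu", "Ma", "Ch"):
        return eu_ma_ch(xf.profile(k), yf.profile(k), m)
    if m == "d2":
        return d2_cosine(xf.profile(k), yf.profile(k))
    if m == "JS":
        return js_divergence(xf.profile(r + 1), yf.profile(r + 1))
    if m == "d2star":
        return d2star(xf.centered(k, r), yf.centered(k, r))
    if m == "d2S":
        return d2s(xf.centered(k, r), yf.centered(k, r))
    if m == "Hao":
        return hao_cvtree(
            xf.profile(k), xf.profile(k - 1), xf.profile(k - 2),
            yf.profile(k), yf.profile(k - 1), yf.profile(k - 2),
        )
    if m == "Teeling":
        return teeling_zscore(
            xf.profile(k), xf.profile(k - 1), xf.profile(k - 2),
            yf.profile(k), yf.profile(k - 1), yf.profile(k - 2),
        )
    if m == "EuF":
        return euf(xf.centered(k, r), yf.centered(k, r))
    if m == "Willner":
        return willner(xf.profile(k), xf.profile(1), yf.profile(k), yf.profile(1))
    raise ConfigurationError(f"unknown measure {m!r}")


MEASURES: dict[str, str] = {
    "Eu": "Euclidean distance on k-mer frequencies",
    "Ma": "Manhattan distance on k-mer frequencies",
    "Ch": "Chebyshev distance on k-mer frequencies",
    "d2": "cosine dissimilarity on k-mer frequencies",
    "JS": "Jensen-Shannon divergence on (order+1)-mer distributions",
    "d2star": "centered counts scaled by sqrt expected counts (correlation form)",
    "d2S": "centered counts scaled by sqrt of summed squares (correlation form)",
    "Hao": "composition-vector (relative deviation) cosine dissimilarity",
    "Teeling": "z-score (maximal-order expectation) correlation dissimilarity",
    "EuF": "Euclidean distance of relative deviations from background",
    "Willner": "mean abs difference of mononucleotide-normalized ratios",
}
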