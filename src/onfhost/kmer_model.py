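"""Observed k-mer profiles, Markov background models, centered profiles, BIC.

Words are indexed lexicographically with A<C<G<T via 2-bit codes, which
fixes the vector layout for every measure and file output. Windows that
contain an N or straddle a contig boundary are never counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from onfhost.sequence_io import SequenceRecord

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ModelEstimationError(ValueError):
    """Raised when a profile or model cannot be estimated from a record."""


def word_index(word: str) -> int:
    """Lexicographic index of a word over A<C<G<T."""
    idx = 0
    for ch in word:
        idx = idx * 4 + _BASES.index(ch)
    return idx


def index_to_word(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes for ACGT, 255 for N."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_counts(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Count k-windows of one encoded contig, skipping windows containing N.

    Returns (counts over 4^k words, number of valid windows).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64), 0
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col != 255
        idx = idx * 4 + np.where(col == 255, 0, col)
    counts = np.bincount(idx[valid], minlength=4**k).astype(np.int64)
    return counts, int(valid.sum())


@dataclass
class KmerProfile:
    """Observed counts of all 4^k words of one genome.

    counts[i] is the count of the i-th word in lexicographic order;
    n_positions is the total number of valid word windows.
    """

    k: int
    counts: np.ndarray
    n_positions: int
    source_id: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4^{self.k}")
        if int(self.counts.sum()) != self.n_positions:
            raise ValueError("sum of counts must equal n_positions")

    @property
    def freqs(self) -> np.ndarray:
        if self.n_positions == 0:
            raise ModelEstimationError(f"empty profile for {self.source_id!r}")
        return self.counts / self.n_positions


def count_kmers(
    record: SequenceRecord, k: int, strand_mode: str = "forward"
) -> KmerProfile:
    """Count all N-free k-windows of every contig of a record.

    strand_mode="both" additionally counts the reverse complement of each
    contig into the same profile (n_positions doubles for N-free contigs).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if max(len(c) for c in record.contigs) < k:
        raise ModelEstimationError(
            f"no contig of {record.id!r} is >= {k} nt; cannot count {k}-mers"
        )
    total = np.zeros(4**k, dtype=np.int64)
    n_positions = 0
    for contig in record.contigs:
        seqs = [contig]
        if strand_mode == "both":
            seqs.append(reverse_complement(contig))
        for seq in seqs:
            c, n = _window_counts(encode(seq), k)
            total += c
            n_positions += n
    if n_positions == 0:
        raise ModelEstimationError(
            f"record {record.id!r} has no valid (N-free) {k}-mer window"
        )
    return KmerProfile(k=k, counts=total, n_positions=n_positions, source_id=record.id)


@dataclass
class MarkovModel:
    """Order-r Markov background estimated from one genome.

    context_probs: empirical r-mer frequencies (length 4^r; [1.0] for r=0).
    transition_probs: (4^r, 4) matrix; rows for contexts with no observed
    successor are all zero.
    """

    order: int
    context_probs: np.ndarray
    transition_probs: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.context_probs = np.asarray(self.context_probs, dtype=float)
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        r = self.order
        if self.context_probs.shape != (4**r,):
            raise ValueError("context_probs must have length 4^order")
        if self.transition_probs.shape != (4**r, 4):
            raise ValueError("transition_probs must have shape (4^order, 4)")


def estimate_markov(
    record: SequenceRecord, order: int, strand_mode: str = "forward"
) -> MarkovModel:
    """Estimate an order-r background from (r+1)-mer counts of the record.

    Transition rows are normalized successor counts; contexts without any
    observed successor get an all-zero row (no pseudocounts). Context
    probabilities are the empirical r-mer frequencies.
    """
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    succ = count_kmers(record, order + 1, strand_mode=strand_mode)
    pair = succ.counts.reshape(4**order, 4).astype(float)
    rows = pair.sum(axis=1)
    trans = np.divide(
        pair, rows[:, None], out=np.zeros_like(pair), where=rows[:, None] > 0
    )
    if order == 0:
        ctx = np.array([1.0])
    else:
        ctx = count_kmers(record, order, strand_mode=strand_mode).freqs
    return MarkovModel(
        order=order, context_probs=ctx, transition_probs=trans, source_id=record.id
    )


def word_probabilities(model: MarkovModel, k: int) -> np.ndarray:
    """p_w for all 4^k words under the model, by the Markov chain product.

    p_w = P(context w_1..w_r) * prod_{i=r+1..k} P(w_i | w_{i-r}..w_{i-1}).
    Words whose context was never observed get probability 0.
    """
    r = model.order
    if r > k - 1:
        raise ValueError(f"model order {r} must be <= k-1 = {k - 1}")
    p = model.context_probs.copy()
    for length in range(r, k):
        ctx_of_prefix = np.arange(4**length) % (4**r)
        p = (p[:, None] * model.transition_probs[ctx_of_prefix, :]).ravel()
    return p


@dataclass
class CenteredProfile:
    """Observed counts minus Markov-expected counts for one genome."""

    profile: KmerProfile
    model: MarkovModel
    word_probs: np.ndarray
    expected: np.ndarray
    centered: np.ndarray

    @property
    def k(self) -> int:
        return self.profile.k


def center_profile(profile: KmerProfile, model: MarkovModel) -> CenteredProfile:
    """Compute expected counts E_w = n * p_w and centered counts N_w - E_w."""
    if model.order >= profile.k:
        raise ValueError(
            f"background order {model.order} must be < k = {profile.k}"
        )
    p = word_probabilities(model, profile.k)
    expected = profile.n_positions * p
    centered = profile.counts - expected
    return CenteredProfile(
        profile=profile, model=model, word_probs=p, expected=expected, centered=centered
    )


def markov_loglik(record: SequenceRecord, order: int) -> tuple[float, int]:
    """Order-r log-likelihood of transitions within contigs.

    Initial-context terms are omitted. Returns (logL, number of scored
    transitions).
    """
    succ = count_kmers(record, order + 1)
    pair = succ.counts.reshape(4**order, 4).astype(float)
    rows = pair.sum(axis=1)
    trans = np.divide(
        pair, rows[:, None], out=np.zeros_like(pair), where=rows[:, None] > 0
    )
    mask = pair > 0
    loglik = float(np.sum(pair[mask] * np.log(trans[mask])))
    return loglik, succ.n_positions


def select_order_bic(record: SequenceRecord, max_order: int) -> int:
    """Pick the Markov order in {0..max_order} minimizing the BIC.

    BIC(r) = -2 logL(r) + 3 * 4^r * log(n_r) with n_r the number of scored
    transitions at order r. Ties go to the smaller order.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    bics = []
    for r in range(max_order + 1):
        loglik, n = markov_loglik(record, r)
        if n == 0:
            raise ModelEstimationError(
                f"record {record.id!r} too short to score order {r}"
            )
        bics.append(-2.0 * loglik + 3.0 * (4**r) * np.log(n))
    return int(np.argmin(bics))


# --- JSON sidecar serialization (sparse word->count map) ---------------------


def profile_to_json(profile: KmerProfile, path: str | Path) -> None:
    nz = np.nonzero(profile.counts)[0]
    data = {
        "id": profile.source_id,
        "k": profile.k,
        "n_positions": profile.n_positions,
        "counts": {index_to_word(int(i), profile.k): int(profile.counts[i]) for i in nz},
    }
    Path(path).write_text(json.dumps(data, indent=1))


def profile_from_json(path: str | Path) -> KmerProfile:
    data = json.loads(Path(path).read_text())
    k = data["k"]
    counts = np.zeros(4**k, dtype=np.int64)
    for word, c in data["counts"].items():
        counts[word_index(word)] = c
    return KmerProfile(
        k=k, counts=counts, n_positions=data["n_positions"], source_id=data["id"]
    )


def model_to_json(model: MarkovModel, path: str | Path) -> None:
    data = {
        "id": model.source_id,
        "order": model.order,
        "context_probs": model.context_probs.tolist(),
        "transition_probs": model.transition_probs.tolist(),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def model_from_json(path: str | Path) -> MarkovModel:
    data = json.loads(Path(path).read_text())
    return MarkovModel(
        order=data["order"],
        context_probs=np.array(data["context_probs"]),
        transition_probs=np.array(data["transition_probs"]),
        source_id=data["id"],
    )
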