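"""Independent brute-force oracles used to verify the package.

Everything here is written directly from the definitions using dictionaries
and explicit loops over all 4^k words — deliberately naive and independent
of the implementations under test.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"


def all_words(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(BASES, repeat=k)]


def naive_count_kmers(contigs: list[str], k: int) -> tuple[dict[str, int], int]:
    """Substring scan; windows containing any non-ACGT character are skipped."""
    counts: dict[str, int] = {}
    n = 0
    for contig in contigs:
        for i in range(len(contig) - k + 1):
            w = contig[i : i + k]
            if all(ch in BASES for ch in w):
                counts[w] = counts.get(w, 0) + 1
                n += 1
    return counts, n


def naive_freqs(contigs: list[str], k: int) -> dict[str, float]:
    counts, n = naive_count_kmers(contigs, k)
    return {w: counts.get(w, 0) / n for w in all_words(k)}


def naive_markov(contigs: list[str], r: int):
    """(context_probs dict, transition dict (ctx, base) -> prob)."""
    succ, _ = naive_count_kmers(contigs, r + 1)
    trans: dict[tuple[str, str], float] = {}
    for ctx in all_words(r) if r > 0 else [""]:
        total = sum(succ.get(ctx + b, 0) for b in BASES)
        for b in BASES:
            trans[(ctx, b)] = succ.get(ctx + b, 0) / total if total else 0.0
    if r == 0:
        ctx_probs = {"": 1.0}
    else:
        counts, n = naive_count_kmers(contigs, r)
        ctx_probs = {w: counts.get(w, 0) / n for w in all_words(r)}
    return ctx_probs, trans


def naive_word_probs(contigs: list[str], k: int, r: int) -> dict[str, float]:
    ctx_probs, trans = naive_markov(contigs, r)
    probs = {}
    for w in all_words(k):
        p = ctx_probs[w[:r]]
        for i in range(r, k):
            p *= trans[(w[i - r : i], w[i])]
        probs[w] = p
    return probs


def naive_expected(contigs: list[str], k: int, r: int) -> dict[str, float]:
    _, n = naive_count_kmers(contigs, k)
    probs = naive_word_probs(contigs, k, r)
    return {w: n * probs[w] for w in all_words(k)}


# --- measures -----------------------------------------------------------------


def oracle_eu(cx: list[str], cy: list[str], k: int) -> float:
    fx, fy = naive_freqs(cx, k), naive_freqs(cy, k)
    return math.sqrt(sum((fx[w] - fy[w]) ** 2 for w in all_words(k)))


def oracle_ma(cx: list[str], cy: list[str], k: int) -> float:
    fx, fy = naive_freqs(cx, k), naive_freqs(cy, k)
    return sum(abs(fx[w] - fy[w]) for w in all_words(k))


def oracle_ch(cx: list[str], cy: list[str], k: int) -> float:
    fx, fy = naive_freqs(cx, k), naive_freqs(cy, k)
    return max(abs(fx[w] - fy[w]) for w in all_words(k))


def oracle_d2(cx: list[str], cy: list[str], k: int) -> float:
    fx, fy = naive_freqs(cx, k), naive_freqs(cy, k)
    dot = sum(fx[w] * fy[w] for w in all_words(k))
    nx = math.sqrt(sum(v * v for v in fx.values()))
    ny = math.sqrt(sum(v * v for v in fy.values()))
    return (1.0 - dot / (nx * ny)) / 2.0


def oracle_js(cx: list[str], cy: list[str], r: int) -> float:
    p = naive_freqs(cx, r + 1)
    q = naive_freqs(cy, r + 1)
    js = 0.0
    for w in all_words(r + 1):
        m = (p[w] + q[w]) / 2.0
        if p[w] > 0:
            js += 0.5 * p[w] * math.log2(p[w] / m)
        if q[w] > 0:
            js += 0.5 * q[w] * math.log2(q[w] / m)
    return js


def oracle_d2star(cx: list[str], cy: list[str], k: int, r: int) -> float:
    nx = naive_count_kmers(cx, k)
    ny = naive_count_kmers(cy, k)
    ex = naive_expected(cx, k, r)
    ey = naive_expected(cy, k, r)
    num = sx = sy = 0.0
    for w in all_words(k):
        if ex[w] > 0 and ey[w] > 0:
            xt = nx[0].get(w, 0) - ex[w]
            yt = ny[0].get(w, 0) - ey[w]
            num += xt * yt / math.sqrt(ex[w] * ey[w])
            sx += xt * xt / ex[w]
            sy += yt * yt / ey[w]
    return 0.5 * (1.0 - num / (math.sqrt(sx) * math.sqrt(sy)))


def oracle_d2s(cx: list[str], cy: list[str], k: int, r: int) -> float:
    nx = naive_count_kmers(cx, k)
    ny = naive_count_kmers(cy, k)
    ex = naive_expected(cx, k, r)
    ey = naive_expected(cy, k, r)
    num = sx = sy = 0.0
    for w in all_words(k):
        xt = nx[0].get(w, 0) - ex[w]
        yt = ny[0].get(w, 0) - ey[w]
        den = math.sqrt(xt * xt + yt * yt)
        if den > 0:
            num += xt * yt / den
            sx += xt * xt / den
            sy += yt * yt / den
    return 0.5 * (1.0 - num / (math.sqrt(sx) * math.sqrt(sy)))


def _hao_a(contigs: list[str], k: int) -> dict[str, float]:
    fk = naive_freqs(contigs, k)
    fk1 = naive_freqs(contigs, k - 1)
    fk2 = naive_freqs(contigs, k - 2)
    a = {}
    for w in all_words(k):
        den = fk2[w[1:-1]]
        f0 = fk1[w[:-1]] * fk1[w[1:]] / den if den > 0 else 0.0
        a[w] = (fk[w] - f0) / f0 if f0 > 0 else 0.0
    return a


def oracle_hao(cx: list[str], cy: list[str], k: int) -> float:
    ax, ay = _hao_a(cx, k), _hao_a(cy, k)
    dot = sum(ax[w] * ay[w] for w in all_words(k))
    nx = math.sqrt(sum(v * v for v in ax.values()))
    ny = math.sqrt(sum(v * v for v in ay.values()))
    return (1.0 - dot / (nx * ny)) / 2.0


def _teeling_z(contigs: list[str], k: int) -> dict[str, float]:
    nk, _ = naive_count_kmers(contigs, k)
    nk1, _ = naive_count_kmers(contigs, k - 1)
    nk2, _ = naive_count_kmers(contigs, k - 2)
    z = {}
    for w in all_words(k):
        den = nk2.get(w[1:-1], 0)
        if den > 0:
            e = nk1.get(w[:-1], 0) * nk1.get(w[1:], 0) / den
            if e > 0:
                z[w] = (nk.get(w, 0) - e) / math.sqrt(e)
    return z


def oracle_teeling(cx: list[str], cy: list[str], k: int) -> float:
    zx, zy = _teeling_z(cx, k), _teeling_z(cy, k)
    shared = sorted(set(zx) & set(zy))
    xs = [zx[w] for w in shared]
    ys = [zy[w] for w in shared]
    n = len(shared)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    rho = cov / math.sqrt(vx * vy)
    return (1.0 - rho) / 2.0


def oracle_euf(cx: list[str], cy: list[str], k: int, r: int) -> float:
    nx = naive_count_kmers(cx, k)[0]
    ny = naive_count_kmers(cy, k)[0]
    ex = naive_expected(cx, k, r)
    ey = naive_expected(cy, k, r)
    total = 0.0
    for w in all_words(k):
        if ex[w] > 0 and ey[w] > 0:
            dx = (nx.get(w, 0) - ex[w]) / ex[w]
            dy = (ny.get(w, 0) - ey[w]) / ey[w]
        else:
            dx = dy = 0.0
        total += (dx - dy) ** 2
    return math.sqrt(total)


def _willner_delta(contigs: list[str], k: int) -> dict[str, float]:
    fk = naive_freqs(contigs, k)
    f1 = naive_freqs(contigs, 1)
    d = {}
    for w in all_words(k):
        prod = 1.0
        for ch in w:
            prod *= f1[ch]
        d[w] = fk[w] / prod if prod > 0 else 0.0
    return d


def oracle_willner(cx: list[str], cy: list[str], k: int) -> float:
    dx, dy = _willner_delta(cx, k), _willner_delta(cy, k)
    return sum(abs(dx[w] - dy[w]) for w in all_words(k)) / 4**k


def oracle_auc(true_scores: list[float], random_scores: list[float]) -> float:
    """Exhaustive all-pairs P(true < random) + 0.5 P(equal)."""
    wins = 0.0
    for t in true_scores:
        for r in random_scores:
            if t < r:
                wins += 1.0
            elif t == r:
                wins += 0.5
    return wins / (len(true_scores) * len(random_scores))


def random_dna(rng, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
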