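"""Scoring predictions against known truth.

Per-rank accuracy with recall, ROC/AUC for true-vs-random pair
discrimination, Welch t-tests on score distributions, an empirical
random-guess baseline, and fragment-length / substitution-error robustness
sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from onfhost.measures import GenomeFeatures, MeasureConfig
from onfhost.prediction import (
    RANKS,
    UNKNOWN,
    PredictionSet,
    TaxonomyTable,
    compute_matrix,
    predict_nearest,
)
from onfhost.sequence_io import SequenceRecord, mutate, subsample_fragment


@dataclass
class TruthTable:
    """virus_id -> true host lineage (six ranks), plus the true host id."""

    rows: dict[str, dict[str, str]]
    host_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for vid, lineage in self.rows.items():
            missing = [r for r in RANKS if r not in lineage]
            if missing:
                raise ValueError(f"virus {vid!r} lacks ranks {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        rows: dict[str, dict[str, str]] = {}
        host_of: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["virus_id", "host_id", *RANKS]
            if header != expected:
                raise ValueError(f"truth header must be {expected}, got {header}")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows[fields[0]] = dict(zip(RANKS, fields[2:]))
                host_of[fields[0]] = fields[1]
        return cls(rows=rows, host_of=host_of)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("virus_id\thost_id\t" + "\t".join(RANKS) + "\n")
            for vid, lineage in self.rows.items():
                fh.write(
                    vid
                    + "\t"
                    + self.host_of.get(vid, UNKNOWN)
                    + "\t"
                    + "\t".join(lineage[r] for r in RANKS)
                    + "\n"
                )


def accuracy_by_level(
    predictions: PredictionSet, truth: TruthTable
) -> dict[str, dict[str, float]]:
    """Per-rank accuracy (correct / predicted) and recall (predicted / total).

    A virus whose truth is 'unknown' at a rank is excluded from that rank's
    denominators; an 'unknown' predicted taxon never counts as correct
    (it is recorded as no prediction upstream).
    """
    shared = [v for v in predictions.predictions if v in truth.rows]
    if not shared:
        raise ValueError("no overlap between predicted and truth virus ids")
    out: dict[str, dict[str, float]] = {}
    for rank in RANKS:
        viruses = [v for v in shared if truth.rows[v][rank] != UNKNOWN]
        n_total = len(viruses)
        predicted = [
            v for v in viruses if predictions.predictions[v].taxa[rank] is not None
        ]
        n_predicted = len(predicted)
        n_correct = sum(
            1
            for v in predicted
            if predictions.predictions[v].taxa[rank] == truth.rows[v][rank]
        )
        out[rank] = {
            "accuracy": n_correct / n_predicted if n_predicted else math.nan,
            "recall": n_predicted / n_total if n_total else math.nan,
            "n_total": n_total,
            "n_predicted": n_predicted,
            "n_correct": n_correct,
        }
    return out


def roc_auc(true_pair_scores, random_pair_scores) -> float:
    """AUC for discriminating true from random pairs; lower score = positive.

    Equals P(true < random) + 0.5 P(true == random), computed from the
    rank-sum statistic, which matches the trapezoidal area under the ROC.
    """
    x = np.asarray(true_pair_scores, dtype=float)
    y = np.asarray(random_pair_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score lists must be non-empty")
    # U counts pairs (random > true) + half ties
    u = stats.mannwhitneyu(y, x, alternative="two-sided").statistic
    return float(u) / (x.size * y.size)


def pair_ttest(true_pair_scores, random_pair_scores) -> float:
    """Two-sided Welch t-test p-value between the two score samples."""
    x = np.asarray(true_pair_scores, dtype=float)
    y = np.asarray(random_pair_scores, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 scores per sample")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def random_baseline(
    taxonomy: TaxonomyTable, truth: TruthTable
) -> dict[str, float]:
    """Expected per-rank accuracy of drawing a host uniformly at random.

    Closed form: the mean over viruses of the fraction of hosts sharing the
    virus's true taxon at that rank. 'unknown' host labels never match;
    viruses with 'unknown' truth at a rank are excluded at that rank.
    """
    if not taxonomy.rows or not truth.rows:
        raise ValueError("empty taxonomy or truth table")
    hosts = list(taxonomy.rows)
    n_hosts = len(hosts)
    out: dict[str, float] = {}
    for rank in RANKS:
        fracs = []
        for vid, lineage in truth.rows.items():
            t = lineage[rank]
            if t == UNKNOWN:
                continue
            match = sum(1 for h in hosts if taxonomy.rows[h][rank] == t)
            fracs.append(match / n_hosts)
        out[rank] = float(np.mean(fracs)) if fracs else math.nan
    return out


def robustness_sweep(
    viruses: list[SequenceRecord],
    hosts: list[SequenceRecord],
    taxonomy: TaxonomyTable,
    truth: TruthTable,
    lengths: list[int | None],
    error_rates: list[float],
    replicates: int,
    config: MeasureConfig,
    seed: int = 0,
    strand_mode: str = "forward",
    error_fragment_length: int | None = None,
) -> list[dict]:
    """Accuracy under fragment subsampling and simulated substitution errors.

    For each grid point and replicate the viruses are perturbed
    (subsampled to a length, or mutated at a rate; None length = full
    sequence), re-scored against the unperturbed hosts and predicted by
    nearest host. If error_fragment_length is set, the error grid mutates
    fragments of that length rather than full genomes (the usual protocol:
    subsample a fixed-length contig, then simulate sequencing error).
    Returns tidy rows: grid_var, value, replicate, rank, accuracy, recall.
    Host profiles are computed once and shared.
    """
    host_features = [GenomeFeatures(h, strand_mode) for h in hosts]
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def run(perturbed: list[SequenceRecord], grid_var: str, value, rep: int) -> None:
        matrix = compute_matrix(perturbed, host_features, config, strand_mode)
        matrix.virus_ids = [v.id for v in viruses]  # undo fragment id suffixes
        preds = predict_nearest(matrix, taxonomy, seed=int(rng.integers(2**31)))
        acc = accuracy_by_level(preds, truth)
        for rank in RANKS:
            rows.append(
                {
                    "grid_var": grid_var,
                    "value": value,
                    "replicate": rep,
                    "rank": rank,
                    "accuracy": acc[rank]["accuracy"],
                    "recall": acc[rank]["recall"],
                }
            )

    for length in lengths:
        for rep in range(replicates):
            if length is None:
                perturbed = list(viruses)
                value = "full"
            else:
                perturbed = [
                    subsample_fragment(v, length, int(rng.integers(2**31)))
                    for v in viruses
                ]
                value = length
            run(perturbed, "length", value, rep)
    for rate in error_rates:
        for rep in range(replicates):
            if error_fragment_length is not None:
                base = [
                    subsample_fragment(
                        v, error_fragment_length, int(rng.integers(2**31))
                    )
                    for v in viruses
                ]
            else:
                base = list(viruses)
            perturbed = [
                mutate(v, rate, int(rng.integers(2**31))) for v in base
            ]
            run(perturbed, "error_rate", rate, rep)
    return rows


def summarize_sweep(rows: list[dict]) -> list[dict]:
    """Mean accuracy and 95% normal-approximation CI per grid point and rank."""
    keys = sorted({(r["grid_var"], str(r["value"]), r["rank"]) for r in rows})
    out = []
    for grid_var, value, rank in keys:
        accs = np.array(
            [
                r["accuracy"]
                for r in rows
                if (r["grid_var"], str(r["value"]), r["rank"]) == (grid_var, value, rank)
            ]
        )
        accs = accs[~np.isnan(accs)]
        mean = float(accs.mean()) if accs.size else math.nan
        se = float(accs.std(ddof=1) / np.sqrt(accs.size)) if accs.size > 1 else 0.0
        out.append(
            {
                "grid_var": grid_var,
                "value": value,
                "rank": rank,
                "mean_accuracy": mean,
                "ci_low": mean - 1.96 * se,
                "ci_high": mean + 1.96 * se,
                "n": int(accs.size),
            }
        )
    return out


def sweep_to_tsv(rows: list[dict], path: str | Path) -> None:
    cols = ["grid_var", "value", "replicate", "rank", "accuracy", "recall"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
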