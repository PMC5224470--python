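"""Dissimilarity matrices and host-taxon selection.

Selection strategies: nearest host, top-n consensus (per-rank modal taxon),
score thresholding (refuse a prediction when the best score is too high),
and a one-sided rank-sum test for taxa scoring systematically lower than
the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from onfhost.measures import (
    DegenerateInputError,
    GenomeFeatures,
    MeasureConfig,
    compute_score,
)
from onfhost.sequence_io import SequenceRecord

RANKS = ("genus", "family", "order", "class", "phylum", "domain")
UNKNOWN = "unknown"


@dataclass
class TaxonomyTable:
    """host_id -> lineage at the six scored ranks; any field may be 'unknown'."""

    rows: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for host_id, lineage in self.rows.items():
            missing = [r for r in RANKS if r not in lineage]
            if missing:
                raise ValueError(f"host {host_id!r} lacks ranks {missing}")

    def lineage(self, host_id: str) -> dict[str, str]:
        if host_id not in self.rows:
            raise KeyError(f"host {host_id!r} missing from taxonomy table")
        return self.rows[host_id]

    def taxon(self, host_id: str, rank: str) -> str:
        return self.lineage(host_id)[rank]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        rows: dict[str, dict[str, str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["host_id", *RANKS]
            if header != expected:
                raise ValueError(f"taxonomy header must be {expected}, got {header}")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows[fields[0]] = dict(zip(RANKS, fields[1:]))
        return cls(rows=rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("host_id\t" + "\t".join(RANKS) + "\n")
            for host_id, lineage in self.rows.items():
                fh.write(host_id + "\t" + "\t".join(lineage[r] for r in RANKS) + "\n")


@dataclass
class DissimilarityMatrix:
    """viruses x hosts score matrix for one (measure, k, order) configuration."""

    virus_ids: list[str]
    host_ids: list[str]
    scores: np.ndarray
    config: MeasureConfig

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.virus_ids), len(self.host_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("matrix contains non-finite scores")

    def row(self, virus_id: str) -> np.ndarray:
        return self.scores[self.virus_ids.index(virus_id)]

    def subset_hosts(self, keep: list[str]) -> "DissimilarityMatrix":
        """Column-subset (e.g. habitat restriction) without recomputation."""
        missing = [h for h in keep if h not in self.host_ids]
        if missing:
            raise KeyError(f"hosts not in matrix: {missing}")
        cols = [self.host_ids.index(h) for h in keep]
        return DissimilarityMatrix(
            virus_ids=list(self.virus_ids),
            host_ids=list(keep),
            scores=self.scores[:, cols],
            config=self.config,
        )

    def to_tsv(self, path: str | Path) -> None:
        # full repr precision so downstream thresholding is exact
        with open(path, "w") as fh:
            fh.write("virus_id\t" + "\t".join(self.host_ids) + "\n")
            for vid, row in zip(self.virus_ids, self.scores):
                fh.write(vid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, config: MeasureConfig) -> "DissimilarityMatrix":
        with open(path) as fh:
            host_ids = fh.readline().rstrip("\n").split("\t")[1:]
            virus_ids, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                virus_ids.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(
            virus_ids=virus_ids, host_ids=host_ids, scores=np.array(rows), config=config
        )


def compute_matrix(
    viruses: list[SequenceRecord] | list[GenomeFeatures],
    hosts: list[SequenceRecord] | list[GenomeFeatures],
    config: MeasureConfig,
    strand_mode: str = "forward",
) -> DissimilarityMatrix:
    """Score every virus against every host under one configuration.

    Per-genome profiles and background models are computed once and reused
    across the whole row/column. Accepts prebuilt GenomeFeatures to share
    caches between configurations.
    """

    def as_features(x) -> GenomeFeatures:
        return x if isinstance(x, GenomeFeatures) else GenomeFeatures(x, strand_mode)

    vf = [as_features(v) for v in viruses]
    hf = [as_features(h) for h in hosts]
    if not vf or not hf:
        raise ValueError("need at least one virus and one host")
    scores = np.empty((len(vf), len(hf)))
    degenerate: set[str] = set()
    for i, v in enumerate(vf):
        for j, h in enumerate(hf):
            try:
                scores[i, j] = compute_score(v, h, config)
            except DegenerateInputError:
                degenerate.add(v.id)
                degenerate.add(h.id)
                scores[i, j] = np.nan
    if degenerate:
        raise DegenerateInputError(
            f"degenerate genomes for {config.measure_id}: {sorted(degenerate)}"
        )
    return DissimilarityMatrix(
        virus_ids=[v.id for v in vf],
        host_ids=[h.id for h in hf],
        scores=scores,
        config=config,
    )


@dataclass
class Prediction:
    """Predicted taxon per rank for one virus (None = no prediction)."""

    virus_id: str
    taxa: dict[str, str | None]
    best_score: float
    supporting_hosts: list[str]


@dataclass
class PredictionSet:
    """All per-virus predictions plus the method metadata that produced them."""

    predictions: dict[str, Prediction]
    method: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        method = ";".join(f"{k}={v}" for k, v in self.method.items())
        with open(path, "w") as fh:
            fh.write("virus_id\trank\tpredicted_taxon\tscore\tmethod\n")
            for vid, pred in self.predictions.items():
                for rank in RANKS:
                    taxon = pred.taxa[rank]
                    fh.write(
                        f"{vid}\t{rank}\t"
                        f"{taxon if taxon is not None else 'no prediction'}\t"
                        f"{pred.best_score!r}\t{method}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictionSet":
        preds: dict[str, Prediction] = {}
        method_str = ""
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["virus_id", "rank", "predicted_taxon"]:
                raise ValueError(f"unexpected predictions header: {header}")
            for line in fh:
                vid, rank, taxon, score, method_str = line.rstrip("\n").split("\t")
                if vid not in preds:
                    preds[vid] = Prediction(
                        virus_id=vid,
                        taxa={r: None for r in RANKS},
                        best_score=float(score),
                        supporting_hosts=[],
                    )
                preds[vid].taxa[rank] = None if taxon == "no prediction" else taxon
        method = dict(
            kv.split("=", 1) for kv in method_str.split(";") if "=" in kv
        )
        return cls(predictions=preds, method=method)


def _check_taxonomy_cover(matrix: DissimilarityMatrix, taxonomy: TaxonomyTable) -> None:
    missing = [h for h in matrix.host_ids if h not in taxonomy.rows]
    if missing:
        raise KeyError(f"hosts missing from taxonomy table: {missing}")


def predict_nearest(
    matrix: DissimilarityMatrix,
    taxonomy: TaxonomyTable,
    threshold: float | None = None,
    seed: int = 0,
) -> PredictionSet:
    """Predict each virus's host lineage from the lowest-scoring host.

    With a threshold, no prediction is made when the minimum score exceeds
    it. Exact score ties are broken by a seeded uniform choice.
    """
    _check_taxonomy_cover(matrix, taxonomy)
    rng = np.random.default_rng(seed)
    predictions: dict[str, Prediction] = {}
    for vid, row in zip(matrix.virus_ids, matrix.scores):
        best = float(row.min())
        if threshold is not None and best > threshold:
            predictions[vid] = Prediction(
                virus_id=vid,
                taxa={r: None for r in RANKS},
                best_score=best,
                supporting_hosts=[],
            )
            continue
        candidates = np.nonzero(row == best)[0]
        j = int(candidates[rng.integers(len(candidates))])
        host = matrix.host_ids[j]
        lineage = taxonomy.lineage(host)
        taxa = {r: (lineage[r] if lineage[r] != UNKNOWN else None) for r in RANKS}
        predictions[vid] = Prediction(
            virus_id=vid, taxa=taxa, best_score=best, supporting_hosts=[host]
        )
    return PredictionSet(
        predictions=predictions,
        method={"strategy": "nearest", "threshold": threshold, "seed": seed},
    )


def predict_consensus(
    matrix: DissimilarityMatrix,
    taxonomy: TaxonomyTable,
    n: int,
    threshold: float | None = None,
    seed: int = 0,
) -> PredictionSet:
    """Predict the modal taxon among the n lowest-scoring hosts, per rank.

    'unknown' labels never vote; modal-frequency ties are broken by a
    seeded uniform choice. The threshold gate applies to the single best
    score, as in predict_nearest.
    """
    if not 1 <= n <= len(matrix.host_ids):
        raise ValueError(f"n must be in [1, {len(matrix.host_ids)}], got {n}")
    _check_taxonomy_cover(matrix, taxonomy)
    rng = np.random.default_rng(seed)
    predictions: dict[str, Prediction] = {}
    for vid, row in zip(matrix.virus_ids, matrix.scores):
        best = float(row.min())
        if threshold is not None and best > threshold:
            predictions[vid] = Prediction(
                virus_id=vid,
                taxa={r: None for r in RANKS},
                best_score=best,
                supporting_hosts=[],
            )
            continue
        # tie-aware top-n: shuffle once, then stable sort by score
        perm = rng.permutation(len(row))
        top = perm[np.argsort(row[perm], kind="stable")][:n]
        top_hosts = [matrix.host_ids[j] for j in top]
        taxa: dict[str, str | None] = {}
        for rank in RANKS:
            votes: dict[str, int] = {}
            for host in top_hosts:
                t = taxonomy.taxon(host, rank)
                if t != UNKNOWN:
                    votes[t] = votes.get(t, 0) + 1
            if not votes:
                taxa[rank] = None
                continue
            top_count = max(votes.values())
            modal = sorted(t for t, c in votes.items() if c == top_count)
            taxa[rank] = modal[int(rng.integers(len(modal)))]
        predictions[vid] = Prediction(
            virus_id=vid, taxa=taxa, best_score=best, supporting_hosts=top_hosts
        )
    return PredictionSet(
        predictions=predictions,
        method={
            "strategy": "consensus",
            "n": n,
            "threshold": threshold,
            "seed": seed,
        },
    )


def ranksum_taxa(
    scores: np.ndarray,
    host_ids: list[str],
    taxonomy: TaxonomyTable,
    rank: str,
    alpha: float = 0.05,
) -> list[tuple[str, float]]:
    """Taxa whose hosts score significantly lower than all other hosts.

    One-sided Wilcoxon rank-sum per taxon at the given rank, Bonferroni
    corrected by the number of taxa tested; returns (taxon, corrected p)
    for corrected p < alpha, sorted by p. Hosts labelled 'unknown' at the
    rank are excluded. Uses the exact null when the combined group size is
    below 30 and there are no ties, otherwise the tie-corrected normal
    approximation.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(host_ids),):
        raise ValueError("scores and host_ids must align")
    groups: dict[str, list[float]] = {}
    for s, host in zip(scores, host_ids):
        t = taxonomy.taxon(host, rank)
        if t != UNKNOWN:
            groups.setdefault(t, []).append(float(s))
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 distinct taxa at rank {rank!r}, found {len(groups)}"
        )
    n_tests = len(groups)
    results = []
    for taxon in sorted(groups):
        x = np.array(groups[taxon])
        y = np.concatenate([np.array(v) for t, v in groups.items() if t != taxon])
        combined = np.concatenate([x, y])
        exact = combined.size < 30 and np.unique(combined).size == combined.size
        res = stats.mannwhitneyu(
            x, y, alternative="less", method="exact" if exact else "asymptotic"
        )
        corrected = min(1.0, float(res.pvalue) * n_tests)
        if corrected < alpha:
            results.append((taxon, corrected))
    results.sort(key=lambda tp: tp[1])
    return results
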