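"""Reference assignment and de novo OTU clustering.

Reads are matched to the reference library at < 3% distance (semi-global
alignment, end gaps free, so truncated amplicon reads align as substrings
of full-length barcodes). Reads matching nothing are greedily clustered
into OTUs at 2%.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio import Align

from .reads import ReadSet

__all__ = [
    "pairwise_distance",
    "assign_read",
    "assign_reads",
    "cluster_unmatched",
    "Otu",
    "AbundanceTable",
    "build_abundance_table",
    "SATURATED_DISTANCE",
]

#: sentinel returned by the K2P model when the correction is undefined
#: (argument of a log is non-positive, i.e. distance saturated)
SATURATED_DISTANCE = math.inf

_PURINES = frozenset("AG")
_ACGT = frozenset("ACGT")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # end gaps free -> semi-global; reads are amplicon substrings
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def _aligned_site_counts(a: str, b: str) -> tuple[int, int, int]:
    """(aligned sites, transitions, transversions) over non-gap, non-ambiguous
    columns of the best semi-global alignment."""
    alignment = _aligner().align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    sites = transitions = transversions = 0
    for (a0, a1), (b0, _) in zip(blocks_a, blocks_b):
        for offset in range(a1 - a0):
            x, y = a[a0 + offset], b[b0 + offset]
            if x not in _ACGT or y not in _ACGT:
                continue
            sites += 1
            if x != y:
                if (x in _PURINES) == (y in _PURINES):
                    transitions += 1
                else:
                    transversions += 1
    return sites, transitions, transversions


def pairwise_distance(a: str, b: str, model: str = "p") -> float:
    """Pairwise distance between two sequences in [0, 1].

    model="p": uncorrected mismatch fraction. model="k2p": Kimura
    two-parameter correction -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q) with P and Q
    the transition/transversion fractions; returns
    :data:`SATURATED_DISTANCE` when the correction is undefined.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    a, b = a.upper(), b.upper()
    sites, p_count, q_count = _aligned_site_counts(a, b)
    if sites == 0:
        return SATURATED_DISTANCE
    if model == "p":
        return (p_count + q_count) / sites
    if model == "k2p":
        P, Q = p_count / sites, q_count / sites
        arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
        if arg1 <= 0 or arg2 <= 0:
            return SATURATED_DISTANCE
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    raise ValueError(f"unknown distance model {model!r}")


def assign_read(
    seq: str,
    library: list[tuple[str, str]],
    threshold: float = 0.03,
    model: str = "p",
) -> tuple[str, float] | None:
    """Assign one sequence to its closest reference, or None if unmatched.

    Returns (bin_id, distance) for the minimum-distance reference when that
    distance is strictly below ``threshold``; ties break to the earliest
    library entry. An exact substring match short-circuits at distance 0.
    """
    if not library:
        raise ValueError("reference library is empty")
    seq = seq.upper()
    for bin_id, ref in library:
        if seq in ref or ref in seq:
            return bin_id, 0.0
    best_id, best_dist = None, math.inf
    for bin_id, ref in library:
        d = pairwise_distance(seq, ref, model=model)
        if d < best_dist:
            best_id, best_dist = bin_id, d
    if best_dist < threshold:
        return best_id, best_dist
    return None


def _kmer_set(seq: str, k: int = 8) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def assign_reads(
    reads: ReadSet,
    library: list[tuple[str, str]],
    threshold: float = 0.03,
    model: str = "p",
    max_candidates: int | None = 5,
) -> tuple[Counter, list[str]]:
    """Assign a read set; returns (per-bin counts, unmatched sequences).

    Reads are dereplicated before alignment, so cost scales with unique
    sequences rather than depth. When ``max_candidates`` is set (default 5),
    each unique read is aligned only against the references sharing the most
    8-mers with it — a safe shortcut here because references are generated
    far apart (>2%) relative to the assignment threshold; pass None for an
    exhaustive scan.
    """
    unique = Counter(r.seq for r in reads)
    counts: Counter = Counter()
    unmatched: list[str] = []
    if max_candidates is not None:
        ref_kmers = [_kmer_set(ref) for _, ref in library]
    for seq, n in unique.items():
        if max_candidates is None:
            hit = assign_read(seq, library, threshold=threshold, model=model)
        else:
            kmers = _kmer_set(seq)
            shared = [(len(kmers & rk), -i) for i, rk in enumerate(ref_kmers)]
            top = sorted(range(len(library)),
                         key=lambda i: shared[i], reverse=True)[:max_candidates]
            candidates = [library[i] for i in sorted(top)]
            hit = assign_read(seq, candidates, threshold=threshold, model=model)
        if hit is None:
            unmatched.extend([seq] * n)
        else:
            counts[hit[0]] += n
    return counts, unmatched


@dataclass
class Otu:
    otu_id: str
    centroid: str
    size: int


def cluster_unmatched(
    seqs: list[str], threshold: float = 0.02, model: str = "p",
) -> list[Otu]:
    """Greedy centroid clustering of unmatched reads.

    Unique sequences are processed in descending dereplicated abundance
    (ties: lexicographic sequence order); each joins the first existing
    centroid within ``threshold``, else founds a new OTU.
    """
    unique = Counter(seqs)
    order = sorted(unique, key=lambda s: (-unique[s], s))
    centroids: list[str] = []
    sizes: list[int] = []
    for seq in order:
        for idx, centroid in enumerate(centroids):
            if pairwise_distance(seq, centroid, model=model) <= threshold:
                sizes[idx] += unique[seq]
                break
        else:
            centroids.append(seq)
            sizes.append(unique[seq])
    return [Otu(f"OTU:{i:04d}", c, s)
            for i, (c, s) in enumerate(zip(centroids, sizes))]


@dataclass
class AbundanceTable:
    """Row (bin/OTU) x column (sample) count matrix with column metadata."""

    counts: pd.DataFrame
    col_metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate row ids in abundance table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts in abundance table")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(counts=df.astype(int))


def build_abundance_table(
    sample_counts: dict[str, Counter],
    sample_metadata: dict[str, dict] | None = None,
    pool_replicates: bool = True,
) -> AbundanceTable:
    """Merge per-sample assignment counts into one table.

    Absent rows are zero-filled. When ``pool_replicates`` is set, an
    in-silico pooled column (row-wise sum) is appended for every treatment
    with more than one replicate, named ``<treatment>_pooled``.
    """
    if len(sample_counts) == 0:
        raise ValueError("no samples to merge")
    sample_metadata = sample_metadata or {}
    if len(set(sample_counts)) != len(sample_counts):
        raise ValueError("duplicate sample ids")
    df = pd.DataFrame(
        {sample: pd.Series(counts, dtype=float)
         for sample, counts in sample_counts.items()}
    ).fillna(0).astype(int)
    df = df.sort_index()
    metadata = {s: dict(sample_metadata.get(s, {})) for s in df.columns}

    if pool_replicates:
        by_treatment: dict[str, list[str]] = {}
        for sample in df.columns:
            treatment = metadata[sample].get("treatment")
            if treatment:
                by_treatment.setdefault(treatment, []).append(sample)
        for treatment, samples in by_treatment.items():
            if len(samples) < 2:
                continue
            pooled = f"{treatment}_pooled"
            if pooled in df.columns:
                raise ValueError(f"sample id collides with pooled column {pooled!r}")
            df[pooled] = df[samples].sum(axis=1)
            metadata[pooled] = {"treatment": treatment, "replicate": "pooled"}
    return AbundanceTable(counts=df, col_metadata=metadata)
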