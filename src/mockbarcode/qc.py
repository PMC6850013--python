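"""Read merging, quality filtering and trimming.

The filtering cascade, applied in this order to each read (merged first when
paired):

1. quality screen — discard if mean QV < 20, or >25% of bases below Q20, or
   >5% of bases below Q10 (all comparisons strict; first tripped rule is the
   recorded reason);
2. 30 bp head trim (forward primer removal), then truncation to the target
   amplicon length;
3. length floor — discard reads shorter than the class minimum after
   trimming (300 bp for the 407 class, 350 bp for the 463 class).
"""

from __future__ import annotations

from dataclasses import dataclass

from .reads import Read, ReadSet, revcomp

__all__ = [
    "QcThresholds",
    "QcReport",
    "merge_paired_reads",
    "qv_filter",
    "trim_and_length_filter",
    "run_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    min_mean_qv: float = 20.0
    max_frac_below_q20: float = 0.25
    max_frac_below_q10: float = 0.05
    head_trim_bp: int = 30
    target_length: int = 407
    min_length: int = 300
    merge_min_overlap: int = 20
    merge_max_diff_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.min_length >= self.target_length:
            raise ValueError("min_length must be < target_length")
        if min(self.min_mean_qv, self.head_trim_bp, self.target_length,
               self.min_length, self.merge_min_overlap) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def for_amplicon(cls, amplicon_class: int, **overrides) -> "QcThresholds":
        """Class-specific defaults: 407 -> min 300 bp, 463 -> min 350 bp."""
        if amplicon_class == 407:
            params = {"target_length": 407, "min_length": 300}
        elif amplicon_class == 463:
            params = {"target_length": 463, "min_length": 350}
        else:
            raise ValueError(f"unknown amplicon class {amplicon_class}")
        params.update(overrides)
        return cls(**params)


@dataclass
class QcReport:
    """Per-sample filtering tally; ``n_in`` is conserved across the outcome
    counters (pairs count once for paired input)."""

    sample: str = ""
    n_in: int = 0
    n_unmerged: int = 0
    n_fail_mean_qv: int = 0
    n_fail_frac_q20: int = 0
    n_fail_frac_q10: int = 0
    n_length_discarded: int = 0
    n_retained: int = 0

    _REASON_FIELDS = {
        "mean_qv": "n_fail_mean_qv",
        "frac_q20": "n_fail_frac_q20",
        "frac_q10": "n_fail_frac_q10",
    }

    @property
    def n_discarded(self) -> int:
        return (self.n_unmerged + self.n_fail_mean_qv + self.n_fail_frac_q20
                + self.n_fail_frac_q10 + self.n_length_discarded)

    def is_conserved(self) -> bool:
        return self.n_in == self.n_retained + self.n_discarded

    def to_row(self) -> dict:
        return {
            "sample": self.sample, "in": self.n_in, "unmerged": self.n_unmerged,
            "fail_mean_qv": self.n_fail_mean_qv,
            "fail_frac_q20": self.n_fail_frac_q20,
            "fail_frac_q10": self.n_fail_frac_q10,
            "length_discarded": self.n_length_discarded,
            "retained": self.n_retained,
        }


def _best_overlap(fwd_seq: str, rc_seq: str, thresholds: QcThresholds):
    """Return (overlap, mismatches) of the best admissible overlap, else None.

    Best = lowest mismatch fraction among overlaps >= merge_min_overlap whose
    mismatch fraction is <= merge_max_diff_frac; ties go to the longer overlap.
    """
    best = None
    max_ov = min(len(fwd_seq), len(rc_seq))
    for ov in range(max_ov, thresholds.merge_min_overlap - 1, -1):
        mismatches = sum(a != b for a, b in zip(fwd_seq[-ov:], rc_seq[:ov]))
        frac = mismatches / ov
        if frac <= thresholds.merge_max_diff_frac:
            if best is None or frac < best[1] / best[0]:
                best = (ov, mismatches)
    return best


def merge_paired_reads(
    fwd: ReadSet, rev: ReadSet, thresholds: QcThresholds | None = None,
) -> tuple[ReadSet, int]:
    """Merge index-matched mate pairs; returns (merged set, pairs dropped).

    The reverse mate is reverse-complemented and overlapped against the 3'
    end of the forward mate. At overlap disagreements the base with the
    higher QV wins.
    """
    thresholds = thresholds or QcThresholds()
    if len(fwd) != len(rev):
        raise ValueError(f"mate count mismatch: {len(fwd)} forward vs {len(rev)} reverse")
    merged, dropped = [], 0
    for r1, r2 in zip(fwd, rev):
        rc_seq = revcomp(r2.seq)
        rc_qual = r2.qual[::-1]
        hit = _best_overlap(r1.seq, rc_seq, thresholds)
        if hit is None:
            dropped += 1
            continue
        ov, _ = hit
        seq, qual = list(r1.seq[:-ov]), list(r1.qual[:-ov])
        for i in range(ov):
            b1, q1 = r1.seq[len(r1.seq) - ov + i], r1.qual[len(r1.qual) - ov + i]
            b2, q2 = rc_seq[i], rc_qual[i]
            if b1 == b2:
                seq.append(b1)
                qual.append(max(q1, q2))
            elif q1 >= q2:
                seq.append(b1)
                qual.append(q1)
            else:
                seq.append(b2)
                qual.append(q2)
        seq += list(rc_seq[ov:])
        qual += rc_qual[ov:]
        merged.append(Read(r1.id, "".join(seq), qual))
    return ReadSet(merged, name=fwd.name, metadata=dict(fwd.metadata)), dropped


def qv_filter(read: Read, thresholds: QcThresholds | None = None) -> str | None:
    """Quality screen; returns the first tripped rule name, or None on pass."""
    thresholds = thresholds or QcThresholds()
    if len(read) == 0:
        raise ValueError(f"read {read.id} is empty")
    n = len(read.qual)
    if sum(read.qual) / n < thresholds.min_mean_qv:
        return "mean_qv"
    if sum(q < 20 for q in read.qual) / n > thresholds.max_frac_below_q20:
        return "frac_q20"
    if sum(q < 10 for q in read.qual) / n > thresholds.max_frac_below_q10:
        return "frac_q10"
    return None


def trim_and_length_filter(
    read: Read, thresholds: QcThresholds | None = None,
) -> Read | None:
    """Head-trim, truncate to the target length, drop if below the floor.

    Idempotent: a read already emitted by this function passes through
    unchanged (the head trim is a primer removal, applied once).
    """
    thresholds = thresholds or QcThresholds()
    if read.trimmed:
        seq, qual = read.seq, read.qual
    else:
        seq = read.seq[thresholds.head_trim_bp:]
        qual = read.qual[thresholds.head_trim_bp:]
    if len(seq) > thresholds.target_length:
        seq = seq[: thresholds.target_length]
        qual = qual[: thresholds.target_length]
    if len(seq) < thresholds.min_length:
        return None
    return Read(read.id, seq, qual, trimmed=True)


def run_qc(
    reads: ReadSet,
    thresholds: QcThresholds | None = None,
    mates: ReadSet | None = None,
    sample: str = "",
) -> tuple[ReadSet, QcReport]:
    """Full cascade: (merge,) quality-filter, trim, length-filter."""
    thresholds = thresholds or QcThresholds()
    report = QcReport(sample=sample or reads.name, n_in=len(reads))
    if mates is not None:
        reads, report.n_unmerged = merge_paired_reads(reads, mates, thresholds)
    retained = []
    for read in reads:
        reason = qv_filter(read, thresholds)
        if reason is not None:
            attr = QcReport._REASON_FIELDS[reason]
            setattr(report, attr, getattr(report, attr) + 1)
            continue
        trimmed = trim_and_length_filter(read, thresholds)
        if trimmed is None:
            report.n_length_discarded += 1
            continue
        retained.append(trimmed)
    report.n_retained = len(retained)
    return ReadSet(retained, name=reads.name, metadata=dict(reads.metadata)), report
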