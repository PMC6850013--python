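"""Synthetic mock community and biased amplicon read simulation.

Generates a community of barcode "species" with known ground truth
(sequences, masses, GC content, primer binding sites), then pushes it
through a three-stage forward model:

1. template pooling   - per-species template share, mass^b scaled with
                        optional lognormal pooling noise (treatment model);
2. PCR amplification  - per-cycle efficiency penalized geometrically per
                        primer mismatch;
3. sequencing         - platform-profiled reads (length, quality trajectory,
                        substitution/indel errors), truth-labelled FASTQ.

All randomness flows through explicit seeds; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primers import (
    DEFAULT_PRIMERS_407,
    DEFAULT_PRIMERS_463,
    IUPAC_SETS,
    best_cocktail_mismatch,
)
from .reads import Read, ReadSet, revcomp

__all__ = [
    "BARCODE_LENGTH",
    "PRIMER_SITE_LENGTH",
    "SpeciesRecord",
    "CommunitySpec",
    "TreatmentModel",
    "PlatformProfile",
    "CommunityGenerationError",
    "generate_community",
    "simulate_template_pool",
    "simulate_amplicon_pool",
    "simulate_reads",
    "write_reference_library",
    "read_reference_library",
    "write_manifest",
    "read_manifest",
    "TREATMENT_PRESETS",
    "PLATFORM_PRESETS",
    "AMPLICON_STARTS",
]

BARCODE_LENGTH = 658
PRIMER_SITE_LENGTH = 30
#: 5' offsets of the two amplicon classes within the barcode; both end at
#: the same 3' coordinate (the reverse primer site is fixed).
_INTERNAL_END = 557
AMPLICON_STARTS = {407: _INTERNAL_END - 407, 463: _INTERNAL_END - 463}

_BASES = np.array(list("ACGT"))
_ORDER_LABELS = (
    "Diptera", "Lepidoptera", "Hymenoptera", "Coleoptera", "Hemiptera",
    "Trichoptera", "Psocodea", "Neuroptera", "Orthoptera", "Thysanoptera",
)

MANIFEST_COLUMNS = [
    "bin_id", "order", "mass_mg", "gc",
    "fwd_mismatches_407", "fwd_mismatches_463", "rev_mismatches",
    "rev_site_known",
]


class CommunityGenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a generator constraint."""


@dataclass
class SpeciesRecord:
    """One mock-community member with its ground-truth attributes."""

    bin_id: str
    order_label: str
    barcode_seq: str
    abdominal_mass_mg: float
    fwd_site_seq: str
    rev_site_seq: str
    rev_site_known: bool
    #: true mismatch counts used by the amplification model (the analysis
    #: side re-derives observable ones from the site sequences)
    fwd_mismatches: int = 0
    rev_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.abdominal_mass_mg <= 0:
            raise ValueError(f"{self.bin_id}: abdominal mass must be positive")
        if set(self.barcode_seq) - set("ACGT"):
            raise ValueError(f"{self.bin_id}: barcode not over {{A,C,G,T}}")

    @property
    def gc_fraction(self) -> float:
        seq = self.barcode_seq
        return (seq.count("G") + seq.count("C")) / len(seq)

    def amplicon_seq(self, amplicon_class: int) -> str:
        """Sequenced amplicon: forward primer site + internal barcode region."""
        start = AMPLICON_STARTS[amplicon_class]
        return self.fwd_site_seq + self.barcode_seq[start:_INTERNAL_END]


@dataclass
class CommunitySpec:
    """Parameters of the community generator."""

    n_species: int = 374
    min_pairwise_divergence: float = 0.02
    mass_ratio: float = 7500.0
    mass_distribution: str = "log_uniform"
    gc_range: tuple[float, float] = (0.30, 0.50)
    mismatch_profile: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "fwd": {0: 0.55, 1: 0.25, 2: 0.12, 3: 0.05, 4: 0.03},
            "rev": {0: 0.60, 1: 0.22, 2: 0.10, 3: 0.05, 4: 0.03},
        }
    )
    rev_site_known_fraction: float = 203 / 369
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.mass_ratio < 1:
            raise ValueError("mass_ratio must be >= 1")
        if self.mass_distribution not in ("log_uniform", "log_normal"):
            raise ValueError(f"unknown mass_distribution {self.mass_distribution!r}")
        for side, profile in self.mismatch_profile.items():
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"mismatch_profile[{side!r}] probabilities sum to {total}, not 1"
                )
        if not 0 <= self.rev_site_known_fraction <= 1:
            raise ValueError("rev_site_known_fraction must be in [0, 1]")


@dataclass
class TreatmentModel:
    """Template pooling + PCR bias mechanism for one treatment."""

    treatment: str = "bulk_abdomen"
    mass_exponent: float = 0.66
    pool_noise_cv: float = 0.0
    pcr_cycles: int = 40  # two 20-cycle rounds
    max_efficiency: float = 0.9
    mismatch_penalty: float = 0.95

    def __post_init__(self) -> None:
        if self.pool_noise_cv < 0:
            raise ValueError("pool_noise_cv must be >= 0")
        if not 0 < self.max_efficiency <= 1:
            raise ValueError("max_efficiency must be in (0, 1]")
        if not 0 < self.mismatch_penalty <= 1:
            raise ValueError("mismatch_penalty must be in (0, 1]")


TREATMENT_PRESETS: dict[str, TreatmentModel] = {
    "bulk_abdomen": TreatmentModel("bulk_abdomen", mass_exponent=0.66,
                                   pool_noise_cv=0.25),
    "bulk_leg": TreatmentModel("bulk_leg", mass_exponent=0.50,
                               pool_noise_cv=0.25),
    "composite_leg": TreatmentModel("composite_leg", mass_exponent=0.30,
                                    pool_noise_cv=0.25),
    "single_leg": TreatmentModel("single_leg", mass_exponent=0.0,
                                 pool_noise_cv=0.10),
}


@dataclass
class PlatformProfile:
    """Caricature of a sequencing platform's read-length/quality/error model.

    Numeric defaults are free parameters of the simulator, not calibrated
    values; see :data:`PLATFORM_PRESETS`.
    """

    platform: str
    read_length_mean: float
    read_length_sd: float
    qv_start: float
    qv_slope: float
    sub_rate: float
    indel_rate: float
    paired: bool

    def __post_init__(self) -> None:
        if self.read_length_mean <= 0:
            raise ValueError("read_length_mean must be positive")
        if min(self.sub_rate, self.indel_rate) < 0:
            raise ValueError("error rates must be >= 0")


PLATFORM_PRESETS: dict[str, PlatformProfile] = {
    # flat quality, long paired reads, few indels
    "miseq_like": PlatformProfile("miseq_like", read_length_mean=250,
                                  read_length_sd=0, qv_start=35.0,
                                  qv_slope=0.0, sub_rate=1e-3,
                                  indel_rate=1e-5, paired=True),
    # single-end, 3'-declining quality, indel-prone
    "pgm_like": PlatformProfile("pgm_like", read_length_mean=380,
                                read_length_sd=40, qv_start=32.0,
                                qv_slope=-0.03, sub_rate=2e-3,
                                indel_rate=2e-3, paired=False),
    "s5_like": PlatformProfile("s5_like", read_length_mean=450,
                               read_length_sd=30, qv_start=34.0,
                               qv_slope=-0.02, sub_rate=1.5e-3,
                               indel_rate=1.5e-3, paired=False),
}


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

def _pairwise_hamming(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance counts for an (n, L) uint8 sequence matrix."""
    n = matrix.shape[0]
    out = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        out[i] = (matrix != matrix[i]).sum(axis=1)
    return out


def _draw_masses(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    n, ratio = spec.n_species, spec.mass_ratio
    if n == 1 or ratio == 1.0:
        return np.full(n, 1.0)
    if spec.mass_distribution == "log_uniform":
        logm = rng.uniform(0.0, np.log(ratio), size=n)
    else:
        logm = rng.normal(0.0, np.log(ratio) / 4, size=n)
    # rescale in log space so the realized max/min ratio is exactly mass_ratio
    lo, hi = logm.min(), logm.max()
    logm = (logm - lo) / (hi - lo) * np.log(ratio)
    return np.exp(logm) * 0.01  # smallest species at 0.01 mg


def _mutate_sites(seq_arr: np.ndarray, k: int, rng: np.random.Generator) -> None:
    """Mutate k random positions of a base array in place (to different bases)."""
    positions = rng.choice(seq_arr.size, size=k, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq_arr[pos]]
        seq_arr[pos] = choices[rng.integers(3)]


def _concretize_primer(primer: str, rng: np.random.Generator) -> np.ndarray:
    """Resolve a degenerate primer into a concrete perfectly matching site."""
    return np.array(
        [sorted(IUPAC_SETS[sym])[rng.integers(len(IUPAC_SETS[sym]))] for sym in primer]
    )


def _site_with_mismatches(
    cocktail: tuple[str, ...], target_mismatches: int, rng: np.random.Generator,
    max_attempts: int = 200,
) -> str:
    """Build a binding site whose best-of-cocktail mismatch count equals
    ``target_mismatches`` (rejection sampling against the other members)."""
    anchor = cocktail[0]
    for _ in range(max_attempts):
        site = _concretize_primer(anchor, rng)
        positions = rng.choice(len(anchor), size=target_mismatches, replace=False)
        for pos in positions:
            allowed = IUPAC_SETS[anchor[pos]]
            bad = [b for b in "ACGT" if b not in allowed]
            if not bad:  # N position: cannot mismatch here, try elsewhere
                break
            site[pos] = bad[rng.integers(len(bad))]
        candidate = "".join(site)
        if best_cocktail_mismatch(cocktail, candidate) == target_mismatches:
            return candidate
    raise CommunityGenerationError(
        f"could not realize a site with exactly {target_mismatches} "
        f"best-of-cocktail mismatches after {max_attempts} attempts"
    )


def _draw_from_profile(profile: dict[int, float], size: int,
                       rng: np.random.Generator) -> np.ndarray:
    classes = np.array(sorted(profile), dtype=int)
    probs = np.array([profile[c] for c in classes], dtype=float)
    return rng.choice(classes, size=size, p=probs / probs.sum())


def generate_community(spec: CommunitySpec) -> list[SpeciesRecord]:
    """Generate the mock community.

    Barcode sequences are produced by mutating a shared random ancestor at
    ~10% of sites per species, then rejection-checked so every pair exceeds
    ``min_pairwise_divergence`` (uncorrected distance). Deterministic for a
    fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_species, BARCODE_LENGTH

    gc_mid = float(np.mean(spec.gc_range))
    base_probs = np.array([(1 - gc_mid) / 2, gc_mid / 2, gc_mid / 2, (1 - gc_mid) / 2])
    ancestor = rng.choice(4, size=length, p=base_probs)
    per_species_mut = max(int(0.10 * length), int(np.ceil(
        spec.min_pairwise_divergence * length)) + 2)

    seqs = np.empty((n, length), dtype=np.uint8)
    for i in range(n):
        s = ancestor.copy()
        positions = rng.choice(length, size=per_species_mut, replace=False)
        s[positions] = (s[positions] + rng.integers(1, 4, size=per_species_mut)) % 4
        seqs[i] = s

    min_diffs = int(np.floor(spec.min_pairwise_divergence * length)) + 1
    for attempt in range(50):
        dists = _pairwise_hamming(seqs)
        np.fill_diagonal(dists, length)
        offenders = np.unique(np.argwhere(dists < min_diffs)[:, 0])
        if offenders.size == 0:
            break
        for i in offenders[:: 2]:  # re-draw one member of each close pair
            s = ancestor.copy()
            positions = rng.choice(length, size=per_species_mut, replace=False)
            s[positions] = (s[positions] + rng.integers(1, 4, size=per_species_mut)) % 4
            seqs[i] = s
    else:
        raise CommunityGenerationError(
            f"pairwise divergence > {spec.min_pairwise_divergence} not "
            f"achievable for n={n}, length={length} after 50 passes"
        )

    masses = _draw_masses(spec, rng)
    fwd_m = _draw_from_profile(spec.mismatch_profile["fwd"], n, rng)
    rev_m = _draw_from_profile(spec.mismatch_profile["rev"], n, rng)
    rev_known = rng.random(n) < spec.rev_site_known_fraction
    orders = rng.choice(len(_ORDER_LABELS), size=n)

    records = []
    for i in range(n):
        barcode = "".join(_BASES[seqs[i]])
        records.append(SpeciesRecord(
            bin_id=f"BIN:{i:04d}",
            order_label=_ORDER_LABELS[orders[i]],
            barcode_seq=barcode,
            abdominal_mass_mg=float(masses[i]),
            fwd_site_seq=_site_with_mismatches(
                DEFAULT_PRIMERS_407.forward, int(fwd_m[i]), rng),
            rev_site_seq=_site_with_mismatches(
                DEFAULT_PRIMERS_407.reverse, int(rev_m[i]), rng),
            rev_site_known=bool(rev_known[i]),
            fwd_mismatches=int(fwd_m[i]),
            rev_mismatches=int(rev_m[i]),
        ))
    return records


# ---------------------------------------------------------------------------
# template pooling and PCR
# ---------------------------------------------------------------------------

def simulate_template_pool(
    community: list[SpeciesRecord], model: TreatmentModel,
    seed: int | None = None,
) -> np.ndarray:
    """Per-species template shares: share_i ~ mass_i^b x lognormal noise.

    With ``mass_exponent`` 0 and ``pool_noise_cv`` 0 the shares are exactly
    uniform (the idealized single-leg pool).
    """
    if not community:
        raise ValueError("community is empty")
    masses = np.array([s.abdominal_mass_mg for s in community])
    shares = masses ** model.mass_exponent
    if model.pool_noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(model.pool_noise_cv ** 2))
        shares = shares * rng.lognormal(-sigma ** 2 / 2, sigma, size=len(community))
    return shares / shares.sum()


def simulate_amplicon_pool(
    template_shares: np.ndarray, mismatch_counts: np.ndarray,
    model: TreatmentModel,
) -> np.ndarray:
    """Amplify template shares: amplicon_i ~ t_i (1 + E p^m_i)^cycles.

    ``mismatch_counts`` is the per-species summed primer mismatch count; the
    amplification factor decreases strictly with it when the per-mismatch
    penalty is < 1.
    """
    shares = np.asarray(template_shares, dtype=float)
    m = np.asarray(mismatch_counts, dtype=float)
    if shares.shape != m.shape:
        raise ValueError("template shares and mismatch counts differ in length")
    eff = 1.0 + model.max_efficiency * model.mismatch_penalty ** m
    # work in log space: cycles * log(eff) overflows float64 well before 40 cycles
    log_amp = np.log(shares, where=shares > 0,
                     out=np.full_like(shares, -np.inf)) + model.pcr_cycles * np.log(eff)
    log_amp -= log_amp.max()
    amplicons = np.exp(log_amp)
    return amplicons / amplicons.sum()


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _quality_vector(n: int, profile: PlatformProfile,
                    rng: np.random.Generator) -> list[int]:
    qv = profile.qv_start + profile.qv_slope * np.arange(n)
    qv = qv + rng.normal(0, 1.5, size=n)
    return np.clip(np.rint(qv), 2, 40).astype(int).tolist()


def _apply_errors(seq: str, profile: PlatformProfile,
                  rng: np.random.Generator) -> str:
    if profile.sub_rate == 0 and profile.indel_rate == 0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r < profile.indel_rate / 2:
            continue  # deletion
        if r < profile.indel_rate:
            out.append("ACGT"[rng.integers(4)])  # insertion before base
        if rng.random() < profile.sub_rate:
            base = [b for b in "ACGT" if b != base][rng.integers(3)]
        out.append(base)
    return "".join(out)


def _read_length(profile: PlatformProfile, max_len: int,
                 rng: np.random.Generator) -> int:
    if profile.read_length_sd == 0:
        n = int(profile.read_length_mean)
    else:
        n = int(np.rint(rng.normal(profile.read_length_mean,
                                   profile.read_length_sd)))
    return max(40, min(n, max_len))


def simulate_reads(
    amplicon_shares: np.ndarray,
    community: list[SpeciesRecord],
    depth: int,
    profile: PlatformProfile,
    amplicon_class: int = 407,
    seed: int | None = None,
) -> ReadSet | tuple[ReadSet, ReadSet]:
    """Draw ``depth`` truth-labelled reads from the amplicon pool.

    Each read originates from species i with probability ``amplicon_shares[i]``
    (multinomial). Paired profiles return an (R1, R2) tuple of mate sets;
    single-end profiles return one :class:`ReadSet`. Read ids carry the source
    bin (``|bin=<id>``) for downstream truth checks.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if amplicon_class not in AMPLICON_STARTS:
        raise ValueError(f"amplicon_class must be one of {sorted(AMPLICON_STARTS)}")
    shares = np.asarray(amplicon_shares, dtype=float)
    if len(shares) != len(community):
        raise ValueError("share vector length does not match community size")
    rng = np.random.default_rng(seed)
    sources = rng.choice(len(community), size=depth, p=shares / shares.sum())
    amplicons = [sp.amplicon_seq(amplicon_class) for sp in community]

    if profile.paired:
        r1, r2 = [], []
        for idx, src in enumerate(sources):
            template = amplicons[src]
            rid = f"read{idx:06d}|bin={community[src].bin_id}"
            for mate, mate_reads in ((template, r1), (revcomp(template), r2)):
                n = _read_length(profile, len(mate), rng)
                seq = _apply_errors(mate[:n], profile, rng)
                mate_reads.append(Read(rid, seq, _quality_vector(len(seq), profile, rng)))
        meta = {"platform": profile.platform, "amplicon_class": amplicon_class}
        return (ReadSet(r1, name="R1", metadata=dict(meta)),
                ReadSet(r2, name="R2", metadata=dict(meta)))

    reads = []
    for idx, src in enumerate(sources):
        template = amplicons[src]
        n = _read_length(profile, len(template), rng)
        seq = _apply_errors(template[:n], profile, rng)
        reads.append(Read(f"read{idx:06d}|bin={community[src].bin_id}", seq,
                          _quality_vector(len(seq), profile, rng)))
    return ReadSet(reads, name=profile.platform,
                   metadata={"platform": profile.platform,
                             "amplicon_class": amplicon_class})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_reference_library(community: list[SpeciesRecord], path) -> None:
    """Write barcode sequences as a FASTA reference library."""
    if not community:
        warnings.warn("writing an empty reference library", stacklevel=2)
    records = (
        SeqRecord(Seq(sp.barcode_seq), id=sp.bin_id, description=sp.order_label)
        for sp in community
    )
    try:
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")
    except OSError as exc:
        raise OSError(f"failed to write reference library {path}: {exc}") from exc


def read_reference_library(path) -> list[tuple[str, str]]:
    """Read a FASTA library back as (bin_id, sequence) pairs in file order."""
    try:
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fasta")]
    except OSError as exc:
        raise OSError(f"failed to read reference library {path}: {exc}") from exc


def community_manifest(community: list[SpeciesRecord]) -> pd.DataFrame:
    """Tabulate the community with *observable* primer mismatch counts.

    Forward counts are recomputed from the stored site sequences against the
    default primer sets (best cocktail member); the reverse count is reported
    only for species whose reverse site is known, mirroring the analysis-side
    view of the data.
    """
    rows = []
    for sp in community:
        rows.append({
            "bin_id": sp.bin_id,
            "order": sp.order_label,
            "mass_mg": sp.abdominal_mass_mg,
            "gc": round(sp.gc_fraction, 6),
            "fwd_mismatches_407": best_cocktail_mismatch(
                DEFAULT_PRIMERS_407.forward, sp.fwd_site_seq),
            "fwd_mismatches_463": best_cocktail_mismatch(
                DEFAULT_PRIMERS_463.forward, sp.fwd_site_seq),
            "rev_mismatches": best_cocktail_mismatch(
                DEFAULT_PRIMERS_407.reverse, sp.rev_site_seq)
            if sp.rev_site_known else pd.NA,
            "rev_site_known": sp.rev_site_known,
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(community: list[SpeciesRecord], path) -> None:
    """Write the community manifest as TSV (columns fixed; NA = unknown)."""
    if not community:
        warnings.warn("writing an empty manifest", stacklevel=2)
        pd.DataFrame(columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    try:
        community_manifest(community).to_csv(path, sep="\t", index=False, na_rep="NA")
    except OSError as exc:
        raise OSError(f"failed to write manifest {path}: {exc}") from exc


def read_manifest(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"])
    except OSError as exc:
        raise OSError(f"failed to read manifest {path}: {exc}") from exc
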