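"""Sequencing-depth requirement model for PCR-free barcode recovery.

Chains four ingredients into read-number requirements:

* a retained fraction — the share of random genomic reads that hit the
  barcode region (COI share of the mitogenome x mitochondrial share of
  cellular DNA, 0.05 x 0.01 = 1/2000 by default);
* the coupon-collector expectation for the number of uniform draws needed
  to observe k of N equally abundant species;
* a body-mass scaling of template copy number (copies ~ mass^0.66), whose
  extreme ratio multiplies the requirement in the worst case;
* the rounding conventions used when the numbers are chained (two
  significant figures for read totals and the large mass ratio, nearest
  ten for the trimmed ratio). Raw values are always reported alongside.

A Monte-Carlo sampler (:func:`simulate_coupon`) provides an independent
check of the analytic expectation and supports unequal template weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepthModelParams",
    "round_to_sig",
    "retained_fraction",
    "expected_draws",
    "draws_per_species",
    "reads_for_first_copies",
    "reads_for_coverage",
    "template_ratio",
    "reads_with_biomass",
    "simulate_coupon",
    "depth_model_table",
]


@dataclass(frozen=True)
class DepthModelParams:
    """Parameter set of the depth model (defaults are the worked example)."""

    n_species: int = 374
    coverage: float = 0.95
    coi_fraction: float = 0.05
    mito_fraction: float = 0.01
    mass_exponent: float = 0.66
    mass_ratio: float = 7500.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if min(self.coi_fraction, self.mito_fraction, self.mass_ratio) <= 0:
            raise ValueError("fractions and mass_ratio must be positive")

    @property
    def k(self) -> int:
        """Number of species to recover: ceil(coverage x N)."""
        return math.ceil(self.coverage * self.n_species)


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)


def retained_fraction(coi_fraction: float = 0.05,
                      mito_fraction: float = 0.01) -> float:
    """Fraction of random genomic reads representing the barcode region."""
    if coi_fraction <= 0 or mito_fraction <= 0:
        raise ValueError("fractions must be positive")
    return coi_fraction * mito_fraction


def expected_draws(n_species: int, k: int) -> float:
    """Expected uniform draws (with replacement) to observe k distinct of N
    equally likely species: sum_{i=0}^{k-1} N/(N-i)."""
    if not 1 <= k <= n_species:
        raise ValueError(f"k must be in [1, N]; got k={k}, N={n_species}")
    return float(sum(n_species / (n_species - i) for i in range(k)))


def draws_per_species(n_species: int, coverage: float) -> int:
    """Average draws per species for the target coverage, rounded to the
    nearest integer (floored at 1: the multiplier can never shrink the
    one-copy-each requirement)."""
    k = math.ceil(coverage * n_species)
    return max(1, round(expected_draws(n_species, k) / n_species))


def reads_for_first_copies(
    n_species: int, retained_frac: float,
) -> tuple[float, float]:
    """Reads needed to retain one barcode read per species.

    Returns (raw, rounded-to-2-significant-figures).
    """
    if retained_frac <= 0:
        raise ValueError("retained fraction must be positive")
    raw = n_species / retained_frac
    return raw, round_to_sig(raw, 2)


def reads_for_coverage(
    n_species: int, coverage: float, retained_frac: float,
) -> tuple[float, float]:
    """Reads needed to recover the coverage target under equal abundance:
    one-copy-each total x per-species coupon-collector multiplier.

    Raw value chains unrounded factors; the headline value chains the
    rounded ones (as the numbers are quoted).
    """
    raw_first, rounded_first = reads_for_first_copies(n_species, retained_frac)
    multiplier = draws_per_species(n_species, coverage)
    raw = raw_first * expected_draws(n_species,
                                     math.ceil(coverage * n_species)) / n_species
    return raw, rounded_first * multiplier


def template_ratio(mass_ratio: float, mass_exponent: float,
                   rounding: str = "sig2") -> tuple[float, float]:
    """Template copy ratio across the body-mass range: R^b.

    Returns (raw, rounded); rounding="sig2" for two significant figures,
    "ten" for nearest ten.
    """
    raw = mass_ratio ** mass_exponent
    if rounding == "sig2":
        return raw, round_to_sig(raw, 2)
    if rounding == "ten":
        return raw, round(raw / 10) * 10
    raise ValueError(f"unknown rounding {rounding!r}")


def reads_with_biomass(
    n_species: int, coverage: float, retained_frac: float,
    mass_ratio: float, mass_exponent: float, ratio_rounding: str = "sig2",
) -> tuple[float, float]:
    """Worst-case reads under biomass scaling: the equal-abundance
    requirement multiplied by the (rounded) extreme template ratio."""
    raw_cov, rounded_cov = reads_for_coverage(n_species, coverage, retained_frac)
    raw_ratio, rounded_ratio = template_ratio(mass_ratio, mass_exponent,
                                              rounding=ratio_rounding)
    return raw_cov * raw_ratio, rounded_cov * rounded_ratio


def simulate_coupon(
    n_species: int, weights=None, coverage: float = 0.95,
    n_runs: int = 1000, seed: int | None = None, chunk: int = 1024,
) -> tuple[float, float]:
    """Monte-Carlo draws-to-coverage: per run, sample species with
    replacement under ``weights`` until ceil(coverage x N) distinct have been
    seen; returns (mean, sd) of the draw count over runs."""
    if weights is None:
        w = np.full(n_species, 1.0 / n_species)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != n_species or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be nonnegative, not all zero, length N")
        w = w / w.sum()
    k = math.ceil(coverage * n_species)
    if int((w > 0).sum()) < k:
        raise ValueError("fewer positive-weight species than the coverage target")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_runs, dtype=np.int64)
    for run in range(n_runs):
        seen = np.zeros(n_species, dtype=bool)
        first_positions: list[np.ndarray] = []
        n_seen = 0
        offset = 0
        while n_seen < k:
            block = rng.choice(n_species, size=chunk, p=w)
            values, idx = np.unique(block, return_index=True)
            new = ~seen[values]
            seen[values[new]] = True
            first_positions.append(idx[new] + offset)
            n_seen += int(new.sum())
            offset += chunk
        # absolute draw index of the k-th distinct species ever seen
        positions = np.sort(np.concatenate(first_positions))
        draws[run] = positions[k - 1] + 1
    return float(draws.mean()), float(draws.std(ddof=1))


def depth_model_table(params: DepthModelParams | None = None) -> pd.DataFrame:
    """Raw and rounded values for every quantity of the model."""
    p = params or DepthModelParams()
    frac = retained_fraction(p.coi_fraction, p.mito_fraction)
    first_raw, first_rounded = reads_for_first_copies(p.n_species, frac)
    cov_raw, cov_rounded = reads_for_coverage(p.n_species, p.coverage, frac)
    rounding = "ten" if p.mass_ratio < 1000 else "sig2"
    ratio_raw, ratio_rounded = template_ratio(p.mass_ratio, p.mass_exponent,
                                              rounding=rounding)
    bio_raw, bio_rounded = reads_with_biomass(
        p.n_species, p.coverage, frac, p.mass_ratio, p.mass_exponent,
        ratio_rounding=rounding)
    rows = [
        ("retained_fraction", frac, frac),
        ("reads_per_retained", 1 / frac, round_to_sig(1 / frac, 2)),
        ("expected_draws", expected_draws(p.n_species, p.k),
         expected_draws(p.n_species, p.k)),
        ("draws_per_species", expected_draws(p.n_species, p.k) / p.n_species,
         draws_per_species(p.n_species, p.coverage)),
        ("reads_for_first_copies", first_raw, first_rounded),
        ("reads_for_coverage", cov_raw, cov_rounded),
        ("template_ratio", ratio_raw, ratio_rounded),
        ("reads_with_biomass", bio_raw, bio_rounded),
    ]
    return pd.DataFrame(rows, columns=["quantity", "raw", "rounded"])
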