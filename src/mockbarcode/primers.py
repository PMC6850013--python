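"""IUPAC-aware primer-template mismatch scoring.

Mismatches are counted as substitutions at fixed, pre-mapped primer
coordinates: a degenerate primer symbol whose degeneracy set contains the
template base counts as a match. No primer-template alignment is performed
and no positional weighting is applied. For primer cocktails the reported
mismatch count of a template is that of the best-matching cocktail member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "IUPAC_SETS",
    "PrimerSet",
    "iupac_match",
    "count_mismatches",
    "best_cocktail_mismatch",
    "combined_mismatch",
    "mismatch_abundance_profile",
    "DEFAULT_PRIMERS_407",
    "DEFAULT_PRIMERS_463",
]

#: Degeneracy sets for the 15-letter IUPAC DNA alphabet (A C G T M R W S Y K
#: V H D B N).  ``X`` is excluded; it is not part of the standard alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    symbol: frozenset(bases)
    for symbol, bases in ambiguous_dna_values.items()
    if symbol != "X"
}

_UNDEFINED = None  # sentinel for "reverse site unknown"


@dataclass(frozen=True)
class PrimerSet:
    """A named set of forward/reverse primers (each side may be a cocktail)."""

    name: str
    forward: tuple[str, ...]
    reverse: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("PrimerSet requires at least one forward primer")
        for primer in (*self.forward, *self.reverse):
            bad = set(primer) - set(IUPAC_SETS)
            if bad:
                raise ValueError(
                    f"primer {primer!r} contains non-IUPAC symbols: {sorted(bad)}"
                )


def iupac_match(primer_symbol: str, template_base: str) -> bool:
    """True iff ``template_base`` is in the degeneracy set of ``primer_symbol``."""
    try:
        allowed = IUPAC_SETS[primer_symbol.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC DNA symbol: {primer_symbol!r}") from None
    return template_base.upper() in allowed


def count_mismatches(primer: str, template_site: str) -> int:
    """Number of primer positions incompatible with the template site.

    Both strings must have equal length (the template site is assumed to have
    been extracted at the primer's mapped coordinates).
    """
    if len(primer) != len(template_site):
        raise ValueError(
            f"primer length {len(primer)} != template site length {len(template_site)}"
        )
    return sum(
        not iupac_match(p, b) for p, b in zip(primer.upper(), template_site.upper())
    )


def best_cocktail_mismatch(cocktail, template_site: str) -> int:
    """Minimum mismatch count over the members of a primer cocktail."""
    members = list(cocktail)
    if not members:
        raise ValueError("empty primer cocktail")
    return min(count_mismatches(p, template_site) for p in members)


def combined_mismatch(fwd_count: int, rev_count, rev_known: bool):
    """Summed forward + reverse mismatches, or ``None`` when the reverse
    binding site is unknown for this template."""
    if not rev_known:
        return _UNDEFINED
    return int(fwd_count) + int(rev_count)


def mismatch_abundance_profile(
    table: pd.DataFrame, mismatch_counts: dict[str, int]
) -> pd.DataFrame:
    """Summarize read counts per primer-mismatch class.

    Parameters
    ----------
    table:
        Abundance matrix, rows = bin ids, columns = samples (integer counts).
    mismatch_counts:
        Mapping bin id -> mismatch count. Rows of ``table`` without an entry
        (e.g. unknown reverse sites) are excluded from the summary.

    Returns
    -------
    DataFrame indexed by mismatch class (0..max observed) with columns
    ``n`` (number of bins), ``median_count`` (median total read count) and
    ``median_rel_abundance`` (median share of the grand total).
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty abundance table")
    totals = table.sum(axis=1)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("abundance table has zero total count")
    rows = []
    scored = {b: m for b, m in mismatch_counts.items() if m is not None}
    classes = sorted(set(scored.values()))
    for cls in range(classes[-1] + 1) if classes else []:
        members = [b for b, m in scored.items() if m == cls and b in table.index]
        if not members:
            rows.append({"mismatches": cls, "n": 0,
                         "median_count": np.nan, "median_rel_abundance": np.nan})
            continue
        counts = totals.loc[members].to_numpy(dtype=float)
        rows.append({
            "mismatches": cls,
            "n": len(members),
            "median_count": float(np.median(counts)),
            "median_rel_abundance": float(np.median(counts / grand)),
        })
    return pd.DataFrame(rows).set_index("mismatches")


# Default degenerate primer sets used by the simulator. These are invented
# 30-mers (all primers bind the same 30 bp site per side), not published
# sequences; they exist so the generator and the scorer agree on coordinates.
_FWD_A = "GGTCAACAAATCATAARGAYATTGGRACWT"
_FWD_B = "GGAACTCAAATCATAARGAYATTGGRACWT"
_FWD_463 = "GGTACWACNATYATAAAGAYATYGGAACWT"
_REV_A = "TAAACTTCWGGRTGWCCAAARAATCAAAAT"
_REV_B = "TAAACYTCWGGRTGICCAAARAATCAAAAT".replace("I", "N")

DEFAULT_PRIMERS_407 = PrimerSet("cocktail_407", forward=(_FWD_A, _FWD_B),
                                reverse=(_REV_A, _REV_B))
DEFAULT_PRIMERS_463 = PrimerSet("single_463", forward=(_FWD_463,),
                                reverse=(_REV_A, _REV_B))
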