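"""Codon adaptation index (CAI) against a reference codon-usage table.

Sharp & Li formulation: relative adaptiveness ``w(c) = f(c) / max f`` over
each synonymous codon family, CAI is the geometric mean of ``w`` over the
codons of a coding sequence.  Methionine (ATG), tryptophan (TGG) and stop
codons are excluded from the mean -- their families are singletons with
``w = 1`` and carry no information about codon preference.  Expression
classes follow the thresholds used for insect lipase genes: high above 0.5,
low below 0.03, intermediate between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formats import (
    CodonUsageTable,
    FormatError,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)

__all__ = [
    "AdaptivenessTable",
    "CAIResult",
    "relative_adaptiveness",
    "cai",
    "classify_expression",
    "HIGH_THRESHOLD",
    "LOW_THRESHOLD",
]

HIGH_THRESHOLD = 0.5
LOW_THRESHOLD = 0.03
#: floor applied to w for codons absent from the reference table (avoids log 0)
W_FLOOR = 0.01

#: codons excluded from the geometric mean (singleton families and stops)
EXCLUDED_CODONS = frozenset({"ATG", "TGG"} | set(STOP_CODONS))


@dataclass(frozen=True)
class AdaptivenessTable:
    """Sense codon -> relative adaptiveness w in (0, 1]."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.w)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)[:5]}")
        if any(not 0 < v <= 1 for v in self.w.values()):
            raise ValueError("w values must lie in (0, 1]")

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]


@dataclass(frozen=True)
class CAIResult:
    gene_id: str
    cai: float
    n_codons: int  # codons contributing to the geometric mean
    expression_class: str


def relative_adaptiveness(usage: CodonUsageTable, w_floor: float = W_FLOOR) -> AdaptivenessTable:
    """Per-family normalization of a usage table to w values.

    Within each synonymous family the most-used codon gets w = 1; zero
    frequencies are floored at ``w_floor`` so downstream log computations
    stay finite.
    """
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fmax = max(usage[c] for c in codons)
        if fmax <= 0:  # unreachable for a validated table; kept as a guard
            raise ValueError(f"synonymous family for {aa} has all-zero frequencies")
        for c in codons:
            w[c] = max(usage[c] / fmax, w_floor)
    return AdaptivenessTable(w)


def _codons(cds: str, gene_id: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FormatError(f"{gene_id or 'CDS'}: length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    internal = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if internal:
        raise FormatError(f"{gene_id or 'CDS'}: internal stop codon at codon {internal[0] + 1}")
    bad = [c for c in codons if set(c) - set("ACGT")]
    if bad:
        raise FormatError(f"{gene_id or 'CDS'}: non-ACGT codon {bad[0]!r}")
    return codons


def cai(cds: str, w: AdaptivenessTable, gene_id: str = "") -> CAIResult:
    """CAI of a coding sequence: geometric mean of w over informative codons.

    A terminal stop codon is trimmed; an internal stop or a length not
    divisible by 3 is an error.  The value is independent of sequence length
    (CAI of a gene concatenated with itself equals CAI of the gene).
    """
    codons = [c for c in _codons(cds, gene_id) if c not in EXCLUDED_CODONS]
    if not codons:
        raise FormatError(f"{gene_id or 'CDS'}: no informative codons")
    log_sum = sum(math.log(w[c]) for c in codons)
    value = math.exp(log_sum / len(codons))
    return CAIResult(gene_id, value, len(codons), classify_expression(value))


def classify_expression(value: float) -> str:
    """Expression class from a CAI value: high > 0.5, low < 0.03."""
    if not 0 < value <= 1:
        raise ValueError(f"CAI value {value} outside (0, 1]")
    if value > HIGH_THRESHOLD:
        return "high"
    if value < LOW_THRESHOLD:
        return "low"
    return "intermediate"
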