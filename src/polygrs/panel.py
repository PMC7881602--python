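"""SNP panel container: per-SNP risk allele, per-allele odds ratio and
reference-population risk-allele frequency.

The panel is the sole source of the odds ratios and frequencies used for
scoring; frequencies are never re-estimated from the cohort being scored,
because the score is standardized to an external reference population
(e.g. gnomAD non-Finnish Europeans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .errors import InvalidParameterError, SchemaError

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNPPanelEntry:
    """One biallelic SNP with its per-allele odds ratio OR and risk-allele
    frequency f in the standardization population."""

    snp_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    risk_allele_freq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.odds_ratio) and self.odds_ratio > 0):
            raise InvalidParameterError(
                f"{self.snp_id}: odds_ratio must be finite and > 0, "
                f"got {self.odds_ratio}"
            )
        if not (0 < self.risk_allele_freq < 1):
            raise InvalidParameterError(
                f"{self.snp_id}: risk_allele_freq must lie in (0, 1), "
                f"got {self.risk_allele_freq}"
            )
        ra, oa = self.risk_allele.upper(), self.other_allele.upper()
        if ra == oa:
            raise InvalidParameterError(
                f"{self.snp_id}: risk and other allele are identical ({ra})"
            )
        for name, allele in (("risk_allele", ra), ("other_allele", oa)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise InvalidParameterError(
                    f"{self.snp_id}: {name} {allele!r} is not an A/C/G/T string"
                )
        if self.pos < 1:
            raise InvalidParameterError(
                f"{self.snp_id}: pos must be 1-based positive, got {self.pos}"
            )


@dataclass
class SNPPanel:
    """Ordered collection of :class:`SNPPanelEntry` with unique identifiers."""

    entries: list[SNPPanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise SchemaError("panel must contain at least one SNP")
        seen: set[str] = set()
        for e in self.entries:
            if e.snp_id in seen:
                raise SchemaError(f"duplicate snp_id in panel: {e.snp_id}")
            seen.add(e.snp_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SNPPanelEntry]:
        return iter(self.entries)

    def __getitem__(self, snp_id: str) -> SNPPanelEntry:
        for e in self.entries:
            if e.snp_id == snp_id:
                return e
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def subset(self, snp_ids: Sequence[str]) -> "SNPPanel":
        """Panel restricted to ``snp_ids``, preserving the requested order."""
        by_id = {e.snp_id: e for e in self.entries}
        missing = [s for s in snp_ids if s not in by_id]
        if missing:
            raise SchemaError(f"snp_ids not in panel: {missing}")
        return SNPPanel([by_id[s] for s in snp_ids])
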