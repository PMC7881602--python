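"""Risk-allele dosage matrix: subjects x SNPs, entries in {0, 1, 2} or missing.

Dosages count copies of the *risk* allele as defined by the panel, after any
allele harmonization done by the readers. Missing genotypes are encoded as
``-1`` internally (``MISSING``) and as NA on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDosageError, SchemaError

#: Sentinel for a missing dosage in the integer matrix.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Dosage matrix with aligned subject and SNP identifiers.

    Parameters
    ----------
    subject_ids
        Row labels, one per subject, unique.
    snp_ids
        Column labels, one per SNP; must be a subset of the scoring panel.
    dosages
        Integer array of shape (n_subjects, n_snps) with entries in
        {0, 1, 2, MISSING}.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.subject_ids) or m != len(self.snp_ids):
            raise SchemaError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != n:
            raise SchemaError("duplicate subject_ids")
        if len(set(self.snp_ids)) != m:
            raise SchemaError("duplicate snp_ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InvalidDosageError(
                f"dosage {self.dosages[i, j]} at subject "
                f"{self.subject_ids[i]!r}, SNP {self.snp_ids[j]!r} "
                "is not in {0, 1, 2, missing}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame (subjects x SNPs) with NA for missing dosages."""
        df = pd.DataFrame(
            self.dosages.astype(float),
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.snp_ids,
        )
        return df.mask(df < 0)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        arr = df.to_numpy(dtype=float)
        out = np.where(np.isnan(arr), MISSING, arr).astype(np.int8)
        return cls(list(map(str, df.index)), list(map(str, df.columns)), out)

    def reorder_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            list(self.subject_ids), list(snp_ids), self.dosages[:, idx]
        )
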