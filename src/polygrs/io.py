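"""Readers and writers for the pipeline's on-disk formats.

Formats
-------
panel TSV
    Header ``snp_id  chrom  pos  risk_allele  other_allele  odds_ratio
    risk_allele_freq``; one SNP per row; ``pos`` is 1-based.
genotypes
    Either VCF 4.x (GT field; read with cyvcf2, sites matched to the panel
    by chrom+pos+allele set) or a wide TSV of subjects x snp_ids with cells
    in {0, 1, 2, NA} already oriented to the risk allele.
phenotype CSV
    Header ``subject_id, age_at_colonoscopy, sex, bmi, family_history,
    outcome, polyp_size_class, polyp_count_class, polyp_location,
    advanced_adenoma``; outcome/family_history as positive/negative;
    polyp_location as a semicolon-joined subset of CA;TD;RS.
scores TSV
    ``subject_id  grs  category  n_snps_used``.

Allele harmonization: a VCF site whose {REF, ALT} equals the panel's
{risk, other} allele pair is used as-is (dosage flipped when the risk
allele is REF). If the pair only matches after reverse-complementing both
alleles, the site is strand-flipped — but A/T and C/G pairs are their own
complement, so ambiguous sites can never be silently flipped. Anything else
is excluded with a warning.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import PolygrsError, SchemaError
from .genotypes import MISSING, GenotypeMatrix
from .grs import GRSResult
from .panel import SNPPanel, SNPPanelEntry
from .phenotypes import PhenotypeRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

PANEL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "risk_allele",
    "other_allele",
    "odds_ratio",
    "risk_allele_freq",
]

PHENOTYPE_COLUMNS = [
    "subject_id",
    "age_at_colonoscopy",
    "sex",
    "bmi",
    "family_history",
    "outcome",
    "polyp_size_class",
    "polyp_count_class",
    "polyp_location",
    "advanced_adenoma",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------- panel ----


def read_panel(path: PathLike) -> SNPPanel:
    """Read and validate a SNP panel TSV."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty panel file")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing panel columns {sorted(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: panel has a header but no SNPs")
    entries = []
    for row in df.itertuples(index=True):
        line_no = row.Index + 2  # header is line 1
        try:
            entries.append(
                SNPPanelEntry(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    risk_allele=str(row.risk_allele).upper(),
                    other_allele=str(row.other_allele).upper(),
                    odds_ratio=float(row.odds_ratio),
                    risk_allele_freq=float(row.risk_allele_freq),
                )
            )
        except (ValueError, PolygrsError) as exc:
            raise SchemaError(f"{path}:{line_no}: {exc}") from exc
    return SNPPanel(entries)


def write_panel(panel: SNPPanel, path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": e.snp_id,
                "chrom": e.chrom,
                "pos": e.pos,
                "risk_allele": e.risk_allele,
                "other_allele": e.other_allele,
                "odds_ratio": e.odds_ratio,
                "risk_allele_freq": e.risk_allele_freq,
            }
            for e in panel
        ],
        columns=PANEL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ genotypes ----


def read_genotypes_vcf(
    path: PathLike, panel: SNPPanel, *, match_by_id: bool = False
) -> GenotypeMatrix:
    """Extract risk-allele dosages from a VCF.

    Sites are matched to the panel by chrom+pos and the biallelic allele
    set; pass ``match_by_id=True`` to fall back to matching on the VCF ID
    column when coordinates do not match. Panel SNPs with no usable site
    yield MISSING for every subject.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    n = len(subjects)
    if n == 0:
        raise SchemaError(f"{path}: VCF has no samples")
    by_coord = {(e.chrom, e.pos): e for e in panel}
    by_id = {e.snp_id: e for e in panel}
    dosages = {e.snp_id: np.full(n, MISSING, dtype=np.int8) for e in panel}
    seen: set[str] = set()

    for var in vcf:
        entry = by_coord.get((var.CHROM, var.POS))
        if entry is None and match_by_id and var.ID in by_id:
            entry = by_id[var.ID]
        if entry is None:
            continue
        if len(var.ALT) != 1:
            logger.warning(
                "%s:%d: skipping non-biallelic site for %s", var.CHROM, var.POS,
                entry.snp_id,
            )
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        site = {ref, alt}
        want = {entry.risk_allele, entry.other_allele}
        if site == want:
            risk_is_alt = alt == entry.risk_allele
        elif {_revcomp(ref), _revcomp(alt)} == want:
            # non-ambiguous pair observed on the opposite strand
            risk_is_alt = _revcomp(alt) == entry.risk_allele
            logger.warning(
                "%s: strand-flipped site %s:%d (%s/%s) to match panel alleles",
                entry.snp_id, var.CHROM, var.POS, ref, alt,
            )
        else:
            logger.warning(
                "%s: alleles %s/%s at %s:%d do not match panel %s/%s in either "
                "orientation; site excluded",
                entry.snp_id, ref, alt, var.CHROM, var.POS,
                entry.risk_allele, entry.other_allele,
            )
            continue
        alt_counts = np.full(n, MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                alt_counts[i] = sum(1 for a in alleles if a == 1)
        dos = np.where(
            alt_counts == MISSING,
            MISSING,
            alt_counts if risk_is_alt else 2 - alt_counts,
        ).astype(np.int8)
        dosages[entry.snp_id] = dos
        seen.add(entry.snp_id)

    for e in panel:
        if e.snp_id not in seen:
            logger.warning(
                "panel SNP %s not found in %s; dosages set to missing",
                e.snp_id, path,
            )
    mat = np.column_stack([dosages[s] for s in panel.snp_ids])
    return GenotypeMatrix(subjects, panel.snp_ids, mat)


def read_genotypes_tsv(path: PathLike, panel: SNPPanel) -> GenotypeMatrix:
    """Read a wide dosage TSV (subjects x snp_ids, cells 0/1/2/NA)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    unknown = set(df.columns) - set(panel.snp_ids)
    if unknown:
        raise SchemaError(f"{path}: columns not in panel: {sorted(unknown)}")
    n, _ = df.shape
    arr = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if pd.isna(cell) or cell in ("NA", ""):
                continue
            if cell not in ("0", "1", "2"):
                raise SchemaError(
                    f"{path}: invalid dosage {cell!r} at subject "
                    f"{df.index[i]!r}, SNP {col!r}"
                )
            arr[i, j] = int(cell)
    return GenotypeMatrix(list(map(str, df.index)), list(df.columns), arr)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: PathLike) -> None:
    df = genotypes.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_genotypes_vcf(
    genotypes: GenotypeMatrix, panel: SNPPanel, path: PathLike
) -> None:
    """Write dosages as a minimal VCF 4.2 with GT-only genotypes.

    The risk allele is emitted as ALT so that the risk-allele dosage equals
    the ALT-allele count.
    """
    sub = panel.subset(genotypes.snp_ids)
    order = sorted(
        range(len(sub.entries)),
        key=lambda i: (_chrom_key(sub.entries[i].chrom), sub.entries[i].pos),
    )
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(sub.entries[i].chrom for i in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for i in order:
            e = sub.entries[i]
            col = genotypes.dosages[:, genotypes.snp_ids.index(e.snp_id)]
            gts = "\t".join(gt_of[int(d)] for d in col)
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.snp_id}\t{e.other_allele}\t"
                f"{e.risk_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


# ----------------------------------------------------------- phenotypes ----


def _parse_binary(value: str, field: str, true_label: str, false_label: str) -> bool:
    v = str(value).strip().lower()
    if v == true_label:
        return True
    if v == false_label:
        return False
    raise SchemaError(f"{field}: expected {true_label}/{false_label}, got {value!r}")


def read_phenotypes(
    path: PathLike, *, apply_inclusion: bool = True
) -> list[PhenotypeRecord]:
    """Read a phenotype CSV; subjects failing the age inclusion rule
    (age at first screening colonoscopy <= 45) are excluded with a logged
    count when ``apply_inclusion`` is set."""
    records: list[PhenotypeRecord] = []
    n_excluded = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "age_at_colonoscopy", "sex", "family_history", "outcome"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing phenotype columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            if not str(row.get("outcome", "")).strip():
                raise SchemaError(f"{path}:{line_no}: outcome is required")
            try:
                loc = row.get("polyp_location") or ""
                adv = row.get("advanced_adenoma") or ""
                bmi = row.get("bmi") or ""
                rec = PhenotypeRecord(
                    subject_id=str(row["subject_id"]),
                    age_at_colonoscopy=float(row["age_at_colonoscopy"]),
                    sex=str(row["sex"]).strip().lower(),
                    bmi=float(bmi) if bmi else None,
                    family_history=_parse_binary(
                        row["family_history"], "family_history", "positive", "negative"
                    ),
                    outcome=_parse_binary(row["outcome"], "outcome", "positive", "negative"),
                    polyp_size_class=(row.get("polyp_size_class") or "none").strip(),
                    polyp_count_class=(row.get("polyp_count_class") or "none").strip(),
                    polyp_location=frozenset(
                        p.strip() for p in loc.split(";") if p.strip()
                    ),
                    advanced_adenoma=(
                        _parse_binary(adv, "advanced_adenoma", "true", "false")
                        if adv
                        else None
                    ),
                )
            except (ValueError, SchemaError) as exc:
                raise SchemaError(f"{path}:{line_no}: {exc}") from exc
            if apply_inclusion and not rec.meets_inclusion:
                n_excluded += 1
                continue
            records.append(rec)
    if n_excluded:
        logger.info(
            "excluded %d subject(s) failing the age > 45 inclusion rule", n_excluded
        )
    return records


def write_phenotypes(records: list[PhenotypeRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=PHENOTYPE_COLUMNS)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "subject_id": r.subject_id,
                    "age_at_colonoscopy": f"{r.age_at_colonoscopy:.2f}",
                    "sex": r.sex,
                    "bmi": "" if r.bmi is None else f"{r.bmi:.2f}",
                    "family_history": "positive" if r.family_history else "negative",
                    "outcome": "positive" if r.outcome else "negative",
                    "polyp_size_class": r.polyp_size_class,
                    "polyp_count_class": r.polyp_count_class,
                    "polyp_location": ";".join(sorted(r.polyp_location)),
                    "advanced_adenoma": (
                        "" if r.advanced_adenoma is None
                        else ("true" if r.advanced_adenoma else "false")
                    ),
                }
            )


# --------------------------------------------------------------- scores ----


def write_scores(results: list[GRSResult], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "grs": f"{r.grs:.10g}",
                "category": r.category,
                "n_snps_used": r.n_snps_used,
            }
            for r in results
        ],
        columns=["subject_id", "grs", "category", "n_snps_used"],
    ).to_csv(path, sep="\t", index=False)


def read_scores(path: PathLike) -> list[GRSResult]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return [
        GRSResult(str(r.subject_id), float(r.grs), str(r.category), int(r.n_snps_used))
        for r in df.itertuples()
    ]
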