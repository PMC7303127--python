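"""Sample-sheet and VCF input, genotype classification, and site-level hard filters.

The analysis works on a four-letter genotype-class alphabet per locus and
sample:

* ``HOM``    -- two identical alleles at a SNP locus (refined to ``HOM_REF`` /
  ``HOM_ALT`` for reporting);
* ``HET``    -- two different alleles (including two distinct ALT alleles at a
  multi-allelic SNP);
* ``INDEL``  -- any called genotype at a locus whose REF/ALT alleles differ in
  length (indel state is treated as a single class);
* ``ABSENT`` -- no genotype call for the sample at the locus.

With four classes the two-group pattern enumeration yields exactly twelve
ordered unequal pairs, which is the pattern space the downstream scan works in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeClass",
    "SexRecord",
    "LocusRecord",
    "GenotypeMatrix",
    "read_sample_sheet",
    "classify_genotype",
    "read_vcf_genotypes",
    "apply_site_filters",
    "write_vcf",
]


class GenotypeClass(str, Enum):
    """Collapsed genotype-class alphabet used by the marker scan."""

    HOM = "HOM"
    HET = "HET"
    INDEL = "INDEL"
    ABSENT = "ABSENT"


#: integer codes used inside per-locus vectors (np.int8)
CLASS_CODES = {
    GenotypeClass.HOM: 0,
    GenotypeClass.HET: 1,
    GenotypeClass.INDEL: 2,
    GenotypeClass.ABSENT: 3,
}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}

#: refined (SNP) alphabet codes; INDEL kept so indel loci are scannable
REFINED_CODES = {"HOM_REF": 0, "HET": 1, "HOM_ALT": 2, "ABSENT": 3, "INDEL": 4}
CODE_TO_REFINED = {v: k for k, v in REFINED_CODES.items()}

_SEX_TOKENS = {"f": "F", "female": "F", "m": "M", "male": "M"}
_UNKNOWN_TOKENS = {"", "na", "nan", "."}


@dataclass(frozen=True)
class SexRecord:
    """Sex of one individual at two consecutive sexual maturation seasons."""

    sample_id: str
    sex_t1: str  # "F" or "M"
    sex_t2: str | None  # "F", "M", or None when lost before second maturation

    @property
    def phenotype(self) -> str | None:
        """Two-letter phenotype code (FF/MM/FM/MF), or None if sex_t2 unknown.

        The first letter is the sex at first maturation, the second at second
        maturation, so FM means female-then-male.
        """
        if self.sex_t2 is None:
            return None
        return self.sex_t1 + self.sex_t2


@dataclass
class LocusRecord:
    """One variant site with per-sample genotype classes and read depths."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    is_indel: bool
    site_info: dict[str, float] = field(default_factory=dict)  # QD/FS/MQ, optional
    per_sample_class: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))
    per_sample_refined: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))
    per_sample_depth: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int32))
    per_sample_gt: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class GenotypeMatrix:
    """Loci x samples container; every per-locus vector follows ``samples`` order."""

    samples: list[str]
    loci: list[LocusRecord]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def class_matrix(self) -> np.ndarray:
        """(n_loci, n_samples) int8 matrix of collapsed class codes."""
        if not self.loci:
            return np.zeros((0, self.n_samples), np.int8)
        return np.vstack([l.per_sample_class for l in self.loci])


def read_sample_sheet(path: str | Path, delimiter: str = "\t") -> list[SexRecord]:
    """Read the per-individual two-season sex sheet.

    The sheet is a delimited text file (tab by default) with a header row
    containing at least ``sample_id``, ``sex_t1`` and ``sex_t2`` columns. Sex
    tokens are case-insensitive F/M/female/male; ``sex_t2`` may be empty or
    "NA" for individuals lost before the second maturation.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty sample sheet")
        header = [h.strip() for h in header_line.rstrip("\n").split(delimiter)]
        required = {"sample_id", "sex_t1", "sex_t2"}
        missing = required - set(header)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        idx = {name: header.index(name) for name in required}

        records: list[SexRecord] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            sample_id = fields[idx["sample_id"]].strip()
            if not sample_id:
                raise ValueError(f"{path}:{lineno}: empty sample_id")
            if sample_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            sex_t1 = _parse_sex(fields[idx["sex_t1"]], path, lineno, allow_unknown=False)
            sex_t2 = _parse_sex(fields[idx["sex_t2"]], path, lineno, allow_unknown=True)
            records.append(SexRecord(sample_id, sex_t1, sex_t2))
    return records


def _parse_sex(token: str, path: Path, lineno: int, allow_unknown: bool) -> str | None:
    t = token.strip().lower()
    if t in _SEX_TOKENS:
        return _SEX_TOKENS[t]
    if allow_unknown and t in _UNKNOWN_TOKENS:
        return None
    raise ValueError(f"{path}:{lineno}: unrecognized sex token {token!r}")


def classify_genotype(
    gt_call: str | None, locus_is_indel: bool
) -> tuple[GenotypeClass, str | None]:
    """Map a diploid VCF GT string onto the class alphabet.

    Returns ``(collapsed_class, refined_label)``; the refined label is one of
    HOM_REF/HET/HOM_ALT/ABSENT at SNP loci and INDEL/ABSENT at indel loci.

    Missing calls ("./.", ".|.", ".", None) are ABSENT; at indel loci every
    called genotype is INDEL; otherwise two identical alleles are HOM
    (HOM_REF when both are 0) and two different alleles are HET (including
    two distinct ALT alleles such as 1/2). Ploidy other than 2 is rejected.
    """
    if gt_call is None:
        return GenotypeClass.ABSENT, "ABSENT"
    gt = gt_call.strip()
    if gt in ("", "."):
        return GenotypeClass.ABSENT, "ABSENT"
    alleles = gt.replace("|", "/").split("/")
    if any(a == "." for a in alleles):
        return GenotypeClass.ABSENT, "ABSENT"
    if len(alleles) != 2:
        raise ValueError(f"unsupported ploidy in genotype call {gt_call!r}")
    if locus_is_indel:
        return GenotypeClass.INDEL, "INDEL"
    a, b = alleles
    if a == b:
        return GenotypeClass.HOM, ("HOM_REF" if a == "0" else "HOM_ALT")
    return GenotypeClass.HET, "HET"


def _locus_is_indel(ref: str, alts: Sequence[str]) -> bool:
    return any(len(alt) != len(ref) for alt in alts if alt not in (".", "*", ""))


def read_vcf_genotypes(path: str | Path, samples: Sequence[SexRecord]) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix aligned to the sheet order.

    Every sheet sample must be present in the VCF header (hard error listing
    the missing ids); VCF samples absent from the sheet are dropped with a
    warning. FORMAT/DP missing means depth 0.
    """
    from cyvcf2 import VCF  # deferred: keeps import cost out of simulation-only use

    path = str(path)
    sheet_ids = [r.sample_id for r in samples]
    vcf = VCF(path)
    vcf_samples = list(vcf.samples)
    missing = [s for s in sheet_ids if s not in vcf_samples]
    if missing:
        raise ValueError(f"{path}: sheet samples missing from VCF: {missing}")
    extra = [s for s in vcf_samples if s not in set(sheet_ids)]
    if extra:
        logger.warning("%s: ignoring %d VCF sample(s) not in sheet: %s", path, len(extra), extra)
    col = [vcf_samples.index(s) for s in sheet_ids]

    loci: list[LocusRecord] = []
    for var in vcf:
        alts = tuple(var.ALT) if var.ALT else ()
        is_indel = _locus_is_indel(var.REF, alts)
        info: dict[str, float] = {}
        for key in ("QD", "FS", "MQ"):
            val = var.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        dp = var.format("DP")
        genos = var.genotypes  # [[a0, a1, phased], ...]
        n = len(sheet_ids)
        classes = np.empty(n, np.int8)
        refined = np.empty(n, np.int8)
        depths = np.zeros(n, np.int32)
        gts: list[str] = []
        for out_i, vcf_i in enumerate(col):
            entry = genos[vcf_i]
            alleles = entry[:-1]
            gt = "/".join("." if a < 0 else str(a) for a in alleles)
            if len(alleles) != 2 and not all(a < 0 for a in alleles):
                raise ValueError(
                    f"{path}: {var.CHROM}:{var.POS} sample {sheet_ids[out_i]}: "
                    f"unsupported ploidy {len(alleles)}"
                )
            if all(a < 0 for a in alleles):
                gt = "./."
            cls, ref_label = classify_genotype(gt, is_indel)
            classes[out_i] = CLASS_CODES[cls]
            refined[out_i] = REFINED_CODES[ref_label]
            if dp is not None:
                d = int(dp[vcf_i][0]) if dp.ndim == 2 else int(dp[vcf_i])
                depths[out_i] = max(d, 0)
            gts.append(gt)
        loci.append(
            LocusRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alts=alts,
                is_indel=is_indel,
                site_info=info,
                per_sample_class=classes,
                per_sample_refined=refined,
                per_sample_depth=depths,
                per_sample_gt=gts,
            )
        )
    return GenotypeMatrix(samples=list(sheet_ids), loci=loci)


def apply_site_filters(
    matrix: GenotypeMatrix,
    qd_min: float = 2.0,
    fs_max: float = 60.0,
    mq_min: float = 40.0,
) -> GenotypeMatrix:
    """Hard-filter sites on the standard VCF quality annotations.

    Removes loci with QD < qd_min OR FS > fs_max OR MQ < mq_min (strict
    inequalities). A locus missing an INFO key passes that key's test: no
    evidence is not treated as failure.
    """
    if min(qd_min, fs_max, mq_min) < 0:
        raise ValueError("filter thresholds must be non-negative")

    def fails(locus: LocusRecord) -> bool:
        info = locus.site_info
        if "QD" in info and info["QD"] < qd_min:
            return True
        if "FS" in info and info["FS"] > fs_max:
            return True
        if "MQ" in info and info["MQ"] < mq_min:
            return True
        return False

    kept = [l for l in matrix.loci if not fails(l)]
    removed = matrix.n_loci - len(kept)
    logger.info("site filters removed %d of %d loci", removed, matrix.n_loci)
    return GenotypeMatrix(samples=list(matrix.samples), loci=kept)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as plain-text VCF 4.2 with GT:DP.

    Output is deterministic (fixed float formatting, fixed header order) so
    that identically seeded simulations produce byte-identical files, and it
    round-trips through :func:`read_vcf_genotypes` to the same classes and
    depths.
    """
    path = Path(path)
    contigs: list[str] = []
    for locus in matrix.loci:
        if locus.chrom not in contigs:
            contigs.append(locus.chrom)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexlink\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for locus in matrix.loci:
            info_parts = [
                f"{key}={locus.site_info[key]:.2f}"
                for key in ("QD", "FS", "MQ")
                if key in locus.site_info
            ]
            info = ";".join(info_parts) if info_parts else "."
            alt = ",".join(locus.alts) if locus.alts else "."
            cells = [
                f"{gt}:{int(dp)}"
                for gt, dp in zip(locus.per_sample_gt, locus.per_sample_depth)
            ]
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{alt}\t.\tPASS\t{info}\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
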