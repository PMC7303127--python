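"""Synthetic cohorts under competing sex-determination models.

The generator emulates a RAD-seq study of a sequentially hermaphroditic
bivalve: a small cohort phenotyped at two maturation seasons (default 8 MF,
6 FM, 6 MM, 6 FF, 26 individuals), genotyped at thousands of Hardy-Weinberg
neutral loci plus planted sex-linked loci, with genotyping error, missingness,
restriction-site allele dropout and negative-binomial read depth (mean 8.39x
by default, matching typical RAD coverage of such studies).

Models:

* ``XY`` / ``ZW``       -- chromosomal sex determination; sex fixed by the
  genotype at the planted locus, no sex change.
* ``SINGLE_LOCUS_2G``   -- heterozygous individuals are always male; homozygous
  individuals draw their sex independently each season (bidirectional change
  arises among them).
* ``SINGLE_LOCUS_3G``   -- MM males, FF females, and protandric FM individuals:
  male at first maturation, female at the second with probability ``f``.
* ``PGSD``              -- polygenic threshold trait: liability is the sum of
  equal additive allelic effects over ``pgsd_n_loci`` loci (heritability
  ``pgsd_h2``) plus an independent per-season environmental deviate; female
  iff liability > 0, so sex change happens when the environmental term flips
  the sign between seasons.

When per-class sample counts are requested, individuals are drawn i.i.d. from
the model and kept while their phenotype class still has open quota -- the
same conditional sampling a field study performs when it selects animals by
observed phenotype.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    CLASS_CODES,
    REFINED_CODES,
    GenotypeMatrix,
    LocusRecord,
    SexRecord,
    classify_genotype,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "Individual",
    "TruthTable",
    "phenotype_cohort",
    "assign_sexes",
    "simulate_locus_genotypes",
    "simulate_cohort",
    "emit_cohort",
]

MODELS = ("XY", "ZW", "SINGLE_LOCUS_2G", "SINGLE_LOCUS_3G", "PGSD")

#: phenotype classes each model can produce (quota requests are validated)
_REACHABLE = {
    "XY": {"FF", "MM"},
    "ZW": {"FF", "MM"},
    "SINGLE_LOCUS_2G": {"FF", "MM", "FM", "MF"},
    "SINGLE_LOCUS_3G": {"FF", "MM", "MF"},
    "PGSD": {"FF", "MM", "FM", "MF"},
}

LOCI_PER_CONTIG = 1000
POS_SPACING = 100


@dataclass
class SimConfig:
    """Simulation parameters; a fixed seed gives byte-identical outputs."""

    model: str = "XY"
    n_per_class: dict[str, int] | None = None  # default 8 MF, 6 FM, 6 MM, 6 FF
    n_total: int | None = None  # alternative: model-driven phenotype counts
    L_neutral: int = 5000
    n_planted: int = 1
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    error_rate: float = 0.05  # prob. a called genotype class is corrupted
    missing_rate: float = 0.05  # prob. a call is ABSENT
    dropout_rate: float = 0.0  # per-haplotype restriction-site loss
    indel_fraction: float = 0.1  # fraction of neutral loci that are indels
    depth_mean: float = 8.39
    depth_dispersion: float = 5.0
    hom_female_prob: float = 0.5  # SINGLE_LOCUS_2G: per-season P(female) for homozygotes
    f: float = 0.5  # SINGLE_LOCUS_3G: P(FM genotype matures female at season 2)
    pgsd_n_loci: int = 50
    pgsd_h2: float = 0.5
    pgsd_allele_freq: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.n_per_class is None and self.n_total is None:
            self.n_per_class = {"MF": 8, "FM": 6, "MM": 6, "FF": 6}
        for name in ("error_rate", "missing_rate", "dropout_rate", "indel_fraction",
                     "hom_female_prob", "f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 < self.pgsd_h2 < 1.0:
            raise ValueError("pgsd_h2 must be in (0, 1)")
        if self.n_per_class is not None:
            if any(v < 0 for v in self.n_per_class.values()):
                raise ValueError("n_per_class counts must be >= 0")
            if sum(self.n_per_class.values()) == 0:
                raise ValueError("cohort size is zero")
            unreachable = {
                c for c, v in self.n_per_class.items()
                if v > 0 and c not in _REACHABLE[self.model]
            }
            if unreachable:
                raise ValueError(
                    f"model {self.model} cannot produce phenotype class(es) "
                    f"{sorted(unreachable)}"
                )


@dataclass
class Individual:
    sample_id: str
    sex_t1: str
    sex_t2: str
    sex_genotype: str | None  # e.g. XY/XX, FM/FF/MM; None under PGSD
    liability_genotypes: np.ndarray | None = None  # alt-allele counts per liability locus
    liability_genetic: float | None = None


@dataclass
class TruthTable:
    """Planted-locus coordinates and per-sample latent state for scoring."""

    loci: pd.DataFrame  # chrom, pos, role, expected_family
    samples: pd.DataFrame  # sample_id, sex_genotype, liability, sex_t1, sex_t2


def phenotype_cohort(counts: dict[str, int], prefix: str = "s") -> list[SexRecord]:
    """Deterministic sheet with the given per-class counts (fixture helper)."""
    records: list[SexRecord] = []
    i = 1
    width = max(2, len(str(sum(counts.values()))))
    for code in ("MF", "FM", "MM", "FF"):
        for _ in range(counts.get(code, 0)):
            records.append(SexRecord(f"{prefix}{i:0{width}d}", code[0], code[1]))
            i += 1
    return records


def _draw_individual(config: SimConfig, rng: np.random.Generator, pgsd_a: float) -> Individual:
    model = config.model
    if model in ("XY", "ZW"):
        carrier = bool(rng.random() < 0.5)  # heterogametic individual
        if model == "XY":
            sex = "M" if carrier else "F"
            genotype = "XY" if carrier else "XX"
        else:
            sex = "F" if carrier else "M"
            genotype = "ZW" if carrier else "ZZ"
        return Individual("", sex, sex, genotype)
    if model == "SINGLE_LOCUS_2G":
        het = bool(rng.random() < 0.5)
        if het:
            return Individual("", "M", "M", "FM")
        s1 = "F" if rng.random() < config.hom_female_prob else "M"
        s2 = "F" if rng.random() < config.hom_female_prob else "M"
        return Individual("", s1, s2, "FF")
    if model == "SINGLE_LOCUS_3G":
        u = rng.random()
        if u < 0.25:
            return Individual("", "M", "M", "MM")
        if u < 0.5:
            return Individual("", "F", "F", "FF")
        s2 = "F" if rng.random() < config.f else "M"
        return Individual("", "M", s2, "FM")
    # PGSD
    g = rng.binomial(2, config.pgsd_allele_freq, size=config.pgsd_n_loci)
    genetic = pgsd_a * float((g - 2 * config.pgsd_allele_freq).sum())
    env_sd = np.sqrt(1.0 - config.pgsd_h2)
    e1, e2 = rng.normal(0.0, env_sd, size=2)
    s1 = "F" if genetic + e1 > 0 else "M"
    s2 = "F" if genetic + e2 > 0 else "M"
    return Individual("", s1, s2, None, liability_genotypes=g, liability_genetic=genetic)


def assign_sexes(config: SimConfig, rng: np.random.Generator) -> list[Individual]:
    """Draw individuals from the model, honouring per-class quotas if set.

    With ``n_per_class``, i.i.d. model draws are kept while their phenotype
    class has open quota (conditional-on-phenotype sampling); with
    ``n_total``, the phenotype composition is whatever the model produces.
    """
    p = config.pgsd_allele_freq
    var_per_locus = 2 * p * (1 - p)
    pgsd_a = float(np.sqrt(config.pgsd_h2 / (config.pgsd_n_loci * var_per_locus)))
    individuals: list[Individual] = []
    if config.n_total is not None:
        for _ in range(config.n_total):
            individuals.append(_draw_individual(config, rng, pgsd_a))
    else:
        quota = {c: v for c, v in config.n_per_class.items() if v > 0}
        remaining = dict(quota)
        max_draws = 500_000
        draws = 0
        while any(v > 0 for v in remaining.values()):
            if draws >= max_draws:
                raise ValueError(
                    f"could not fill phenotype quotas {remaining} under model "
                    f"{config.model} within {max_draws} draws"
                )
            ind = _draw_individual(config, rng, pgsd_a)
            draws += 1
            code = ind.sex_t1 + ind.sex_t2
            if remaining.get(code, 0) > 0:
                remaining[code] -= 1
                individuals.append(ind)
    width = max(2, len(str(len(individuals))))
    for i, ind in enumerate(individuals, start=1):
        ind.sample_id = f"s{i:0{width}d}"
    return individuals


def _locus_coords(index: int) -> tuple[str, int]:
    contig = index // LOCI_PER_CONTIG + 1
    within = index % LOCI_PER_CONTIG
    return f"ctg{contig:04d}", (within + 1) * POS_SPACING


def _noisy_locus(
    geno: np.ndarray,  # alt-allele counts 0/1/2 per sample
    is_indel: bool,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray]:
    """Apply dropout -> genotyping error -> missingness; draw depths.

    Dropout acts per haplotype: one silenced haplotype turns a call into the
    homozygote of the remaining allele, both silenced give ABSENT with depth 0.
    Error moves a called genotype to a uniformly chosen other called state
    (SNP loci only: at indel loci the class alphabet has a single called
    state). Missingness blanks the call but keeps the drawn depth (a no-call
    at a covered site).
    """
    n = len(geno)
    disp = config.depth_dispersion
    depths = rng.negative_binomial(disp, disp / (disp + config.depth_mean), size=n).astype(np.int32)
    gts: list[str] = []
    for i in range(n):
        state: int | None = int(geno[i])
        if config.dropout_rate > 0:
            drop = rng.random(2) < config.dropout_rate
            if drop[0] and drop[1]:
                state = None
                depths[i] = 0
            elif drop[0] or drop[1]:
                if state == 1:
                    # haplotype 0 carries REF, haplotype 1 carries ALT
                    state = 2 if drop[0] else 0
        if state is not None and not is_indel and config.error_rate > 0:
            if rng.random() < config.error_rate:
                others = [s for s in (0, 1, 2) if s != state]
                state = others[int(rng.integers(2))]
        if state is not None and config.missing_rate > 0:
            if rng.random() < config.missing_rate:
                state = None  # no-call at a covered site: depth retained
        gts.append("./." if state is None else ("0/0", "0/1", "1/1")[state])
    return gts, depths


def _build_locus(
    index: int,
    gts: list[str],
    depths: np.ndarray,
    is_indel: bool,
    info: dict[str, float],
) -> LocusRecord:
    chrom, pos = _locus_coords(index)
    n = len(gts)
    classes = np.empty(n, np.int8)
    refined = np.empty(n, np.int8)
    for i, gt in enumerate(gts):
        cls, ref_label = classify_genotype(gt, is_indel)
        classes[i] = CLASS_CODES[cls]
        refined[i] = REFINED_CODES[ref_label]
    ref, alts = ("A", ("AT",)) if is_indel else ("A", ("C",))
    return LocusRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts,
        is_indel=is_indel,
        site_info=info,
        per_sample_class=classes,
        per_sample_refined=refined,
        per_sample_depth=depths,
        per_sample_gt=gts,
    )


_SEX_LOCUS_GENO = {
    # model -> latent sex genotype -> alt-allele count at the planted locus
    "XY": {"XY": 1, "XX": 0},
    "ZW": {"ZW": 1, "ZZ": 0},
    "SINGLE_LOCUS_2G": {"FM": 1, "FF": 0},
    "SINGLE_LOCUS_3G": {"MM": 2, "FM": 1, "FF": 0},
}


def simulate_locus_genotypes(
    individuals: Sequence[Individual],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Planted sex-linked loci plus i.i.d. Hardy-Weinberg neutral loci.

    Planted loci come first in coordinate order; under PGSD the planted loci
    are the liability loci themselves. Neutral allele frequencies are drawn
    uniformly from ``allele_freq_range``; a fraction of neutral loci are
    indels (their called genotypes all collapse to the INDEL class).
    """
    n = len(individuals)
    loci: list[LocusRecord] = []
    truth_rows: list[dict] = []
    index = 0
    safe_info = {"QD": 30.0, "FS": 3.0, "MQ": 60.0}

    if config.model == "PGSD":
        for j in range(config.pgsd_n_loci):
            geno = np.array([ind.liability_genotypes[j] for ind in individuals])
            gts, depths = _noisy_locus(geno, False, config, rng)
            locus = _build_locus(index, gts, depths, False, dict(safe_info))
            loci.append(locus)
            truth_rows.append(
                {"chrom": locus.chrom, "pos": locus.pos, "role": "liability",
                 "expected_family": "none"}
            )
            index += 1
    else:
        geno_map = _SEX_LOCUS_GENO[config.model]
        for _ in range(config.n_planted):
            geno = np.array([geno_map[ind.sex_genotype] for ind in individuals])
            gts, depths = _noisy_locus(geno, False, config, rng)
            locus = _build_locus(index, gts, depths, False, dict(safe_info))
            loci.append(locus)
            truth_rows.append(
                {"chrom": locus.chrom, "pos": locus.pos, "role": "sex_locus",
                 "expected_family": "HET_VS_HOM"}
            )
            index += 1

    lo, hi = config.allele_freq_range
    for _ in range(config.L_neutral):
        freq = float(rng.uniform(lo, hi))
        is_indel = bool(rng.random() < config.indel_fraction)
        geno = rng.binomial(2, freq, size=n)
        gts, depths = _noisy_locus(geno, is_indel, config, rng)
        info = {
            "QD": float(max(0.1, rng.normal(25.0, 6.0))),
            "FS": float(rng.exponential(5.0)),
            "MQ": float(rng.normal(55.0, 5.0)),
        }
        locus = _build_locus(index, gts, depths, is_indel, info)
        loci.append(locus)
        truth_rows.append(
            {"chrom": locus.chrom, "pos": locus.pos, "role": "neutral",
             "expected_family": "none"}
        )
        index += 1

    matrix = GenotypeMatrix(samples=[ind.sample_id for ind in individuals], loci=loci)
    truth = TruthTable(
        loci=pd.DataFrame(truth_rows, columns=["chrom", "pos", "role", "expected_family"]),
        samples=pd.DataFrame(
            {
                "sample_id": [ind.sample_id for ind in individuals],
                "sex_genotype": [ind.sex_genotype or "polygenic" for ind in individuals],
                "liability": [
                    "" if ind.liability_genetic is None else f"{ind.liability_genetic:.6f}"
                    for ind in individuals
                ],
                "sex_t1": [ind.sex_t1 for ind in individuals],
                "sex_t2": [ind.sex_t2 for ind in individuals],
            }
        ),
    )
    return matrix, truth


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[SexRecord], GenotypeMatrix, TruthTable]:
    """One seeded end-to-end draw: sheet records, genotype matrix, truth."""
    rng = np.random.default_rng(config.seed)
    individuals = assign_sexes(config, rng)
    matrix, truth = simulate_locus_genotypes(individuals, config, rng)
    records = [SexRecord(i.sample_id, i.sex_t1, i.sex_t2) for i in individuals]
    return records, matrix, truth


def emit_cohort(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, sample sheet, truth tables and a run log to ``out_dir``.

    Identical configs (including seed) give byte-identical files, and the VCF
    round-trips through :func:`sexlink.genotype_io.read_vcf_genotypes` to the
    same genotype-class matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, matrix, truth = simulate_cohort(config)

    paths = {
        "vcf": out_dir / "cohort.vcf",
        "samples": out_dir / "samples.tsv",
        "truth_loci": out_dir / "truth_loci.tsv",
        "truth_samples": out_dir / "truth_samples.tsv",
        "log": out_dir / "run_log.txt",
    }
    write_vcf(matrix, paths["vcf"])
    with paths["samples"].open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tsex_t1\tsex_t2\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.sex_t1}\t{r.sex_t2 or 'NA'}\n")
    truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    with paths["log"].open("w", encoding="utf-8") as fh:
        fh.write("sexlink simulation log\n")
        for key, value in sorted(asdict(config).items()):
            fh.write(f"{key} = {value!r}\n")
        vcf_md5 = hashlib.md5(paths["vcf"].read_bytes()).hexdigest()
        fh.write(f"vcf_md5 = {vcf_md5}\n")
    logger.info(
        "emitted cohort: %d samples, %d loci -> %s", matrix.n_samples, matrix.n_loci, out_dir
    )
    return paths
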