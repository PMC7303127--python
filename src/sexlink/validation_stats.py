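"""Genotype-frequency association tests and the neutral null for the scan.

Candidate markers are validated by tabulating targeted genotypes (e.g. from a
SNaPshot assay) against phenotype groups and testing the contingency table
with Pearson's chi-square (no continuity correction; the reference contrasts
are 3 genotypes x 2 groups, df = 2). The standard contrasts are the stable
sexes against each other (MM vs FF), and each stable sex against all other
phenotypes pooled (MM vs rest, FF vs rest), plus the full four-group table.

``null_pass_probability`` gives the probability that a *neutral*
Hardy-Weinberg locus passes the pattern scan by chance given the group sizes,
the concordance threshold and the noise model -- the expectation against
which apparent candidates (the false-positive problem of small-cohort RAD
scans) should be judged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genotype_io import SexRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "ContrastResult",
    "contingency_table",
    "pearson_chi_square",
    "marker_validation_report",
    "null_pass_probability",
    "NullPassEstimate",
    "read_validation_genotypes",
]

#: the published validation contrasts, in report order
STANDARD_CONTRASTS: list[tuple[str, list[tuple[str, tuple[str, ...]]]]] = [
    ("MM_vs_FF", [("MM", ("MM",)), ("FF", ("FF",))]),
    ("MM_vs_rest", [("MM", ("MM",)), ("rest", ("FF", "FM", "MF"))]),
    ("FF_vs_rest", [("FF", ("FF",)), ("rest", ("MM", "FM", "MF"))]),
    ("four_group", [("MM", ("MM",)), ("FF", ("FF",)), ("MF", ("MF",)), ("FM", ("FM",))]),
]


@dataclass
class ContingencyTable:
    """Genotype categories x phenotype groups count table."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (rows, cols) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    low_expected_flag: bool  # any expected cell < 5


@dataclass(frozen=True)
class ContrastResult:
    contrast: str
    table: ContingencyTable
    chi_square: ChiSquareResult
    significant: bool
    p_bonferroni: float


def _canonical_genotype(genotype: str) -> str:
    alleles = genotype.replace("|", "/").split("/")
    return "/".join(sorted(a.strip() for a in alleles))


def contingency_table(
    genotypes: Mapping[str, str],
    sheet: Sequence[SexRecord],
    grouping: Sequence[tuple[str, tuple[str, ...]]],
) -> ContingencyTable:
    """Tabulate marker genotypes against a phenotype grouping.

    ``grouping`` maps group labels to sets of phenotype codes (disjoint).
    Samples without a genotype, without a phenotype code, or outside the
    grouping are excluded (logged). Genotypes are canonicalized so T/G and
    G/T count together.
    """
    seen_codes: set[str] = set()
    for _, codes in grouping:
        overlap = seen_codes & set(codes)
        if overlap:
            raise ValueError(f"grouping labels overlap on phenotype codes {sorted(overlap)}")
        seen_codes.update(codes)
    pheno = {r.sample_id: r.phenotype for r in sheet}
    col_of: dict[str, int] = {}
    for j, (_, codes) in enumerate(grouping):
        for code in codes:
            col_of[code] = j
    tallies: dict[str, np.ndarray] = {}
    n_excluded = 0
    for sample_id, genotype in genotypes.items():
        code = pheno.get(sample_id)
        if genotype is None or str(genotype).strip() in ("", "NA", ".") or code is None:
            n_excluded += 1
            continue
        if code not in col_of:
            n_excluded += 1
            continue
        g = _canonical_genotype(str(genotype))
        if g not in tallies:
            tallies[g] = np.zeros(len(grouping), dtype=np.int64)
        tallies[g][col_of[code]] += 1
    if n_excluded:
        logger.info("contingency_table: excluded %d sample(s)", n_excluded)
    if not tallies:
        raise ValueError("contingency table is empty after exclusions")
    row_labels = sorted(tallies)
    counts = np.vstack([tallies[r] for r in row_labels])
    return ContingencyTable(row_labels, [g for g, _ in grouping], counts)


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square on a contingency table, no continuity correction.

    All-zero rows and columns are dropped first; df = (rows-1)(cols-1) on the
    reduced table. Expected counts below 5 set ``low_expected_flag`` (the
    asymptotic p-value is then questionable) but do not change the test.
    """
    counts = table.counts
    if counts.sum() == 0:
        raise ValueError("chi-square undefined for a zero table")
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    res = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        low_expected_flag=bool((res.expected_freq < 5).any()),
    )


def marker_validation_report(
    genotypes: Mapping[str, str],
    sheet: Sequence[SexRecord],
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Run the standard phenotype-group contrasts for one marker.

    Contrasts: MM vs FF, MM vs pooled others, FF vs pooled others, and the
    full four-group table. Each is flagged significant at ``alpha``; a
    Bonferroni-adjusted p across the contrasts is reported alongside (the
    unadjusted flag is the primary readout).
    """
    present = {r.phenotype for r in sheet if r.sample_id in genotypes and r.phenotype}
    if len(present) < 2:
        raise ValueError("need genotyped samples from at least two phenotype groups")
    results: list[ContrastResult] = []
    n_contrasts = len(STANDARD_CONTRASTS)
    for name, grouping in STANDARD_CONTRASTS:
        try:
            table = contingency_table(genotypes, sheet, grouping)
            chi = pearson_chi_square(table)
        except ValueError as exc:
            logger.warning("contrast %s skipped: %s", name, exc)
            continue
        results.append(
            ContrastResult(
                contrast=name,
                table=table,
                chi_square=chi,
                significant=chi.p_value < alpha,
                p_bonferroni=min(1.0, chi.p_value * n_contrasts),
            )
        )
    return results


def read_validation_genotypes(path: str | Path) -> dict[str, dict[str, str]]:
    """Read targeted-genotyping TSV (sample_id, marker_id, genotype) into
    {marker_id: {sample_id: genotype}}."""
    path = Path(path)
    markers: dict[str, dict[str, str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"sample_id", "marker_id", "genotype"}
        if not required <= set(header):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        idx = {name: header.index(name) for name in required}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            marker = fields[idx["marker_id"]].strip()
            sample = fields[idx["sample_id"]].strip()
            markers.setdefault(marker, {})[sample] = fields[idx["genotype"]].strip()
    return markers


# ---------------------------------------------------------------------------
# Neutral null expectation for the pattern scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullPassEstimate:
    probability: float
    se: float | None  # None for the exact path
    method: str


def _class_probs_snp(
    allele_freq: float,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    dropout_rate: float = 0.0,
) -> dict[str, float]:
    """Per-sample class probabilities {HOM, HET, ABSENT} for a neutral SNP.

    Composition mirrors the simulator: Hardy-Weinberg genotype, then
    haplotype-level restriction-site dropout (one haplotype lost -> apparent
    homozygote of the remaining allele; both lost -> ABSENT), then genotyping
    error (the call moves to a uniformly chosen other called refined class),
    then missingness (the call becomes ABSENT).
    """
    p = allele_freq
    q = 1.0 - p
    r, t, s = p * p, 2 * p * q, q * q  # HOM_REF, HET, HOM_ALT
    d = dropout_rate
    both, one = d * d, 2 * d * (1 - d)
    keep = (1 - d) ** 2
    r1 = keep * r + one * (r + t / 2)
    s1 = keep * s + one * (s + t / 2)
    t1 = keep * t
    a1 = both
    e = error_rate
    r2 = (1 - e) * r1 + (e / 2) * (t1 + s1)
    s2 = (1 - e) * s1 + (e / 2) * (r1 + t1)
    t2 = (1 - e) * t1 + (e / 2) * (r1 + s1)
    mu = missing_rate
    return {
        "HOM": (1 - mu) * (r2 + s2),
        "HET": (1 - mu) * t2,
        "ABSENT": mu + (1 - mu) * a1,
    }


def _min_count(theta: Fraction, n: int) -> int:
    """Smallest count m with m/n >= theta (m >= 1 for n >= 1)."""
    need = theta * n
    return max(1, int(-(-need.numerator // need.denominator)))


def _group_dominant_probs(
    n: int, probs: dict[str, float], theta: Fraction
) -> dict[str, float]:
    """P(dominant class = c) for one group under the scan's dominance rule.

    ABSENT dominates at >= theta of the whole group; a called class dominates
    at >= theta of the called samples. theta > 0.5 makes at most one called
    class dominant, so the probability reduces to binomial tails over the
    absent count and the class count among called samples.
    """
    a = probs["ABSENT"]
    m_full = _min_count(theta, n)
    out = {"ABSENT": float(stats.binom.sf(m_full - 1, n, a))}
    called_classes = [c for c in probs if c != "ABSENT" and probs[c] > 0]
    pmf_absent = [float(stats.binom.pmf(k, n, a)) for k in range(m_full)]
    for c in called_classes:
        cond = probs[c] / (1 - a) if a < 1 else 0.0
        total = 0.0
        for k_abs in range(m_full):
            n_called = n - k_abs
            if n_called <= 0:
                continue
            m_sub = _min_count(theta, n_called)
            total += pmf_absent[k_abs] * float(stats.binom.sf(m_sub - 1, n_called, cond))
        out[c] = total
    return out


def null_pass_probability(
    group_sizes: Sequence[int],
    theta: float | str | Fraction,
    allele_freq: float,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    dropout_rate: float = 0.0,
    method: str = "exact",
    n_sims: int = 100_000,
    rng: np.random.Generator | None = None,
) -> NullPassEstimate:
    """Probability a neutral HWE locus passes the scan criterion by chance.

    Exact path: per-group dominant-class probabilities from binomial tails
    (the threshold theta > 0.5 makes dominance unique), combined across
    independent groups as P(all dominant) - P(all dominant and equal). The
    Monte-Carlo path simulates per-group class counts and applies the same
    dominance rule, returning a standard error.
    """
    theta_f = theta if isinstance(theta, Fraction) else Fraction(str(theta))
    if not Fraction(1, 2) < theta_f <= 1:
        raise ValueError(f"theta must be in (0.5, 1], got {theta}")
    if any(n < 1 for n in group_sizes):
        raise ValueError("group sizes must be >= 1")
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must be in (0, 1)")
    probs = _class_probs_snp(allele_freq, error_rate, missing_rate, dropout_rate)

    if method == "exact":
        per_group = [_group_dominant_probs(n, probs, theta_f) for n in group_sizes]
        classes = set().union(*(g.keys() for g in per_group))
        p_all_dominant = math.prod(sum(g.values()) for g in per_group)
        p_all_equal = sum(
            math.prod(g.get(c, 0.0) for g in per_group) for c in classes
        )
        return NullPassEstimate(p_all_dominant - p_all_equal, None, "exact")

    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    names = ["HOM", "HET", "ABSENT"]
    pvec = np.array([probs[c] for c in names])
    passes = 0
    for _ in range(n_sims):
        dominants = []
        ok = True
        for n in group_sizes:
            counts = rng.multinomial(n, pvec)
            dom = _dominant_from_counts(dict(zip(names, counts)), n, theta_f)
            if dom is None:
                ok = False
                break
            dominants.append(dom)
        if ok and len(set(dominants)) > 1:
            passes += 1
    p_hat = passes / n_sims
    se = math.sqrt(p_hat * (1 - p_hat) / n_sims)
    return NullPassEstimate(p_hat, se, "monte_carlo")


def _dominant_from_counts(counts: dict[str, int], n: int, theta: Fraction) -> str | None:
    n_absent = counts.get("ABSENT", 0)
    if Fraction(n_absent, n) >= theta:
        return "ABSENT"
    n_called = n - n_absent
    if n_called == 0:
        return None
    for c, k in counts.items():
        if c != "ABSENT" and Fraction(k, n_called) >= theta:
            return c
    return None
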