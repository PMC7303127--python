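"""Genotype-pattern scan for sex-linked markers across phenotype groupings.

Individuals sexed at two consecutive maturation seasons fall in four phenotype
classes (FF, MM, FM, MF; first letter = first-season sex). Three groupings are
scanned, each matching a hypothesis about sex determination:

* ``FIRST_SEX`` -- two groups by first-season sex, FF_FM vs MM_MF (a single
  predominant sex-determining region / sex-chromosome hypothesis);
* ``STABILITY`` -- three groups MM, FF and MF_FM (the single-locus genetic
  models in which sex-changers are the heterozygous class);
* ``FULL``      -- all four classes separately.

A locus is a candidate when every group has a *dominant* genotype class at a
concordance threshold theta (default 80%, absorbing genotyping and phenotyping
errors) and the dominant classes are not all equal. ABSENT is itself a class:
RAD loci can be sex-limited through restriction-site polymorphism, so a group
whose samples are mostly ungenotyped at a locus is "absent" there. Dominance
of ABSENT is judged against the whole group; dominance of a called class is
judged among the genotyped samples of the group, so ordinary missingness does
not veto a locus. Threshold comparisons use exact rational arithmetic.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import (
    CLASS_CODES,
    CODE_TO_CLASS,
    CODE_TO_REFINED,
    GenotypeClass,
    GenotypeMatrix,
    LocusRecord,
    SexRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupPartition",
    "DominantClassResult",
    "ScanConfig",
    "PatternCall",
    "build_partition",
    "dominant_class",
    "scan_locus",
    "scan_all",
    "enumerate_patterns",
    "coverage_filter",
    "candidates_frame",
]

PARTITION_NAMES = ("FIRST_SEX", "STABILITY", "FULL")

#: phenotype-code membership of each named grouping, in fixed group order
_PARTITION_GROUPS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "FIRST_SEX": [("FF_FM", ("FF", "FM")), ("MM_MF", ("MM", "MF"))],
    "STABILITY": [("MM", ("MM",)), ("FF", ("FF",)), ("MF_FM", ("MF", "FM"))],
    "FULL": [("MM", ("MM",)), ("FF", ("FF",)), ("MF", ("MF",)), ("FM", ("FM",))],
}


@dataclass(frozen=True)
class GroupPartition:
    """Named assignment of samples to k >= 2 disjoint groups."""

    name: str
    groups: tuple[tuple[str, tuple[str, ...]], ...]  # (label, sample ids)

    @property
    def k(self) -> int:
        return len(self.groups)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("a partition needs at least 2 groups")
        seen: set[str] = set()
        for label, ids in self.groups:
            if not ids:
                raise ValueError(f"partition {self.name}: group {label!r} is empty")
            overlap = seen & set(ids)
            if overlap:
                raise ValueError(f"partition {self.name}: samples in >1 group: {sorted(overlap)}")
            seen.update(ids)


@dataclass(frozen=True)
class DominantClassResult:
    """Dominant genotype class of one group at one locus, if any."""

    group_label: str
    dominant: GenotypeClass | None
    fraction: Fraction  # count of dominant class over its denominator
    n_group: int
    n_called: int
    dominant_refined: str | None = None  # refined label when scanned refined


def _to_theta(theta: float | str | Fraction) -> Fraction:
    frac = theta if isinstance(theta, Fraction) else Fraction(str(theta))
    if not Fraction(1, 2) < frac <= 1:
        raise ValueError(f"theta must be in (0.5, 1], got {theta}")
    return frac


@dataclass
class ScanConfig:
    """Scan parameters: concordance threshold, coverage floor, class alphabet."""

    partition: GroupPartition
    theta: float | str | Fraction = Fraction(4, 5)
    min_mean_depth: float = 15.0
    alphabet: str = "collapsed4"  # or "refined"

    def __post_init__(self) -> None:
        self.theta = _to_theta(self.theta)
        if self.min_mean_depth < 0:
            raise ValueError("min_mean_depth must be >= 0")
        if self.alphabet not in ("collapsed4", "refined"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


@dataclass
class PatternCall:
    """Per-locus scan verdict with per-group dominant classes."""

    locus: LocusRecord
    per_group: list[DominantClassResult]
    passes: bool
    family: str | None = None  # HET_VS_HOM / HOM_VS_HET / PRESENCE_ABSENCE / OTHER
    subcode: str | None = None
    mean_depth: float | None = None
    passes_coverage: bool | None = None


def build_partition(records: Sequence[SexRecord], name: str) -> GroupPartition:
    """Build one of the three named groupings from the sample sheet.

    Records with unknown second-season sex have no phenotype code and are
    excluded with a warning; an empty group is a hard error because the
    partition is unusable for scanning.
    """
    if name not in _PARTITION_GROUPS:
        raise ValueError(f"unknown partition {name!r}; expected one of {PARTITION_NAMES}")
    usable = [r for r in records if r.phenotype is not None]
    dropped = len(records) - len(usable)
    if dropped:
        logger.warning("partition %s: excluded %d record(s) with unknown sex_t2", name, dropped)
    groups = []
    for label, codes in _PARTITION_GROUPS[name]:
        ids = tuple(r.sample_id for r in usable if r.phenotype in codes)
        if not ids:
            raise ValueError(f"partition {name}: no samples with phenotype in {codes}")
        groups.append((label, ids))
    return GroupPartition(name=name, groups=tuple(groups))


def dominant_class(
    classes: Sequence[GenotypeClass] | np.ndarray,
    theta: float | str | Fraction,
    group_label: str = "",
) -> DominantClassResult:
    """Find the group's dominant genotype class at threshold theta, if any.

    ABSENT dominates when it reaches theta of the whole group (the locus is
    effectively not genotyped there); otherwise a called class dominates when
    it reaches theta of the genotyped samples. theta > 0.5 makes the dominant
    class unique. Comparisons are exact rationals: 5/6 >= 4/5 is decided
    without floating point.
    """
    theta = _to_theta(theta)
    if len(classes) == 0:
        raise ValueError("dominant_class: empty group")
    counts: Counter = Counter()
    for c in classes:
        cls = CODE_TO_CLASS[int(c)] if isinstance(c, (int, np.integer)) else GenotypeClass(c)
        counts[cls] += 1
    n = sum(counts.values())
    n_absent = counts.get(GenotypeClass.ABSENT, 0)
    n_called = n - n_absent

    if Fraction(n_absent, n) >= theta:
        return DominantClassResult(
            group_label, GenotypeClass.ABSENT, Fraction(n_absent, n), n, n_called, "ABSENT"
        )
    if n_called > 0:
        best_cls, best_count = None, -1
        for cls in (GenotypeClass.HOM, GenotypeClass.HET, GenotypeClass.INDEL):
            if counts.get(cls, 0) > best_count:
                best_cls, best_count = cls, counts.get(cls, 0)
        frac = Fraction(best_count, n_called)
        if frac >= theta:
            return DominantClassResult(
                group_label, best_cls, frac, n, n_called, best_cls.value
            )
    # no class reaches theta
    top = counts.most_common(1)[0]
    denom = n if top[0] is GenotypeClass.ABSENT else max(n_called, 1)
    return DominantClassResult(group_label, None, Fraction(top[1], denom), n, n_called)


def _classify_family(dominants: list[GenotypeClass], k: int) -> tuple[str, str]:
    n_abs = sum(1 for d in dominants if d is GenotypeClass.ABSENT)
    if 0 < n_abs < k:
        return "PRESENCE_ABSENCE", f"absent-in-{n_abs}-of-{k}"
    klasses = set(dominants)
    if klasses <= {GenotypeClass.HET, GenotypeClass.HOM}:
        n_het = sum(1 for d in dominants if d is GenotypeClass.HET)
        if n_het <= k - n_het:
            return "HET_VS_HOM", f"het-in-{n_het}-of-{k}"
        return "HOM_VS_HET", f"hom-in-{k - n_het}-of-{k}"
    parts = sorted(f"{d.value}:{dominants.count(d)}" for d in klasses)
    return "OTHER", "|".join(parts)


def scan_locus(
    locus: LocusRecord,
    partition: GroupPartition,
    config: ScanConfig,
    sample_index: dict[str, int] | None = None,
) -> PatternCall:
    """Scan one locus: per-group dominant classes, pass verdict, pattern family.

    Passes iff every group has a dominant class and the dominant classes are
    not all equal (so a locus uniformly ABSENT, or uniformly HET, fails).
    """
    if sample_index is None:
        raise ValueError("scan_locus needs a sample_id -> column index mapping")
    refined = config.alphabet == "refined"
    per_group: list[DominantClassResult] = []
    for label, ids in partition.groups:
        cols = [sample_index[s] for s in ids]
        if refined:
            labels = [CODE_TO_REFINED[int(locus.per_sample_refined[c])] for c in cols]
            res = _dominant_refined(labels, config.theta, label)
        else:
            res = dominant_class(locus.per_sample_class[cols], config.theta, label)
        per_group.append(res)
    passes = all(g.dominant is not None for g in per_group)
    family = subcode = None
    if passes:
        collapsed = [g.dominant for g in per_group]
        distinct = {g.dominant_refined for g in per_group} if refined else set(collapsed)
        if len(distinct) == 1:
            passes = False
        else:
            family, subcode = _classify_family(collapsed, partition.k)
    return PatternCall(locus=locus, per_group=per_group, passes=passes, family=family, subcode=subcode)


_REFINED_TO_COLLAPSED = {
    "HOM_REF": GenotypeClass.HOM,
    "HOM_ALT": GenotypeClass.HOM,
    "HET": GenotypeClass.HET,
    "INDEL": GenotypeClass.INDEL,
    "ABSENT": GenotypeClass.ABSENT,
}


def _dominant_refined(labels: list[str], theta: Fraction, group_label: str) -> DominantClassResult:
    """Dominance over the refined SNP alphabet; same ABSENT-precedence rule.

    The dominant value is reported through DominantClassResult.dominant as a
    collapsed GenotypeClass for family naming, but dominance itself is decided
    on the refined labels (HOM_REF vs HOM_ALT count separately).
    """
    n = len(labels)
    counts = Counter(labels)
    n_absent = counts.get("ABSENT", 0)
    n_called = n - n_absent
    if Fraction(n_absent, n) >= theta:
        return DominantClassResult(
            group_label, GenotypeClass.ABSENT, Fraction(n_absent, n), n, n_called, "ABSENT"
        )
    if n_called > 0:
        called = {k: v for k, v in counts.items() if k != "ABSENT"}
        best = max(sorted(called), key=lambda k: called[k])
        frac = Fraction(called[best], n_called)
        if frac >= theta:
            return DominantClassResult(
                group_label, _REFINED_TO_COLLAPSED[best], frac, n, n_called, best
            )
    top = counts.most_common(1)[0]
    denom = n if top[0] == "ABSENT" else max(n_called, 1)
    return DominantClassResult(group_label, None, Fraction(top[1], denom), n, n_called)


def scan_all(
    matrix: GenotypeMatrix, config: ScanConfig
) -> tuple[list[PatternCall], Counter]:
    """Scan every locus; return passing calls ordered by (chrom, pos) and
    per-family counts.

    The result is invariant to sample column order because groups are gathered
    by sample id.
    """
    sample_index = {s: i for i, s in enumerate(matrix.samples)}
    for label, ids in config.partition.groups:
        missing = [s for s in ids if s not in sample_index]
        if missing:
            raise ValueError(f"group {label}: samples not in matrix: {missing}")
    calls: list[PatternCall] = []
    for locus in sorted(matrix.loci, key=lambda l: l.key):
        call = scan_locus(locus, config.partition, config, sample_index)
        if call.passes:
            calls.append(call)
    families = Counter(c.family for c in calls)
    logger.info(
        "scan %s: %d/%d loci pass; families: %s",
        config.partition.name,
        len(calls),
        matrix.n_loci,
        dict(families),
    )
    return calls, families


def enumerate_patterns(k: int, alphabet_size: int = 4) -> list[tuple[int, ...]]:
    """All ordered k-tuples of class assignments that are not all equal.

    For k groups over an a-letter alphabet there are a^k - a such patterns:
    12 for the two-group analysis over the 4-class alphabet.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    return [
        pattern
        for pattern in itertools.product(range(alphabet_size), repeat=k)
        if len(set(pattern)) > 1
    ]


def coverage_filter(
    calls: Iterable[PatternCall], min_mean_depth: float = 15.0
) -> list[PatternCall]:
    """Keep calls whose locus mean depth, over samples with a called genotype,
    strictly exceeds ``min_mean_depth`` (the validation-quality criterion).

    Annotates every call with ``mean_depth`` and ``passes_coverage``.
    """
    if min_mean_depth < 0:
        raise ValueError("min_mean_depth must be >= 0")
    kept: list[PatternCall] = []
    absent_code = CLASS_CODES[GenotypeClass.ABSENT]
    for call in calls:
        locus = call.locus
        called = locus.per_sample_class != absent_code
        mean_depth = float(locus.per_sample_depth[called].mean()) if called.any() else 0.0
        call.mean_depth = mean_depth
        call.passes_coverage = mean_depth > min_mean_depth
        if call.passes_coverage:
            kept.append(call)
    return kept


def candidates_frame(calls: Sequence[PatternCall], partition_name: str):
    """Candidate table as a DataFrame (one row per passing locus)."""
    import pandas as pd

    rows = []
    for call in calls:
        locus = call.locus
        row = {
            "chrom": locus.chrom,
            "pos": locus.pos,
            "ref": locus.ref,
            "alt": ",".join(locus.alts) if locus.alts else ".",
            "is_indel": locus.is_indel,
            "partition": partition_name,
            "family": call.family,
            "subcode": call.subcode,
            "mean_depth": call.mean_depth,
            "passes_coverage": call.passes_coverage,
        }
        for g in call.per_group:
            row[f"dominant_{g.group_label}"] = g.dominant.value if g.dominant else "none"
            row[f"fraction_{g.group_label}"] = float(g.fraction)
        rows.append(row)
    return pd.DataFrame(rows)
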