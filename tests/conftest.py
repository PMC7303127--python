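"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from sexlink import GenotypeMatrix, LocusRecord, SexRecord, phenotype_cohort

#: collapsed class codes used when building matrices by hand
HOM, HET, INDEL, ABSENT = 0, 1, 2, 3

_GT_FOR_CODE = {HOM: "0/0", HET: "0/1", INDEL: "0/1", ABSENT: "./."}
_REFINED_FOR_CODE = {HOM: 0, HET: 1, INDEL: 4, ABSENT: 3}


def make_locus(
    classes,
    chrom: str = "chr1",
    pos: int = 100,
    depths=None,
    is_indel: bool = False,
    site_info=None,
) -> LocusRecord:
    classes = np.asarray(classes, dtype=np.int8)
    n = len(classes)
    if depths is None:
        depths = np.full(n, 20, dtype=np.int32)
    refined = np.array([_REFINED_FOR_CODE[int(c)] for c in classes], dtype=np.int8)
    ref, alts = ("A", ("AT",)) if is_indel else ("A", ("C",))
    return LocusRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts,
        is_indel=is_indel,
        site_info=dict(site_info or {}),
        per_sample_class=classes,
        per_sample_refined=refined,
        per_sample_depth=np.asarray(depths, dtype=np.int32),
        per_sample_gt=[_GT_FOR_CODE[int(c)] for c in classes],
    )


def make_matrix(loci_classes, samples=None, **locus_kwargs) -> GenotypeMatrix:
    """Matrix from a list of per-locus class-code lists."""
    n_samples = len(loci_classes[0]) if loci_classes else 0
    if samples is None:
        samples = [f"s{i+1:02d}" for i in range(n_samples)]
    loci = [
        make_locus(classes, pos=100 * (i + 1), **locus_kwargs)
        for i, classes in enumerate(loci_classes)
    ]
    return GenotypeMatrix(samples=list(samples), loci=loci)


def random_matrix(rng: np.random.Generator, n_loci: int, n_samples: int) -> GenotypeMatrix:
    probs = [0.35, 0.30, 0.10, 0.25]  # HOM, HET, INDEL, ABSENT
    loci_classes = rng.choice(4, size=(n_loci, n_samples), p=probs)
    return make_matrix([row.tolist() for row in loci_classes])


def oracle_dominant(class_codes, theta: Fraction):
    """Direct-counting dominance oracle, independent of the implementation.

    ABSENT dominates at >= theta of the whole group, else a called class
    dominates at >= theta of the called samples.
    """
    vals = [int(v) for v in class_codes]
    n = len(vals)
    n_abs = vals.count(ABSENT)
    if Fraction(n_abs, n) >= theta:
        return ABSENT
    called = [v for v in vals if v != ABSENT]
    if not called:
        return None
    for code in (HOM, HET, INDEL):
        if Fraction(called.count(code), len(called)) >= theta:
            return code
    return None


def oracle_scan(matrix: GenotypeMatrix, partition, theta: Fraction):
    """Brute-force scanner: locus keys that pass, by direct per-group counting."""
    idx = {s: i for i, s in enumerate(matrix.samples)}
    passing = []
    for locus in sorted(matrix.loci, key=lambda l: (l.chrom, l.pos)):
        dominants = []
        ok = True
        for _, ids in partition.groups:
            dom = oracle_dominant([locus.per_sample_class[idx[s]] for s in ids], theta)
            if dom is None:
                ok = False
                break
            dominants.append(dom)
        if ok and len(set(dominants)) > 1:
            passing.append(locus.key)
    return passing


def random_partition(rng: np.random.Generator, samples, k: int):
    """Random disjoint partition of all samples into k non-empty groups."""
    from sexlink import GroupPartition

    while True:
        assignment = rng.integers(k, size=len(samples))
        if len(set(assignment.tolist())) == k:
            break
    groups = tuple(
        (f"g{j}", tuple(s for s, a in zip(samples, assignment) if a == j))
        for j in range(k)
    )
    return GroupPartition(name="random", groups=groups)


@pytest.fixture
def paper_cohort() -> list[SexRecord]:
    """26 individuals: 8 MF, 6 FM, 6 MM, 6 FF."""
    return phenotype_cohort({"MF": 8, "FM": 6, "MM": 6, "FF": 6})


@pytest.fixture
def table1_cohort() -> list[SexRecord]:
    """130 individuals: 20 FM, 76 FF, 16 MM, 18 MF."""
    return phenotype_cohort({"FM": 20, "FF": 76, "MM": 16, "MF": 18})


def write_sheet(path, rows, header="sample_id\tsex_t1\tsex_t2"):
    lines = [header] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
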