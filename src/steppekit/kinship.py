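"""Mismatch-based kinship classification with uniparental consistency checks.

Following the READ approach, pairwise mismatch rates are normalised by the
median pair rate within a group (sites share a genetic background, so the
median is the expected-unrelated level and is robust to a minority of true
relatives).  Under random allele sampling from diploid genotypes the expected
normalised score is 0.5 for identical individuals/twins, 0.75 for first-degree
relatives (parent-offspring or full siblings) and 1.0 for unrelated pairs;
degrees are assigned by thresholds at the midpoints between successive
expectations (0.625, 0.8125, 0.90625), boundary values going to the more
related class.

First-degree calls are cross-checked against uniparentally inherited markers:
a mother and her child must share the mtDNA haplotype, a father and his son
the Y haplogroup.  Genetic sex itself is determined from the ratio of Y- to
X-aligned counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_tables import IndividualRecord
from .mismatch import PairwiseMismatch

__all__ = [
    "KinshipCall",
    "DEGREE_THRESHOLDS",
    "normalize_scores",
    "classify_degree",
    "check_uniparental",
    "infer_sex",
    "kinship_calls",
]

#: upper normalised-score bounds (inclusive) for identical / first / second
DEGREE_THRESHOLDS: tuple[float, float, float] = (0.625, 0.8125, 0.90625)

_DEGREES = ("identical", "first", "second", "unrelated")


@dataclass(frozen=True)
class KinshipCall:
    id_a: str
    id_b: str
    normalized_score: float
    degree: str
    n_overlap: int
    mt_consistent: str = "not_applicable"
    y_consistent: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.normalized_score <= 0:
            raise ValueError("normalized score must be positive")
        if self.degree not in _DEGREES:
            raise ValueError(f"unknown degree {self.degree!r}")


def normalize_scores(
    pairs: Sequence[PairwiseMismatch],
    records: Sequence[IndividualRecord] | None = None,
    grouping: str = "global",
) -> list[tuple[PairwiseMismatch, float]]:
    """Normalise each pair's mismatch rate by its group's median rate.

    ``grouping="site"`` uses the median over pairs whose two members share a
    site (cross-site pairs fall back to the global median); ``"global"`` uses
    one cohort-wide median.  A zero baseline means the group's individuals
    are effectively identical and normalisation is meaningless.
    """
    if grouping not in ("global", "site"):
        raise ValueError(f"grouping must be 'global' or 'site', got {grouping!r}")
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs to estimate an unrelated baseline")

    global_baseline = float(np.median([p.rate for p in pairs]))

    def baseline_for(p: PairwiseMismatch) -> float:
        if grouping == "global" or records is None:
            return global_baseline
        site_of = {r.id: r.site for r in records}
        sa, sb = site_of.get(p.id_a), site_of.get(p.id_b)
        if sa is None or sb is None or sa != sb:
            return global_baseline
        same_site = [
            q.rate
            for q in pairs
            if site_of.get(q.id_a) == sa and site_of.get(q.id_b) == sa
        ]
        if len(same_site) < 2:
            return global_baseline
        return float(np.median(same_site))

    out: list[tuple[PairwiseMismatch, float]] = []
    for p in pairs:
        b = baseline_for(p)
        if b <= 0:
            raise ValueError(
                f"degenerate baseline (median rate {b}) for pair "
                f"({p.id_a}, {p.id_b})"
            )
        out.append((p, p.rate / b))
    return out


def classify_degree(score: float) -> str:
    """Step classification of a normalised mismatch score into a degree.

    Boundary values are assigned to the more related class (score exactly
    0.625 is 'identical').
    """
    if score <= 0:
        raise ValueError("score must be positive")
    t_ident, t_first, t_second = DEGREE_THRESHOLDS
    if score <= t_ident:
        return "identical"
    if score <= t_first:
        return "first"
    if score <= t_second:
        return "second"
    return "unrelated"


def check_uniparental(
    id_a: str,
    id_b: str,
    records: Mapping[str, IndividualRecord],
    degree: str,
) -> tuple[str, str]:
    """Consistency of a first-degree call with mtDNA / Y haplogroup labels.

    Returns (mt_consistent, y_consistent), each 'yes', 'no' or
    'not_applicable'.  Only first-degree (and identical) pairs are checkable.
    Matching mtDNA labels are consistent for any such pair; a mismatch
    refutes only female-female links (which are matrilineal either way),
    while father-daughter and father-son links legitimately differ.  Two
    first-degree males (father-son or brothers) must share the Y haplogroup.
    Missing labels or sexes yield 'not_applicable', never an error.
    """
    if degree not in ("identical", "first"):
        return "not_applicable", "not_applicable"
    ra, rb = records.get(id_a), records.get(id_b)
    if ra is None or rb is None:
        return "not_applicable", "not_applicable"

    mt = "not_applicable"
    # matching labels are consistent with any first-degree link; differing
    # labels only refute links that must share a matriline, i.e. a
    # female-female pair (mother-daughter or sisters).  A mixed-sex pair
    # could be father-daughter and a male-male pair father-son, neither of
    # which shares the mtDNA, so a mismatch there is undecidable.
    if ra.mt_label and rb.mt_label:
        if ra.mt_label == rb.mt_label:
            mt = "yes"
        elif ra.sex == "female" and rb.sex == "female":
            mt = "no"

    y = "not_applicable"
    if ra.sex == "male" and rb.sex == "male":
        if ra.y_label and rb.y_label:
            y = "yes" if ra.y_label == rb.y_label else "no"
    return mt, y


def infer_sex(
    x_count: int,
    y_count: int,
    female_max: float = 0.05,
    male_min: float = 0.20,
) -> str:
    """Genetic sex from X- vs Y-aligned read (or call) counts.

    R = y / (x + y); below ``female_max`` is female, above ``male_min`` male,
    otherwise undetermined.  The gap between the thresholds absorbs low
    coverage and mismapping noise.
    """
    if x_count < 0 or y_count < 0:
        raise ValueError("counts must be non-negative")
    total = x_count + y_count
    if total == 0:
        raise ValueError("no X or Y counts; sex cannot be inferred")
    r = y_count / total
    if r < female_max:
        return "female"
    if r > male_min:
        return "male"
    return "undetermined"


def kinship_calls(
    pairs: Sequence[PairwiseMismatch],
    records: Sequence[IndividualRecord],
    grouping: str = "site",
) -> list[KinshipCall]:
    """Full pipeline: normalise, classify, and run uniparental checks."""
    rec_map = {r.id: r for r in records}
    calls = []
    for pair, score in normalize_scores(pairs, records, grouping=grouping):
        degree = classify_degree(score)
        mt, y = check_uniparental(pair.id_a, pair.id_b, rec_map, degree)
        calls.append(
            KinshipCall(
                id_a=pair.id_a,
                id_b=pair.id_b,
                normalized_score=score,
                degree=degree,
                n_overlap=pair.n_overlap,
                mt_consistent=mt,
                y_consistent=y,
            )
        )
    return calls
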