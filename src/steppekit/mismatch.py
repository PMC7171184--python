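"""Pairwise mismatch rates and the before/after-2700-BCE diversity shift.

The pairwise mismatch rate between two pseudo-haploid individuals is the
fraction of jointly non-missing SNPs at which they carry different alleles —
a simple proxy for genetic diversity (between unrelated individuals) and
relatedness (depressed between kin).  Pairs sharing too few SNPs are
unreliable and are dropped; the study convention keeps pairs with more than
10,000 overlapping sites of the 1240k panel.

The diversity-shift analysis asks whether mean pairwise mismatch among
individuals living after a cutoff date (default 2700 calBCE, the arrival of
steppe ancestry) exceeds that among earlier individuals.  Because every
individual appears in many pairs, pair-level observations are dependent;
significance is therefore assessed by permuting *individual* period labels
and recomputing the group means from the induced pairs, which preserves the
shared-individual dependence that a mixed model's random effects would
absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_tables import GenotypeMatrix, IndividualRecord, MISSING

__all__ = [
    "PairwiseMismatch",
    "DiversityShiftResult",
    "pairwise_mismatch",
    "pairwise_mismatch_matrix",
    "diversity_shift",
]


@dataclass(frozen=True)
class PairwiseMismatch:
    id_a: str
    id_b: str
    n_overlap: int
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate {self.rate} outside [0, 1]")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))


@dataclass(frozen=True)
class DiversityShiftResult:
    effect: float
    p_value: float
    n_pairs_before: int
    n_pairs_after: int
    mean_before: float
    mean_after: float
    ci95: tuple[float, float]
    per_group_effects: dict[str, float]
    n_perm: int


def _select_chrom_mask(g: GenotypeMatrix, chroms: str) -> np.ndarray:
    if chroms == "autosomes":
        return g.is_autosomal
    if chroms == "X":
        return g.is_x
    if chroms == "all":
        return np.ones(g.n_snps, dtype=bool)
    raise ValueError(f"chroms must be 'autosomes', 'X' or 'all', got {chroms!r}")


def pairwise_mismatch_matrix(
    g: GenotypeMatrix, chroms: str = "autosomes"
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (n_individuals x n_individuals) mismatch counts and overlaps.

    Vectorised over all pairs: for haploid 0/1 calls the number of
    mismatching sites between a and b is sum over jointly called sites of
    ``c_a + c_b - 2 c_a c_b``, which reduces to three matrix products.
    """
    mask = _select_chrom_mask(g, chroms)
    calls = g.calls[:, mask]
    valid = (calls != MISSING).astype(np.float64)
    alt = np.where(calls == 1, 1.0, 0.0)  # alt calls, zero where missing
    n_overlap = valid @ valid.T
    mismatches = alt @ valid.T + valid @ alt.T - 2.0 * (alt @ alt.T)
    return mismatches, n_overlap


def pairwise_mismatch(
    g: GenotypeMatrix,
    min_overlap: int = 10_000,
    chroms: str = "autosomes",
) -> tuple[list[PairwiseMismatch], int]:
    """All unordered pairs with more than ``min_overlap`` shared SNPs.

    Returns the retained pairs (in individual order) and the count of pairs
    dropped for insufficient overlap.  The threshold is strict: a pair with
    exactly ``min_overlap`` shared SNPs is dropped.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    mismatches, n_overlap = pairwise_mismatch_matrix(g, chroms=chroms)
    pairs: list[PairwiseMismatch] = []
    n_dropped = 0
    n = g.n_individuals
    for i in range(n):
        for j in range(i + 1, n):
            ov = int(round(n_overlap[i, j]))
            if ov <= min_overlap:
                n_dropped += 1
                continue
            pairs.append(
                PairwiseMismatch(
                    id_a=g.individuals[i],
                    id_b=g.individuals[j],
                    n_overlap=ov,
                    rate=float(mismatches[i, j]) / ov,
                )
            )
    return pairs, n_dropped


def _period_labels(
    records: Sequence[IndividualRecord],
    cutoff_bce: float,
    include_straddlers: bool,
) -> dict[str, str]:
    """'before' / 'after' per individual by interval midpoint vs the cutoff.

    Individuals whose date interval contains the cutoff are excluded unless
    ``include_straddlers`` (then classified by midpoint).
    """
    labels: dict[str, str] = {}
    for r in records:
        if not include_straddlers and r.date.contains(cutoff_bce) and r.date.width > 0:
            continue
        labels[r.id] = "before" if r.date.midpoint >= cutoff_bce else "after"
    return labels


def diversity_shift(
    pairs: Sequence[PairwiseMismatch],
    records: Sequence[IndividualRecord],
    cutoff_bce: float = 2700.0,
    n_perm: int = 9999,
    seed: int | None = None,
    include_straddlers: bool = False,
) -> DiversityShiftResult:
    """Mean mismatch-rate difference (after - before) with permutation inference.

    Only pairs whose two members fall on the same side of the cutoff enter
    the observed effect.  The null distribution permutes individual period
    labels and recomputes both group means from the induced within-period
    pairs; the two-sided p-value uses the add-one correction.  A 95%
    confidence interval for the effect is formed by recentring the null
    distribution on the observed effect.  Site-level effects (after - before
    mean within each site with pairs on both sides) are reported alongside.
    """
    labels = _period_labels(records, cutoff_bce, include_straddlers)
    site_of = {r.id: r.site for r in records}

    ids = sorted({i for p in pairs for i in (p.id_a, p.id_b) if p.id_a in labels and p.id_b in labels})
    idx = {i: k for k, i in enumerate(ids)}
    usable = [p for p in pairs if p.id_a in idx and p.id_b in idx]
    if not usable:
        raise ValueError("no pairs among period-labelled individuals")

    ii = np.array([idx[p.id_a] for p in usable])
    jj = np.array([idx[p.id_b] for p in usable])
    rates = np.array([p.rate for p in usable])
    lab = np.array([1 if labels[i] == "after" else 0 for i in ids])

    def group_means(label_vec: np.ndarray) -> tuple[float, float, int, int]:
        la, lb = label_vec[ii], label_vec[jj]
        before = (la == 0) & (lb == 0)
        after = (la == 1) & (lb == 1)
        nb, na = int(before.sum()), int(after.sum())
        mb = float(rates[before].mean()) if nb else np.nan
        ma = float(rates[after].mean()) if na else np.nan
        return mb, ma, nb, na

    mean_before, mean_after, n_before, n_after = group_means(lab)
    if n_before < 2 or n_after < 2:
        raise ValueError(
            f"need >= 2 pairs on each side of {cutoff_bce} calBCE, got "
            f"{n_before} before / {n_after} after"
        )
    effect = mean_after - mean_before

    rng = np.random.default_rng(seed)
    null = np.full(n_perm, np.nan)
    for k in range(n_perm):
        perm = rng.permutation(lab)
        mb, ma, nb, na = group_means(perm)
        if nb and na:
            null[k] = ma - mb
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("no informative permutations (labels too unbalanced)")
    p_value = (1.0 + np.sum(np.abs(null) >= abs(effect))) / (null.size + 1.0)

    centred = null - null.mean()
    lo, hi = np.quantile(centred, [0.025, 0.975])
    ci95 = (effect - hi, effect - lo)

    per_group: dict[str, float] = {}
    sites = sorted({site_of[i] for i in ids})
    for site in sites:
        in_site = np.array([site_of[ids[k]] == site for k in range(len(ids))])
        sel = in_site[ii] & in_site[jj]
        if not sel.any():
            continue
        la, lb = lab[ii[sel]], lab[jj[sel]]
        r = rates[sel]
        before = (la == 0) & (lb == 0)
        after = (la == 1) & (lb == 1)
        if before.any() and after.any():
            per_group[site] = float(r[after].mean() - r[before].mean())

    return DiversityShiftResult(
        effect=float(effect),
        p_value=float(p_value),
        n_pairs_before=n_before,
        n_pairs_after=n_after,
        mean_before=mean_before,
        mean_after=mean_after,
        ci95=(float(ci95[0]), float(ci95[1])),
        per_group_effects=per_group,
        n_perm=int(null.size),
    )
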