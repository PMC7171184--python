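"""Allele frequencies, outgroup-f3 and D-statistics with block-jackknife
errors, the autosome-vs-X sex-bias contrast, and phenotypic-SNP frequency
reports.

All statistics work on derived-allele frequencies computed from
pseudo-haploid calls: each individual contributes at most one haploid call
per site, so group frequencies are haploid counts with no diploid or
within-group heterozygosity correction.  Standard errors come from a
delete-one block jackknife over contiguous SNP blocks (no genetic map is
assumed), with block weights proportional to the number of usable SNPs,
following the weighted-jackknife formulae standard in the f-statistics
literature.

* outgroup f3(O; A, B) = mean over SNPs of (fO - fA)(fO - fB): the shared
  drift of A and B relative to outgroup O; larger means more shared ancestry.
* D(W, X; Y, Z) = sum (fW - fX)(fY - fZ) / sum (fW + fX - 2 fW fX)
  (fY + fZ - 2 fY fZ): zero under treeness; with gene flow Y -> X the
  numerator's expectation is negative under this ordering.
* The sex-bias contrast compares f3(O; steppe_ref, test) between autosomes
  and the X chromosome: male-driven steppe admixture leaves the X with less
  steppe affinity, so delta = f3_auto - f3_X > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_tables import GenotypeMatrix, MISSING

__all__ = [
    "GroupFrequencies",
    "FStatResult",
    "AlleleFrequencyEstimate",
    "PHENOTYPE_SNPS",
    "group_freqs",
    "outgroup_f3",
    "d_stat",
    "x_autosome_contrast",
    "phenotype_report",
]

#: phenotypic SNPs routinely reported for European ancient cohorts:
#: pigmentation (SLC45A2, SLC24A5), eye colour (HERC2), lactase persistence (LCT)
PHENOTYPE_SNPS = ("rs16891982", "rs1426654", "rs12913832", "rs4988235")


@dataclass(frozen=True)
class GroupFrequencies:
    """Per-SNP derived-allele frequency (NaN where no calls) and call count."""

    group: str
    freq: np.ndarray
    n_obs: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n_obs > 0


@dataclass(frozen=True)
class FStatResult:
    statistic: str
    value: float
    se: float
    z: float
    n_snps_used: int
    n_blocks: int


@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    group: str
    snp_id: str
    freq: float | None
    n_covered: int
    n_total: int
    damage_flag: bool


def group_freqs(
    g: GenotypeMatrix, assignment: Mapping[str, str]
) -> dict[str, GroupFrequencies]:
    """Derived-allele frequency per SNP per group from pseudo-haploid calls."""
    groups: dict[str, list[int]] = {}
    for ind_id, grp in assignment.items():
        if ind_id not in g.individuals:
            raise ValueError(f"assigned individual {ind_id!r} not in matrix")
        groups.setdefault(grp, []).append(g.index_of(ind_id))
    out: dict[str, GroupFrequencies] = {}
    for grp, rows in groups.items():
        if not rows:
            raise ValueError(f"group {grp!r} is empty")
        calls = g.calls[rows]
        valid = calls != MISSING
        n_obs = valid.sum(axis=0)
        derived = (calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_obs > 0, derived / np.maximum(n_obs, 1), np.nan)
        out[grp] = GroupFrequencies(group=grp, freq=freq, n_obs=n_obs.astype(np.int64))
    return out


def _block_ids(n_snps: int, block_size: int) -> np.ndarray:
    """Contiguous fixed-size SNP blocks (last block may be short)."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    return np.arange(n_snps) // block_size


def _weighted_jackknife(
    theta_hat: float, theta_loo: np.ndarray, m: np.ndarray
) -> float:
    """Weighted delete-one-block jackknife SE (Busing et al. 1999).

    ``m`` holds per-block SNP counts; unequal block sizes get the standard
    weighting used by the f-statistics tooling.
    """
    n = m.sum()
    g_blocks = len(m)
    h = n / m
    theta_j = g_blocks * theta_hat - float(np.sum((1.0 - m / n) * theta_loo))
    tau = h * theta_hat - (h - 1.0) * theta_loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g_blocks)
    return np.sqrt(max(var, 0.0))


def _jackknife_ratio(
    num: np.ndarray, den: np.ndarray, blocks: np.ndarray, statistic: str
) -> FStatResult:
    """Ratio-of-sums statistic with delete-one-block jackknife over blocks."""
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError(
            f"need >= 2 jackknife blocks with usable SNPs, got {len(uniq)}"
        )
    num_tot, den_tot = num.sum(), den.sum()
    if den_tot == 0:
        raise ValueError("zero denominator over all usable SNPs")
    theta_hat = num_tot / den_tot
    num_b = np.array([num[blocks == b].sum() for b in uniq])
    den_b = np.array([den[blocks == b].sum() for b in uniq])
    m = np.array([(blocks == b).sum() for b in uniq], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_loo = (num_tot - num_b) / (den_tot - den_b)
    if not np.isfinite(theta_loo).all():
        raise ValueError("zero denominator in a leave-one-block-out estimate")
    se = _weighted_jackknife(theta_hat, theta_loo, m)
    if se > 0:
        z = theta_hat / se
    else:
        z = 0.0 if theta_hat == 0 else np.sign(theta_hat) * np.inf
    return FStatResult(
        statistic=statistic,
        value=float(theta_hat),
        se=float(se),
        z=float(z),
        n_snps_used=int(len(num)),
        n_blocks=int(len(uniq)),
    )


def outgroup_f3(
    f_out: GroupFrequencies,
    f_a: GroupFrequencies,
    f_b: GroupFrequencies,
    block_size: int = 500,
) -> FStatResult:
    """f3(O; A, B) = mean over jointly defined SNPs of (fO-fA)(fO-fB)."""
    defined = f_out.defined & f_a.defined & f_b.defined
    if defined.sum() < 2:
        raise ValueError("fewer than 2 jointly defined SNPs")
    blocks_all = _block_ids(len(defined), block_size)
    prod = (f_out.freq - f_a.freq) * (f_out.freq - f_b.freq)
    num = prod[defined]
    den = np.ones_like(num)
    return _jackknife_ratio(num, den, blocks_all[defined], "f3")


def d_stat(
    f_w: GroupFrequencies,
    f_x: GroupFrequencies,
    f_y: GroupFrequencies,
    f_z: GroupFrequencies,
    block_size: int = 500,
) -> FStatResult:
    """D(W, X; Y, Z) in allele-frequency-product form with jackknife SE."""
    defined = f_w.defined & f_x.defined & f_y.defined & f_z.defined
    if defined.sum() < 2:
        raise ValueError("fewer than 2 jointly defined SNPs")
    blocks_all = _block_ids(len(defined), block_size)
    w, x, y, z = (f.freq for f in (f_w, f_x, f_y, f_z))
    num = ((w - x) * (y - z))[defined]
    den = ((w + x - 2.0 * w * x) * (y + z - 2.0 * y * z))[defined]
    return _jackknife_ratio(num, den, blocks_all[defined], "D")


def x_autosome_contrast(
    g: GenotypeMatrix,
    assignment: Mapping[str, str],
    steppe_ref_group: str,
    test_group: str,
    outgroup: str,
    block_size: int = 500,
    x_block_size: int | None = None,
) -> tuple[FStatResult, FStatResult, dict[str, float]]:
    """Outgroup-f3 affinity to the steppe reference, autosomes vs X.

    Returns (f3_autosomes, f3_X, delta) where delta carries the difference
    f3_auto - f3_X with an SE combined from the two independent block sets.
    A positive delta indicates the autosomes share more drift with the
    steppe reference than the X does — the signature of male-biased steppe
    admixture (the X spends two thirds of its history in females).
    """
    x_mask = g.is_x
    n_x = int(x_mask.sum())
    xbs = x_block_size if x_block_size is not None else block_size
    if n_x < 2 * xbs:
        raise ValueError(
            f"only {n_x} X-chromosome SNPs: fewer than 2 blocks of {xbs}; "
            "reduce x_block_size or supply more X SNPs"
        )
    g_auto = g.subset_snps(~x_mask)
    g_x = g.subset_snps(x_mask)

    def f3_of(sub: GenotypeMatrix, bs: int) -> FStatResult:
        freqs = group_freqs(sub, assignment)
        for name in (outgroup, steppe_ref_group, test_group):
            if name not in freqs:
                raise ValueError(f"group {name!r} missing from assignment")
        return outgroup_f3(
            freqs[outgroup], freqs[steppe_ref_group], freqs[test_group], block_size=bs
        )

    f3_auto = f3_of(g_auto, block_size)
    f3_x = f3_of(g_x, xbs)
    delta_val = f3_auto.value - f3_x.value
    delta_se = float(np.hypot(f3_auto.se, f3_x.se))
    delta = {
        "delta": float(delta_val),
        "se": delta_se,
        "z": float(delta_val / delta_se) if delta_se > 0 else np.inf,
    }
    return f3_auto, f3_x, delta


def phenotype_report(
    g: GenotypeMatrix,
    assignment: Mapping[str, str],
    snp_ids: Sequence[str] = PHENOTYPE_SNPS,
) -> list[AlleleFrequencyEstimate]:
    """Derived-allele frequency of selected phenotypic SNPs per group.

    SNPs absent from the panel are reported with zero coverage rather than
    raising.  The damage flag is set automatically wherever the ref/alt pair
    involves an A or T allele: at such sites post-mortem cytosine deamination
    (C->T, and G->A on the opposite strand) can mimic a real call at low
    coverage, the situation the original workflow inspected manually.
    """
    group_rows: dict[str, list[int]] = {}
    for ind_id, grp in assignment.items():
        if ind_id not in g.individuals:
            raise ValueError(f"assigned individual {ind_id!r} not in matrix")
        group_rows.setdefault(grp, []).append(g.index_of(ind_id))

    snp_index = {s: k for k, s in enumerate(g.snps["snp_id"])}
    out: list[AlleleFrequencyEstimate] = []
    for grp in sorted(group_rows):
        rows = group_rows[grp]
        for snp_id in snp_ids:
            k = snp_index.get(snp_id)
            if k is None:
                out.append(
                    AlleleFrequencyEstimate(
                        group=grp,
                        snp_id=snp_id,
                        freq=None,
                        n_covered=0,
                        n_total=len(rows),
                        damage_flag=False,
                    )
                )
                continue
            calls = g.calls[rows, k]
            covered = calls != MISSING
            n_cov = int(covered.sum())
            freq = float((calls == 1).sum() / n_cov) if n_cov else None
            ref, alt = str(g.snps["ref"][k]).upper(), str(g.snps["alt"][k]).upper()
            damage = bool({ref, alt} & {"A", "T"})
            out.append(
                AlleleFrequencyEstimate(
                    group=grp,
                    snp_id=snp_id,
                    freq=freq,
                    n_covered=n_cov,
                    n_total=len(rows),
                    damage_flag=damage,
                )
            )
    return out
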