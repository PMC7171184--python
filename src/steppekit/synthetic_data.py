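"""Synthetic cohorts with the statistical structure of a Late Neolithic
ancient-DNA study, so every downstream analysis is testable offline.

Three generators cover the three data layers the analyses consume:

* :func:`simulate_cohort` — dated individuals spanning the Middle Neolithic
  to Early Bronze Age with interval-censored radiocarbon dates and
  per-individual steppe-ancestry proportions that follow a jump at ``te``
  then exponential decline, plus a configurable fraction of post-arrival
  individuals (female-biased) carrying exactly zero steppe ancestry.
* :func:`simulate_genotypes` — two-source admixed pseudo-haploid genotype
  matrices.  Source allele-frequency pools (Neolithic-like and steppe-like)
  drift from common ancestral frequencies under the Balding-Nichols model
  with configurable FST; each call first picks a source chromosome according
  to the individual's ancestry proportion (X-chromosome sites use a
  female-shifted proportion when admixture is male-biased), then draws one
  allele from that pool.  The true source of every allele is exported so
  estimators can be scored against truth.
* :func:`simulate_pedigree` — three-generation pedigrees with Mendelian
  transmission of internally simulated diploid genotypes, a pseudo-haploid
  observation layer on top, matrilineal mtDNA and patrilineal Y labels, and
  true pairwise relatedness degrees.

All randomness flows from one seed via named substreams, making every output
bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .arrival_model import ArrivalParams, model_curve
from .io_tables import (
    AncestryObservation,
    GenotypeMatrix,
    IndividualRecord,
    MISSING,
    RadiocarbonInterval,
)

__all__ = [
    "SimulationConfig",
    "GenotypeBookkeeping",
    "PedigreeSpec",
    "PedigreeSim",
    "stage_rng",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_pedigree",
    "simulate_diversity_cohort",
    "simulate_pool_individuals",
    "simulate_drifted_populations",
    "concat_individuals",
    "three_generation_pedigree",
    "kinship_coefficient",
    "true_degree",
]

_SITES = {
    "Oberbipp": "Switzerland",
    "Aesch": "Switzerland",
    "Spreitenbach": "Switzerland",
    "Niederried": "Switzerland",
    "Singen": "Southern Germany",
    "Lingolsheim": "Alsace",
}
_MT_POOL = ("H", "J1c", "K1a", "T2b", "U5a", "U5b", "W", "X2", "N1a")
_Y_POOL = ("R1b", "R1a", "G2a", "I2a")
_BASES = np.array(list("ACGT"))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible generator for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-cohort conditions for the generators.

    Defaults mirror the study setting: ~100 individuals spanning 4800-1700
    calBCE with date intervals of decades to centuries, a steppe-ancestry
    jump to ~60% near 2750 calBCE declining towards ~10% projected at time
    zero (passing 25-35% in the Early Bronze Age), ~10% of post-arrival
    individuals without any steppe ancestry, and male-biased admixture
    depressing steppe ancestry on the X.
    """

    n_individuals: int = 100
    date_span: tuple[float, float] = (4800.0, 1700.0)  # (oldest, youngest) calBCE
    interval_width_range: tuple[float, float] = (40.0, 300.0)
    true_params: ArrivalParams = field(
        default_factory=lambda: ArrivalParams(p0=0.1, pe=0.6, te=2750.0)
    )
    noise_sd: float = 0.05
    zero_ancestry_fraction: float = 0.1
    n_snps: int = 20_000
    n_x_snps: int = 1_000
    fst_sources: float = 0.08
    missing_rate: float = 0.3
    male_admixture_bias: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        oldest, youngest = self.date_span
        if oldest <= youngest:
            raise ValueError("date_span must be (oldest, youngest) with oldest > youngest")
        lo, hi = self.interval_width_range
        if not 0 <= lo <= hi:
            raise ValueError("interval_width_range must be ordered and non-negative")
        for name in ("noise_sd",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("zero_ancestry_fraction", "missing_rate", "male_admixture_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.fst_sources < 1.0:
            raise ValueError("fst_sources must be in [0, 1)")
        if self.n_snps < 1 or self.n_x_snps < 0:
            raise ValueError("need n_snps >= 1 and n_x_snps >= 0")


def _truncated_noise(
    rng: np.random.Generator, mean: np.ndarray, sd: float
) -> np.ndarray:
    """mean + N(0, sd) resampled (not clipped) into [0, 1]."""
    out = np.empty_like(mean)
    todo = np.ones(len(mean), dtype=bool)
    while todo.any():
        draw = mean[todo] + rng.normal(0.0, sd, size=int(todo.sum()))
        ok = (draw >= 0.0) & (draw <= 1.0)
        idx = np.flatnonzero(todo)[ok]
        out[idx] = draw[ok]
        todo[idx] = False
    return out


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[IndividualRecord], dict[str, AncestryObservation], dict[str, float]]:
    """Dated individuals with ancestry observations following the jump model.

    True dates are uniform on the span; the reported interval is centred on
    the true date with a width drawn from ``interval_width_range`` (so it
    always contains the truth).  Observed proportions sit on the model curve
    plus truncated Gaussian noise, except the designated zero-ancestry
    individuals (a female-biased subset of the post-arrival cohort) whose
    observation is exactly 0.  Also returns the latent true dates.
    """
    rng = stage_rng(cfg.seed, "cohort")
    n = cfg.n_individuals
    oldest, youngest = cfg.date_span
    true_dates = rng.uniform(youngest, oldest, size=n)
    widths = rng.uniform(*cfg.interval_width_range, size=n)
    sexes = np.where(rng.random(n) < 0.5, "female", "male").astype(object)

    curve = np.asarray(model_curve(true_dates, cfg.true_params))
    if cfg.noise_sd > 0:
        props = _truncated_noise(rng, curve, cfg.noise_sd)
    else:
        props = curve.copy()

    post = np.flatnonzero(true_dates < cfg.true_params.te)
    n_zero = int(round(cfg.zero_ancestry_fraction * len(post)))
    zero_idx = rng.choice(post, size=n_zero, replace=False) if n_zero else np.array([], int)
    props[zero_idx] = 0.0
    # zero-ancestry individuals are female with probability 0.9, mirroring
    # the observation that such individuals were women, without hard-coding it
    for k in zero_idx:
        sexes[k] = "female" if rng.random() < 0.9 else "male"

    site_names = list(_SITES)
    site_choice = rng.integers(0, len(site_names), size=n)
    mt_choice = rng.integers(0, len(_MT_POOL), size=n)
    y_choice = rng.integers(0, len(_Y_POOL), size=n)

    records: list[IndividualRecord] = []
    observations: dict[str, AncestryObservation] = {}
    truth: dict[str, float] = {}
    for k in range(n):
        ind_id = f"SYN{k:03d}"
        site = site_names[site_choice[k]]
        sex = str(sexes[k])
        rec = IndividualRecord(
            id=ind_id,
            sex=sex,
            site=site,
            region=_SITES[site],
            date=RadiocarbonInterval(
                upper_bce=float(true_dates[k] + widths[k] / 2.0),
                lower_bce=float(true_dates[k] - widths[k] / 2.0),
            ),
            mt_label=_MT_POOL[mt_choice[k]],
            y_label=_Y_POOL[y_choice[k]] if sex == "male" else None,
        )
        records.append(rec)
        observations[ind_id] = AncestryObservation(
            id=ind_id, steppe_prop=float(props[k]), se=cfg.noise_sd or None
        )
        truth[ind_id] = float(true_dates[k])
    return records, observations, truth


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeBookkeeping:
    """Generator truth exported for scoring estimators.

    ``source`` marks, per (individual, SNP), whether the sampled allele came
    from the steppe-like pool; ``q_auto``/``q_x`` are the per-individual
    source probabilities used on autosomes and X.
    """

    ancestral: np.ndarray
    pool_neolithic: np.ndarray
    pool_steppe: np.ndarray
    source: np.ndarray
    q_auto: np.ndarray
    q_x: np.ndarray

    @property
    def mean_steppe_fraction_auto(self) -> float:
        return float(self.q_auto.mean())

    @property
    def mean_steppe_fraction_x(self) -> float:
        return float(self.q_x.mean())


def _balding_nichols(
    rng: np.random.Generator, ancestral: np.ndarray, fst: float
) -> np.ndarray:
    """One descendant frequency pool drifted from ``ancestral`` at ``fst``."""
    if fst == 0.0:
        return ancestral.copy()
    c = (1.0 - fst) / fst
    return rng.beta(c * ancestral, c * (1.0 - ancestral))


def _synthetic_snp_table(
    rng: np.random.Generator, n_auto: int, n_x: int
) -> pd.DataFrame:
    m = n_auto + n_x
    chrom = np.empty(m, dtype=object)
    if n_auto:
        # contiguous chromosome chunks so fixed-size jackknife blocks are
        # within-chromosome most of the time
        chrom[:n_auto] = [str(1 + (22 * k) // n_auto) for k in range(n_auto)]
    chrom[n_auto:] = "X"
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame(
        {
            "snp_id": [f"snp{k:06d}" for k in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1, dtype=np.int64) * 1000,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def simulate_genotypes(
    cfg: SimulationConfig,
    observations: Mapping[str, AncestryObservation],
    snp_table: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, GenotypeBookkeeping]:
    """Two-source admixed pseudo-haploid calls for the cohort.

    Each call chooses its source chromosome (steppe vs Neolithic pool) with
    probability equal to the individual's steppe proportion — shifted down by
    ``male_admixture_bias`` on the X, emulating steppe ancestry having been
    transmitted predominantly through males — then samples one allele from
    the chosen pool.  Missingness is independent per call.
    """
    rng = stage_rng(cfg.seed, "genotypes")
    ids = list(observations)
    n = len(ids)
    if snp_table is None:
        snp_table = _synthetic_snp_table(rng, cfg.n_snps, cfg.n_x_snps)
    m = len(snp_table)
    is_x = (snp_table["chrom"].astype(str) == "X").to_numpy()

    ancestral = rng.uniform(0.05, 0.95, size=m)
    pool_neo = _balding_nichols(rng, ancestral, cfg.fst_sources)
    pool_steppe = _balding_nichols(rng, ancestral, cfg.fst_sources)

    q_auto = np.array([observations[i].steppe_prop for i in ids])
    q_x = np.clip(q_auto * (1.0 - cfg.male_admixture_bias), 0.0, 1.0)
    q_matrix = np.where(is_x[None, :], q_x[:, None], q_auto[:, None])

    source = rng.random((n, m)) < q_matrix  # True = steppe-pool allele
    pool = np.where(source, pool_steppe[None, :], pool_neo[None, :])
    calls = (rng.random((n, m)) < pool).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = MISSING

    g = GenotypeMatrix(individuals=ids, snps=snp_table, calls=calls)
    bk = GenotypeBookkeeping(
        ancestral=ancestral,
        pool_neolithic=pool_neo,
        pool_steppe=pool_steppe,
        source=source,
        q_auto=q_auto,
        q_x=q_x,
    )
    return g, bk


def simulate_diversity_cohort(
    n_before: int,
    n_after: int,
    n_snps: int,
    mismatch_gap: float = 0.0,
    missing_rate: float = 0.0,
    cutoff_bce: float = 2700.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[IndividualRecord]]:
    """Two burial periods with a controlled expected-mismatch difference.

    Individuals dated before the cutoff draw pseudo-haploid calls from a
    frequency pool ``p``; individuals after the cutoff from the pool shrunk
    towards 0.5, ``p' = 0.5 + c (p - 0.5)``, with ``c`` solved so that the
    expected pairwise mismatch rate (mean over SNPs of 2 f (1 - f)) is
    exactly ``mismatch_gap`` higher after the cutoff.  ``mismatch_gap=0``
    gives one shared pool — the exchangeable null for calibration tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"diversity")]))
    p = rng.uniform(0.1, 0.9, size=n_snps)
    if mismatch_gap > 0:
        spread = float(np.mean((p - 0.5) ** 2))
        c2 = 1.0 - mismatch_gap / (2.0 * spread)
        if not 0.0 <= c2 <= 1.0:
            raise ValueError(f"mismatch_gap {mismatch_gap} unattainable for this pool")
        p_after = 0.5 + np.sqrt(c2) * (p - 0.5)
    else:
        p_after = p

    n = n_before + n_after
    pools = np.vstack([np.tile(p, (n_before, 1)), np.tile(p_after, (n_after, 1))])
    calls = (rng.random((n, n_snps)) < pools).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, n_snps)) < missing_rate] = MISSING
    snps = _synthetic_snp_table(rng, n_snps, 0)
    ids = [f"B{k:03d}" for k in range(n_before)] + [f"A{k:03d}" for k in range(n_after)]
    g = GenotypeMatrix(individuals=ids, snps=snps, calls=calls)
    records = []
    for k, ind_id in enumerate(ids):
        mid = cutoff_bce + 300.0 if k < n_before else cutoff_bce - 300.0
        records.append(
            IndividualRecord(
                id=ind_id,
                sex="unknown",
                site=f"Site{k % 3}",
                region="Synthetic",
                date=RadiocarbonInterval(upper_bce=mid + 50.0, lower_bce=mid - 50.0),
            )
        )
    return g, records


def simulate_pool_individuals(
    pool: np.ndarray,
    n: int,
    id_prefix: str,
    rng: np.random.Generator,
    snp_table: pd.DataFrame | None = None,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Pseudo-haploid individuals drawn directly from one frequency pool."""
    pool = np.asarray(pool, dtype=float)
    m = len(pool)
    if snp_table is None:
        snp_table = _synthetic_snp_table(rng, m, 0)
    if len(snp_table) != m:
        raise ValueError("snp_table length must match pool length")
    calls = (rng.random((n, m)) < pool[None, :]).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, m)) < missing_rate] = MISSING
    ids = [f"{id_prefix}{k:03d}" for k in range(n)]
    return GenotypeMatrix(individuals=ids, snps=snp_table, calls=calls)


def concat_individuals(*matrices: GenotypeMatrix) -> GenotypeMatrix:
    """Stack matrices sharing one SNP table into a single cohort matrix."""
    first = matrices[0]
    for g in matrices[1:]:
        if not first.snps.equals(g.snps):
            raise ValueError("matrices must share an identical SNP table")
    ids = [i for g in matrices for i in g.individuals]
    calls = np.concatenate([g.calls for g in matrices], axis=0)
    return GenotypeMatrix(individuals=ids, snps=first.snps, calls=calls)


def simulate_drifted_populations(
    sizes: Mapping[str, int],
    fsts: Mapping[str, float],
    n_snps: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    admixture: Mapping[str, tuple[str, float]] | None = None,
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Several populations drifting independently from one ancestral pool.

    Each population's frequency pool is a Balding-Nichols draw from shared
    Uniform(0.05, 0.95) ancestral frequencies at its own FST.  ``admixture``
    optionally replaces a recipient pool by a mixture: ``{"X": ("Y", 0.3)}``
    makes X's pool 70% its own drifted pool and 30% Y's (gene flow Y -> X).
    Returns the combined pseudo-haploid matrix (population recorded per
    individual) and the final per-population pools.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"pops")]))
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    pools = {
        name: _balding_nichols(rng, ancestral, float(fsts[name])) for name in sizes
    }
    if admixture:
        mixed = {}
        for recipient, (donor, alpha) in admixture.items():
            mixed[recipient] = (1.0 - alpha) * pools[recipient] + alpha * pools[donor]
        pools.update(mixed)
    snp_table = _synthetic_snp_table(rng, n_snps, 0)
    parts = []
    pop_labels: list[str] = []
    for name, n in sizes.items():
        part = simulate_pool_individuals(
            pools[name], n, f"{name}_", rng, snp_table=snp_table, missing_rate=missing_rate
        )
        parts.append(part)
        pop_labels.extend([name] * n)
    g = concat_individuals(*parts)
    g.populations = pop_labels
    return g, pools


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeSpec:
    """An acyclic parent map with sexes.

    ``sexes`` maps every member to 'female'/'male'; ``parents`` maps
    non-founder ids to (father, mother); ``clones`` maps an id to the member
    whose genome it duplicates (identical twins).
    """

    sexes: Mapping[str, str]
    parents: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    clones: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, (father, mother) in self.parents.items():
            for p in (father, mother):
                if p not in self.sexes:
                    raise ValueError(f"parent {p!r} of {child!r} has no sex entry")
            if self.sexes[father] != "male":
                raise ValueError(f"father {father!r} of {child!r} is not male")
            if self.sexes[mother] != "female":
                raise ValueError(f"mother {mother!r} of {child!r} is not female")
        for twin, src in self.clones.items():
            if src not in self.sexes:
                raise ValueError(f"clone source {src!r} unknown")
            if twin in self.parents:
                raise ValueError(f"clone {twin!r} cannot also have parents")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if node in stack:
                raise ValueError(f"pedigree cycle through {node!r}")
            if state.get(node) == 2:
                return
            for dep in self.parents.get(node, ()):  # parents first
                visit(dep, stack + (node,))
            if node in self.clones:
                visit(self.clones[node], stack + (node,))
            state[node] = 2
            order.append(node)

        for member in self.sexes:
            visit(member, ())
        return order

    @property
    def founders(self) -> list[str]:
        return [
            m for m in self.sexes if m not in self.parents and m not in self.clones
        ]


@dataclass(frozen=True)
class PedigreeSim:
    genotypes: GenotypeMatrix
    truth_degrees: dict[frozenset[str], str]
    mt_labels: dict[str, str]
    y_labels: dict[str, str | None]
    records: list[IndividualRecord]
    diploid: dict[str, np.ndarray]


def kinship_coefficient(spec: PedigreeSpec) -> dict[tuple[str, str], float]:
    """Exact kinship coefficients phi by the standard recursive algorithm."""
    order = spec.topological_order()
    depth = {m: k for k, m in enumerate(order)}

    def resolve(m: str) -> str:
        while m in spec.clones:
            m = spec.clones[m]
        return m

    phi: dict[frozenset[str], float] = {}

    def get(a: str, b: str) -> float:
        a, b = resolve(a), resolve(b)
        if a == b:
            return 0.5
        key = frozenset((a, b))
        if key in phi:
            return phi[key]
        # recurse on the later-born member (its parents are earlier)
        x, y = (a, b) if depth[a] >= depth[b] else (b, a)
        if x in spec.parents:
            f, m = spec.parents[x]
            val = 0.5 * (get(y, f) + get(y, m))
        else:
            val = 0.0
        phi[key] = val
        return val

    out: dict[tuple[str, str], float] = {}
    members = list(spec.sexes)
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            out[(a, b)] = get(a, b)
    return out


def true_degree(phi: float, clone: bool = False) -> str:
    """Relatedness degree from a kinship coefficient (KING-style cutoffs)."""
    if clone or phi > 0.354:
        return "identical"
    if phi > 0.177:
        return "first"
    if phi > 0.0884:
        return "second"
    return "unrelated"


def three_generation_pedigree(n_unrelated: int = 6) -> PedigreeSpec:
    """A three-generation family plus unrelated individuals.

    Grandparents GF/GM, their children F (married into U-M) and AUNT, and
    grandchildren S (son) and D (daughter); ``n_unrelated`` extra singletons
    provide the unrelated baseline the normalisation needs.
    """
    sexes = {
        "GF": "male",
        "GM": "female",
        "F": "male",
        "AUNT": "female",
        "M": "female",
        "S": "male",
        "D": "female",
    }
    parents = {
        "F": ("GF", "GM"),
        "AUNT": ("GF", "GM"),
        "S": ("F", "M"),
        "D": ("F", "M"),
    }
    for k in range(n_unrelated):
        sexes[f"U{k}"] = "male" if k % 2 else "female"
    return PedigreeSpec(sexes=sexes, parents=parents)


def simulate_pedigree(
    founder_pool: np.ndarray,
    structure: PedigreeSpec,
    n_snps: int | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PedigreeSim:
    """Mendelian transmission through a pedigree with a pseudo-haploid layer.

    Founders draw diploid genotypes from ``founder_pool`` allele frequencies
    under Hardy-Weinberg; each child inherits, independently per SNP, one
    random allele from each parent's diploid genotype; clones copy their
    source's diploid genome.  The observed pseudo-haploid call samples one of
    the two alleles per individual per SNP, then missingness is applied.
    mtDNA labels follow the maternal line and Y labels the paternal line.
    """
    founder_pool = np.asarray(founder_pool, dtype=float)
    if n_snps is None:
        n_snps = len(founder_pool)
    if len(founder_pool) != n_snps:
        raise ValueError("founder_pool length must equal n_snps")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"pedigree")]))

    order = structure.topological_order()
    diploid: dict[str, np.ndarray] = {}
    mt: dict[str, str] = {}
    y: dict[str, str | None] = {}
    founder_count = 0
    for member in order:
        if member in structure.clones:
            src = structure.clones[member]
            diploid[member] = diploid[src].copy()
            mt[member] = mt[src]
            y[member] = y[src] if structure.sexes[member] == "male" else None
        elif member in structure.parents:
            father, mother = structure.parents[member]
            gametes = []
            for parent in (father, mother):
                pick = rng.integers(0, 2, size=n_snps)
                gametes.append(diploid[parent][np.arange(n_snps), pick])
            diploid[member] = np.stack(gametes, axis=1)  # (snp, 2): paternal, maternal
            mt[member] = mt[mother]
            y[member] = y[father] if structure.sexes[member] == "male" else None
        else:
            founder_count += 1
            diploid[member] = (
                rng.random((n_snps, 2)) < founder_pool[:, None]
            ).astype(np.int8)
            mt[member] = f"mt{founder_count:02d}"
            y[member] = (
                f"y{founder_count:02d}" if structure.sexes[member] == "male" else None
            )

    members = list(structure.sexes)
    calls = np.empty((len(members), n_snps), dtype=np.int8)
    for k, member in enumerate(members):
        pick = rng.integers(0, 2, size=n_snps)
        calls[k] = diploid[member][np.arange(n_snps), pick]
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING

    snp_rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"pedigree-snps")]))
    snps = _synthetic_snp_table(snp_rng, n_snps, 0)
    g = GenotypeMatrix(individuals=members, snps=snps, calls=calls)

    phi = kinship_coefficient(structure)

    def is_clone_pair(a: str, b: str) -> bool:
        def root(m: str) -> str:
            while m in structure.clones:
                m = structure.clones[m]
            return m

        return root(a) == root(b)

    truth = {
        frozenset((a, b)): true_degree(v, clone=is_clone_pair(a, b))
        for (a, b), v in phi.items()
    }

    records = [
        IndividualRecord(
            id=m,
            sex=structure.sexes[m],
            site="PedigreeSite",
            region="Synthetic",
            date=RadiocarbonInterval(upper_bce=3000.0, lower_bce=2800.0),
            mt_label=mt[m],
            y_label=y[m],
        )
        for m in members
    ]
    return PedigreeSim(
        genotypes=g,
        truth_degrees=truth,
        mt_labels=mt,
        y_labels=y,
        records=records,
        diploid=diploid,
    )
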