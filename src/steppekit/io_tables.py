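"""Readers/writers for EIGENSTRAT genotypes and cohort metadata tables.

The on-disk formats are the ones standard in ancient-DNA work:

* EIGENSTRAT triplets ``prefix.geno`` / ``prefix.snp`` / ``prefix.ind`` holding
  pseudo-haploid genotype calls for a panel of SNPs.  Two coding dialects
  circulate for pseudo-haploid data: *haploid* coding ``{0 = ref, 1 = derived,
  9 = missing}`` and *diploid* coding ``{0 = ref/ref, 2 = derived "homozygote",
  9 = missing}`` in which a pseudo-haploid call is stored as a homozygote and
  the value ``1`` (a true heterozygote) must never occur.
* A metadata TSV (one dated individual per row) and an ancestry TSV carrying
  per-individual steppe-ancestry proportions as estimated upstream by
  qpAdm-style admixture modelling.

Dates are calibrated radiocarbon years BCE (calBCE), positive and increasing
into the past; CE dates are represented as negative calBCE values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "RadiocarbonInterval",
    "IndividualRecord",
    "AncestryObservation",
    "GenotypeMatrix",
    "FormatError",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_cohort",
    "write_cohort",
    "META_COLUMNS",
    "ANCESTRY_COLUMNS",
]

#: sentinel for a missing pseudo-haploid call in the in-memory int8 matrix
MISSING: int = -1

META_COLUMNS = [
    "id",
    "sex",
    "site",
    "region",
    "upper_bce",
    "lower_bce",
    "mt_label",
    "y_label",
]
ANCESTRY_COLUMNS = ["id", "steppe_prop", "se"]

_SEXES = ("female", "male", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class RadiocarbonInterval:
    """A calibrated radiocarbon date range, interpreted as a 95% interval.

    ``upper_bce`` is the older bound, ``lower_bce`` the younger one; both in
    calBCE (positive into the past, negative values denote CE dates).
    """

    upper_bce: float
    lower_bce: float

    def __post_init__(self) -> None:
        if self.upper_bce < self.lower_bce:
            raise ValueError(
                f"interval upper bound {self.upper_bce} calBCE is younger than "
                f"lower bound {self.lower_bce} calBCE"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.upper_bce + self.lower_bce)

    @property
    def width(self) -> float:
        return self.upper_bce - self.lower_bce

    def contains(self, year_bce: float) -> bool:
        return self.lower_bce <= year_bce <= self.upper_bce

    @property
    def is_ce(self) -> bool:
        """True when any part of the interval falls in the common era."""
        return self.lower_bce < 0


@dataclass(frozen=True)
class IndividualRecord:
    """One dated ancient individual with sex, site and uniparental labels."""

    id: str
    sex: str
    site: str
    region: str
    date: RadiocarbonInterval
    mt_label: str | None = None
    y_label: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.sex == "female" and self.y_label is not None:
            raise ValueError(
                f"individual {self.id}: genetic females carry no Y haplogroup "
                f"label (got {self.y_label!r})"
            )


@dataclass(frozen=True)
class AncestryObservation:
    """Per-individual steppe-ancestry proportion (qpAdm-style point estimate)."""

    id: str
    steppe_prop: float
    se: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.steppe_prop <= 1.0:
            raise ValueError(
                f"individual {self.id}: steppe proportion {self.steppe_prop} "
                "outside [0, 1]"
            )
        if self.se is not None and self.se < 0:
            raise ValueError(f"individual {self.id}: negative SE {self.se}")


class GenotypeMatrix:
    """Pseudo-haploid genotype calls for individuals x SNPs.

    ``calls`` is an int8 array with 0 = reference allele, 1 = derived
    (alternative) allele and ``MISSING`` (-1) = no call.  Calls are haploid by
    construction — a heterozygote cannot be represented.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        snps: pd.DataFrame,
        calls: np.ndarray,
        populations: Sequence[str] | None = None,
    ) -> None:
        required = {"snp_id", "chrom", "pos", "ref", "alt"}
        missing_cols = required - set(snps.columns)
        if missing_cols:
            raise ValueError(f"snp table lacks columns {sorted(missing_cols)}")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape != (len(individuals), len(snps)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(individuals)} individuals x {len(snps)} SNPs"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1))
        if bad.any():
            raise ValueError(
                f"calls contain values outside {{0, 1, missing}}: "
                f"{np.unique(calls[bad])}"
            )
        ids = list(individuals)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        self.individuals: list[str] = ids
        self.snps = snps.reset_index(drop=True)
        self.calls = calls
        self.populations = list(populations) if populations is not None else None

    # -- basic queries -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def is_x(self) -> np.ndarray:
        """Boolean mask over SNPs: True for X-chromosome sites."""
        return (self.snps["chrom"].astype(str) == "X").to_numpy()

    @property
    def is_autosomal(self) -> np.ndarray:
        return ~self.is_x

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.individuals,
            self.snps.loc[mask].reset_index(drop=True),
            self.calls[:, mask],
            populations=self.populations,
        )

    def index_of(self, individual_id: str) -> int:
        return self.individuals.index(individual_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.snps.equals(other.snps)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

_SEX_TO_IND = {"female": "F", "male": "M", "unknown": "U"}
_IND_TO_SEX = {"F": "female", "M": "male", "U": "unknown"}


def _detect_dialect(geno_lines: Iterable[str], scan_limit: int = 100) -> str:
    """Auto-detect the geno coding dialect.

    Pseudo-haploid data stored in diploid coding uses only ``{0, 2, 9}``, so
    any ``1`` marks a haploid-coded file.  If no ``1`` is seen among at least
    ``scan_limit`` non-missing values (or the whole file, whichever comes
    first) but a ``2`` is present, the file is diploid-coded.  A file holding
    only ``{0, 9}`` reads identically under both dialects.
    """
    seen_nonmissing = 0
    seen_two = False
    for line in geno_lines:
        for ch in line.strip():
            if ch == "1":
                return "haploid"
            if ch == "2":
                seen_two = True
            if ch != "9":
                seen_nonmissing += 1
        if seen_two and seen_nonmissing > scan_limit:
            break
    return "diploid" if seen_two else "haploid"


def read_eigenstrat(prefix: str | os.PathLike, dialect: str = "auto") -> GenotypeMatrix:
    """Read an EIGENSTRAT triplet into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    prefix:
        Path prefix; ``prefix.geno``, ``prefix.snp`` and ``prefix.ind`` must
        exist.
    dialect:
        ``"haploid"`` (values 0/1/9), ``"diploid"`` (0/2/9, pseudo-haploid
        stored as homozygotes) or ``"auto"`` to detect from the data.

    Raises
    ------
    FormatError
        On dimension mismatches between the three files, on characters outside
        the dialect's alphabet, and in particular on a ``1`` (heterozygote) in
        a diploid-coded file, which cannot occur in pseudo-haploid data.
    """
    prefix = os.fspath(prefix)
    with open(prefix + ".geno") as fh:
        geno_lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    snp = pd.read_csv(
        prefix + ".snp",
        sep=r"\s+",
        header=None,
        names=["snp_id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"snp_id": str, "chrom": str, "ref": str, "alt": str},
    )
    ind = pd.read_csv(
        prefix + ".ind",
        sep=r"\s+",
        header=None,
        names=["id", "sex", "pop"],
        dtype=str,
    )

    if len(geno_lines) != len(snp):
        raise FormatError(
            f"{prefix}.geno has {len(geno_lines)} SNP rows but {prefix}.snp "
            f"lists {len(snp)} SNPs"
        )
    n_ind = len(ind)
    widths = {len(ln) for ln in geno_lines}
    if widths and widths != {n_ind}:
        raise FormatError(
            f"{prefix}.geno row widths {sorted(widths)} do not match the "
            f"{n_ind} individuals in {prefix}.ind"
        )

    if dialect == "auto":
        dialect = _detect_dialect(geno_lines)
    if dialect not in ("haploid", "diploid"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if geno_lines:
        raw = np.frombuffer(
            "".join(geno_lines).encode("ascii"), dtype=np.uint8
        ).reshape(len(geno_lines), n_ind) - ord("0")
    else:
        raw = np.zeros((0, n_ind), dtype=np.uint8)

    derived_code = 1 if dialect == "haploid" else 2
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    calls[raw == 0] = 0
    calls[raw == derived_code] = 1
    valid = (raw == 0) | (raw == derived_code) | (raw == 9)
    if not valid.all():
        offending = sorted(int(v) for v in np.unique(raw[~valid]))
        if dialect == "diploid" and 1 in offending:
            raise FormatError(
                f"{prefix}.geno is diploid-coded but contains a heterozygote "
                "call '1'; pseudo-haploid data cannot be heterozygous"
            )
        raise FormatError(
            f"{prefix}.geno contains invalid codes {offending} for the "
            f"{dialect} dialect"
        )

    chrom = snp["chrom"].astype(str).str.replace(r"\.0$", "", regex=True)
    chrom = chrom.where(chrom != "23", "X")
    snp_table = pd.DataFrame(
        {
            "snp_id": snp["snp_id"].astype(str),
            "chrom": chrom,
            "pos": snp["pos"].astype(np.int64),
            "ref": snp["ref"].astype(str),
            "alt": snp["alt"].astype(str),
        }
    )
    return GenotypeMatrix(
        individuals=list(ind["id"]),
        snps=snp_table,
        calls=calls.T,  # file is SNP-major, matrix is individual-major
        populations=list(ind["pop"]),
    )


def write_eigenstrat(
    g: GenotypeMatrix, prefix: str | os.PathLike, dialect: str = "haploid"
) -> None:
    """Write ``prefix.geno/.snp/.ind`` (SNP-major geno, X encoded as 23)."""
    if dialect not in ("haploid", "diploid"):
        raise ValueError(f"unknown dialect {dialect!r}")
    prefix = os.fspath(prefix)
    derived_char = "1" if dialect == "haploid" else "2"
    lut = {0: "0", 1: derived_char, MISSING: "9"}

    snp_major = g.calls.T
    with open(prefix + ".geno", "w") as fh:
        for row in snp_major:
            fh.write("".join(lut[int(v)] for v in row))
            fh.write("\n")

    chrom_out = g.snps["chrom"].astype(str).where(
        g.snps["chrom"].astype(str) != "X", "23"
    )
    snp_df = pd.DataFrame(
        {
            "snp_id": g.snps["snp_id"],
            "chrom": chrom_out,
            "gpos": 0.0,
            "pos": g.snps["pos"],
            "ref": g.snps["ref"],
            "alt": g.snps["alt"],
        }
    )
    with open(prefix + ".snp", "w") as fh:
        for row in snp_df.itertuples(index=False):
            fh.write(
                f"{row.snp_id}\t{row.chrom}\t{row.gpos:.6f}\t{row.pos}\t"
                f"{row.ref}\t{row.alt}\n"
            )

    pops = g.populations if g.populations is not None else ["Pop"] * g.n_individuals
    with open(prefix + ".ind", "w") as fh:
        for ind_id, pop in zip(g.individuals, pops):
            fh.write(f"{ind_id}\tU\t{pop}\n")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def _parse_optional(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s and s != "." else None


def read_cohort(
    meta_path: str | os.PathLike, ancestry_path: str | os.PathLike
) -> tuple[list[IndividualRecord], dict[str, AncestryObservation]]:
    """Read the metadata and ancestry TSVs and join them on individual id.

    Individuals without an ancestry row are retained without an observation.
    Validation errors (duplicate ids, proportions outside [0, 1], inverted
    date intervals, ancestry rows for unknown individuals) raise
    :class:`FormatError`.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    if list(meta.columns) != META_COLUMNS:
        raise FormatError(
            f"metadata columns {list(meta.columns)} != expected {META_COLUMNS}"
        )
    if meta["id"].duplicated().any():
        dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise FormatError(f"duplicate individual ids in metadata: {dups}")

    records: list[IndividualRecord] = []
    for row in meta.itertuples(index=False):
        try:
            interval = RadiocarbonInterval(
                upper_bce=float(row.upper_bce), lower_bce=float(row.lower_bce)
            )
            rec = IndividualRecord(
                id=row.id,
                sex=row.sex,
                site=row.site,
                region=row.region,
                date=interval,
                mt_label=_parse_optional(row.mt_label),
                y_label=_parse_optional(row.y_label),
            )
        except ValueError as exc:
            raise FormatError(f"metadata row for {row.id!r}: {exc}") from exc
        records.append(rec)
    known = {r.id for r in records}

    ancestry = pd.read_csv(ancestry_path, sep="\t", dtype=str, keep_default_na=False)
    if list(ancestry.columns) != ANCESTRY_COLUMNS:
        raise FormatError(
            f"ancestry columns {list(ancestry.columns)} != expected "
            f"{ANCESTRY_COLUMNS}"
        )
    observations: dict[str, AncestryObservation] = {}
    for row in ancestry.itertuples(index=False):
        if row.id in observations:
            raise FormatError(f"duplicate ancestry row for {row.id!r}")
        if row.id not in known:
            raise FormatError(f"ancestry row for unknown individual {row.id!r}")
        se_str = _parse_optional(row.se)
        try:
            obs = AncestryObservation(
                id=row.id,
                steppe_prop=float(row.steppe_prop),
                se=float(se_str) if se_str is not None else None,
            )
        except ValueError as exc:
            raise FormatError(f"ancestry row for {row.id!r}: {exc}") from exc
        observations[row.id] = obs
    return records, observations


def write_cohort(
    records: Sequence[IndividualRecord],
    observations: Mapping[str, AncestryObservation],
    meta_path: str | os.PathLike,
    ancestry_path: str | os.PathLike,
) -> None:
    """Write the two TSVs :func:`read_cohort` reads, preserving order."""

    def fmt(x: float) -> str:
        return repr(float(x))

    with open(meta_path, "w") as fh:
        fh.write("\t".join(META_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.sex,
                        r.site,
                        r.region,
                        fmt(r.date.upper_bce),
                        fmt(r.date.lower_bce),
                        r.mt_label or "",
                        r.y_label or "",
                    ]
                )
                + "\n"
            )
    with open(ancestry_path, "w") as fh:
        fh.write("\t".join(ANCESTRY_COLUMNS) + "\n")
        for r in records:
            if r.id not in observations:
                continue
            obs = observations[r.id]
            fh.write(
                "\t".join(
                    [obs.id, fmt(obs.steppe_prop), fmt(obs.se) if obs.se is not None else ""]
                )
                + "\n"
            )
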