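"""GWAS summary-statistic containers, validation, and text I/O.

Summary statistics are one variant per row with the fields a two-sample MR
analysis needs: rsID, chromosome, 1-based position, effect/other allele,
effect-allele frequency, beta, SE, p-value, sample size and (for binary
traits) case/control counts.  Files are tab-separated text, transparently
gzipped when the path ends in ``.gz``.  Coordinates are 1-based and all
intervals in this package are fully closed.

Only single-nucleotide A/C/G/T alleles are accepted; indels and multi-allelic
records are rejected by validation.  Genome build is carried as opaque
metadata — callers are responsible for feeding consistent builds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

#: canonical column order for written sumstats files
SUMSTAT_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case", "n_control",
]

#: shipped column-name presets for common sumstats layouts
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "default": {c: c for c in SUMSTAT_COLUMNS},
    "decode": {
        "rsid": "rsids", "chrom": "Chrom", "pos": "Pos",
        "effect_allele": "effectAllele", "other_allele": "otherAllele",
        "eaf": "ImpMAF", "beta": "Beta", "se": "SE", "pval": "Pval", "n": "N",
    },
    "ukb_ppp": {
        "rsid": "ID", "chrom": "CHROM", "pos": "GENPOS",
        "effect_allele": "ALLELE1", "other_allele": "ALLELE0",
        "eaf": "A1FREQ", "beta": "BETA", "se": "SE", "pval": "P", "n": "N",
    },
    "finngen": {
        "rsid": "rsids", "chrom": "#chrom", "pos": "pos",
        "effect_allele": "alt", "other_allele": "ref",
        "eaf": "af_alt", "beta": "beta", "se": "sebeta", "pval": "pval",
        "n": "n", "n_case": "n_cases", "n_control": "n_controls",
    },
}

MANDATORY_FIELDS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


class SumstatsError(Exception):
    """Base error for summary-statistic I/O and validation."""


class ConfigurationError(SumstatsError):
    """A column map or configuration value is unusable."""


class InputError(SumstatsError):
    """An input file is empty or structurally malformed."""


class FormatError(SumstatsError):
    """A structured input (e.g. an LD matrix) violates its format contract."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic SNP: rsID, locus and allele pair."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            raise ValueError(f"{self.rsid}: alleles must be single-nucleotide A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1 (1-based)")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, where strand cannot be read off the alleles."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's summary association with one trait.

    ``beta`` is per copy of the effect allele: SD units for quantitative
    traits, log-odds for binary ones.
    """

    variant: VariantKey
    beta: float
    se: float
    pval: float
    eaf: float
    n: float
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.rsid}: eaf must be in (0, 1)")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.rsid}: pval must be in (0, 1]")
        if not self.n > 0:
            raise ValueError(f"{self.rsid}: n must be > 0")
        if self.n_case is not None and self.n_control is not None:
            if not math.isclose(self.n_case + self.n_control, self.n, rel_tol=1e-9):
                raise ValueError(f"{self.rsid}: n_case + n_control != n")

    @property
    def rsid(self) -> str:
        return self.variant.rsid

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def z(self) -> float:
        return self.beta / self.se

    def replace(self, **kw) -> "AssociationRecord":
        return dataclasses.replace(self, **kw)


@dataclass
class DropReport:
    """Accounting of rows excluded by validation; counts always add up."""

    n_input: int = 0
    n_kept: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.reasons.values())

    def drop(self, reason: str) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


@dataclass
class SummaryStatSet:
    """A validated set of association records for one trait.

    rsIDs are unique within the set; duplicate rows beyond the first are
    dropped at construction.
    """

    trait_id: str
    trait_type: str = "quantitative"  # quantitative | binary
    platform: str = ""
    build: str = "unknown"
    records: dict[str, AssociationRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __iter__(self):
        return iter(self.records.values())

    def get(self, rsid: str) -> AssociationRecord | None:
        return self.records.get(rsid)

    def add(self, rec: AssociationRecord) -> bool:
        if rec.rsid in self.records:
            return False
        self.records[rec.rsid] = rec
        return True

    def subset(self, rsids: Iterable[str]) -> "SummaryStatSet":
        keep = {r: self.records[r] for r in rsids if r in self.records}
        return SummaryStatSet(self.trait_id, self.trait_type, self.platform, self.build, keep)

    def in_window(self, chrom: str, start: int, end: int) -> "SummaryStatSet":
        """Records with start <= pos <= end on ``chrom`` (closed interval)."""
        keep = {
            r: rec for r, rec in self.records.items()
            if rec.variant.chrom == chrom and start <= rec.variant.pos <= end
        }
        return SummaryStatSet(self.trait_id, self.trait_type, self.platform, self.build, keep)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            v = rec.variant
            rows.append({
                "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
                "effect_allele": v.effect_allele, "other_allele": v.other_allele,
                "eaf": rec.eaf, "beta": rec.beta, "se": rec.se, "pval": rec.pval,
                "n": rec.n, "n_case": rec.n_case, "n_control": rec.n_control,
            })
        df = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
        return df


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's symbol, chromosome, and transcription start site (1-based)."""

    gene_symbol: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_symbol}: tss must be >= 1")


@dataclass
class LDMatrix:
    """Square matrix of pairwise LD correlation r, with rsIDs and positions."""

    rsids: list[str]
    r: np.ndarray
    positions: list[int]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.rsids)
        if self.r.shape != (m, m):
            raise FormatError(f"LD matrix shape {self.r.shape} does not match {m} rsids")
        if len(self.positions) != m:
            raise FormatError("positions must align with rsids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise FormatError("LD matrix is asymmetric beyond tolerance 1e-8")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise FormatError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise FormatError("LD matrix entries must satisfy |r| <= 1")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def r_between(self, rsid_a: str, rsid_b: str) -> float | None:
        """Signed r between two variants, or None if either is missing."""
        ia = self._index.get(rsid_a)
        ib = self._index.get(rsid_b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib])

    def r2_between(self, rsid_a: str, rsid_b: str) -> float | None:
        r = self.r_between(rsid_a, rsid_b)
        return None if r is None else r * r

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _float_or_nan(x) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | str = "default",
    trait_id: str = "trait",
    trait_type: str = "quantitative",
    platform: str = "",
    build: str = "unknown",
    check_z_consistency: bool = False,
    z_tolerance: float = 0.10,
) -> tuple[SummaryStatSet, DropReport]:
    """Read a delimited sumstats file into a validated :class:`SummaryStatSet`.

    ``column_map`` maps canonical field names to source column names, or names
    a shipped preset ("default", "decode", "ukb_ppp", "finngen").  Rows
    violating record invariants are dropped and counted in the report rather
    than raising.  ``check_z_consistency`` optionally drops rows where
    |beta/se| disagrees with the z implied by the p-value by more than
    ``z_tolerance`` (relative) — off by default because LMM-derived p-values
    need not match the Wald z exactly.
    """
    if isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise ConfigurationError(f"unknown column preset {column_map!r}") from None
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty sumstats file") from None
    missing = [f for f in MANDATORY_FIELDS if column_map.get(f) not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns for fields {missing}")

    report = DropReport(n_input=len(df))
    sset = SummaryStatSet(trait_id, trait_type, platform, build)
    from scipy import stats as _st

    has_cc = (
        column_map.get("n_case") in df.columns
        and column_map.get("n_control") in df.columns
    )
    for _, row in df.iterrows():
        try:
            variant = VariantKey(
                rsid=str(row[column_map["rsid"]]),
                chrom=str(row[column_map["chrom"]]),
                pos=int(float(row[column_map["pos"]])),
                effect_allele=str(row[column_map["effect_allele"]]).upper(),
                other_allele=str(row[column_map["other_allele"]]).upper(),
            )
            kwargs = {}
            if has_cc:
                nc = _float_or_nan(row[column_map["n_case"]])
                nco = _float_or_nan(row[column_map["n_control"]])
                if not (math.isnan(nc) or math.isnan(nco)):
                    kwargs = {"n_case": nc, "n_control": nco}
            rec = AssociationRecord(
                variant=variant,
                beta=float(row[column_map["beta"]]),
                se=float(row[column_map["se"]]),
                pval=float(row[column_map["pval"]]),
                eaf=float(row[column_map["eaf"]]),
                n=float(row[column_map["n"]]),
                **kwargs,
            )
        except (ValueError, TypeError) as exc:
            report.drop(f"invalid: {exc.__class__.__name__}")
            continue
        if check_z_consistency and rec.pval < 1:
            z_p = float(_st.norm.isf(rec.pval / 2.0))
            if z_p > 0 and abs(abs(rec.z) - z_p) > z_tolerance * z_p:
                report.drop("z_p_mismatch")
                continue
        if not sset.add(rec):
            report.drop("duplicate_rsid")
            continue
        report.n_kept += 1
    return sset, report


def write_sumstats(sset: SummaryStatSet, path) -> None:
    """Write a sumstats TSV with fixed column order.

    Floats are written in shortest round-trip representation, so
    write→read→write is byte-identical and values survive exactly.
    """
    df = sset.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_annotations(path) -> dict[str, GeneAnnotation]:
    """Read a 3-column TSV (gene_symbol, chrom, tss) of gene annotations."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "chrom": str, "tss": int})
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty annotation file") from None
    for col in ("gene_symbol", "chrom", "tss"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing annotation column {col!r}")
    return {
        str(r.gene_symbol): GeneAnnotation(str(r.gene_symbol), str(r.chrom), int(r.tss))
        for r in df.itertuples()
    }


def write_gene_annotations(genes: Mapping[str, GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [{"gene_symbol": g.gene_symbol, "chrom": g.chrom, "tss": g.tss} for g in genes.values()]
    )
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path, positions: Iterable[int] | None = None) -> LDMatrix:
    """Read a labelled square LD-r TSV (rsids as header row and index column).

    Positions may be encoded in the rsid labels as ``rsid:pos``; otherwise
    pass them explicitly (defaults to 1..m if unavailable).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty LD file") from None
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square ({df.shape})")
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise FormatError(f"{path}: LD row and column labels disagree")
    if all(":" in lb for lb in labels):
        rsids = [lb.rsplit(":", 1)[0] for lb in labels]
        pos = [int(lb.rsplit(":", 1)[1]) for lb in labels]
    else:
        rsids = labels
        pos = list(positions) if positions is not None else list(range(1, len(labels) + 1))
    return LDMatrix(rsids=rsids, r=df.to_numpy(dtype=float), positions=pos)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    labels = [f"{rs}:{p}" for rs, p in zip(ld.rsids, ld.positions)]
    df = pd.DataFrame(ld.r, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.12g")


def ld_from_haplotypes(
    panel: np.ndarray, rsids: list[str], positions: list[int]
) -> LDMatrix:
    """Empirical LD-r matrix from a 0/1 haplotype panel (rows = haplotypes).

    Monomorphic columns get r = 0 off-diagonal (undefined correlation).
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2 or panel.shape[1] != len(rsids):
        raise FormatError("panel columns must align with rsids")
    sd = panel.std(axis=0)
    ok = sd > 0
    r = np.eye(panel.shape[1])
    if ok.any():
        sub = np.corrcoef(panel[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.where(ok)[0]
        r[np.ix_(idx, idx)] = sub
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return LDMatrix(rsids=list(rsids), r=r, positions=list(positions))
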