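"""Domain data model, HLA/KIR nomenclature parsing and cohort table I/O.

The central objects are :class:`SubjectRecord` (one typed individual: KIR gene
content plus HLA class-I typing reduced to KIR-ligand epitope flags) and
:class:`PairRecord` (a donor/recipient transplant pair with clinical
covariates and competing-risks outcome).

Cohort files are UTF-8 TSV/CSV with one row per pair; see
:func:`read_cohort` for the column contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "KIR_GENES",
    "KIR_PSEUDOGENES",
    "KIR_LOCI",
    "CEN_B_GENES",
    "TEL_B_GENES",
    "A_HAPLOTYPE_GENES",
    "HLAAllele",
    "KIRGenotype",
    "HLATyping",
    "LigandProfile",
    "SubjectRecord",
    "PairRecord",
    "OutcomeRecord",
    "CohortParseError",
    "parse_hla_allele",
    "read_cohort",
    "write_cohort",
    "allele_frequencies",
    "round_half_up",
]

#: The 15 KIR genes tracked per subject.
KIR_GENES = (
    "KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR2DL4", "KIR2DL5A", "KIR2DL5B",
    "KIR2DS1", "KIR2DS2", "KIR2DS3", "KIR2DS4", "KIR2DS5",
    "KIR3DL1", "KIR3DS1", "KIR3DL2", "KIR3DL3",
)

#: Two pseudogenes typed alongside the expressed genes.
KIR_PSEUDOGENES = ("KIR2DP1", "KIR3DP1")

#: All 17 loci a complete genotype must report.
KIR_LOCI = KIR_GENES + KIR_PSEUDOGENES

#: Genes whose presence defines a centromeric B motif.
CEN_B_GENES = ("KIR2DS2", "KIR2DL2", "KIR2DL5B", "KIR2DS3")

#: Genes whose presence defines a telomeric B motif.
TEL_B_GENES = ("KIR3DS1", "KIR2DL5A", "KIR2DS5", "KIR2DS1")

#: Gene content of the canonical A haplotype (plus the two pseudogenes).
A_HAPLOTYPE_GENES = (
    "KIR3DL3", "KIR2DL3", "KIR2DL1", "KIR2DL4", "KIR3DL1", "KIR2DS4", "KIR3DL2",
)

#: Loci with optional allele-level (high-resolution) typing.
ALLELE_TYPED_LOCI = ("KIR3DL1", "KIR2DL1", "KIR2DL3")


class CohortParseError(ValueError):
    """Raised for malformed nomenclature strings or cohort files."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed percentage
    tables), unlike Python's banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# HLA nomenclature
# ---------------------------------------------------------------------------

_HLA_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Z]+[0-9]*)\*(?P<f1>\d+)(?::(?P<f2>\d+))?"
    r"(?P<rest>(?::\d+)*[NLSCAQ]?)$"
)


@dataclass(frozen=True)
class HLAAllele:
    """A class-I HLA allele at two-field resolution.

    Extra fields and expression-suffix letters are retained in ``raw`` but
    ignored for epitope grouping, which only needs locus + allele group +
    protein.
    """

    locus: str
    field1: int
    field2: int
    raw: str

    def __post_init__(self) -> None:
        if self.locus not in ("A", "B", "C"):
            raise CohortParseError(f"unsupported HLA locus {self.locus!r}")
        if self.field1 < 1:
            raise CohortParseError(f"allele group must be >= 1: {self.raw!r}")

    @property
    def key(self) -> str:
        """Canonical two-field name, e.g. ``C*01:02``."""
        return f"{self.locus}*{self.field1:02d}:{self.field2:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def parse_hla_allele(text: str) -> HLAAllele:
    """Parse an HLA class-I allele string such as ``A*11:01``.

    Raises :class:`CohortParseError` for strings without a ``*`` separator or
    with a locus other than A/B/C.
    """
    if not isinstance(text, str) or "*" not in text:
        raise CohortParseError(f"not an HLA allele name: {text!r}")
    m = _HLA_RE.match(text.strip())
    if m is None:
        raise CohortParseError(f"cannot parse HLA allele: {text!r}")
    locus = m.group("locus")
    if locus not in ("A", "B", "C"):
        raise CohortParseError(f"unknown HLA locus {locus!r} in {text!r}")
    f2 = m.group("f2")
    return HLAAllele(
        locus=locus,
        field1=int(m.group("f1")),
        field2=int(f2) if f2 is not None else 0,
        raw=text.strip(),
    )


# ---------------------------------------------------------------------------
# KIR genotype
# ---------------------------------------------------------------------------


@dataclass
class KIRGenotype:
    """Presence/absence of the 15 KIR genes + 2 pseudogenes, with optional
    allele-level typing for KIR3DL1/KIR2DL1/KIR2DL3.

    ``jointly_typed`` records loci whose presence was reported through a
    combined probe (KIR2DL2/3 or KIR3DL1/3DS1 on SSO panels) and therefore
    carries less information than a per-gene call.
    """

    presence: dict[str, bool]
    alleles: dict[str, list[str]] = field(default_factory=dict)
    jointly_typed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = [g for g in KIR_LOCI if g not in self.presence]
        if missing:
            raise ValueError(f"incomplete KIR genotype, missing {missing}")
        extra = [g for g in self.presence if g not in KIR_LOCI]
        if extra:
            raise ValueError(f"unknown KIR loci {extra}")
        for locus, lst in self.alleles.items():
            if locus not in ALLELE_TYPED_LOCI:
                raise ValueError(f"allele typing not supported at {locus}")
            if not 1 <= len(lst) <= 2:
                raise ValueError(f"{locus}: allele list must have 1-2 entries")

    def has(self, gene: str) -> bool:
        return bool(self.presence[gene])

    @classmethod
    def from_present(cls, genes: Iterable[str], **kw) -> "KIRGenotype":
        present = set(genes)
        unknown = present - set(KIR_LOCI)
        if unknown:
            raise ValueError(f"unknown KIR loci {sorted(unknown)}")
        return cls({g: g in present for g in KIR_LOCI}, **kw)


@dataclass
class HLATyping:
    """Up to two alleles per class-I locus."""

    alleles: dict[str, tuple[HLAAllele, ...]]

    def __post_init__(self) -> None:
        for locus, al in self.alleles.items():
            if locus not in ("A", "B", "C"):
                raise ValueError(f"unknown HLA locus {locus}")
            if not 1 <= len(al) <= 2:
                raise ValueError(f"locus {locus}: need 1-2 alleles, got {len(al)}")
            if any(a.locus != locus for a in al):
                raise ValueError(f"allele at wrong locus under {locus}")

    def at(self, locus: str) -> tuple[HLAAllele, ...]:
        return self.alleles.get(locus, ())

    @classmethod
    def from_strings(cls, names: Sequence[str]) -> "HLATyping":
        by_locus: dict[str, list[HLAAllele]] = {}
        for s in names:
            a = parse_hla_allele(s)
            by_locus.setdefault(a.locus, []).append(a)
        return cls({k: tuple(v) for k, v in by_locus.items()})


@dataclass(frozen=True)
class LigandProfile:
    """KIR-ligand epitope content of one subject's HLA class-I typing.

    ``has_Bw4_80I`` and ``has_Bw4_80T`` are independent flags: a subject can
    carry both dimorphic Bw4 subtypes on different HLA-B alleles.
    """

    has_C1: bool
    has_C2: bool
    has_Bw4_80I: bool
    has_Bw4_80T: bool
    has_Bw6: bool
    has_A3A11: bool

    @property
    def has_Bw4(self) -> bool:
        """Either Bw4 dimorph counts as the KIR3DL1 ligand at gene level."""
        return self.has_Bw4_80I or self.has_Bw4_80T

    def has_ligand(self, name: str) -> bool:
        return {
            "C1": self.has_C1,
            "C2": self.has_C2,
            "Bw4": self.has_Bw4,
            "Bw4-80I": self.has_Bw4_80I,
            "Bw4-80T": self.has_Bw4_80T,
            "Bw6": self.has_Bw6,
            "A3/A11": self.has_A3A11,
        }[name]


@dataclass
class OutcomeRecord:
    """Event-time data for one pair.

    relapse_event: 0 = censored, 1 = relapse, 2 = death without relapse
    (non-relapse mortality, the competing risk). os_event: 0/1 death.
    """

    relapse_time: float
    relapse_event: int
    os_time: float
    os_event: int

    def __post_init__(self) -> None:
        if self.relapse_time <= 0 or self.os_time <= 0:
            raise ValueError("event times must be positive")
        if self.relapse_event not in (0, 1, 2):
            raise ValueError("relapse_event must be 0/1/2")
        if self.os_event not in (0, 1):
            raise ValueError("os_event must be 0/1")
        if self.relapse_event == 2 and self.os_event != 1:
            # an NRM death is, by definition, a death
            raise ValueError("relapse_event=2 (NRM) requires os_event=1")


@dataclass
class SubjectRecord:
    id: str
    role: str  # "donor" | "recipient"
    kir: KIRGenotype
    hla: HLATyping
    ligands: LigandProfile | None = None  # always derived, never read from file

    def __post_init__(self) -> None:
        if self.role not in ("donor", "recipient"):
            raise ValueError(f"role must be donor/recipient, got {self.role!r}")


#: Recognised covariate names and their value domains (None = free-form).
COVARIATE_REGISTRY: dict[str, tuple | None] = {
    "donor_age": None,
    "donor_sex_female": (0, 1, True, False),
    "disease_status": ("CR", "NR"),
    "hla_full_match": (0, 1, True, False),
    "disease_type": None,
}


@dataclass
class PairRecord:
    pair_id: str
    donor: SubjectRecord
    recipient: SubjectRecord
    covariates: dict[str, object] = field(default_factory=dict)
    outcome: OutcomeRecord | None = None

    def __post_init__(self) -> None:
        for name, value in self.covariates.items():
            if name not in COVARIATE_REGISTRY:
                raise ValueError(f"unknown covariate {name!r}")
            domain = COVARIATE_REGISTRY[name]
            if domain is not None and value not in domain:
                raise ValueError(f"covariate {name}={value!r} outside {domain}")


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

_OUTCOME_COLS = ("relapse_time", "relapse_event", "os_time", "os_event")
_COVARIATE_COLS = {
    "donor_age": "donor_age",
    "donor_sex": "donor_sex_female",
    "disease_type": "disease_type",
    "disease_status": "disease_status",
    "hla_match": "hla_full_match",
}


def _kir_columns(prefix: str) -> dict[str, str]:
    return {f"{prefix}{g.lower()}": g for g in KIR_LOCI}


def _parse_kir_row(row: pd.Series, prefix: str, idx) -> KIRGenotype:
    presence: dict[str, bool] = {}
    joint: set[str] = set()
    for col, gene in _kir_columns(prefix).items():
        v = row[col]
        if v not in (0, 1, "0", "1", 0.0, 1.0, True, False):
            raise CohortParseError(
                f"row {idx}: KIR column {col} must be 0/1, got {v!r}"
            )
        presence[gene] = bool(int(v))
    # jointly typed columns override the per-gene ones when present
    jcol = f"{prefix}kir2dl2_3"
    if jcol in row.index and not pd.isna(row[jcol]):
        flag = bool(int(row[jcol]))
        presence["KIR2DL2"] = presence["KIR2DL3"] = flag
        joint |= {"KIR2DL2", "KIR2DL3"}
    jcol = f"{prefix}kir3dl1_3ds1"
    if jcol in row.index and not pd.isna(row[jcol]):
        flag = bool(int(row[jcol]))
        presence["KIR3DL1"] = presence["KIR3DS1"] = flag
        joint |= {"KIR3DL1", "KIR3DS1"}
    alleles: dict[str, list[str]] = {}
    for locus in ALLELE_TYPED_LOCI:
        vals = []
        for n in (1, 2):
            col = f"{prefix}{locus.lower()}_al{n}"
            if col in row.index and isinstance(row[col], str) and row[col].strip():
                vals.append(row[col].strip())
        if vals:
            alleles[locus] = vals
    return KIRGenotype(presence, alleles=alleles, jointly_typed=frozenset(joint))


def _parse_hla_row(row: pd.Series, prefix: str) -> HLATyping:
    names = []
    for locus in ("a", "b", "c"):
        for n in (1, 2):
            col = f"{prefix}hla_{locus}{n}"
            v = row.get(col)
            if isinstance(v, str) and v.strip():
                names.append(v.strip())
    return HLATyping.from_strings(names)


def read_cohort(path, sep: str | None = None) -> tuple[list[PairRecord], int]:
    """Read a cohort file into validated :class:`PairRecord` objects.

    Returns ``(pairs, n_excluded)``; rows lacking any required outcome field
    are dropped and counted rather than failing the whole file, mirroring the
    exclusion of incomplete cases from analysis.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype={"pair_id": str})
    required = (
        ["pair_id"]
        + list(_kir_columns("d_"))
        + [f"d_hla_{l}{n}" for l in "abc" for n in (1, 2)]
        + [f"r_hla_{l}{n}" for l in "abc" for n in (1, 2)]
        + list(_kir_columns("r_"))
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortParseError(f"cohort file missing required columns: {missing}")

    pairs: list[PairRecord] = []
    excluded = 0
    for idx, row in df.iterrows():
        outcome = None
        if all(c in df.columns for c in _OUTCOME_COLS):
            if any(pd.isna(row[c]) for c in _OUTCOME_COLS):
                excluded += 1
                continue
            outcome = OutcomeRecord(
                relapse_time=float(row["relapse_time"]),
                relapse_event=int(row["relapse_event"]),
                os_time=float(row["os_time"]),
                os_event=int(row["os_event"]),
            )
        donor = SubjectRecord(
            id=f"{row['pair_id']}-D", role="donor",
            kir=_parse_kir_row(row, "d_", idx), hla=_parse_hla_row(row, "d_"),
        )
        recipient = SubjectRecord(
            id=f"{row['pair_id']}-R", role="recipient",
            kir=_parse_kir_row(row, "r_", idx), hla=_parse_hla_row(row, "r_"),
        )
        cov: dict[str, object] = {}
        for col, name in _COVARIATE_COLS.items():
            if col in df.columns and not pd.isna(row[col]):
                v = row[col]
                if name in ("donor_sex_female", "hla_full_match"):
                    v = int(v)
                elif name == "donor_age":
                    v = float(v)
                cov[name] = v
        pairs.append(PairRecord(str(row["pair_id"]), donor, recipient, cov, outcome))
    return pairs, excluded


def write_cohort(pairs: Sequence[PairRecord], path, sep: str = "\t") -> None:
    """Write pairs back to the cohort table format (inverse of read_cohort)."""
    rows = []
    for p in pairs:
        row: dict[str, object] = {"pair_id": p.pair_id}
        for prefix, subj in (("d_", p.donor), ("r_", p.recipient)):
            for gene in KIR_LOCI:
                row[f"{prefix}{gene.lower()}"] = int(subj.kir.presence[gene])
            for locus in "ABC":
                al = subj.hla.at(locus)
                for n in (1, 2):
                    a = al[n - 1] if n <= len(al) else (al[0] if al else None)
                    row[f"{prefix}hla_{locus.lower()}{n}"] = a.raw if a else ""
            for locus in ALLELE_TYPED_LOCI:
                lst = subj.kir.alleles.get(locus, [])
                for n in (1, 2):
                    v = lst[n - 1] if n <= len(lst) else ""
                    row[f"{prefix}{locus.lower()}_al{n}"] = v
        inv = {v: k for k, v in _COVARIATE_COLS.items()}
        for name, v in p.covariates.items():
            row[inv[name]] = v
        if p.outcome is not None:
            row["relapse_time"] = p.outcome.relapse_time
            row["relapse_event"] = p.outcome.relapse_event
            row["os_time"] = p.outcome.os_time
            row["os_event"] = p.outcome.os_event
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def allele_frequencies(
    subjects: Sequence[SubjectRecord], locus: str
) -> dict[str, float]:
    """Allele frequencies (%) at a high-resolution KIR locus by direct counting.

    The denominator is two chromosomes per subject typed at the locus; a
    subject reported with a single allele is counted as homozygous.
    Percentages are rounded half-up to one decimal.
    """
    if not subjects:
        raise ValueError("no subjects given")
    if locus not in ALLELE_TYPED_LOCI:
        raise ValueError(f"no allele-level typing at {locus}")
    counts: dict[str, int] = {}
    n_typed = 0
    for s in subjects:
        lst = s.kir.alleles.get(locus)
        if not lst:
            continue
        n_typed += 1
        expanded = list(lst) if len(lst) == 2 else [lst[0], lst[0]]
        for a in expanded:
            counts[a] = counts.get(a, 0) + 1
    if n_typed == 0:
        raise ValueError(f"no subject has allele typing at {locus}")
    total = 2 * n_typed
    return {
        a: round_half_up(100.0 * c / total, 1)
        for a, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
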