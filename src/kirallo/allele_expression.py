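"""Allele-level KIR classifiers.

High-resolution typing distinguishes KIR allotypes with very different
biology: KIR3DL1 alleles are expressed at high or low surface density or not
at all (*004 null), and KIR2DL1 alleles with arginine at residue 245 signal
more weakly than cysteine-245 allotypes. This module provides the allotype
lookup tables, the KIR3DL1/HLA-Bw4 inhibition-strength grouping and the
donor/recipient allele-mismatch call used in subgroup analyses.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import pandas as pd

from .core_types import LigandProfile

__all__ = [
    "AllotypeTable",
    "load_default_allotypes",
    "kir3dl1_class",
    "kir2dl1_residue245",
    "kir3dl1_bw4_strength",
    "allele_mismatch",
    "NOT_EVALUABLE",
]

NOT_EVALUABLE = "NotEvaluable"

_ALLELE_RE = re.compile(r"^(?:(?P<locus>KIR[23]D[LSP]\d[AB]?))?\*?(?P<num>\w+)$")


def _norm(allele: str) -> str:
    """Normalise an allele label to ``*NNN`` form, dropping the locus prefix."""
    m = _ALLELE_RE.match(allele.strip())
    if m is None:
        raise ValueError(f"cannot parse KIR allele name {allele!r}")
    return f"*{m.group('num')}"


@dataclass
class AllotypeTable:
    """Lookup tables for KIR3DL1 expression class and KIR2DL1 residue 245.

    Alleles not listed map to ``unknown`` for the 3DL1 expression class
    (never silently high); residue-245 lookups have no default and raise.
    """

    kir3dl1_class: dict[str, str]
    kir2dl1_residue245: dict[str, str]
    kir2dl1_group: dict[str, str] = field(default_factory=dict)
    #: expression classes treated as capable of strong inhibition
    strong_classes: tuple[str, ...] = ("high",)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "AllotypeTable":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str,
                         keep_default_na=False)
        k3, k2, grp = {}, {}, {}

        def _s(row, col):
            v = row.get(col)
            return v if isinstance(v, str) and v.strip() else None

        for _, row in df.iterrows():
            allele = _norm(str(row["allele"]))
            if row["locus"] == "KIR3DL1" and _s(row, "expression_class"):
                k3[allele] = row["expression_class"]
            if row["locus"] == "KIR2DL1":
                if _s(row, "residue_245"):
                    k2[allele] = row["residue_245"]
                if _s(row, "allele_group"):
                    grp[allele] = row["allele_group"]
        return cls(kir3dl1_class=k3, kir2dl1_residue245=k2, kir2dl1_group=grp)


def load_default_allotypes() -> AllotypeTable:
    ref = importlib.resources.files("kirallo.data") / "kir_allotypes.tsv"
    with ref.open("r") as fh:
        return AllotypeTable.from_tsv(fh)


def kir3dl1_class(allele: str, table: AllotypeTable) -> str:
    """Expression class of a KIR3DL1 allele: high, low, null or unknown."""
    if "KIR" in allele and not allele.upper().startswith("KIR3DL1"):
        raise ValueError(f"not a KIR3DL1 allele: {allele!r}")
    return table.kir3dl1_class.get(_norm(allele), "unknown")


def kir2dl1_residue245(allele: str, table: AllotypeTable) -> str:
    """Residue at position 245 (R or C) of a KIR2DL1 allele; unlisted
    alleles raise rather than defaulting."""
    if "KIR" in allele and not allele.upper().startswith("KIR2DL1"):
        raise ValueError(f"not a KIR2DL1 allele: {allele!r}")
    key = _norm(allele)
    try:
        return table.kir2dl1_residue245[key]
    except KeyError:
        raise KeyError(
            f"KIR2DL1 allele {allele!r} not in residue-245 table"
        ) from None


def kir3dl1_bw4_strength(
    donor_3dl1_alleles: list[str],
    patient: LigandProfile,
    table: AllotypeTable | None = None,
) -> str:
    """Strong versus weak/non-inhibiting KIR3DL1/Bw4 combination.

    ``strong`` requires a donor high-expression KIR3DL1 allotype together
    with a Bw4-80I+ patient; low/null allotypes, Bw4-80T-only or Bw6/Bw6
    patients are ``weak_non``. High allotype with 80T counts as weak, per
    the convention recorded in the editable strength table.
    """
    if table is None:
        table = load_default_allotypes()
    if not donor_3dl1_alleles:
        raise ValueError("no donor KIR3DL1 alleles given")
    classes = {kir3dl1_class(a, table) for a in donor_3dl1_alleles}
    if classes == {"unknown"}:
        return NOT_EVALUABLE
    if any(c in table.strong_classes for c in classes) and patient.has_Bw4_80I:
        return "strong"
    return "weak_non"


def allele_mismatch(
    donor_alleles: list[str],
    recipient_alleles: list[str],
    directional: bool = False,
) -> str:
    """Donor/recipient allele-mismatch call at one KIR locus.

    Default is undirected set comparison at two-field resolution (so
    homozygous {*003,*003} equals {*003}); ``directional=True`` instead
    flags donor alleles absent from the recipient (GvH direction).
    """
    if not donor_alleles or not recipient_alleles:
        raise ValueError("both allele lists must be non-empty")

    def prefix(a: str) -> str | None:
        m = re.match(r"^(KIR[23]D[LSP]\d[AB]?)", a.strip())
        return m.group(1) if m else None

    loci = {prefix(a) for a in donor_alleles + recipient_alleles} - {None}
    if len(loci) > 1:
        raise ValueError(f"alleles from different loci: {sorted(loci)}")
    d = {_norm(a) for a in donor_alleles}
    r = {_norm(a) for a in recipient_alleles}
    if directional:
        return "mismatch" if d - r else "match"
    return "match" if d == r else "mismatch"
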