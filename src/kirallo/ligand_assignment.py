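"""Reduce HLA class-I typing to KIR-ligand epitope groups.

HLA-C alleles split into C1 (Asn80) versus C2 (Lys80); HLA-B alleles into
Bw4-80I (isoleucine-80, the strong KIR3DL1 ligand), Bw4-80T (threonine-80,
weak) and Bw6 (no KIR3DL1 ligand); HLA-A3/A11 is the KIR3DL2 ligand and is
recognised by allele group alone. Assignments come from a packaged snapshot
table keyed on two-field allele names; an optional residue-80 fallback can
classify HLA-C alleles missing from the table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .core_types import HLAAllele, HLATyping, LigandProfile

__all__ = [
    "LigandTable",
    "LigandLookupError",
    "load_default_table",
    "hla_c_group",
    "hla_b_group",
    "has_a3a11",
    "ligand_profile",
]

C_GROUPS = ("C1", "C2")
B_GROUPS = ("Bw4-80I", "Bw4-80T", "Bw6")

#: HLA-A allele groups carrying a Bw4 public epitope (off by default, see
#: ``include_hla_a_bw4``).
HLA_A_BW4_GROUPS = (23, 24, 32)


class LigandLookupError(KeyError):
    """An allele absent from the ligand table (and no fallback applies)."""


@dataclass
class LigandTable:
    """Versioned epitope-group lookup for HLA-B and HLA-C alleles."""

    c_groups: dict[str, str]
    b_groups: dict[str, str]
    version: str
    residue80: dict[str, str] = field(default_factory=dict)  # fallback: key -> N|K

    def __post_init__(self) -> None:
        bad = {g for g in self.c_groups.values()} - set(C_GROUPS)
        if bad:
            raise ValueError(f"invalid C groups {bad}")
        bad = {g for g in self.b_groups.values()} - set(B_GROUPS)
        if bad:
            raise ValueError(f"invalid B groups {bad}")

    @classmethod
    def from_tsv(cls, path_or_buf, version: str | None = None) -> "LigandTable":
        df = pd.read_csv(path_or_buf, sep="\t")
        need = {"allele", "epitope_group"}
        if not need <= set(df.columns):
            raise ValueError(f"ligand table needs columns {need}")
        if version is None:
            version = (
                str(df["source_version"].iloc[0])
                if "source_version" in df.columns
                else "unversioned"
            )
        c, b = {}, {}
        for _, row in df.iterrows():
            allele, grp = str(row["allele"]), str(row["epitope_group"])
            if allele.startswith("C"):
                c[allele] = grp
            elif allele.startswith("B"):
                b[allele] = grp
            else:
                raise ValueError(f"unexpected locus in ligand table: {allele}")
        return cls(c_groups=c, b_groups=b, version=version)


def load_default_table() -> LigandTable:
    """The packaged ligand-group snapshot."""
    ref = importlib.resources.files("kirallo.data") / "hla_ligand_groups.tsv"
    with ref.open("r") as fh:
        return LigandTable.from_tsv(fh)


def hla_c_group(allele: HLAAllele, table: LigandTable, fallback: bool = False) -> str:
    """Classify an HLA-C allele as C1 or C2.

    With ``fallback=True``, alleles missing from the table are resolved via a
    user-supplied residue-80 annotation in ``table.residue80`` (Asn -> C1,
    Lys -> C2); the fallback is off by default so results stay tied to the
    versioned snapshot.
    """
    if allele.locus != "C":
        raise ValueError(f"hla_c_group needs an HLA-C allele, got {allele.raw}")
    try:
        return table.c_groups[allele.key]
    except KeyError:
        if fallback and allele.key in table.residue80:
            return "C1" if table.residue80[allele.key].upper().startswith("N") else "C2"
        raise LigandLookupError(
            f"HLA-C allele {allele.key} not in ligand table "
            f"(version {table.version})"
        ) from None


def hla_b_group(allele: HLAAllele, table: LigandTable) -> str:
    """Classify an HLA-B allele as Bw4-80I, Bw4-80T or Bw6."""
    if allele.locus != "B":
        raise ValueError(f"hla_b_group needs an HLA-B allele, got {allele.raw}")
    try:
        return table.b_groups[allele.key]
    except KeyError:
        raise LigandLookupError(
            f"HLA-B allele {allele.key} not in ligand table "
            f"(version {table.version})"
        ) from None


def has_a3a11(typing: HLATyping) -> bool:
    """True iff any HLA-A allele belongs to allele group 3 or 11."""
    alleles = typing.at("A")
    if not alleles:
        raise ValueError("no HLA-A typing present")
    return any(a.field1 in (3, 11) for a in alleles)


def ligand_profile(
    typing: HLATyping,
    table: LigandTable,
    include_hla_a_bw4: bool = False,
    fallback: bool = False,
) -> LigandProfile:
    """Union of epitope flags over a subject's class-I alleles.

    Bw4 status derives from HLA-B only; ``include_hla_a_bw4=True`` addition-
    ally counts the HLA-A Bw4 epitopes (A*23/24/32, treated as 80I) for
    sensitivity analyses.
    """
    flags = dict(C1=False, C2=False, I80=False, T80=False, Bw6=False)
    for a in typing.at("C"):
        flags[hla_c_group(a, table, fallback=fallback)] = True
    for b in typing.at("B"):
        grp = hla_b_group(b, table)
        if grp == "Bw4-80I":
            flags["I80"] = True
        elif grp == "Bw4-80T":
            flags["T80"] = True
        else:
            flags["Bw6"] = True
    if include_hla_a_bw4 and any(
        a.field1 in HLA_A_BW4_GROUPS for a in typing.at("A")
    ):
        flags["I80"] = True
    return LigandProfile(
        has_C1=flags["C1"],
        has_C2=flags["C2"],
        has_Bw4_80I=flags["I80"],
        has_Bw4_80T=flags["T80"],
        has_Bw6=flags["Bw6"],
        has_A3A11=has_a3a11(typing),
    )
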