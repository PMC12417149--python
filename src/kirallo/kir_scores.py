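"""Haplotype-motif calling and donor KIR scoring systems.

The KIR locus splits into a centromeric and a telomeric half, each carrying
an A or B gene-content motif. From presence/absence typing alone the motifs
are called Bx when any B-defining gene is present; homozygous B/B is
*inferred* when the A-motif anchor gene of that half (KIR2DL3 centromeric,
KIR3DL1 telomeric) is absent — an approximation of true haplotype phasing.

Scores:

* B content (0-4): number of B motifs over both halves of both haplotypes,
  with donor categories neutral (<=1), better (>=2) and best (>=2 with
  centromeric B/B) following the published donor-selection calculator.
* ct-KIR (0/1/2): 0 for CenB-/TelB+, 1 for CenB+/TelB+ or CenB-/TelB-,
  2 for CenB+/TelB-.
* CF-iKIR (0-3): count of donor inhibitory KIRs that are *functional*,
  i.e. whose cognate ligand is present in the recipient (2DL1-C2,
  2DL2/3-C1 pooled, 3DL1-Bw4).
* weighted inhibitory score: 1 per functional 2DL1 and 3DL1, 1 for strong
  functional 2DL2 (recipient C1+) or 0.5 for weak functional 2DL2
  (recipient C1- but C2+, cross-reactive recognition), 0.75 per functional
  2DL3; maximum 3.75.
* Bx genotype identifiers G2/G8 for the two most prevalent Bx gene-content
  patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_types import (
    CEN_B_GENES,
    KIR_LOCI,
    TEL_B_GENES,
    KIRGenotype,
    LigandProfile,
)

__all__ = [
    "MotifCall",
    "DonorScoreSet",
    "call_motifs",
    "b_content",
    "ct_kir",
    "cf_ikir",
    "weighted_inhibitory",
    "genotype_id",
    "score_donor",
]


@dataclass(frozen=True)
class MotifCall:
    cen: str  # "AA" | "Bx"
    tel: str
    cen_bb_inferred: bool = False
    tel_bb_inferred: bool = False

    def __post_init__(self) -> None:
        if self.cen not in ("AA", "Bx") or self.tel not in ("AA", "Bx"):
            raise ValueError("motifs must be AA or Bx")
        if self.cen_bb_inferred and self.cen != "Bx":
            raise ValueError("cen B/B inference requires cen=Bx")
        if self.tel_bb_inferred and self.tel != "Bx":
            raise ValueError("tel B/B inference requires tel=Bx")


@dataclass(frozen=True)
class DonorScoreSet:
    motif: MotifCall
    b_content: int
    b_category: str
    ct_kir: int
    cf_ikir: int
    weighted_inhibitory: float
    genotype_id: str


def call_motifs(kir: KIRGenotype) -> MotifCall:
    """Call Cen/Tel A-or-B motifs from gene content.

    Cen is Bx when any of KIR2DS2/2DL2/2DL5B/2DS3 is present; Tel is Bx when
    any of KIR3DS1/2DL5A/2DS5/2DS1 is present. B/B homozygosity is inferred
    from absence of the opposite anchor (2DL3 / 3DL1).
    """
    cen_b = any(kir.has(g) for g in CEN_B_GENES)
    tel_b = any(kir.has(g) for g in TEL_B_GENES)
    return MotifCall(
        cen="Bx" if cen_b else "AA",
        tel="Bx" if tel_b else "AA",
        cen_bb_inferred=cen_b and not kir.has("KIR2DL3"),
        tel_bb_inferred=tel_b and not kir.has("KIR3DL1"),
    )


def _copies(motif: str, bb: bool) -> int:
    if motif == "AA":
        return 0
    return 2 if bb else 1


def b_content(motif: MotifCall) -> tuple[int, str]:
    """B content score 0-4 and the neutral/better/best donor category."""
    score = _copies(motif.cen, motif.cen_bb_inferred) + _copies(
        motif.tel, motif.tel_bb_inferred
    )
    if score <= 1:
        category = "neutral"
    elif motif.cen_bb_inferred:
        category = "best"
    else:
        category = "better"
    return score, category


def ct_kir(motif: MotifCall) -> int:
    """Centromeric/telomeric score: CenB-/TelB+ -> 0; CenB+/TelB+ or
    CenB-/TelB- -> 1; CenB+/TelB- -> 2."""
    cen_b = motif.cen == "Bx"
    tel_b = motif.tel == "Bx"
    if cen_b and not tel_b:
        return 2
    if cen_b == tel_b:
        return 1
    return 0


def _functional(kir: KIRGenotype, gene: str, recipient: LigandProfile, ligand: str) -> bool:
    return kir.has(gene) and recipient.has_ligand(ligand)


def cf_ikir(donor_kir: KIRGenotype, recipient: LigandProfile) -> int:
    """Count of functional inhibitory KIRs: one point each for functional
    2DL1, functional 2DL2 and/or 2DL3 (pooled), and functional 3DL1."""
    score = 0
    if _functional(donor_kir, "KIR2DL1", recipient, "C2"):
        score += 1
    if _functional(donor_kir, "KIR2DL2", recipient, "C1") or _functional(
        donor_kir, "KIR2DL3", recipient, "C1"
    ):
        score += 1
    if _functional(donor_kir, "KIR3DL1", recipient, "Bw4"):
        score += 1
    return score


def weighted_inhibitory(donor_kir: KIRGenotype, recipient: LigandProfile) -> float:
    """Inhibition-strength weighted score (max 3.75).

    KIR2DL2 scores 1 when strongly functional (recipient C1+) and 0.5 when
    weakly functional through cross-reactive C2 recognition (recipient C1-
    but C2+).
    """
    score = 0.0
    if _functional(donor_kir, "KIR2DL1", recipient, "C2"):
        score += 1.0
    if donor_kir.has("KIR2DL2"):
        if recipient.has_C1:
            score += 1.0
        elif recipient.has_C2:
            score += 0.5
    if _functional(donor_kir, "KIR2DL3", recipient, "C1"):
        score += 0.75
    if _functional(donor_kir, "KIR3DL1", recipient, "Bw4"):
        score += 1.0
    return score


#: Gene-content patterns of the two most prevalent Bx genotypes: all loci
#: present except the named ones.
_GENOTYPE_PATTERNS = {
    "G2": frozenset({"KIR2DL2", "KIR2DS2", "KIR2DS3"}),
    "G8": frozenset({"KIR2DL2", "KIR2DS2", "KIR2DS5"}),
}


def genotype_id(kir: KIRGenotype) -> str:
    """Label a genotype G2, G8, otherBx or AA by gene-content pattern."""
    absent = frozenset(g for g in KIR_LOCI if not kir.has(g))
    for name, pattern in _GENOTYPE_PATTERNS.items():
        if absent == pattern:
            return name
    motif = call_motifs(kir)
    if motif.cen == "Bx" or motif.tel == "Bx":
        return "otherBx"
    return "AA"


def score_donor(donor_kir: KIRGenotype, recipient: LigandProfile) -> DonorScoreSet:
    """All donor scores for one pair."""
    motif = call_motifs(donor_kir)
    score, category = b_content(motif)
    return DonorScoreSet(
        motif=motif,
        b_content=score,
        b_category=category,
        ct_kir=ct_kir(motif),
        cf_ikir=cf_ikir(donor_kir, recipient),
        weighted_inhibitory=weighted_inhibitory(donor_kir, recipient),
        genotype_id=genotype_id(donor_kir),
    )
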