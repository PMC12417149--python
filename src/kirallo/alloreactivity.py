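"""NK-cell alloreactivity prediction models.

Three families of rules predict whether donor NK cells are alloreactive
(ALLO) toward the recipient:

* **ligand-ligand** — compares donor and recipient HLA ligand content only:
  ALLO when the donor carries an epitope the recipient lacks.
* **receptor-ligand (missing ligand)** — ALLO when the donor carries an
  inhibitory KIR whose cognate ligand is absent from the recipient,
  ignoring whether the donor's NK cells were ever educated on that ligand.
* **educational (licensing)** — ALLO only when the donor carries the
  inhibitory KIR *and* its ligand (licensed NK cells) while the recipient
  lacks that ligand; unlicensed donor NK cells are hyporesponsive and call
  Non-ALLO. The activating-receptor variant uses KIR2DS1: donors educated
  on C1 produce NK cells that respond to C2+ recipients, while 2DS1+/C1-
  donors are hyporesponsive.

Cognate pairs: 2DL1-C2, 2DL2/3-C1, 3DL1-Bw4 (either dimorph), 3DL2-A3/A11;
2DS1-C2 for the activating pathway.

All predictors are pure functions of the typed genotypes/profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_types import KIRGenotype, LigandProfile

__all__ = [
    "ALLO",
    "NON_ALLO",
    "NOT_EVALUABLE",
    "EDU_MODELS",
    "AlloPrediction",
    "ligand_ligand",
    "receptor_ligand",
    "education_ikir",
    "education_2ds1",
    "synthesis_ikir",
    "combined_ikir_2ds1",
    "predict_all",
]

ALLO = "ALLO"
NON_ALLO = "NonALLO"
NOT_EVALUABLE = "NotEvaluable"

#: The four inhibitory-KIR education models and their cognate ligands.
EDU_MODELS: dict[str, tuple[tuple[str, ...], str]] = {
    "2DL1": (("KIR2DL1",), "C2"),
    "2DL2/3": (("KIR2DL2", "KIR2DL3"), "C1"),
    "3DL1": (("KIR3DL1",), "Bw4"),
    "3DL2": (("KIR3DL2",), "A3/A11"),
}


@dataclass(frozen=True)
class AlloPrediction:
    model: str
    call: str  # ALLO | NonALLO | NotEvaluable
    rationale: str
    ikir_count: int | None = None  # SYNTH-iKIR only

    @property
    def is_allo(self) -> bool:
        return self.call == ALLO


def _check(profile: LigandProfile | None, model: str) -> AlloPrediction | None:
    if profile is None:
        return AlloPrediction(model, NOT_EVALUABLE, "ligand profile unavailable")
    return None


def ligand_ligand(
    donor: LigandProfile | None, recipient: LigandProfile | None
) -> AlloPrediction:
    """ALLO iff the donor has an epitope group the recipient lacks."""
    for p in (donor, recipient):
        na = _check(p, "LL")
        if na:
            return na
    missing = [
        name
        for name in ("C1", "C2", "Bw4", "A3/A11")
        if donor.has_ligand(name) and not recipient.has_ligand(name)
    ]
    if missing:
        return AlloPrediction("LL", ALLO, f"recipient lacks {'+'.join(missing)}")
    return AlloPrediction("LL", NON_ALLO, "no donor epitope missing in recipient")


def receptor_ligand(
    donor_kir: KIRGenotype, recipient: LigandProfile | None
) -> AlloPrediction:
    """ALLO iff any donor iKIR lacks its cognate ligand in the recipient."""
    na = _check(recipient, "RL")
    if na:
        return na
    fired = []
    for model, (genes, ligand) in EDU_MODELS.items():
        if any(donor_kir.has(g) for g in genes) and not recipient.has_ligand(ligand):
            fired.append(f"{model} without {ligand}")
    if fired:
        return AlloPrediction("RL", ALLO, "; ".join(fired))
    return AlloPrediction("RL", NON_ALLO, "every donor iKIR finds its ligand")


def education_ikir(
    model: str,
    donor_kir: KIRGenotype,
    donor: LigandProfile | None,
    recipient: LigandProfile | None,
) -> AlloPrediction:
    """Education/licensing rule for one inhibitory KIR.

    ALLO requires donor KIR+, donor ligand+ (licensed) and recipient
    ligand-. A KIR+ donor lacking its own ligand is unlicensed -> Non-ALLO.
    """
    if model not in EDU_MODELS:
        raise ValueError(f"unknown education model {model!r}")
    name = f"EDU-{model}"
    for p in (donor, recipient):
        na = _check(p, name)
        if na:
            return na
    genes, ligand = EDU_MODELS[model]
    if not any(donor_kir.has(g) for g in genes):
        return AlloPrediction(name, NON_ALLO, f"donor {model} absent")
    if not donor.has_ligand(ligand):
        return AlloPrediction(name, NON_ALLO, f"donor {ligand}-: unlicensed")
    if recipient.has_ligand(ligand):
        return AlloPrediction(name, NON_ALLO, f"recipient carries {ligand}")
    return AlloPrediction(
        name, ALLO, f"licensed {model} and recipient lacks {ligand}"
    )


def education_2ds1(
    donor_kir: KIRGenotype,
    donor: LigandProfile | None,
    recipient: LigandProfile | None,
) -> AlloPrediction:
    """Activating KIR2DS1 education: ALLO iff donor 2DS1+ and C1+ (educated)
    and the recipient expresses C2."""
    for p in (donor, recipient):
        na = _check(p, "EDU-2DS1")
        if na:
            return na
    if not donor_kir.has("KIR2DS1"):
        return AlloPrediction("EDU-2DS1", NON_ALLO, "donor 2DS1 absent")
    if not donor.has_C1:
        return AlloPrediction("EDU-2DS1", NON_ALLO, "donor C1-: hyporesponsive")
    if not recipient.has_C2:
        return AlloPrediction("EDU-2DS1", NON_ALLO, "recipient C2-")
    return AlloPrediction("EDU-2DS1", ALLO, "educated 2DS1 meets recipient C2")


def synthesis_ikir(
    donor_kir: KIRGenotype,
    donor: LigandProfile | None,
    recipient: LigandProfile | None,
) -> AlloPrediction:
    """Count of iKIR education models predicting alloreactivity (0-4); the
    binary call is ALLO iff at least one model fires.

    Models that cannot be evaluated are excluded from the count and noted in
    the rationale; a pair where no model is evaluable is NotEvaluable.
    """
    calls = [
        education_ikir(m, donor_kir, donor, recipient) for m in EDU_MODELS
    ]
    evaluable = [c for c in calls if c.call != NOT_EVALUABLE]
    if not evaluable:
        return AlloPrediction("SYNTH-iKIR", NOT_EVALUABLE, "no model evaluable")
    count = sum(c.is_allo for c in evaluable)
    skipped = len(calls) - len(evaluable)
    note = f"{count} of {len(evaluable)} iKIR models fired"
    if skipped:
        note += f" ({skipped} not evaluable)"
    return AlloPrediction(
        "SYNTH-iKIR", ALLO if count >= 1 else NON_ALLO, note, ikir_count=count
    )


def combined_ikir_2ds1(
    donor_kir: KIRGenotype,
    donor: LigandProfile | None,
    recipient: LigandProfile | None,
) -> AlloPrediction:
    """Disjunction of Synthesis-iKIR and the KIR2DS1 education model."""
    synth = synthesis_ikir(donor_kir, donor, recipient)
    ds1 = education_2ds1(donor_kir, donor, recipient)
    if NOT_EVALUABLE in (synth.call, ds1.call) and not (
        synth.is_allo or ds1.is_allo
    ):
        return AlloPrediction("COMBINED", NOT_EVALUABLE, "component not evaluable")
    call = ALLO if (synth.is_allo or ds1.is_allo) else NON_ALLO
    return AlloPrediction(
        "COMBINED", call, f"synth={synth.call}, 2DS1={ds1.call}"
    )


def predict_all(
    donor_kir: KIRGenotype,
    donor: LigandProfile | None,
    recipient: LigandProfile | None,
) -> dict[str, AlloPrediction]:
    """Run every model; keys match the model identifiers."""
    out = {
        "LL": ligand_ligand(donor, recipient),
        "RL": receptor_ligand(donor_kir, recipient),
        "EDU-2DS1": education_2ds1(donor_kir, donor, recipient),
        "SYNTH-iKIR": synthesis_ikir(donor_kir, donor, recipient),
        "COMBINED": combined_ikir_2ds1(donor_kir, donor, recipient),
    }
    for m in EDU_MODELS:
        out[f"EDU-{m}"] = education_ikir(m, donor_kir, donor, recipient)
    return out
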