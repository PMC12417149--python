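import itertools

import pytest

from kirallo.core_types import KIRGenotype
from kirallo.alloreactivity import (
    ALLO,
    NON_ALLO,
    NOT_EVALUABLE,
    EDU_MODELS,
    combined_ikir_2ds1,
    education_2ds1,
    education_ikir,
    ligand_ligand,
    receptor_ligand,
    synthesis_ikir,
)

ALL_IKIR = ["KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1", "KIR3DL2",
            "KIR3DL3", "KIR2DL4"]


def geno(*genes):
    return KIRGenotype.from_present(genes)


def test_ligand_ligand_rules(profile_factory):
    donor = profile_factory(C1=True, C2=True)
    recip = profile_factory(C1=True)
    pred = ligand_ligand(donor, recip)
    assert pred.call == ALLO and "C2" in pred.rationale
    assert ligand_ligand(donor, donor).call == NON_ALLO  # identical profiles
    donor = profile_factory(I80=True, Bw6=False)
    recip = profile_factory(Bw6=True)
    assert ligand_ligand(donor, recip).call == ALLO


def test_receptor_ligand_rules(profile_factory):
    donor = geno(*ALL_IKIR)
    all_lig = profile_factory(C1=True, C2=True, I80=True, A3A11=True)
    assert receptor_ligand(donor, all_lig).call == NON_ALLO
    no_a3 = profile_factory(C1=True, C2=True, I80=True, A3A11=False)
    assert receptor_ligand(geno("KIR3DL2"), no_a3).call == ALLO


def test_receptor_ligand_exhaustive_against_clause_enumeration(profile_factory):
    """Brute-force the 4-clause disjunction over all donor-gene and
    recipient-ligand combinations."""
    genes = ["KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1", "KIR3DL2"]
    for present in itertools.product([0, 1], repeat=5):
        donor = geno(*(g for g, p in zip(genes, present) if p))
        for lig in itertools.product([0, 1], repeat=4):
            c2, c1, bw4, a3 = lig
            recip = profile_factory(C1=bool(c1), C2=bool(c2), I80=bool(bw4),
                                    A3A11=bool(a3))
            expected = (
                (donor.has("KIR2DL1") and not c2)
                or ((donor.has("KIR2DL2") or donor.has("KIR2DL3")) and not c1)
                or (donor.has("KIR3DL1") and not bw4)
                or (donor.has("KIR3DL2") and not a3)
            )
            got = receptor_ligand(donor, recip).call == ALLO
            assert got == expected


@pytest.mark.parametrize(
    "model,donor_genes,donor_flags,recip_flags,expected",
    [
        # licensed donor, recipient lacks the ligand
        ("3DL2", ("KIR3DL2",), dict(A3A11=True), dict(A3A11=False), ALLO),
        # unlicensed: donor lacks its own ligand
        ("2DL1", ("KIR2DL1",), dict(C2=False), dict(C2=False), NON_ALLO),
        # ligand present in recipient
        ("3DL1", ("KIR3DL1",), dict(I80=True), dict(T80=True), NON_ALLO),
        # gene absent
        ("2DL2/3", (), dict(C1=True), dict(C1=False), NON_ALLO),
    ],
)
def test_education_ikir(model, donor_genes, donor_flags, recip_flags,
                        expected, profile_factory):
    pred = education_ikir(
        model, geno(*donor_genes), profile_factory(**donor_flags),
        profile_factory(**recip_flags),
    )
    assert pred.call == expected


def test_education_unknown_model(profile_factory):
    with pytest.raises(ValueError):
        education_ikir("2DS4", geno(), profile_factory(), profile_factory())


def test_education_2ds1(profile_factory):
    d_c1 = profile_factory(C1=True)
    r_c1c2 = profile_factory(C1=True, C2=True)
    assert education_2ds1(geno("KIR2DS1"), d_c1, r_c1c2).call == ALLO
    # C2/C2 donor -> hyporesponsive regardless of recipient ligands
    d_c2 = profile_factory(C2=True)
    assert education_2ds1(geno("KIR2DS1"), d_c2, r_c1c2).call == NON_ALLO
    assert education_2ds1(geno(), d_c1, r_c1c2).call == NON_ALLO


def test_education_subset_of_receptor_ligand(profile_factory):
    """Education ALLO implies receptor-ligand ALLO: the education rule adds
    the donor-ligand conjunct. Exhaustive over the relevant flags."""
    for model, (genes, ligand) in EDU_MODELS.items():
        for d_gene, d_lig, r_lig in itertools.product([0, 1], repeat=3):
            donor_kir = geno(*(genes if d_gene else ()))
            flags = {"C2": "C2", "C1": "C1", "Bw4": "I80", "A3/A11": "A3A11"}
            key = flags[ligand]
            donor = profile_factory(**{key: bool(d_lig)})
            recip = profile_factory(**{key: bool(r_lig)})
            edu = education_ikir(model, donor_kir, donor, recip).call
            rl = receptor_ligand(donor_kir, recip).call
            if edu == ALLO:
                assert rl == ALLO


def test_synthesis_counts_match_individual_calls(profile_factory):
    donor_kir = geno(*ALL_IKIR)
    donor = profile_factory(C1=True, C2=True, I80=True, A3A11=True)
    recip = profile_factory(Bw6=True)  # lacks all four ligands
    pred = synthesis_ikir(donor_kir, donor, recip)
    assert pred.ikir_count == 4 and pred.call == ALLO
    indiv = sum(
        education_ikir(m, donor_kir, donor, recip).call == ALLO
        for m in EDU_MODELS
    )
    assert pred.ikir_count == indiv

    none = synthesis_ikir(geno(), donor, recip)
    assert none.ikir_count == 0 and none.call == NON_ALLO

    only_3dl2 = synthesis_ikir(
        geno("KIR3DL2"), profile_factory(A3A11=True), recip
    )
    assert only_3dl2.ikir_count == 1 and only_3dl2.call == ALLO


def test_combined_is_disjunction(profile_factory):
    donor_kir = geno("KIR2DS1")
    donor = profile_factory(C1=True)
    recip = profile_factory(C2=True)
    # synthesis NonALLO (no licensed iKIR fires) but 2DS1 fires
    assert combined_ikir_2ds1(donor_kir, donor, recip).call == ALLO
    assert combined_ikir_2ds1(geno(), donor, recip).call == NON_ALLO


def test_combined_dominates_components_on_cohort(rng):
    """|ALLO(combined)| >= max(|ALLO(synth)|, |ALLO(2DS1)|) over a cohort."""
    from kirallo.synthetic_cohort import SimConfig, make_pair
    from kirallo.alloreactivity import predict_all

    cfg = SimConfig(n_pairs=2, seed=0)
    counts = {"SYNTH-iKIR": 0, "EDU-2DS1": 0, "COMBINED": 0}
    for i in range(150):
        p = make_pair(cfg, rng, pair_id=str(i))
        preds = predict_all(p.donor.kir, p.donor.ligands, p.recipient.ligands)
        for m in counts:
            counts[m] += preds[m].call == ALLO
    assert counts["COMBINED"] >= max(counts["SYNTH-iKIR"], counts["EDU-2DS1"])


def test_not_evaluable_propagation(profile_factory):
    donor_kir = geno(*ALL_IKIR)
    assert ligand_ligand(None, profile_factory()).call == NOT_EVALUABLE
    assert receptor_ligand(donor_kir, None).call == NOT_EVALUABLE
    assert synthesis_ikir(donor_kir, profile_factory(), None).call == NOT_EVALUABLE


def test_predictions_are_pure(profile_factory):
    donor_kir = geno(*ALL_IKIR, "KIR2DS1")
    donor = profile_factory(C1=True, C2=True, I80=True, A3A11=True)
    recip = profile_factory(C1=True)
    first = synthesis_ikir(donor_kir, donor, recip)
    for _ in range(3):
        again = synthesis_ikir(donor_kir, donor, recip)
        assert again == first
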