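# kirallo

**KIR–HLA NK-cell alloreactivity prediction, donor KIR scoring, and
competing-risks outcome analysis for pediatric haploidentical stem-cell
transplantation.**

In haploidentical HSCT, several donors are usually available and donor choice
matters: donor natural-killer cells can attack residual leukemia when their
inhibitory receptors (KIRs) find no cognate HLA class-I ligand on recipient
cells. `kirallo` implements, as a tested reusable pipeline, the standard
prediction frameworks and donor scoring systems used to rank donors by this
predicted alloreactivity, together with the survival machinery needed to
evaluate them against relapse and overall-survival outcomes:

* **Ligand assignment** — HLA-C alleles reduced to C1/C2 (residue 80:
  Asn → C1, Lys → C2), HLA-B to Bw4-80I / Bw4-80T / Bw6, HLA-A3/A11 as the
  KIR3DL2 ligand, from a versioned packaged lookup table.
* **Alloreactivity models** — ligand–ligand, receptor–ligand (missing
  ligand), and the educational (licensing) models for the four inhibitory
  receptors (2DL1–C2, 2DL2/3–C1, 3DL1–Bw4, 3DL2–A3/A11) plus the activating
  KIR2DS1–C2 pathway; the Synthesis-iKIR count (0–4 models firing) and the
  combined iKIR/2DS1 classifier.
* **Donor scoring** — Cen/Tel A/B motif calls, the B-content score (0–4,
  neutral/better/best), the ct-KIR score (CenB+/TelB− → 2, CenB−/TelB+ → 0,
  otherwise 1), the count of functional inhibitory KIRs (CF-iKIR, 0–3), the
  inhibition-strength-weighted score (max 3.75), and the G2/G8 Bx genotype
  identifiers.
* **Allele-level classifiers** — KIR3DL1 expression classes (high/low/null),
  KIR2DL1 residue-245 dimorphism, KIR3DL1/Bw4 inhibition-strength grouping,
  donor/recipient allele-mismatch calls.
* **Survival statistics** — Kaplan–Meier with log(−log) CIs, the K-sample
  log-rank test, the Aalen–Johansen cumulative incidence estimator with
  delta-method pointwise variance, **Gray's K-sample test** for equality of
  cumulative incidence under competing risks (a native implementation that
  reproduces the canonical `cmprsk` statistic to near machine precision),
  and multivariate Cox proportional-hazards fits (Efron ties; cause-specific
  censoring for relapse endpoints).
* **Synthetic cohorts** — a generator of haploidentical donor–recipient
  pairs with Chinese-population-like HLA/KIR structure and competing-risks
  outcomes under configurable hazard ratios, so the full stack can be
  exercised and calibrated without patient-level data.

## Worked example

Simulate a 189-pair cohort and run the full analysis (predict → score →
univariate CIR/OS → adjusted Cox):

```bash
kirallo run-all --n-pairs 189 --seed 7 --out-dir demo
```

The run summary reports how many pairs each model calls alloreactive:

```json
"allo_counts": {
 "EDU-2DL1": 23, "EDU-2DL2/3": 8, "EDU-3DL1": 24, "EDU-3DL2": 16,
 "EDU-2DS1": 38, "SYNTH-iKIR": 64, "COMBINED": 90
}
```

i.e. 64/189 pairs have at least one licensed inhibitory KIR whose ligand the
recipient lacks (Synthesis-iKIR ALLO), and 90/189 are alloreactive once the
activating KIR2DS1 pathway is added. `demo/univariate.tsv` holds, per group,
the 5-year cumulative incidence of relapse (with NRM as a competing risk,
Gray's test) and 5-year overall survival (log-rank):

```
variable     group    n    cir_5y  cir_lower  cir_upper  gray_p  os_5y
EDU-3DL2     ALLO     16   0.373   0.038      0.743      0.625   0.833
EDU-3DL2     NonALLO  173  0.311   0.231      0.394      0.625   0.788
SYNTH-iKIR   ALLO     64   0.335   0.186      0.492      0.693   0.869
SYNTH-iKIR   NonALLO  125  0.304   0.214      0.399      0.693   0.755
```

and `demo/multivariate.tsv` the covariate-adjusted hazard ratios, e.g. the
cause-specific relapse HR for EDU-3DL2 ALLO vs Non-ALLO (0.847, 95% CI
0.26–2.79 on this null cohort — the generator applied no effect here) and
the overall-survival HR for Synthesis-iKIR (0.445, CI 0.18–1.09). Adding
`--config` with an `effects` entry such as `{"EDU-3DL2": {"relapse": 0.136}}`
injects a true protective effect that the same pipeline then recovers.

The library surface mirrors the CLI (`kirallo.predict_all`,
`kirallo.score_donor`, `kirallo.grays_test`, `kirallo.cox_fit`,
`kirallo.generate_cohort`, …); see `docs/methods.md` for the models,
parameter defaults and their rationale.

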