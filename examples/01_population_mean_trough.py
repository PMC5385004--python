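"""Population-mean trough prediction (PMMPV) for one planned regimen.

Builds a typical elderly inpatient, estimates creatinine clearance by
Cockcroft-Gault with the 0.6 mg/dL SCr floor, and projects the steady-state
trough of a 750 mg q12h vancomycin regimen from population PK parameters.
"""

import vcmtdm as v

patient = v.PatientRecord(
    patient_id="example", sex="female", age=80.0, height=150.0, weight=45.0,
    scr=0.55, bun=24.0,                      # SCr below the 0.6 floor
    regimen=v.DoseRegimen.regular(dose_mg=750, duration_h=1.0,
                                  interval_h=12.0, n_doses=8),
)

cov = v.renal_covariates(patient)
print(f"SCr {patient.scr} mg/dL -> adjusted {cov.scr_adjusted} "
      f"(+{cov.scr_adjusted_amount:.2f})")
print(f"CLcr (Cockcroft-Gault, female): {cov.clcr:.1f} mL/min")
print(f"BUN/adjusted SCr: {cov.bun_over_adjscr:.1f} "
      "(> 20 warns of renal-function overestimation)")

pop = v.PopulationPKModel()
result = v.pmm_predict(patient, pop)
print(f"\nPMMPV (population-mean steady-state trough): {result.pmmpv:.2f} ug/mL")
print("Target range is 10-20 ug/mL: this prediction decides whether the")
print("planned dose/interval is kept or revised before the first infusion.")
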