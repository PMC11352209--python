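"""Train all four classifiers with a patient-level split and compare them.

Patients are shuffled and assigned 10:3:5 to train/validation/test (the
CNN uses the validation set for model selection; the classical models
train on train+validation, 13:5).  Metrics are spectrum-level on the
held-out test patients; a smaller cohort and coarser grid keep this
example fast — the full-size run is `sersdx run-all` or
scripts/acceptance.py.
"""

from sersdx import (
    CnnConfig, GridSpec, RfConfig, SimulationConfig,
    apply_split, evaluate_model, fit_model, preprocess_dataset, simulate, split_patients,
)

config = SimulationConfig(n_patients=18, spectra_per_sample=25,
                          grid=GridSpec(300.0, 2000.0, 5.0), seed=2)
processed = preprocess_dataset(simulate(config))
patients = sorted(set(processed.manifest["patient_id"]))
three = split_patients(patients, (10, 3, 5), "three_way", seed=2)
two = split_patients(patients, (10, 3, 5), "two_way", seed=2)
parts3, parts2 = apply_split(processed, three), apply_split(processed, two)

print(f"{'model':8s} {'accuracy':>9s} {'sensitivity':>12s} {'specificity':>12s} {'AUC':>7s}")
for kind in ("pca_lda", "rf", "svm", "cnn"):
    if kind == "cnn":
        model = fit_model("cnn", parts3["train"], parts3["validation"],
                          CnnConfig(max_epochs=20, seed=2))
    else:
        cfg = RfConfig(seed=2) if kind == "rf" else None
        model = fit_model(kind, parts2["train"], config=cfg)
    r = evaluate_model(model, parts3["test"])
    print(f"{kind:8s} {r.accuracy:9.4f} {r.sensitivity:12.4f} {r.specificity:12.4f} {r.roc.auc:7.3f}")
print("(spectrum-level metrics on the 5 held-out test patients)")
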