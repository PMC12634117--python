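"""Train the survival network on a small synthetic cohort and evaluate it.

Uses a 400-patient cohort and the CPU-friendly backbone profile, so this
runs in about a minute. The survival head is read out twice: the
first-interval hazard is the diagnosis score for prevalent disease, and the
composed post-baseline hazards give the 5-year progression risk.
"""

from ecgsurv import BackboneConfig, EcgRiskModel, SimulationConfig, TrainConfig, train_model
from ecgsurv.pipeline import (assemble_model_data, evaluate_model,
                              make_survival_sets)

VALVE = "mr"

data = assemble_model_data(SimulationConfig(n_patients=400, seed=5))
train_set, tune_set = make_survival_sets(data, VALVE)
print(f"training pairs: {len(train_set)}   tuning pairs: {len(tune_set)}")

model = EcgRiskModel(BackboneConfig.tiny(), head="survival", seed=1)
log = train_model(model, train_set, tune_set, TrainConfig(max_epochs=12), seed=1)
print(f"trained {len(log)} epochs; tuning loss "
      f"{log.attrs['epoch0_tune_loss']:.3f} -> {log.attrs['best_tune_loss']:.3f}")

metrics = evaluate_model(model, data, VALVE)
print(f"test patients: diagnosis n={metrics['n_diagnosis']}, "
      f"prediction n={metrics['n_prediction']} ({metrics['n_events']} events)")
print(f"diagnosis AUROC (prevalent {VALVE.upper()}):    "
      f"{metrics['auroc_diagnosis']:.3f}")
print(f"prediction C-index (future {VALVE.upper()}):    "
      f"{metrics['c_index_prediction']:.3f}")
print(f"5-year Brier score:                 {metrics['brier_5y']:.3f}")
print("\nAUROC near 0.9 reflects the strong prevalent-disease morphology; the "
      "C-index around 0.7-0.8 tracks the planted morphology-hazard coupling "
      "(a perfect reader of the generator's morphology reaches ~0.78).")
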