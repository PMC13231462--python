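"""Leave-dyad-out classification of conversation scenarios.

Trains the serial valence-first architecture (stage 1: positive vs
negative valence; stage 2: high vs low arousal within each predicted
valence) with relief-based feature selection and gradient boosting,
holding out one dyad per fold.
"""

from dyadaffect import lodo_crossvalidate
from dyadaffect.experiments import default_arch, featurized_datasets
from dyadaffect.stats import (
    accuracy_from_confusion,
    stage2_conditional_accuracy,
    valence_collapsed_accuracy,
)

dataset, _ = featurized_datasets(10, seed=4)
run = lodo_crossvalidate(default_arch(), dataset, seed=0)

print(f"mean LODO accuracy over {len(run.per_dyad_accuracy)} dyads: "
      f"{100 * run.mean_accuracy:.1f}%")
print("confusion matrix (rows=actual, cols=predicted, "
      "order PV-HA, PV-LA, NV-HA, NV-LA):")
print(run.confusion)
print(f"first-stage valence accuracy: "
      f"{valence_collapsed_accuracy(run.confusion):.1f}%")
print(f"stage-2 arousal accuracy | valence correct: "
      f"P {stage2_conditional_accuracy(run.confusion, 'P'):.1f}%, "
      f"N {stage2_conditional_accuracy(run.confusion, 'N'):.1f}%")
print(f"(overall from matrix: {accuracy_from_confusion(run.confusion):.1f}%)")

# On the default synthetic conditions the scenario effects are strong, so
# recovery is far above the 25% chance level; per-dyad accuracies can only
# take the values 0, .25, .5, .75, 1 (four segments per held-out dyad).
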