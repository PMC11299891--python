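"""Train both stage classifiers and score the pipeline on unseen phantoms.

This is the package's headline experiment at desk scale: auto-labeled
corpora from training phantoms, sample-based training with a fixed pooled
validation set, then object-level scoring of the full two-stage pipeline on
held-out volumes.  Takes a minute or two on one CPU.
"""

from octtm.experiments import (
    classifier_curves_experiment,
    pipeline_accuracy_experiment,
)

curves = classifier_curves_experiment(seed=1)
print("coarse-stage classifier:")
print(f"  corpus: {curves['n_patches']} patches, "
      f"{curves['n_validation']} pooled validation images, "
      f"{curves['n_samples']} samples")
print(f"  final validation accuracy: {curves['validation_accuracy_pct']:.2f} %")
print(f"  training-pool accuracy at plateau: "
      f"{curves['training_pool_accuracy_pct']:.1f} %")

pipe = pipeline_accuracy_experiment(seed=1)
print("full pipeline on held-out phantoms:")
print(f"  {pipe['n_objects']} detected objects, "
      f"{pipe['n_correct']} labeled correctly "
      f"({pipe['object_accuracy_pct']:.2f} %)")
print(f"  mean volume Dice vs membrane truth: {pipe['mean_volume_dice']:.3f}")
# Object accuracy is the per-object audit a human would do by hand; the
# lower volume Dice reflects slices where a saturation line welds the
# membrane into one large artifact object that is (correctly) rejected.
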