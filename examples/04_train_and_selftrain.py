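"""Train the pixel-classifier segmenter, then grow its dataset by
iterative self-training.

Seven manually labeled frames seed the first model; each round the model
drafts masks for 20 unlabeled frames, a corrector (here: the generator's
ground truth, standing in for a human) fixes them, and the model retrains
on the grown set. Validation IoU per round and the per-round correction
effort (fraction of pixels the corrector had to flip) are printed — effort
falling toward zero is the annotation time self-training saves.
"""

import wellquant as wq

spec = wq.WellSpec(shape="flat", top_radius_um=120, bottom_diameter_um=240,
                   pixel_scale_um_per_px=1.6)
initial, pool, truth_lookup, validation, roi = wq.benchmark_dataset(
    spec, n_initial=7, n_pool=60, n_validation=10, mean_cells=30, seed=17,
)

model, state = wq.self_train(
    initial, pool, validation,
    corrector=lambda image, draft: truth_lookup[id(image)],
    roi=roi, rounds=3, batch=20, seed=17,
)

effort = wq.correction_effort(state)
print("round  labeled  val IoU   correction effort")
sizes = [7 + 20 * r for r in range(1, state.round + 1)]
for r, (iou_r, eff) in enumerate(zip(state.history, effort), start=1):
    print(f"  {r}      {sizes[r-1]:3d}    {iou_r:.3f}     {eff:.4f}")
print(f"\nfinal labeled set: {len(state.labeled)} frames "
      f"({sum(it.provenance == 'manual' for it in state.labeled)} manual)")
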