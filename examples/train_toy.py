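"""Supervised fine-tuning on the synthetic 3-class pattern task.

Runs the full semi-supervised pipeline (STDP pre-training of the conv
kernels followed by spike-based backpropagation) on 8x8 oriented-bar
patterns with pixel noise 0.1, then evaluates on held-out noisy samples.
"""

from stdpnet import RunConfig, run_semisupervised

cfg = RunConfig(
    topology="8x8-6C3-3FC",
    eta_bp=0.4, batch_size=10,
    present_ms_first_epoch=50, present_ms=50, infer_ms=100,
    n_classes=3, image_size=(8, 8), samples_per_class=100, test_per_class=20,
    noise_level=0.1, n_epochs=5,
    seed_weights=1, seed_encoding=2, seed_data=3,
)
result = run_semisupervised(cfg)

print("iteration  epoch  loss     batch error")
for row in result.train_log[::10] + result.train_log[-1:]:
    print(f"{row.iteration:>9}  {row.epoch:>5}  {row.loss:.4f}  {row.batch_error:.2f}")
rep = result.report
print(f"\ntest error: {100 * rep.error:.1f}%  ({rep.n_samples} samples)")
print(f"mean test NLL: {rep.mean_nll:.4f}")
print("confusion matrix (rows = true class, columns = predicted):")
print(rep.confusion)
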