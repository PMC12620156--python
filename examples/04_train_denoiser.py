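"""Desk-scale training of the learned spectral denoiser.

Generates synthetic pseudo-anatomy volumes, retrospectively undersamples
them at R = 4 with varying patterns plus noise, and trains the NumPy
encoder-decoder to map the spectral projection of the aliased first iterate
to the projection of the fully sampled reference (L1 loss, Adam, lr 1e-4,
batch 1, 60/20/20 split).  The validation loss must drop from its initial
value; the trained network can then drive the unrolled reconstruction.
"""

from llrpdff import FatSpectrum
from llrpdff.nn import save_weights
from llrpdff.presets import get_preset
from llrpdff.unrolled import TrainConfig, make_training_pairs, train

echoes = get_preset("protocol1_055T").echo_train()
spectrum = FatSpectrum.nine_peak_liver()

pairs = make_training_pairs(
    n_volumes=12, shape=(2, 32, 32), echoes=echoes, spectrum=spectrum,
    acceleration=4, noise_sd=0.03, seed=0,
)
print(f"{len(pairs)} slice pairs, {pairs[0][0].shape[0]} channels each")

net, history = train(pairs, TrainConfig(epochs=5), seed=0)
print(f"network parameters: {net.n_parameters():,}")
print("validation L1 loss per epoch:", [f"{v:.4f}" for v in history["val_loss"]])
print(f"held-out test loss: {history['test_loss']:.4f}")
save_weights("scratch_weights.npz", net, metadata={"seed": 0, "epochs": 5})
print("saved checkpoint to scratch_weights.npz")
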