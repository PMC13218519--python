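"""NCC frame registration, averaging and the defocus step.

Simulates a 30-frame video of a template patch under integer jitter and
noise (SNR 5), registers every frame back to the template by normalized
cross-correlation, averages the aligned patches, and reports how many
shifts were recovered exactly and how much the averaging suppressed the
noise.  Also prints the axial defocus step for a 95 um deep region imaged
in 13 focal planes.
"""

import numpy as np

from trivasc.registration import defocus_step_um, ncc_register, synth_video

rng = np.random.default_rng(4)
template = rng.uniform(0, 1, size=(16, 16))
shifts = [(int(rng.integers(-5, 6)), int(rng.integers(-5, 6)))
          for _ in range(30)]
noise_sd = float(template.std()) / 5.0  # SNR 5

stack, base = synth_video(template, shifts, noise_sd=noise_sd, seed=rng,
                          margin=5)
result = ncc_register(stack, template, min_corr=0.5, origin=base)

exact = int(np.sum(np.all(result.shifts == np.array(shifts), axis=1)))
resid_sd = float((result.average - template).std())
print(f"frames kept: {result.n_kept}/30 (min peak NCC "
      f"{result.peaks.min():.3f})")
print(f"shifts recovered exactly: {exact}/30")
print(f"residual noise SD after averaging: {resid_sd:.4f} "
      f"(single frame: {noise_sd:.4f}, expected ~1/sqrt(30): "
      f"{noise_sd / np.sqrt(30):.4f})")
print(f"defocus step for a 95 um region in 13 planes: "
      f"{defocus_step_um(95.0, 13):.2f} um")
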