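"""Train the conditional GAN on simulated windows and sample new ones.

After desk-scale training the generator is asked for windows of each
intensity domain; the printout compares per-channel means of generated
vs real windows, which is the fidelity the training history tracks.
Takes about half a minute.
"""

import numpy as np

from cpetml import cgan
from cpetml.simulate import (noise_free_second_table, population_stats,
                             sample_config, simulate_cpet)

rng = np.random.default_rng(0)
sts, gts = [], []
for _ in range(8):
    cfg = sample_config(rng, noise_level=0.1)
    st, gt = noise_free_second_table(cfg)
    sts.append(st)
    gts.append(gt)
windows, labels = cgan.prepare_gan_windows(sts, gts, stride_s=20)
print(f"training on {len(windows)} real windows "
      f"(labels: {labels.sum(0).astype(int)})")

gen, disc, hist = cgan.train_cgan(windows, labels, epochs=200, seed=0)
print(f"label-matched mean discrepancy: epoch 1 "
      f"{hist['mean_discrepancy'][0]:.3f} -> final "
      f"{hist['mean_discrepancy'][-1]:.3f} (smaller = closer to real)")

ve = cgan.GAN_CHANNELS.index("VE")
for d, name in enumerate(("moderate", "heavy", "severe")):
    fake = cgan.generate_window(gen, name, seed=10 + d, count=100)
    real = windows[labels.argmax(1) == d]
    print(f"{name:9s}: generated mean VE {fake[:, :, ve].mean():.2f} "
          f"vs real {real[:, :, ve].mean():.2f} (normalized units)")
print("normalized VE must rise across the domains: ventilation climbs "
      "monotonically through an incremental test")

# back to absolute units via a synthetic population summary
tables = [simulate_cpet(sample_config(rng))[0] for _ in range(10)]
pop = population_stats(tables)
stats = {ch: (pop[ch]["mean_min"], pop[ch]["mean_max"])
         for ch in cgan.GAN_CHANNELS}
window_abs = cgan.denormalize_window(
    cgan.generate_window(gen, "heavy", seed=99)[0], stats)
bt = cgan.generated_to_breath(window_abs)
print(f"one denormalized heavy-domain window resampled to the breath "
      f"domain: {len(bt)} breaths, "
      f"VO2 {bt.channel('VO2').min():.0f}-{bt.channel('VO2').max():.0f} "
      f"ml/min")
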