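"""Remove impulse noise and bright artifacts with the adaptive median filter.

Builds a seeded synthetic mammogram phantom corrupted with 5% salt-and-pepper
noise plus bright label-like artifact spots, filters it, and reports the mean
absolute error to the clean phantom before and after.
"""

import numpy as np

from mammoprep import apply_ceamf, detect_light_spots, window_cap
from mammoprep.phantom import NoiseSpec, PhantomConfig, generate_phantom_case

clean, _ = generate_phantom_case(PhantomConfig(side=256, seed=42))
noisy, _ = generate_phantom_case(PhantomConfig(
    side=256, seed=42, noise=NoiseSpec(kind="salt_pepper", params={"rate": 0.05})))

spots = detect_light_spots(noisy)
filtered = apply_ceamf(noisy, spots=spots)

mae_before = np.abs(noisy.pixels - clean.pixels).mean()
mae_after = np.abs(filtered.pixels - clean.pixels).mean()

print(f"detected light spots : {len(spots)}")
print(f"window-size cap      : {window_cap(spots)}")
print(f"MAE before filtering : {mae_before:.3f} gray levels")
print(f"MAE after filtering  : {mae_after:.3f} gray levels")
print("Lower MAE after filtering means the adaptive median removed the")
print("impulse corruption without inventing new intensities.")
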