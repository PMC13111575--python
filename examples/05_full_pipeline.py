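"""Run the full preprocessing chain over a small synthetic cohort.

Standardize -> adaptive median filter -> z-score -> re-quantize -> contrast
enhance, with a per-image report row and deterministic reruns.
"""

import numpy as np

from mammoprep import PipelineConfig, run_pipeline
from mammoprep.phantom import PhantomConfig, generate_cohort

cases = generate_cohort(4, benign_fraction=0.5, seed=31,
                        base_config=PhantomConfig(side=128), materialize=True)
config = PipelineConfig(standardize_side=128, seed=31)

images, report = run_pipeline(cases, config)
cols = ["case_id", "view", "label", "n_spots", "window_max", "lo_low", "lo_high"]
print(report[cols].to_string(index=False))

images_again, _ = run_pipeline(cases, config)
identical = all(np.array_equal(a.pixels, b.pixels)
                for a, b in zip(images, images_again))
print(f"rerun bit-identical : {identical}")
print("Each row reports the artifacts found and the contrast bands used;")
print("identical reruns confirm the chain is fully deterministic.")
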