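"""Run the whole pipeline end to end and audit the manifest.

Simulation -> normalization -> PCA -> DE -> signature -> GSEA ->
modules, everything written under one run directory with per-stage
subdirectories and a manifest of counts and timings.
"""

import json

from kdsig import GseaParams
from kdsig.pipeline import PipelineConfig, default_sim_config, run_pipeline

cfg = PipelineConfig(out_dir="scratch/example_run", seed=1,
                     simulate=default_sim_config(seed=0),
                     gsea=GseaParams(n_perm=2000, min_size=10))
manifest = run_pipeline(cfg)
print("gene counts at each stage:")
print(json.dumps(manifest["counts"], indent=2))
print("\nstage timings (s):", manifest["stages"])
print("\nOutputs live under scratch/example_run/<stage>/; rerunning with "
      "the same seed reproduces them byte for byte.")
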