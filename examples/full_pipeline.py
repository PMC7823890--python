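"""The whole pipeline on files: simulate, network, annotate, score.

Writes a synthetic experiment to disk (MGF + TSV tables), runs the
file-based pipeline on it with default thresholds, and lists the
result files — the same flow as the `pefanet net` command.
"""

import tempfile
from pathlib import Path

from pefanet import GeneratorConfig, PipelineConfig, generate_dataset, run_pipeline

workdir = Path(tempfile.mkdtemp())
paths = generate_dataset(GeneratorConfig(seed=1)).write(workdir / "data")

results = run_pipeline(
    PipelineConfig(
        mgf=str(paths["mgf"]),
        quant=str(paths["quant"]),
        metadata=str(paths["metadata"]),
        bioactivity=str(paths["bioactivity"]),
        outdir=str(workdir / "results"),
    )
)

network = results["network"]
annotations = results["annotations"]
print(f"families  : {len(network.families)}")
print(f"annotated : {sum(a.matched_species is not None for a in annotations)}"
      f" / {len(annotations)} features")
print(f"flagged   : {sum(s.flagged for s in results['scores'])} bioactive candidates")
print("outputs:")
for p in sorted(Path(results["outdir"]).iterdir()):
    print(f"  {p.name}")
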