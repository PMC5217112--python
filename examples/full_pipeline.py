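"""Run the whole pipeline in one call on a simulated design.

One `run_pipeline` invocation covers: restricted-reference normalization,
basal/variance filters, NB-GLM differential expression with doubled-factor
reruns for disomic chromosomes, per-chromosome dosage summaries, and the
TLS / second-PC interaction analysis.  Writes provenance-stamped TSVs.
"""

import tempfile
from pathlib import Path

import karyodiff as kd

cfg = kd.default_disome_design(n_genes=2400, seed=1)
counts, annotation, karyotype, truth = kd.simulate_experiment(cfg)

out = Path(tempfile.mkdtemp(prefix="karyodiff_"))
pipeline_cfg = kd.PipelineConfig(
    contrasts=[
        ("disomeXV", "F45"),
        ("disomeXVI", "F45"),
        ("hemiXVI", "disomeXVI"),
        ("overexpression", "vector_control"),
    ],
    interaction=kd.InteractionDesign(
        hemizygote="hemiXVI",
        disome="disomeXVI",
        overexpression="overexpression",
        control="vector_control",
    ),
    seed=1,
    output_dir=str(out),
)
report = kd.run_pipeline(
    pipeline_cfg, counts=counts, annotation=annotation, karyotype=karyotype
)

batch = report.batches["batch1"]
for name, cr in batch.contrasts.items():
    print(f"{name}: {len(cr.up)} up / {len(cr.down)} down "
          f"(FDR<0.01, >=2-fold, copy-adjusted)")
ir = batch.interaction
print(f"TLS slope {ir.slope:+.3f}; {len(ir.classification)} interaction genes")
print(f"outputs written under {out}")
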