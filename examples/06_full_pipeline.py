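"""Run the whole pipeline from PED/MAP files to tables and figures.

Equivalent shell usage:
    galdiv simulate --seed 7 --out-prefix study
    galdiv run --config pipeline.yaml
    galdiv plot --out-dir galdiv_out
"""

import tempfile
from pathlib import Path

from galdiv import make_study_fixture, write_ped_map
from galdiv.pipeline import PipelineConfig, plot_outputs, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="galdiv_demo_"))
ds, _ = make_study_fixture(seed=7)
write_ped_map(ds, workdir / "study.ped", workdir / "study.map")

config = PipelineConfig(
    ped=str(workdir / "study.ped"),
    map=str(workdir / "study.map"),
    out_dir=str(workdir / "out"),
)
out = run_pipeline(config)
print("tables:", sorted(p.name for p in out.glob("*.tsv")))
figures = plot_outputs(out)
print("figures:", [p.name for p in figures])
print(f"all outputs under {out}")
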