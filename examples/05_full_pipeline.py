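"""Run the whole pipeline (simulate -> call -> stats) from one config.

Equivalent to: eccv run --config examples/demo_config.yaml --outdir demo_out
Re-running over the same output directory skips unchanged stages.
"""

import json
import tempfile
from pathlib import Path

from eccv import run_pipeline

config = Path(__file__).parent / "demo_config.yaml"

with tempfile.TemporaryDirectory() as tmp:
    manifest = run_pipeline(config, tmp)
    print("stages:", {k: v["status"] for k, v in manifest.stages.items()})
    summary = json.loads((Path(tmp) / "stats" / "summary.json").read_text())
    h = summary["headline"]
    print(f"EPM higher in:    {h['epm_higher_group']} "
          f"({h['epm_mean']['LF-like']:.1f} vs {h['epm_mean']['HC-like']:.1f})")
    print(f"shorter lengths:  {h['shorter_length_group']} (KS p = {h['ks_p']:.2e})")
    print(f"higher GC:        {h['higher_gc_group']} (rank-sum p = {h['gc_p']:.2e})")
    print(f"shared start-end circles: {summary['common_circles']['shared']}")
print("-> the pipeline reproduces the three programmed group contrasts and writes")
print("   per-stage TSV tables, plots, and a run manifest with file digests.")
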