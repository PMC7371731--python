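"""Derive the senescence-up ("SUVARness") signature and its core.

Selects the TIS-upregulated differentially expressed genes of the
in-vitro comparison, runs preranked GSEA of that signature in all four
simulated comparisons (mouse in-vitro, mouse in-vivo, two human
cohorts; humanized through the ortholog map), intersects the four
leading edges into the core signature, and median-splits both human
cohorts on core-signature average expression to test survival.
Artifacts land in results/suvarness/.
"""

import importlib
import sys
from dataclasses import replace
from pathlib import Path

from suvarness.workflows import run_suvarness_workflow

sys.path.insert(0, str(Path(__file__).resolve().parent))
config = importlib.import_module("00_config")

OUT = Path(__file__).resolve().parent.parent / "results" / "suvarness"
report = run_suvarness_workflow(replace(config.STUDY, outdir=str(OUT)))

print(f"SUVARness signature: {report['suvarness_size']} TIS-upregulated genes")
for row in report["gsea"]:
    print(f"  {row['comparison']}: ES = {row['es']:.3f}, NES = {row['nes']:.2f}, "
          f"p = {row['p_perm']:.3g}, leading edge = {row['leading_edge_size']} genes")
print(f"core signature (leading-edge intersection): {report['core_size']} genes")
for label, entry in (report["survival"] or {}).items():
    print(f"  {label}: above/below median {entry['n_above']}/{entry['n_below']}, "
          f"log-rank p = {entry['logrank_p']:.2e}")
print(f"artifacts in {OUT}")
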