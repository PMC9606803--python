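"""Shared locations for the analysis scripts.

Volumes and other bulky intermediates live under scratch/ (disposable);
tables and reports land in results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

COHORT_DIR = SCRATCH / "cohort"
CLEAN_ASSO_DIR = SCRATCH / "clean_asso"
CLEAN_FC_DIR = SCRATCH / "clean_fc"
MAPS_DIR = SCRATCH / "maps"

for d in (SCRATCH, RESULTS):
    d.mkdir(parents=True, exist_ok=True)
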