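"""Brain-behaviour correlations of the imaging features with MMSE and MoCA.

Pearson r per (feature, score) pair with Benjamini-Hochberg FDR over the
whole family; writes results/correlations.tsv and prints which associations
survive q < 0.05.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import COHORT_DIR, RESULTS

from assomap.biomarker_eval import (
    FeatureMatrix,
    pearson_with_fdr,
    phenotype_scores,
)
from assomap.data_io import load_phenotypes


def main() -> None:
    fm = FeatureMatrix.from_frame(pd.read_csv(RESULTS / "features.tsv", sep="\t"))
    phenos = load_phenotypes(COHORT_DIR / "phenotypes.tsv")
    scores = phenotype_scores(phenos)
    out = pearson_with_fdr(fm, scores)
    out.to_csv(RESULTS / "correlations.tsv", sep="\t", index=False)
    print(out.round(4).to_string(index=False))
    sig = out[out.q < 0.05]
    print(f"\n{len(sig)} of {len(out)} associations significant at q < 0.05:")
    for _, row in sig.iterrows():
        direction = "positive" if row.r > 0 else "negative"
        print(f"  {row.feature} vs {row.score.upper()}: {direction} "
              f"(r={row.r:.2f}, q={row.q:.4f})")


if __name__ == "__main__":
    main()
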