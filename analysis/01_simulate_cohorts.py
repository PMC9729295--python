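#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Writes to results/data/:
  matrix.tsv / annotations.tsv / motifs.tsv / truth.json
      a discovery-trial-like phospho dataset: 20 responders vs 20
      nonresponders, 1200 phosphopeptides, 40 kinases with 12 substrates
      each; kinase K001 is planted +2 log2 units more active in responders
      and 2% of peptides are detectable in only one group;
  ihc_cohort.csv
      a 400-patient TNBC-like cohort with two correlated markers (CDK4,
      FLNA) where patients upper-quartile on both have a 90% pCR rate
      versus 30% otherwise;
  pulldown_wt.tsv / pulldown_cdk4.tsv
      bait/IgG pull-down tables for two cell lines; CLIP170 is planted as a
      true interactor, strongly enriched only in the second line.
"""

import json
from pathlib import Path

from phosphoscreen.ihc import records_to_frame
from phosphoscreen.io import write_annotation_table, write_intensity_table
from phosphoscreen.ksea import write_motif_library
from phosphoscreen.pulldown import write_pulldown_table
from phosphoscreen.simulate import (IhcSimConfig, PhosphoSimConfig,
                                    simulate_ihc_cohort,
                                    simulate_phospho_dataset,
                                    simulate_pulldown_tables)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20220711


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = PhosphoSimConfig(
        n_responders=20, n_nonresponders=20, n_peptides=1200, n_kinases=40,
        substrates_per_kinase=12, planted_kinases=(("K001", 2.0),),
        exclusive_fraction=0.02, seed=SEED)
    matrix, anns, patterns, truth = simulate_phospho_dataset(cfg)
    write_intensity_table(matrix, OUT / "matrix.tsv")
    write_annotation_table(anns, OUT / "annotations.tsv")
    write_motif_library(patterns, OUT / "motifs.tsv")
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))
    print(f"phospho matrix: {matrix.shape[0]} peptides x {matrix.shape[1]} samples, "
          f"planted kinase K001 (+2 log2), "
          f"{len(truth['exclusive_peptides'])} group-exclusive peptides")

    ihc = records_to_frame(simulate_ihc_cohort(IhcSimConfig(
        n_patients=400, markers=("CDK4", "FLNA"), pcr_rate_low=0.30,
        pcr_rate_upper_quartile=0.90, marker_correlation=0.6,
        driver_markers=("CDK4", "FLNA"), seed=SEED + 1)))
    ihc.to_csv(OUT / "ihc_cohort.csv", index=False)
    print(f"IHC cohort: {ihc['patient_id'].nunique()} patients, "
          f"markers {sorted(ihc['marker'].unique())}")

    wt = simulate_pulldown_tables(500, [("CLIP170", 1.0)], replicates=2,
                                  seed=SEED + 2, igg_absent_fraction=0.0,
                                  cell_line="WT", bait="FLNA")
    cdk4 = simulate_pulldown_tables(500, [("CLIP170", 8.0)], replicates=2,
                                    seed=SEED + 3, igg_absent_fraction=1.0,
                                    cell_line="CDK4", bait="FLNA")
    write_pulldown_table(wt, OUT / "pulldown_wt.tsv")
    write_pulldown_table(cdk4, OUT / "pulldown_cdk4.tsv")
    print("pull-down tables: 500 background proteins + CLIP170 "
          "(enriched only in the CDK4-overexpressing line)")


if __name__ == "__main__":
    main()
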