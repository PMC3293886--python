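#!/usr/bin/env python
"""Heritabilities, trait correlations and genetic-constraint scan.

From the experiment-A table: broad-sense H² per trait × treatment from
ANOVA mean squares, phenotypic (individual-level) and genotypic
(line-mean) Pearson correlation matrices per treatment, and the pairwise
constraint scan (joint directional selection opposed by the genetic
correlation).  Writes heritability_report.csv, per-treatment correlation
CSVs and constraints.csv under results/.
"""

import argparse
from pathlib import Path

import phenosel as ps


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table_path = args.out_dir / "experiment_a_phenotypes.csv"
    table = ps.read_phenotypes(table_path) if table_path.exists() else None
    cfg = ps.PipelineConfig(seed=args.seed, out_dir=str(args.out_dir))
    reports = ps.run_experiment_a(cfg, table=table)

    herit = reports["heritability"]
    print("broad-sense heritability (H²) per trait × treatment:")
    print(
        herit.pivot(index="trait", columns="treatment", values="H2")
        .round(2)
        .to_string()
    )
    constraints = reports["constraints"]
    print(f"\ngenetic constraints flagged ({len(constraints)}):")
    if len(constraints):
        print(constraints.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
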