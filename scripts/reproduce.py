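#!/usr/bin/env python
"""Re-run the leave-one-family-out benchmark on downloaded real datasets.

Point this at genotype/phenotype CSVs (canonical layout: genotype CSV with
``line_id`` + one dosage column per marker; phenotype CSV with ``line_id``,
``family``, ``env`` and one numeric column per trait) and it emits the
long-format records plus the two summary tables (per-trait and overall mean
NRMSE per model) for side-by-side comparison with published results.

Example:
    python scripts/reproduce.py --geno Maize_1_geno.csv \
        --pheno Maize_1_pheno.csv --dataset Maize_1 --out-dir results/maize1
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mismatchnet import RunConfig, read_genotypes, read_phenotypes, \
    run_benchmark  # noqa: E402


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--geno", required=True, type=Path)
    ap.add_argument("--pheno", required=True, type=Path)
    ap.add_argument("--geno-format", choices=["csv", "plink_raw"],
                    default="csv")
    ap.add_argument("--dataset", default="dataset")
    ap.add_argument("--models", default="enet,lasso,ridge,wenet,wlasso,wridge")
    ap.add_argument("--traits", default=None,
                    help="Comma-separated trait columns (default: all).")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cv-folds", type=int, default=10)
    ap.add_argument("--out-dir", required=True, type=Path)
    args = ap.parse_args(argv)

    geno = read_genotypes(args.geno, fmt=args.geno_format)
    pheno = read_phenotypes(args.pheno)
    cfg = RunConfig(models=tuple(args.models.split(",")),
                    traits=tuple(args.traits.split(",")) if args.traits
                    else None,
                    cv_folds=args.cv_folds, seed=args.seed)
    report = run_benchmark(geno, pheno, cfg, dataset=args.dataset)
    report.write(args.out_dir)
    print(report.summary_by_trait().to_string(index=False))
    print()
    print(report.summary_overall().to_string(index=False))
    print(f"\nreports written to {args.out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
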