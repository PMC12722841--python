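"""Case-control and covariate statistics on the fitted regional T1 tables.

Reads the ROI table and covariates written by 02_fit_t1_maps.py, runs the
age/sex-adjusted group GLM with hemisphere-wise FDR for each protocol, and
the within-patient covariate analysis (age, sex, CPZe). Prints which ROIs
reach FDR-adjusted p < 0.05 and writes the result tables back under
results/pipeline/.
"""

import argparse
from pathlib import Path

from qt1pipe.io import read_table, write_table
from qt1pipe.roistats import covariate_analysis, group_analysis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()

    roi_table = read_table(args.results / "roi_table.csv",
                           required_columns=["subject_id", "roi_id", "protocol", "mean_qt1"])
    covariates = read_table(args.results / "covariates.csv",
                            required_columns=["subject_id", "group", "age", "sex", "cpze"])

    for proto in sorted(roi_table["protocol"].unique()):
        sub = roi_table[roi_table["protocol"] == proto]
        stats = group_analysis(sub, covariates)
        write_table(stats, args.results / f"group_stats_{proto}.csv")
        sig = stats[stats["p_fdr"] < 0.05]
        print(f"\n{proto}: {len(sig)}/{len(stats)} ROIs FDR-significant "
              f"(adjusted SSD - HC difference)")
        if len(sig):
            cols = ["roi_name", "hemisphere", "group_coef", "coef_se", "cohens_d", "p_fdr"]
            print(sig[cols].round(3).to_string(index=False))

        covstats = covariate_analysis(sub, covariates)
        write_table(covstats, args.results / f"covariate_stats_{proto}.csv")
        sig_cov = covstats[covstats["p_fdr"] < 0.05]
        print(f"{proto}: significant covariate modulations in SSD: "
              f"{sig_cov['covariate'].value_counts().to_dict() if len(sig_cov) else 'none'}")


if __name__ == "__main__":
    main()
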