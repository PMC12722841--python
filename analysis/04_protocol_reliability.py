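"""Inter-protocol reliability: regional correlation, SD summaries, and the
Monte-Carlo noise-propagation comparison.

Reads the fitted ROI table, correlates single-echo against multi-echo
regional T1 across subjects per ROI (hemisphere-wise FDR), summarizes the
across-subject SD per hemisphere for each protocol, and runs the
matched-signal Monte-Carlo experiment that isolates which protocol
propagates more noise into the fitted T1.
"""

import argparse
from pathlib import Path

import pandas as pd

from qt1pipe.io import read_table, write_table
from qt1pipe.reliability import compare_protocol_variability
from qt1pipe.roistats import hemisphere_sd_summary, interprotocol_correlation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    roi_table = read_table(args.results / "roi_table.csv")
    se = roi_table[roi_table["protocol"] == "SE-qT1"]
    me = roi_table[roi_table["protocol"] == "ME-qT1"]

    corr = interprotocol_correlation(se, me)
    write_table(corr, args.results / "interprotocol_correlation.csv")
    n_sig = (corr["p_fdr"] < 0.05).sum()
    print(f"inter-protocol correlation: {n_sig}/{len(corr)} ROIs FDR-significant, "
          f"median r = {corr['r'].median():.2f}")

    sd = hemisphere_sd_summary(roi_table)
    write_table(sd, args.results / "sd_summary.csv")
    print("\nmean across-subject regional SD (ms):")
    print(sd.pivot(index="hemisphere", columns="protocol", values="mean_roi_sd").round(1))

    mc = compare_protocol_variability(n_replicates=200, seed=args.seed)
    mc_df = pd.DataFrame({"sd_se": mc["sd_se"], "sd_me": mc["sd_me"]})
    write_table(mc_df, args.results / "protocol_noise_mc.csv")
    print(f"\nMonte-Carlo noise propagation at matched total signal: "
          f"ME fit noisier than SE in {100 * mc['fraction_me_noisier']:.0f}% of replicates "
          f"(median SD {mc['median_sd_me']:.2f} vs {mc['median_sd_se']:.2f} ms)")


if __name__ == "__main__":
    main()
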