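"""Performance report: confusion metrics with exact 95% CIs, AUC, averaged
class spectra and metabolite annotation of the selected bins.

Runs the full chain (reusing the cohort of step 01 if present) and writes
report.json / report.txt, averaged_spectra.csv and optional figures.
"""

import argparse

from mrsidh.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/analysis")
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    cfg = RunConfig(output_dir=args.outdir, seed=args.seed, make_plots=args.plots)
    report = run_pipeline(cfg)
    print(report.summary_text())


if __name__ == "__main__":
    main()
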