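#!/usr/bin/env python
"""Classify flux directions and fit EVEa templates for the synthetic network.

Reads the FLUXNET-style CSVs written by 01_simulate_network.py, runs the full
chain (quality filters, nighttime selection, (RHa, VWC) binning, dominance
classification, template scoring with dew exclusion) and writes the site-fit
table plus per-site bin-grid matrices to results/.

Expected outcome: each adsorbing site recovers its generating template, the
null site falls back to VWC_RH80 = 0, and the decoupled tall tower shows a
weaker accuracy improvement than its short twin.
"""

from pathlib import Path

import pandas as pd

from svadetect import PipelineConfig, SiteInput
from svadetect.pipeline import run_pipeline

SCRATCH = Path("scratch/network")
RESULTS = Path("results")


def main() -> None:
    manifest = pd.read_csv(RESULTS / "network_manifest.csv")
    cfg = PipelineConfig(
        sites=[
            SiteInput(
                path=str(SCRATCH / f"{row.site}.csv"),
                site_id=row.site,
                meta={"pft": row.pft, "kind": row.kind},
            )
            for row in manifest.itertuples()
        ],
        template_values=[2.31, 4.20, 8.08, 11.0],
        out_dir=str(RESULTS),
        seed=0,
    )
    results = run_pipeline(cfg)

    fits = pd.read_csv(RESULTS / "site_fits.csv").merge(
        manifest[["site", "true_vwc_rh80", "kind"]], on="site"
    )
    lib_values = [0.0, 2.31, 4.20, 8.08, 11.0]
    step = {
        v: i for i, v in enumerate(lib_values)
    }
    fits["step_error"] = [
        abs(step[b] - step[t])
        for b, t in zip(fits["vwc_rh80"], fits["true_vwc_rh80"])
    ]
    fits.to_csv(RESULTS / "site_fits_vs_truth.csv", index=False)

    print("Template fits vs ground truth:")
    print(
        fits[
            ["site", "kind", "true_vwc_rh80", "vwc_rh80", "step_error",
             "acc_at_0", "max_acc", "tp"]
        ].to_string(index=False)
    )
    sva = fits[fits["kind"] == "sva"]
    n_ok = int((sva["step_error"] <= 1).sum())
    print(
        f"\n{n_ok}/{len(sva)} adsorbing sites selected a template within one"
        " library step of the truth (bin-center evaluation makes neighbouring"
        " templates tie when the soil rests close to the boundary)."
    )
    null_row = fits[fits["kind"] == "noise"].iloc[0]
    print(f"Null site best template: VWC_RH80 = {null_row.vwc_rh80:g} (expected 0).")


if __name__ == "__main__":
    main()
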