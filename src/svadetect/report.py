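"""Render figures and a plain-text summary from pipeline artifacts.

Reads only the CSV artifacts written by :func:`svadetect.pipeline.run_pipeline`:
per-site fraction-negative matrices become heat maps with the fitted boundary
overlaid, the site-fit table becomes a baseline-vs-best accuracy comparison,
and the event tables become an occurrence summary.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .eve_templates import build_template

__all__ = ["report"]


def _grid_figure(grid_csv: Path, vwc_rh80: float, out_png: Path) -> None:
    mat = pd.read_csv(grid_csv, index_col=0)
    rha_lo = mat.columns.astype(float).to_numpy()
    vwc_lo = mat.index.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(
        np.append(rha_lo, rha_lo[-1] + (rha_lo[1] - rha_lo[0])),
        np.append(vwc_lo, vwc_lo[-1] + (vwc_lo[1] - vwc_lo[0])),
        mat.to_numpy(),
        cmap="RdBu",
        vmin=0,
        vmax=1,
    )
    if vwc_rh80 > 0:
        t = build_template(vwc_rh80)
        rr = np.linspace(0.5, 100, 200)
        ax.plot(rr, t.vwc_eq(rr), "k-", lw=1.5, label=f"EVEa {vwc_rh80:g}")
        ax.legend(loc="upper left", fontsize=8)
    ax.set_xlabel("RHa (%)")
    ax.set_ylabel("VWC (vol-%)")
    ax.set_title(grid_csv.stem.replace("grid_", ""))
    fig.colorbar(mesh, label="fraction of negative $\\lambda E$")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def report(artifact_dir: str | Path, out_dir: str | Path | None = None) -> Path:
    """Build figures + ``report.md`` from an artifact directory.

    Returns the path of the written summary document.
    """
    artifact_dir = Path(artifact_dir)
    out_dir = Path(out_dir) if out_dir else artifact_dir / "report"
    out_dir.mkdir(parents=True, exist_ok=True)

    fits_path = artifact_dir / "site_fits.csv"
    events_path = artifact_dir / "site_events.csv"
    for p in (fits_path, events_path):
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline artifact: {p}")
    fits = pd.read_csv(fits_path)
    ev = pd.read_csv(events_path)

    lines = ["# SVA detection report", ""]

    if fits.empty:
        lines += ["No qualifying sites.", ""]
    else:
        fits = fits.sort_values("site").reset_index(drop=True)
        # accuracy comparison figure
        fig, ax = plt.subplots(figsize=(6, 3.5))
        x = np.arange(len(fits))
        ax.bar(x - 0.2, fits["acc_at_0"], 0.4, label="baseline (null)")
        ax.bar(x + 0.2, fits["max_acc"], 0.4, label="best EVEa")
        ax.set_xticks(x, fits["site"], rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "accuracy.png", dpi=120)
        plt.close(fig)

        for _, row in fits.iterrows():
            g = artifact_dir / f"grid_{row['site']}.csv"
            if g.exists():
                _grid_figure(g, float(row["vwc_rh80"]), out_dir / f"grid_{row['site']}.png")

        lines += ["## Template fits", "", fits.to_markdown(index=False), ""]
        ranked = fits.assign(improvement=fits["max_acc"] - fits["acc_at_0"]).sort_values(
            "improvement", ascending=False
        )
        lines += [
            "Sites by accuracy improvement over the null baseline: "
            + ", ".join(
                f"{r.site} (+{r.improvement:.3f})" for r in ranked.itertuples()
            ),
            "",
        ]

    included = ev[ev["included"]] if not ev.empty else ev
    lines += ["## SVA occurrence", ""]
    if included.empty:
        lines += ["No qualifying sites (no year with enough SVA days).", ""]
    else:
        lines += [included.to_markdown(index=False), ""]

    doc = out_dir / "report.md"
    doc.write_text("\n".join(lines))
    return doc
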