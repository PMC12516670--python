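#!/usr/bin/env python
"""Render the figure report for the synthetic-network run.

Reads the CSV artifacts under results/ and writes bin-grid heat maps with the
fitted boundary overlaid, the baseline-vs-best accuracy comparison and the
occurrence summary to results/report/.
"""

from svadetect.report import report


def main() -> None:
    doc = report("results")
    print(f"report written to {doc}")


if __name__ == "__main__":
    main()
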