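#!/usr/bin/env python
"""Classify peaks between the two cell-cycle states: a peak is condition-
specific when its 200-bp region is more than 4-fold enriched over the other
population (depth-normalized, strict) with Poisson p < 1e-4; everything else
is common, paired across conditions and centered on the asynchronous peak.

Reports the class counts and the retained/unique percentages."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import load_genome, load_peaks, load_tags, make_parser

from mitobook import classify_peaks, summarize_comparison
from mitobook import io as mio


def main() -> None:
    args = make_parser(__doc__).parse_args()
    genome, _ = load_genome(args.run_dir)
    tags = load_tags(args.run_dir, genome)
    peaks = load_peaks(args.run_dir, genome)

    comp = classify_peaks(peaks["asynchronous"], peaks["mitotic"],
                          tags["asynchronous"], tags["mitotic"])
    counts = comp.counts()
    pct = summarize_comparison(counts["async_specific"],
                               counts["mitotic_specific"], counts["common"])
    mio.write_json({"counts": counts, "percent": pct},
                   args.results / "class_summary.json")

    half = 100
    for label, rows in (
        ("async_specific", [(p.chrom, p.center) for p in comp.async_specific]),
        ("mitotic_specific", [(p.chrom, p.center) for p in comp.mitotic_specific]),
        ("common", [(c.chrom, c.reference_center) for c in comp.common]),
    ):
        with open(args.run_dir / f"{label}.bed", "w") as fh:
            for chrom, center in sorted(rows):
                fh.write(f"{chrom}\t{center - half}\t{center + half}\t{label}\t0\t.\n")

    print(f"classes: {counts}")
    print(f"retained on mitotic chromatin: {pct['common_of_async']:.1f}% of "
          f"asynchronous sites; {pct['async_unique']:.1f}% asynchronous-unique")


if __name__ == "__main__":
    main()
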