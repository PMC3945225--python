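#!/usr/bin/env python
"""Annotate each peak class by genomic category with the six-way priority
scheme (promoter > TTS > exon > intron > dTSS > intergenic) and write the
per-class category fractions (pie-chart data)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import load_genome, load_peaks, load_tags, make_parser

from mitobook import annotation_summary, classify_peaks
from mitobook import io as mio


def main() -> None:
    args = make_parser(__doc__).parse_args()
    genome, _ = load_genome(args.run_dir)
    tags = load_tags(args.run_dir, genome)
    peaks = load_peaks(args.run_dir, genome)
    comp = classify_peaks(peaks["asynchronous"], peaks["mitotic"],
                          tags["asynchronous"], tags["mitotic"])

    out = {}
    groups = {
        "async_specific": [(p.chrom, p.center) for p in comp.async_specific],
        "mitotic_specific": [(p.chrom, p.center) for p in comp.mitotic_specific],
        "common": [(c.chrom, c.reference_center) for c in comp.common],
    }
    for label, pairs in groups.items():
        centers = {}
        for chrom, x in pairs:
            centers.setdefault(chrom, []).append(x)
        out[label] = annotation_summary(centers, genome)
        top = sorted(out[label]["fractions"].items(), key=lambda kv: -kv[1])[:3]
        print(f"{label}: " + ", ".join(f"{k} {100 * v:.0f}%" for k, v in top))
    mio.write_json(out, args.results / "annotation_summary.json")


if __name__ == "__main__":
    main()
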