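#!/usr/bin/env python
"""Call RBPJ peaks in the asynchronous and mitotic ChIP libraries against the
matched input: 200-bp Poisson windows at p < 1e-4, sample-swap FDR 0.001,
then a 1 RPM height floor — writing one BED6+ peak file per condition."""

import dataclasses
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import load_genome, load_tags, make_parser

from mitobook import PeakCallParams, call_peaks
from mitobook import io as mio


def main() -> None:
    args = make_parser(__doc__).parse_args()
    genome, _ = load_genome(args.run_dir)
    tags = load_tags(args.run_dir, genome)
    params = PeakCallParams()

    n_peaks = {}
    for cond in ("asynchronous", "mitotic"):
        peaks = call_peaks(tags[cond], tags["input"], params, condition=cond)
        mio.write_peaks_bed(peaks, args.run_dir / f"peaks_{cond}.bed")
        n_peaks[cond] = len(peaks)
        print(f"{cond}: {len(peaks)} peaks "
              f"(depth {tags[cond].total_tags}, 1 RPM = "
              f"{tags[cond].total_tags / 1e6:.2f} tags)")

    mio.write_json(
        {"params": dataclasses.asdict(params),
         "depths": {c: t.total_tags for c, t in tags.items()},
         "n_peaks": n_peaks},
        args.results / "peak_calling_summary.json",
    )


if __name__ == "__main__":
    main()
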