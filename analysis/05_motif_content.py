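#!/usr/bin/env python
"""Score motif content of each peak class (RBPJ consensus TTCCCAC(A/G) and
the CTCF-like 12-mer) in 200-bp windows around class-appropriate centers,
and test known-motif enrichment of the common peaks against length-matched
background windows resampled from the genome."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import load_genome, load_peaks, load_tags, make_parser

from mitobook import MotifModel, classify_peaks, motif_enrichment, peak_motif_content
from mitobook import io as mio
from mitobook.motifs import CTCF_LIKE_CONSENSUS, RBPJ_CONSENSUS


def main() -> None:
    args = make_parser(__doc__).parse_args()
    genome, sequences = load_genome(args.run_dir)
    tags = load_tags(args.run_dir, genome)
    peaks = load_peaks(args.run_dir, genome)
    comp = classify_peaks(peaks["asynchronous"], peaks["mitotic"],
                          tags["asynchronous"], tags["mitotic"])

    rbpj = MotifModel(name="RBPJ", consensus=RBPJ_CONSENSUS)
    ctcf = MotifModel(name="CTCF-like", consensus=CTCF_LIKE_CONSENSUS)

    groups = {
        "async_specific": [(p.chrom, p.center) for p in comp.async_specific],
        "mitotic_specific": [(p.chrom, p.center) for p in comp.mitotic_specific],
        "common": [(c.chrom, c.reference_center) for c in comp.common],
    }
    rows = []
    for label, pairs in groups.items():
        centers = {}
        for chrom, x in pairs:
            centers.setdefault(chrom, []).append(x)
        table = peak_motif_content(centers, sequences, rbpj, ctcf, label=label)
        rows.append(table.as_dict())
        print(f"{label}: {table.with_first}/{table.n_peaks} RBPJ, "
              f"{table.with_second}/{table.n_peaks} CTCF-like")
    mio.write_table(rows, args.results / "motif_content.tsv")

    centers = {}
    for chrom, x in groups["common"]:
        centers.setdefault(chrom, []).append(x)
    enrich = {}
    for model in (rbpj, ctcf):
        enrich[model.name] = motif_enrichment(centers, sequences, model,
                                              n_resamples=200,
                                              seed=args.seed + 101)
        print(f"{model.name} enrichment in common peaks: "
              f"{enrich[model.name]['fold']:.1f}-fold, "
              f"p = {enrich[model.name]['p_value']:.4g}")
    mio.write_json(enrich, args.results / "motif_enrichment.json")


if __name__ == "__main__":
    main()
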