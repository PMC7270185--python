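"""Resolve fold coordinates to sequences and design cloning primers.

Builds a two-contig toy genome, extracts a plus- and a minus-strand fold,
then designs amplification primers (shortest prefix whose Wallace Tm exceeds
58 degrees C) and the T7/S1-tagged bait template for one fold.
"""

import pandas as pd

from foldscreen.fold_catalog import (
    build_bait_template,
    design_amplification_primers,
    load_fold_regions,
    wallace_tm,
)

genome = "genome_example.fa"
with open(genome, "w") as fh:
    fh.write(">chrI\n" + "ACGTAAGGCCTTACGATCGATCGGATCCAAGGTTCCAACGTACGTAACCGGCATG" * 3 + "\n")

folds = pd.DataFrame(
    [
        ["fold_plus", "chrI", 10, 60, "+", "GENE1"],
        ["fold_minus", "chrI", 10, 60, "-", "GENE1"],
    ],
    columns=["fold_id", "chrom", "start", "end", "strand", "gene"],
)
catalog = load_fold_regions(folds, genome)
for fold in catalog:
    print(f"{fold.fold_id}: {fold.sequence[:24]}... ({fold.length} nt)")

template = catalog[0].sequence.replace("U", "T")
primers = design_amplification_primers(template, tm_threshold=58)
print(f"forward primer {primers.forward_seq} (Tm {primers.forward_tm} C)")
print(f"reverse primer {primers.reverse_seq} (Tm {primers.reverse_tm} C)")
bait = build_bait_template(template)
print(f"bait template: {len(bait)} nt (T7 tag + insert + S1 aptamer tag)")
# The primers are exact template prefixes extended base by base until the
# 4*(G+C) + 2*(A+T) melting temperature strictly exceeds the threshold.
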