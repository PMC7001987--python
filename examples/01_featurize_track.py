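"""Featurize a coverage track into a TPM profile over a BED feature list.

Writes a tiny bedGraph track and feature list, extracts per-feature
coverage sums, and converts them to transcripts-per-million.
"""

import tempfile
from pathlib import Path

from covrec import build_profile, load_feature_set, DatasetRecord
from covrec.synthetic import generate_track

workdir = Path(tempfile.mkdtemp())

# a coverage track: constant 2x over one region, 6x over another
track = generate_track(
    [("chr1", 0, 1000), ("chr1", 2000, 2500), ("chr2", 0, 800)],
    [2.0, 6.0, 1.0],
    workdir / "sample.bedgraph",
)

bed = workdir / "features.bed"
bed.write_text(
    "chr1\t100\t600\tgeneA\n"   # 500 bp inside the 2x region
    "chr1\t2000\t2500\tgeneB\n"  # 500 bp inside the 6x region
    "chr2\t0\t400\tgeneC\n"      # 400 bp inside the 1x region
)
features = load_feature_set(bed, feature_class="transcript", assembly="toy1")

record = DatasetRecord(
    dataset_id="sample1", experiment_id="exp1", assembly="toy1",
    experiment_type="RNA-seq", cell_type="heart",
)
profile = build_profile(record, track, features)

print("feature  length  TPM")
for iv, tpm in zip(features.intervals, profile.tpm):
    print(f"{iv.name:8s} {iv.length:6d} {tpm:12.1f}")
print(f"sum of TPM: {profile.tpm.sum():.1f}")
# The TPM values are per-base coverage rates rescaled to sum to 1e6:
# geneB has 3x geneA's rate and geneC 0.5x, so the profile splits
# 1,000,000 in the ratio 2 : 6 : 1.
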