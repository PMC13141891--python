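"""Demultiplex dual-barcoded long amplicon reads.

Simulates nanopore-style 16S reads for three samples (strand-mixed, 10%
missing a barcode, 10% off-length), writes them as FASTQ, demultiplexes with
a 100 bp search window and the 1,000-2,000 bp length filter, and compares the
status counts with the generator's truth table.
"""

import tempfile
from pathlib import Path

from neutralline import BarcodeSpec, ReadSimConfig, demux_fastq, simulate_reads
from neutralline.synthetic import write_fastq

specs = [
    BarcodeSpec("S1", "ACGTACGTACGT", "TTGGCCAATTGG"),
    BarcodeSpec("S2", "GGTTAACCGGTT", "CAGTCAGTCAGT"),
    BarcodeSpec("S3", "TCTCTCTCAGAG", "GACGACGACGAC"),
]
cfg = ReadSimConfig(
    n_reads_per_sample=300, fraction_missing_barcode=0.1, fraction_off_length=0.1, seed=3
)
reads, truth = simulate_reads(specs, cfg)

with tempfile.TemporaryDirectory() as tmp:
    fastq = Path(tmp) / "reads.fastq"
    write_fastq(reads, fastq)
    summary = demux_fastq(fastq, specs, Path(tmp) / "demux")
    print("demultiplexing summary (per sample and status):")
    print(summary.to_string(index=False), "\n")
    print("generator truth (expected status counts):")
    print(truth["expected_status"].value_counts().to_string())

# Interpretation: with exact barcode matching every status count equals the
# generator's truth — clean reads are assigned to their intended sample, reads
# missing a barcode fail with no_forward/no_reverse, off-length reads are
# rejected by the inclusive 1,000-2,000 bp window after trimming.
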