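"""Dual-barcode demultiplexing of long amplicon reads.

Reads carry a sample-specific forward barcode near the 5' end and the reverse
complement of a sample-specific reverse barcode near the 3' end. A read is
assigned to a sample only when both barcodes of the same sample are found,
each within a fixed search window at its end of the read; the barcode regions
(and everything outside them) are then trimmed and an inclusive length filter
retains near-full-length 16S sequences (1,000-2,000 bp by default).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DEFAULT_WINDOW = 100
DEFAULT_MIN_LEN = 1000
DEFAULT_MAX_LEN = 2000

STATUSES = ("assigned", "no_forward", "no_reverse", "ambiguous", "too_short", "too_long")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeSpec:
    """Barcode pair defining one sample.

    Both barcodes are stored in the orientation of the PCR primers; the
    reverse barcode is searched on the read as its reverse complement.
    """

    sample_id: str
    fwd_barcode: str
    rev_barcode: str

    def __post_init__(self) -> None:
        for name, bc in (("fwd_barcode", self.fwd_barcode), ("rev_barcode", self.rev_barcode)):
            if not bc:
                raise ValueError(f"{name} for sample {self.sample_id!r} is empty")
            if set(bc.upper()) - set("ACGT"):
                raise ValueError(f"{name} for sample {self.sample_id!r} contains non-ACGT characters: {bc}")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r} has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id!r}: quality string length != sequence length")


@dataclass(frozen=True)
class DemuxResult:
    read_id: str
    status: str
    sample_id: Optional[str] = None
    trimmed_sequence: Optional[str] = None
    trimmed_qualities: Optional[str] = None
    orientation: Optional[str] = None  # "as_is" | "reverse_complement"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "assigned") != (self.sample_id is not None and self.trimmed_sequence is not None):
            raise ValueError("sample_id and trimmed_sequence must be set iff status is 'assigned'")


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def find_barcode(
    sequence: str,
    barcode: str,
    end: str = "head",
    window: int = DEFAULT_WINDOW,
    max_mismatches: int = 0,
) -> Optional[int]:
    """Locate a barcode within the first or last `window` bases of a read.

    Returns the 0-based start position of the leftmost (head) or rightmost
    (tail) occurrence at Hamming distance <= max_mismatches, or None if the
    barcode does not occur in the window.
    """
    if end not in ("head", "tail"):
        raise ValueError("end must be 'head' or 'tail'")
    k = len(barcode)
    if window < k:
        raise ValueError(f"window ({window}) must be >= barcode length ({k})")
    n = len(sequence)
    sequence = sequence.upper()
    barcode = barcode.upper()
    if end == "head":
        region_start = 0
        region = sequence[: min(window, n)]
    else:
        region_start = max(0, n - window)
        region = sequence[region_start:]
    # starts are offsets within `region`; the barcode must lie fully inside it
    last_start = len(region) - k
    if last_start < 0:
        return None
    if max_mismatches == 0:
        if end == "head":
            pos = region.find(barcode)
        else:
            pos = region.rfind(barcode)
        return None if pos < 0 else region_start + pos
    starts: Iterable[int] = range(last_start + 1) if end == "head" else range(last_start, -1, -1)
    for s in starts:
        if _hamming_leq(region[s : s + k], barcode, max_mismatches):
            return region_start + s
    return None


def _match_both_ends(seq, specs, window, max_mismatches):
    """Samples whose fwd barcode hits the head AND revcomp(rev) hits the tail."""
    hits = []
    any_fwd = False
    for spec in specs:
        f = find_barcode(seq, spec.fwd_barcode, "head", window, max_mismatches)
        if f is None:
            continue
        any_fwd = True
        r = find_barcode(seq, reverse_complement(spec.rev_barcode), "tail", window, max_mismatches)
        if r is None:
            continue
        hits.append((spec, f, r))
    return hits, any_fwd


def demux_read(
    read: Read,
    specs: list[BarcodeSpec],
    window: int = DEFAULT_WINDOW,
    max_mismatches: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    search_revcomp: bool = True,
) -> DemuxResult:
    """Assign one read to a sample by its dual barcodes and trim it.

    The forward barcode is searched in the head window and the reverse
    complement of the reverse barcode in the tail window; if no sample matches
    and `search_revcomp` is set the reverse-complemented read is tried. Both
    ends must match the SAME sample; ties between distinct samples are
    reported as ambiguous. Trimming removes everything up to and including the
    forward barcode and everything from the reverse-barcode match onward, then
    the inclusive [min_len, max_len] filter is applied.
    """
    if not specs:
        raise ValueError("at least one BarcodeSpec is required")

    candidates = [(read.sequence, read.qualities, "as_is")]
    if search_revcomp:
        rq = read.qualities[::-1] if read.qualities is not None else None
        candidates.append((reverse_complement(read.sequence), rq, "reverse_complement"))

    saw_fwd = False
    for seq, quals, orientation in candidates:
        hits, any_fwd = _match_both_ends(seq, specs, window, max_mismatches)
        saw_fwd = saw_fwd or any_fwd
        if not hits:
            continue
        distinct = {spec.sample_id for spec, _, _ in hits}
        if len(distinct) > 1:
            return DemuxResult(read.read_id, "ambiguous", orientation=orientation)
        spec, fpos, rpos = hits[0]
        start = fpos + len(spec.fwd_barcode)
        end = rpos
        trimmed = seq[start:end]
        tq = quals[start:end] if quals is not None else None
        if len(trimmed) < min_len:
            return DemuxResult(read.read_id, "too_short", orientation=orientation)
        if len(trimmed) > max_len:
            return DemuxResult(read.read_id, "too_long", orientation=orientation)
        if orientation == "reverse_complement":
            # report the trim in the original read's frame
            trimmed = reverse_complement(trimmed)
            tq = tq[::-1] if tq is not None else None
        return DemuxResult(read.read_id, "assigned", spec.sample_id, trimmed, tq, orientation)

    return DemuxResult(read.read_id, "no_reverse" if saw_fwd else "no_forward")


def read_barcode_table(path) -> list[BarcodeSpec]:
    """Read a TSV with columns sample_id, fwd_barcode, rev_barcode."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fwd_barcode", "rev_barcode"}
    if not required.issubset(df.columns):
        raise ValueError(f"barcode table must have columns {sorted(required)}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in barcode table: {dupes}")
    specs = [BarcodeSpec(r.sample_id, r.fwd_barcode, r.rev_barcode) for r in df.itertuples()]
    pairs = [(s.fwd_barcode.upper(), s.rev_barcode.upper()) for s in specs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("barcode (fwd, rev) pairs are not unique across samples")
    return specs


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(handle):
    for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        try:
            yield Read(rec.id, str(rec.seq), quals)
        except ValueError as e:
            raise ValueError(f"malformed FASTQ record #{i}: {e}") from e


def demux_fastq(
    reads_path,
    specs_path,
    out_dir,
    window: int = DEFAULT_WINDOW,
    max_mismatches: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    search_revcomp: bool = True,
) -> pd.DataFrame:
    """Demultiplex a FASTQ file into per-sample FASTQ files.

    Writes `<out_dir>/<sample_id>.fastq` with trimmed assigned reads and
    `<out_dir>/demux_summary.tsv` with one row per (sample, status); unassigned
    statuses are tallied under sample_id "unassigned". Returns the summary
    frame. The status counts always sum to the number of input reads.
    """
    specs = read_barcode_table(specs_path) if not isinstance(specs_path, list) else specs_path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handles = {s.sample_id: open(out_dir / f"{s.sample_id}.fastq", "w") for s in specs}
    counts: dict[tuple[str, str], int] = {}
    try:
        with _open_maybe_gzip(reads_path) as fh:
            for read in _iter_fastq(fh):
                res = demux_read(read, specs, window, max_mismatches, min_len, max_len, search_revcomp)
                key = (res.sample_id if res.sample_id else "unassigned", res.status)
                counts[key] = counts.get(key, 0) + 1
                if res.status == "assigned":
                    quals = res.trimmed_qualities or "I" * len(res.trimmed_sequence)
                    handles[res.sample_id].write(f"@{read.read_id}\n{res.trimmed_sequence}\n+\n{quals}\n")
    finally:
        for h in handles.values():
            h.close()

    summary = pd.DataFrame(
        [(s, st, n) for (s, st), n in sorted(counts.items())],
        columns=["sample_id", "status", "count"],
    )
    summary.to_csv(out_dir / "demux_summary.tsv", sep="\t", index=False)
    return summary
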