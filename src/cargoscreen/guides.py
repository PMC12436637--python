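"""Guide counting from single-end sequencing reads.

Reads carry the guide sequence directly (19-bp single-end protocol with
custom primers), so counting is an exact hash lookup of the read
subsequence [offset, offset + guide_length) against the library. Optional
one-mismatch rescue scans the Hamming-1 neighborhood; reads matching two or
more guides at distance 1 are ambiguous and counted as unmapped. Matching
is forward-strand only; vector/stagger trimming is expressed through the
offset, not adapter detection.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from cargoscreen.io import GuideLibrary, logger

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class CountingStats:
    total_reads: int
    mapped: int
    unmapped: int
    ambiguous: int  # subset of unmapped

    def as_dict(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "mapped": self.mapped,
            "unmapped": self.unmapped,
            "ambiguous": self.ambiguous,
        }


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _hamming1_candidates(seq: str) -> set[str]:
    out = set()
    for i, c in enumerate(seq):
        for b in _ALPHABET:
            if b != c:
                out.add(seq[:i] + b + seq[i + 1:])
    return out


def count_guides(
    fastq_path: str | Path,
    library: GuideLibrary,
    offset: int = 0,
    guide_length: int | None = None,
    allow_one_mismatch: bool = False,
) -> tuple[pd.Series, CountingStats]:
    """Count reads per guide by exact (optionally 1-mismatch) matching.

    Returns (counts indexed by guide_id covering the whole library, stats).
    Conservation holds by construction: mapped + unmapped == total_reads.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    lib_len = library.guide_length
    if guide_length is None:
        guide_length = lib_len
    if guide_length is None:
        raise ValueError("library has no sequences and no guide_length given")
    if lib_len is not None and guide_length != lib_len:
        raise ValueError(
            f"guide_length {guide_length} != library sequence length {lib_len}")

    seq_to_guides = library.sequence_to_guides()
    counts: dict[str, int] = {g: 0 for g in library.table["guide_id"]}
    total = mapped = ambiguous = 0
    end = offset + guide_length

    with _open_maybe_gzip(fastq_path) as fh:
        for record in SeqIO.parse(fh, "fastq"):
            total += 1
            read = str(record.seq).upper()
            if len(read) < end:
                continue  # unmapped: too short
            sub = read[offset:end]
            hit = seq_to_guides.get(sub)
            if hit is None and allow_one_mismatch:
                neighbors = [seq_to_guides[c]
                             for c in _hamming1_candidates(sub)
                             if c in seq_to_guides]
                if len(neighbors) == 1:
                    hit = neighbors[0]
                elif len(neighbors) > 1:
                    ambiguous += 1
                    continue
            if hit is None:
                continue
            if len(hit) > 1:
                ambiguous += 1
                continue  # one sequence shared by several guides
            counts[hit[0]] += 1
            mapped += 1

    if total == 0:
        logger.warning("empty FASTQ %s: zero counts", fastq_path)
    stats = CountingStats(total, mapped, total - mapped, ambiguous)
    series = pd.Series(counts, name="count")
    series.index.name = "sgRNA"
    return series, stats
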