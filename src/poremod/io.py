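"""Small shared readers/writers: FASTA references and truth BED files.

All user-facing coordinates in this package are 1-based inclusive; BED is
the one 0-based half-open interchange format, converted at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase-sequence mapping."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"no sequences found in FASTA {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> list[tuple[str, int, str]]:
    """Read a truth BED (chrom, start, end, name) into (chrom, 1-based position, name).

    Intervals must have length 1 — one modified nucleotide per record.
    """
    out: list[tuple[str, int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected ≥4 BED columns")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if end - start != 1:
            raise FormatError(
                f"{path}:{lineno}: truth intervals must have length 1, got {end - start}"
            )
        out.append((chrom, start + 1, name))
    return out


def write_bed(entries, path) -> None:
    """Write (chrom, 1-based position, name) triples as length-1 BED intervals."""
    with open(path, "w") as fh:
        for chrom, position, name in entries:
            fh.write(f"{chrom}\t{position - 1}\t{position}\t{name}\n")
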