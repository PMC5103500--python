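"""FASTA/MultiFASTA input and TSV result serialisation.

Sequences are uppercased on ingest; multi-line records, CRLF endings and
lowercase letters are accepted.  Result tables carry a ``#``-prefixed
metadata header (model, parameters, input digests, seed, version) that is
sufficient to re-run the command that produced them.
"""

from __future__ import annotations

import hashlib
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FlasmError


class FastaFormatError(FlasmError):
    """Malformed FASTA input."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a (Multi)FASTA file into ``(id, sequence)`` pairs.

    Rejects files whose first non-blank line is not a header (naming the
    offending line), empty sequences, and duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path.name}, line {lineno}: expected a '>' header, "
                    f"got {line[:30]!r}")
            break
    else:
        raise FastaFormatError(f"{path.name}: no records found")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path.name}: record {rec.id!r} has an "
                                   f"empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path.name}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapped at 60 columns."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def sequence_digest(seqs: list[str]) -> str:
    """Stable short digest of a sequence collection, for result headers."""
    h = hashlib.sha256()
    for s in seqs:
        h.update(s.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def write_results(rows: list[tuple], path, metadata: dict,
                  columns: tuple[str, ...] = ("text_end", "pattern_end", "distance")
                  ) -> None:
    """Serialise result rows as TSV under ``#key\\tvalue`` metadata lines.

    Rows are written sorted; coordinates are 0-based unless the caller
    already converted them (the header should say which).
    """
    with open(path, "w") as fh:
        for key in sorted(metadata):
            fh.write(f"#{key}\t{metadata[key]}\n")
        fh.write("\t".join(columns) + "\n")
        for row in sorted(rows):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_results(path) -> tuple[dict, list[list[str]], list[str]]:
    """Inverse of :func:`write_results`: (metadata, rows, column names)."""
    metadata: dict = {}
    rows: list[list[str]] = []
    header: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                metadata[key] = value
            elif not header:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    return metadata, rows, header
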