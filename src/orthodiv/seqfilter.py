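"""Intact-receptor filtering of nucleotide sequences.

A receptor sequence is kept as *intact* only if it is at least 650 bp long
(shorter fragments cannot encode a complete seven-transmembrane domain) and
carries an uninterrupted open reading frame of at least 650 bp on one of the
six reading frames. Anything else is a pseudogene, with the reason recorded:

* ``too_short`` — raw length below 650 bp, regardless of ORF content;
* ``premature_stop`` — the best ORF is terminated by a stop codon before
  reaching the 650 bp minimum;
* ``frameshift`` — the sequence is long enough and no premature stop
  terminates the best ORF, yet no frame sustains a 650 bp reading frame (the
  operational signature of an indel-induced frame break on an assembled
  contig without a reference).

Exact duplicate sequences (string-identical nucleotides) are collapsed to
their first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MIN_INTACT_LENGTH",
    "ReceptorSequence",
    "OrfLocation",
    "locate_best_orf",
    "classify_sequence",
    "dedupe",
    "filter_repertoire",
]

MIN_INTACT_LENGTH = 650  # bp floor for a complete seven-transmembrane domain

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReceptorSequence:
    """A classified receptor sequence."""

    id: str
    nucleotides: str
    classification: str  # "intact" | "pseudogene"
    reason: str | None  # None | "frameshift" | "premature_stop" | "too_short"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class OrfLocation:
    """Location of the longest start-to-stop ORF over the six frames."""

    span: int  # nt, stop codon included when present
    stop_terminated: bool
    strand: int  # +1 forward, -1 reverse complement
    offset: int  # frame offset on that strand, 0..2
    start_codon_index: int  # codon index of the ATG within the frame


def locate_best_orf(seq: str) -> OrfLocation:
    """Find the longest ORF (ATG to stop, or ATG to sequence end) in 6 frames."""
    best = OrfLocation(0, False, +1, 0, 0)
    for strand, strand_seq in ((+1, seq), (-1, _revcomp(seq))):
        for offset in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(offset, len(strand_seq) - 2, 3)
            ]
            start = None
            for ci, codon in enumerate(codons):
                if start is None:
                    if codon == "ATG":
                        start = ci
                    continue
                if codon in _STOPS:
                    span = (ci - start + 1) * 3
                    if span > best.span:
                        best = OrfLocation(span, True, strand, offset, start)
                    start = None
            if start is not None:
                span = (len(codons) - start) * 3
                if span > best.span:
                    best = OrfLocation(span, False, strand, offset, start)
    return best


def _best_orf(seq: str) -> tuple[int, bool]:
    loc = locate_best_orf(seq)
    return loc.span, loc.stop_terminated


def classify_sequence(seq: str) -> tuple[str, str | None]:
    """Classify one nucleotide sequence as intact or pseudogene (with reason).

    Accepts A/C/G/T/N, case-insensitive; any other character is an input
    error. Precedence: too_short (raw length), then premature_stop, then
    frameshift.
    """
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    if len(s) < MIN_INTACT_LENGTH:
        return "pseudogene", "too_short"
    span, stopped = _best_orf(s)
    if span >= MIN_INTACT_LENGTH:
        return "intact", None
    if stopped:
        return "pseudogene", "premature_stop"
    return "pseudogene", "frameshift"


def dedupe(records: list[SeqRecord]) -> tuple[list[SeqRecord], list[str]]:
    """Collapse exact string-identical sequences to their first occurrence.

    Returns (unique records in input order, ids of removed duplicates).
    Reverse complements are *not* considered duplicates.
    """
    seen: set[str] = set()
    unique: list[SeqRecord] = []
    removed: list[str] = []
    for rec in records:
        key = str(rec.seq).upper()
        if key in seen:
            removed.append(rec.id)
        else:
            seen.add(key)
            unique.append(rec)
    return unique, removed


def _read_fasta(path: str | Path) -> list[SeqRecord]:
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            if len(rec.seq) == 0:
                raise ValueError(f"record {i} ({rec.id!r}) has an empty sequence")
            records.append(rec)
    except ValueError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    return records


def filter_repertoire(
    fasta_in: str | Path,
    fasta_out: str | Path | None = None,
    report_out: str | Path | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Remove exact duplicates and pseudogenes from a FASTA repertoire.

    Returns the intact records and a per-class count report
    (intact / too_short / premature_stop / frameshift / duplicate); the
    classes partition the input, so their counts sum to the input record
    count. Optionally writes the intact FASTA and the TSV report.
    """
    records = _read_fasta(fasta_in)
    unique, removed = dedupe(records)
    counts = {
        "intact": 0,
        "too_short": 0,
        "premature_stop": 0,
        "frameshift": 0,
        "duplicate": len(removed),
    }
    intact: list[SeqRecord] = []
    for rec in unique:
        classification, reason = classify_sequence(str(rec.seq))
        if classification == "intact":
            counts["intact"] += 1
            intact.append(rec)
        else:
            counts[reason] += 1
    report = pd.DataFrame(
        [{"class": k, "count": v} for k, v in counts.items()],
        columns=["class", "count"],
    )
    if fasta_out is not None:
        SeqIO.write(intact, str(fasta_out), "fasta")
    if report_out is not None:
        report.to_csv(report_out, sep="\t", index=False)
    return intact, report
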