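"""Percent-spliced-in, splice-junction event frequencies, and transcript consequences.

PSI for exon *i* uses length-normalized inclusion/exclusion read counts:

    IR_norm = IR_i / (exon_length + read_length - 1)
    ER_norm = ER_i / (read_length - 1)
    PSI_i   = 100 * IR_norm / (IR_norm + ER_norm)

Junction-locus event frequencies are simple read shares over
{canonical junction, each alternative junction, intron retention}.

Consequence classification applies an aberrant splice choice (donor/acceptor
shift, intron retention, exon skip) to a toy transcript model, asks whether
the inserted/removed length is a multiple of three (in-frame vs frameshift),
translates the modified mRNA, and reports any premature termination codon
(PTC) together with the exon containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# PSI

@dataclass(frozen=True)
class ExonCountRecord:
    """Inclusion/exclusion read counts for one exon."""

    exon_id: str
    exon_index: int
    exon_length: int   # bp
    read_length: int   # bp
    inclusion_reads: int
    exclusion_reads: int

    def __post_init__(self) -> None:
        if self.exon_length < 1:
            raise ValueError("exon_length must be >= 1")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2 (ER normalization divides by read_length - 1)")
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class PSIRecord:
    exon_id: str
    ir_norm: float           # reads / bp
    er_norm: float           # reads / bp
    psi: Optional[float]     # percent in [0, 100]; None when coverage is zero


def psi(record: ExonCountRecord) -> PSIRecord:
    """Percent-spliced-in for one exon; undefined (None) at zero coverage."""
    ir_norm = record.inclusion_reads / (record.exon_length + record.read_length - 1)
    er_norm = record.exclusion_reads / (record.read_length - 1)
    denom = ir_norm + er_norm
    value = None if denom == 0 else 100.0 * ir_norm / denom
    return PSIRecord(exon_id=record.exon_id, ir_norm=ir_norm, er_norm=er_norm, psi=value)


# ---------------------------------------------------------------------------
# junction event frequencies

@dataclass(frozen=True)
class JunctionLocus:
    """Observed junction-read counts around one splice site."""

    locus_id: str
    canonical_reads: int
    alternative_junctions: tuple  # of (label, offset bp != 0, reads)
    retention_reads: int

    def __post_init__(self) -> None:
        if self.canonical_reads < 0 or self.retention_reads < 0:
            raise ValueError("counts must be non-negative")
        for label, offset, reads in self.alternative_junctions:
            if int(offset) == 0:
                raise ValueError(f"alternative junction {label!r} has zero offset")
            if reads < 0:
                raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return (self.canonical_reads + self.retention_reads
                + sum(r for _, _, r in self.alternative_junctions))


@dataclass(frozen=True)
class SpliceEventFrequency:
    label: str
    kind: str        # canonical | alternative | intron_retention
    reads: int
    frequency: float  # percent of locus reads


def event_frequencies(locus: JunctionLocus) -> list[SpliceEventFrequency]:
    """Percent read share of each event at the locus; raises on zero coverage."""
    total = locus.total_reads
    if total < 1:
        raise ValueError(f"locus {locus.locus_id!r} has no reads: frequencies undefined")
    out = [SpliceEventFrequency("canonical", "canonical", locus.canonical_reads,
                                100.0 * locus.canonical_reads / total)]
    for label, _offset, reads in locus.alternative_junctions:
        out.append(SpliceEventFrequency(label, "alternative", reads, 100.0 * reads / total))
    out.append(SpliceEventFrequency("intron_retention", "intron_retention",
                                    locus.retention_reads,
                                    100.0 * locus.retention_reads / total))
    return out


# ---------------------------------------------------------------------------
# transcript models and splice events

@dataclass(frozen=True)
class TranscriptModel:
    """A toy gene model: genomic sequence plus exon coordinates.

    Coordinates are genomic, 1-based inclusive, sorted ascending and
    non-overlapping.  ``cds_start_offset`` is 0-based into the spliced mRNA.
    Minus-strand models are normalized to an equivalent plus-strand view
    before any sequence operation.
    """

    sequence: str
    exons: tuple            # of (start, end), 1-based inclusive
    strand: str = "+"
    cds_start_offset: int = 0
    transcript_id: str = "toy"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "exons", tuple(tuple(map(int, e)) for e in self.exons))
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        last = 0
        for s, e in self.exons:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"exon ({s}, {e}) outside sequence")
            if s <= last:
                raise ValueError("exons must be sorted and non-overlapping")
            last = e

    def _plus_view(self) -> "TranscriptModel":
        if self.strand == "+":
            return self
        n = len(self.sequence)
        exons = tuple(sorted((n - e + 1, n - s + 1) for s, e in self.exons))
        return TranscriptModel(sequence=_revcomp(self.sequence), exons=exons,
                               strand="+", cds_start_offset=self.cds_start_offset,
                               transcript_id=self.transcript_id)

    def exon_sequences(self) -> list[str]:
        tm = self._plus_view()
        return [tm.sequence[s - 1:e] for s, e in tm.exons]

    def intron_sequences(self) -> list[str]:
        tm = self._plus_view()
        return [tm.sequence[e0:s1 - 1]
                for (_, e0), (s1, _) in zip(tm.exons[:-1], tm.exons[1:])]

    def canonical_mrna(self) -> str:
        return "".join(self.exon_sequences())


@dataclass(frozen=True)
class SpliceEvent:
    """One aberrant splice choice on a transcript model.

    ``target`` indexes the affected intron (1-based, for shifts and
    retention) or exon (for skips).  ``delta_bp`` is the signed change in
    mRNA length (>0 bases added, <0 removed); for retention and skip it is
    derived from the model if left at 0.
    """

    kind: str                  # donor_shift | acceptor_shift | intron_retention | exon_skip
    target: int
    delta_bp: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"donor_shift", "acceptor_shift", "intron_retention", "exon_skip"}:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in {"donor_shift", "acceptor_shift"} and self.delta_bp == 0:
            raise ValueError("splice-site shifts must change the mRNA (delta_bp != 0)")


def _modified_parts(tm: TranscriptModel, ev: SpliceEvent) -> list[tuple[str, int]]:
    """(sequence, exon label) segments of the event-modified transcript.

    Exon labels keep canonical numbering; a retained intron carries its
    upstream exon's label, and shift-added intronic bases the label of the
    exon they extend.
    """
    tm = tm._plus_view()
    exon_seqs = tm.exon_sequences()
    intron_seqs = tm.intron_sequences()
    n_ex = len(exon_seqs)
    parts: list[tuple[str, int]] = [(s, i + 1) for i, s in enumerate(exon_seqs)]

    if ev.kind == "exon_skip":
        if not (1 <= ev.target <= n_ex):
            raise ValueError(f"no exon {ev.target}")
        if n_ex < 2:
            raise ValueError("cannot skip the only exon")
        del parts[ev.target - 1]
        return parts

    if not (1 <= ev.target <= len(intron_seqs)):
        raise ValueError(f"no intron {ev.target}")
    intron = intron_seqs[ev.target - 1]
    i = ev.target - 1  # upstream exon index (0-based)

    if ev.kind == "intron_retention":
        parts.insert(i + 1, (intron, i + 1))
        return parts

    d = ev.delta_bp
    if ev.kind == "donor_shift":
        # donor moves into the intron (d>0: exon i extended) or into the exon
        # (d<0: its last |d| bases skipped)
        if d > 0:
            if d >= len(intron):
                raise ValueError("donor shift runs past the intron (use intron_retention)")
            parts[i] = (parts[i][0] + intron[:d], i + 1)
        else:
            if -d >= len(parts[i][0]):
                raise ValueError("donor shift removes the whole exon")
            parts[i] = (parts[i][0][:d], i + 1)
    else:  # acceptor_shift
        if d > 0:
            if d >= len(intron):
                raise ValueError("acceptor shift runs past the intron (use intron_retention)")
            parts[i + 1] = (intron[-d:] + parts[i + 1][0], i + 2)
        else:
            if -d >= len(parts[i + 1][0]):
                raise ValueError("acceptor shift removes the whole exon")
            parts[i + 1] = (parts[i + 1][0][-d:], i + 2)
    return parts


def event_delta(tm: TranscriptModel, ev: SpliceEvent) -> int:
    """Signed mRNA length change of the event."""
    if ev.kind == "intron_retention":
        return len(tm.intron_sequences()[ev.target - 1])
    if ev.kind == "exon_skip":
        return -len(tm.exon_sequences()[ev.target - 1])
    return ev.delta_bp


def apply_splice_event(tm: TranscriptModel, ev: SpliceEvent) -> str:
    """Spliced mRNA with the aberrant event applied."""
    return "".join(seq for seq, _ in _modified_parts(tm, ev))


@dataclass(frozen=True)
class ConsequenceCall:
    frame_status: str                 # in_frame | frameshift
    ptc: bool
    ptc_exon_index: Optional[int]     # exon containing the first novel stop's first base
    n_stops_introduced: int
    no_stop_found: bool = False


def classify_consequence(tm: TranscriptModel, ev: SpliceEvent) -> ConsequenceCall:
    """Frame and PTC outcome of an aberrant splice on a transcript model.

    A stop is *novel* (premature) when its first base lies 5' of the
    canonical stop codon's first base in the modified mRNA; a frameshift
    that runs through the canonical stop without hitting any stop is
    reported with ``no_stop_found``.
    """
    if tm.cds_start_offset is None:
        raise ValueError("transcript has no annotated CDS")
    delta = event_delta(tm, ev)
    frame_status = "in_frame" if delta % 3 == 0 else "frameshift"
    parts = _modified_parts(tm, ev)
    mrna = "".join(seq for seq, _ in parts)
    labels: list[int] = []
    for seq, lab in parts:
        labels.extend([lab] * len(seq))
    cds0 = tm.cds_start_offset
    if cds0 >= len(mrna):
        raise ValueError("CDS start beyond modified mRNA")
    # the canonical stop occupies the last 3 bases of the canonical mRNA; any
    # upstream event leaves those bases at the modified mRNA's tail
    canon_stop_first = len(mrna) - 3
    novel: list[int] = []   # first-base positions of premature stops
    for p in range(cds0, len(mrna) - 2, 3):
        if mrna[p:p + 3] in _STOPS:
            if p < canon_stop_first:
                novel.append(p)
            else:
                break
    ptc = bool(novel)
    no_stop = False
    if not ptc:
        # did translation reach a terminal stop at all?
        tail_ok = any(mrna[p:p + 3] in _STOPS
                      for p in range(cds0, len(mrna) - 2, 3))
        no_stop = not tail_ok
    return ConsequenceCall(frame_status=frame_status, ptc=ptc,
                           ptc_exon_index=labels[novel[0]] if ptc else None,
                           n_stops_introduced=len(novel), no_stop_found=no_stop)


# ---------------------------------------------------------------------------
# I/O: TSV schemas shared with the simulators, FASTA + GFF3 transcript models

def read_exon_counts_tsv(path) -> list[ExonCountRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [ExonCountRecord(exon_id=str(r.exon_id), exon_index=i,
                            exon_length=int(r.exon_length),
                            read_length=int(r.read_length),
                            inclusion_reads=int(r.inclusion_reads),
                            exclusion_reads=int(r.exclusion_reads))
            for i, r in enumerate(df.itertuples(index=False), start=1)]


def psi_records_to_frame(records: Sequence[PSIRecord]):
    import pandas as pd

    return pd.DataFrame([{"exon_id": r.exon_id, "ir_norm": r.ir_norm,
                          "er_norm": r.er_norm,
                          "psi_percent": np.nan if r.psi is None else r.psi}
                         for r in records])


def read_junction_tsv(path) -> JunctionLocus:
    """Junction TSV (junction_id, kind, start, end, reads) -> one locus."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    canonical = 0
    retention = 0
    alts = []
    locus_id = "locus"
    for r in df.itertuples(index=False):
        locus_id = str(r.junction_id).rsplit(":", 1)[0]
        if r.kind == "canonical":
            canonical += int(r.reads)
        elif r.kind == "intron_retention":
            retention += int(r.reads)
        else:
            offset = int(r.end) - int(r.start)
            alts.append((str(r.junction_id), offset if offset else 1, int(r.reads)))
    return JunctionLocus(locus_id=locus_id, canonical_reads=canonical,
                         alternative_junctions=tuple(alts), retention_reads=retention)


def frequencies_to_frame(freqs: Sequence[SpliceEventFrequency]):
    import pandas as pd

    return pd.DataFrame([{"label": f.label, "kind": f.kind, "reads": f.reads,
                          "frequency_percent": f.frequency} for f in freqs])


def write_transcript(tm: TranscriptModel, fasta_path, gff3_path,
                     seqid: str = "toy_chr") -> None:
    """Write a transcript model as FASTA + GFF3 (exon and CDS features)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(tm.sequence), id=seqid, description="")],
                str(fasta_path), "fasta")
    lines = ["##gff-version 3",
             f"##sequence-region {seqid} 1 {len(tm.sequence)}"]
    gid, tid = f"{tm.transcript_id}_gene", tm.transcript_id
    span = (tm.exons[0][0], tm.exons[-1][1])
    lines.append("\t".join([seqid, "nebfish", "gene", str(span[0]), str(span[1]),
                            ".", tm.strand, ".", f"ID={gid}"]))
    lines.append("\t".join([seqid, "nebfish", "mRNA", str(span[0]), str(span[1]),
                            ".", tm.strand, ".", f"ID={tid};Parent={gid}"]))
    for k, (s, e) in enumerate(tm.exons, start=1):
        lines.append("\t".join([seqid, "nebfish", "exon", str(s), str(e), ".",
                                tm.strand, ".", f"ID={tid}.exon{k};Parent={tid}"]))
        lines.append("\t".join([seqid, "nebfish", "CDS", str(s), str(e), ".",
                                tm.strand, "0", f"ID={tid}.cds{k};Parent={tid}"]))
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_transcript(fasta_path, gff3_path) -> TranscriptModel:
    """Load a transcript model from FASTA + GFF3 (first mRNA's exons)."""
    import gffutils
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    mrna = next(db.features_of_type("mRNA"))
    exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
    return TranscriptModel(sequence=str(rec.seq), exons=tuple(exons),
                           strand=mrna.strand, cds_start_offset=0,
                           transcript_id=mrna.id)
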