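"""Readers and writers for the standard formats the pipeline touches.

FASTA for insert sequences, 12(+1)-column tabular output for protein
homology hits, and GFF3 for ab initio prediction tracks and spliced EST
alignments. Multi-contig inserts are assembled into a single concatenated
coordinate frame by :func:`assemble_insert`.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .records import (
    ESTAlignment,
    FosmidRecord,
    HomologyHit,
    PredictedGene,
    PredictionTrack,
    VALID_BASES,
)

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """A consumed file violates its format contract."""


def read_fasta(path: Union[str, os.PathLike]) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]``.

    Sequences are uppercased; any character outside {A,C,G,T,N} raises a
    :class:`FormatError` naming the record and the 1-based offset.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq, start=1):
            if ch not in VALID_BASES:
                raise FormatError(
                    f"record {rec.id!r}: illegal character {ch!r} at position {i}"
                )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: Union[str, os.PathLike], records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def assemble_insert(
    contigs: list[tuple[str, str]],
    gap_pad: int = 100,
    insert_id: Optional[str] = None,
    accession: Optional[str] = None,
) -> FosmidRecord:
    """Assemble ordered contigs into one insert coordinate frame.

    Contigs are concatenated in the given order with ``gap_pad`` 'N'
    characters between them; gap sentinels are recorded at each junction
    and ``total_length`` excludes the padding.
    """
    if not contigs:
        raise ValueError("cannot assemble an insert from an empty contig list")
    if insert_id is None:
        insert_id = contigs[0][0]
    return FosmidRecord(
        insert_id=insert_id,
        contigs=[(cid, seq.upper()) for cid, seq in contigs],
        accession=accession,
        gap_pad=gap_pad,
    )


def read_blast_tab(path: Union[str, os.PathLike]) -> list[HomologyHit]:
    """Parse 12-column tabular homology hits (optional 13th = description).

    Minus-strand hits (``qstart > qend`` in the file, or a negative frame)
    are normalized to ``query_start <= query_end`` with ``strand='-'``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise FormatError(
                    f"line {lineno}: expected 12 (or 13) tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                pident = float(fields[2])
                aln_len = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field ({exc})") from exc
            strand = "+"
            if qstart > qend:
                qstart, qend = qend, qstart
                strand = "-"
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=pident,
                    aln_length=aln_len,
                    query_start=qstart,
                    query_end=qend,
                    subject_start=min(sstart, send),
                    subject_end=max(sstart, send),
                    strand=strand,
                    e_value=evalue,
                    bit_score=bitscore,
                    description=fields[12] if len(fields) == 13 else None,
                )
            )
    return hits


def write_blast_tab(path: Union[str, os.PathLike], hits: Iterable[HomologyHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qstart, qend = h.query_start, h.query_end
            if h.strand == "-":
                qstart, qend = qend, qstart
            row = [
                h.query_id,
                h.subject_id,
                f"{h.pct_identity:g}",
                str(h.aln_length if h.aln_length is not None else h.length),
                "0",
                "0",
                str(qstart),
                str(qend),
                str(h.subject_start or 1),
                str(h.subject_end or 1),
                f"{h.e_value:g}",
                f"{h.bit_score:g}",
            ]
            if h.description is not None:
                row.append(h.description)
            fh.write("\t".join(row) + "\n")


def _gff_db(path: Union[str, os.PathLike]) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _check_orphans(db: gffutils.FeatureDB) -> None:
    ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in ids:
                raise FormatError(
                    f"feature {feat.id!r} references missing parent {parent!r}"
                )


def read_gff_track(
    path: Union[str, os.PathLike],
    kind: str,
    seq_lengths: Optional[dict[str, int]] = None,
    model_name: Optional[str] = None,
) -> Union[PredictionTrack, list[ESTAlignment]]:
    """Read a GFF3 track.

    ``kind='prediction'`` expects gene (optionally mRNA) features with
    exon/CDS children and returns a :class:`PredictionTrack`;
    ``kind='est'`` expects match features with match_part children and
    returns a list of :class:`ESTAlignment`. Coordinates are 1-based
    inclusive as in GFF3. When ``seq_lengths`` is given, features beyond a
    sequence's length are rejected.
    """
    if kind not in ("prediction", "est"):
        raise ValueError("kind must be 'prediction' or 'est'")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    db = _gff_db(path)
    _check_orphans(db)

    def _bounds_check(feat) -> None:
        if seq_lengths is not None and feat.seqid in seq_lengths:
            if feat.end > seq_lengths[feat.seqid] or feat.start < 1:
                raise FormatError(
                    f"feature {feat.id!r} at {feat.seqid}:{feat.start}-{feat.end} "
                    f"lies outside sequence bounds (length "
                    f"{seq_lengths[feat.seqid]})"
                )

    if kind == "est":
        ests = []
        for match in db.features_of_type(("match", "cDNA_match", "EST_match")):
            _bounds_check(match)
            parts = list(db.children(match, featuretype="match_part"))
            segments = sorted((p.start, p.end) for p in parts) or [
                (match.start, match.end)
            ]
            identity = float(match.attributes.get("identity", ["100"])[0])
            genus = match.attributes.get("genus", [None])[0]
            ests.append(
                ESTAlignment(
                    est_id=match.id,
                    pct_identity=identity,
                    segments=segments,
                    strand=match.strand if match.strand in "+-" else "+",
                    insert_id=match.seqid,
                    source_genus=genus,
                )
            )
        return ests

    track = PredictionTrack(model_name=model_name or os.path.basename(str(path)))
    for gene in db.features_of_type("gene"):
        _bounds_check(gene)
        exon_feats = [
            f
            for f in db.children(gene, featuretype=("exon", "CDS"))
        ]
        # prefer CDS rows when both are present (codon-bearing extent)
        cds = [f for f in exon_feats if f.featuretype == "CDS"]
        chosen = cds if cds else exon_feats
        exons = sorted({(f.start, f.end) for f in chosen}) or [(gene.start, gene.end)]
        attrs = gene.attributes
        start_codon = attrs.get("start_codon", [None])[0]
        stop_codon = attrs.get("stop_codon", [None])[0]
        pg = PredictedGene(
            gene_id=gene.id,
            start=gene.start,
            end=gene.end,
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=exons,
            predicted_start_codon=int(start_codon) if start_codon else None,
            predicted_stop_codon=int(stop_codon) if stop_codon else None,
        )
        track.genes.setdefault(gene.seqid, []).append(pg)
    for insert_id in track.genes:
        track.genes[insert_id].sort(key=lambda g: (g.start, g.end))
    return track


def write_gff_track(
    path: Union[str, os.PathLike],
    kind: str,
    data: Union[PredictionTrack, list[ESTAlignment]],
) -> None:
    """Write a prediction track or EST alignments as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if kind == "prediction":
            assert isinstance(data, PredictionTrack)
            source = data.model_name
            for insert_id in sorted(data.genes):
                for g in data.for_insert(insert_id):
                    attrs = [f"ID={g.gene_id}"]
                    if g.predicted_start_codon is not None:
                        attrs.append(f"start_codon={g.predicted_start_codon}")
                    if g.predicted_stop_codon is not None:
                        attrs.append(f"stop_codon={g.predicted_stop_codon}")
                    fh.write(
                        f"{insert_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\t{';'.join(attrs)}\n"
                    )
                    for i, (s, e) in enumerate(g.exons, start=1):
                        fh.write(
                            f"{insert_id}\t{source}\tCDS\t{s}\t{e}\t.\t{g.strand}\t"
                            f".\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                        )
        elif kind == "est":
            assert not isinstance(data, PredictionTrack)
            for est in data:
                insert_id = est.insert_id or "seq"
                attrs = f"ID={est.est_id};identity={est.pct_identity:g}"
                if est.source_genus:
                    attrs += f";genus={est.source_genus}"
                fh.write(
                    f"{insert_id}\test\tmatch\t{est.start}\t{est.end}\t.\t"
                    f"{est.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(est.segments, start=1):
                    fh.write(
                        f"{insert_id}\test\tmatch_part\t{s}\t{e}\t.\t{est.strand}"
                        f"\t.\tID={est.est_id}.p{i};Parent={est.est_id}\n"
                    )
        else:
            raise ValueError("kind must be 'prediction' or 'est'")
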