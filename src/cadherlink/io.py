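"""FASTA / tabular input-output for annotation results.

FASTA headers are parsed as ``id|species`` (species defaults to "na").
Annotations serialize to GFF3-like TSV records (source ``cadherlink``,
1-based inclusive coordinates) and to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence_annotation import EctodomainAnnotation, ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "annotation_to_gff",
    "annotation_to_json",
]


def read_fasta(path: str) -> list:
    """Read processed protein sequences; header "id|species"."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        species = parts[1] if len(parts) > 1 else "na"
        records.append(
            ProteinRecord(id=parts[0], species=species,
                          sequence=str(rec.seq).upper())
        )
    return records


def write_fasta(records: Iterable, path: str, gapped_rows=None) -> None:
    seqs = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            seqs.append(
                SeqRecord(Seq(rec.sequence), id=f"{rec.id}|{rec.species}",
                          description="")
            )
        else:  # (id, sequence) pair, e.g. aligned rows
            seqs.append(SeqRecord(Seq(rec[1]), id=rec[0], description=""))
    SeqIO.write(seqs, str(path), "fasta")


def _gff_line(seqid: str, type_: str, start: int, end: int, attrs: dict) -> str:
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join(
        [seqid, "cadherlink", type_, str(start), str(end), ".", ".", ".", attr_s]
    )


def annotation_to_gff(ann: EctodomainAnnotation) -> str:
    """Serialize an ectodomain annotation as GFF3-like TSV."""
    sid = ann.record.id
    lines = ["##gff-version 3"]
    for rep in ann.repeats:
        lines.append(
            _gff_line(sid, "EC_repeat", rep.start, rep.end,
                      {"index": rep.index, "boundary_motif": rep.boundary_motif,
                       "typical_length": rep.typical_length})
        )
    for link in ann.linkers:
        coords = [c for _, (s, e, _) in sorted(link.motif_matches.items(),
                                               key=lambda kv: kv[1][0])
                  for c in (s, e)] or [0, 0]
        lines.append(
            _gff_line(sid, "linker", min(coords), max(coords),
                      {"junction": link.upstream_repeat_index,
                       "classification": link.classification,
                       "predicted_calcium_count": link.predicted_calcium_count})
        )
    if ann.site0 and ann.site0.present:
        pos = ann.site0.element_positions
        start = min(s for s, _ in pos.values())
        end = max(e for _, e in pos.values())
        lines.append(_gff_line(sid, "site0", start, end,
                               {"elements": ",".join(sorted(pos))}))
    for feat in ann.features:
        lines.append(
            _gff_line(sid, feat.kind, min(feat.positions), max(feat.positions),
                      {"detail": feat.detail.replace(";", ",")})
        )
    return "\n".join(lines) + "\n"


def annotation_to_json(ann: EctodomainAnnotation) -> str:
    payload = {
        "id": ann.record.id,
        "species": ann.record.species,
        "length": len(ann.record),
        "repeats": [
            {"index": r.index, "start": r.start, "end": r.end,
             "length": r.length, "boundary_motif": r.boundary_motif}
            for r in ann.repeats
        ],
        "linkers": [asdict(l) for l in ann.linkers],
        "site0": asdict(ann.site0) if ann.site0 else None,
        "features": [asdict(f) for f in ann.features],
    }
    return json.dumps(payload, indent=2, default=str)
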