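"""File formats: FASTA, GFF3 and the truth sidecar.

Coordinates are 0-based half-open everywhere in memory; the GFF3 writer
converts to the format's 1-based inclusive convention and the reader
converts back.
"""
from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils.feature

from .annotate import AnnotatedElement
from .sim import SimResult, TruthRecord

GFF_VERSION_LINE = "##gff-version 3"


def write_fasta(path, records: list[tuple[str, str, str]]) -> None:
    """Write (id, description, sequence) triples, wrapped at 60 columns."""
    seqrecords = [SeqRecord(Seq(seq), id=rid, description=desc)
                  for rid, desc, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _gff_line(seqid: str, source: str, ftype: str, interval, strand: str,
              attrs: dict) -> str:
    start, end = interval
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)
    return "\t".join([seqid, source, ftype, str(start + 1), str(end), ".",
                      strand, ".", attr_str])


def write_truth_gff3(path, result: SimResult) -> None:
    """Planted features as GFF3 with fate/age/pattern attributes."""
    lines = [GFF_VERSION_LINE,
             f"##sequence-region {result.region_id} 1 {len(result.sequence)}"]
    for t in result.truths:
        attrs = {"ID": t.feature_id, "family": t.family_name,
                 "fate": t.fate.name if t.fate else None,
                 "age_years": t.age_years, "tsd": t.tsd_sequence,
                 "pattern": t.pattern, "nested_in": t.nested_in,
                 "donor_id": t.donor_id}
        lines.append(_gff_line(result.region_id, "ltrfate_sim", t.kind,
                               t.interval, "+", attrs))
        for role, iv in sorted(t.sub_intervals.items()):
            lines.append(_gff_line(result.region_id, "ltrfate_sim", "part",
                                   iv, "+",
                                   {"ID": f"{t.feature_id}.{role}",
                                    "Parent": t.feature_id, "role": role}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_elements_gff3(path, region_id: str,
                        elements: list[AnnotatedElement]) -> None:
    """Annotated elements (+ sub-features) as GFF3."""
    lines = [GFF_VERSION_LINE]
    for el in elements:
        attrs = {"ID": el.element_id, "family": el.family_name,
                 "class": el.class_label,
                 "tsd": el.tsd.sequence if el.tsd else None,
                 "tsd_left": (f"{el.tsd.left_copy[0]}-{el.tsd.left_copy[1]}"
                              if el.tsd else None),
                 "tsd_right": (f"{el.tsd.right_copy[0]}-{el.tsd.right_copy[1]}"
                               if el.tsd else None),
                 "structural_pair": int(el.structural_pair)}
        lines.append(_gff_line(region_id, "ltrfate", "repeat_region",
                               el.interval, el.strand, attrs))
        for i, sf in enumerate(el.sub_features, start=1):
            attrs = {"ID": f"{el.element_id}.{i}", "Parent": el.element_id,
                     "role": sf.role, "family": sf.family,
                     "identity": None if sf.identity is None else round(sf.identity, 4),
                     "coverage": None if sf.coverage is None else round(sf.coverage, 4)}
            lines.append(_gff_line(region_id, "ltrfate", "repeat_fragment",
                                   sf.interval, el.strand, attrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list:
    """Parse a GFF3 file into gffutils Feature objects.

    Raises ``ValueError`` naming the offending line number on a corrupt row.
    """
    features = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
            raise ValueError(f"{path}: corrupt GFF3 at line {lineno}: "
                             f"expected 9 tab-separated fields")
        try:
            features.append(gffutils.feature.feature_from_line(line))
        except Exception as exc:
            raise ValueError(f"{path}: corrupt GFF3 at line {lineno}: {exc}") from exc
    return features


def write_truth_sidecar(path, truths: list[TruthRecord]) -> None:
    """One-record-per-line key=value truth file (lossless round trip)."""
    Path(path).write_text("".join(t.to_line() + "\n" for t in truths))


def load_truth_sidecar(path) -> list[TruthRecord]:
    return [TruthRecord.from_line(line)
            for line in Path(path).read_text().splitlines() if line.strip()]


def emit_truth(result: SimResult, outdir) -> dict[str, Path]:
    """Write a simulated region as FASTA + GFF3 + truth sidecar (+ library).

    Returns the paths written; reading the sidecar back reproduces the
    truth records exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{result.region_id}.fa",
        "gff3": outdir / f"{result.region_id}.truth.gff3",
        "truth": outdir / f"{result.region_id}.truth.tsv",
        "library": outdir / "library.fa",
    }
    try:
        write_fasta(paths["fasta"], [(result.region_id, "synthetic region",
                                      result.sequence)])
        write_truth_gff3(paths["gff3"], result)
        write_truth_sidecar(paths["truth"], result.truths)
        result.library.to_fasta(paths["library"])
    except OSError as exc:
        raise OSError(f"failed writing truth bundle under {outdir}: {exc}") from exc
    return paths
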