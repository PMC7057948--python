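"""Reading annotated genomes and writing screen outputs.

Coordinates are normalised to 0-based half-open intervals internally
(GenBank flat files are 1-based inclusive); interval length is always
``end - start`` and promoter intervals serialise directly to BED.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: matches "EC 1.2.3.4" / "EC:1.2.3.4" inside free-text product annotations;
#: the last field may be "-" for incompletely classified enzymes.
EC_PATTERN = re.compile(r"\bEC[:\s]*(\d+\.\d+\.\d+\.(?:\d+|-))", re.IGNORECASE)


@dataclass
class GeneRecord:
    """One annotated protein-coding gene.

    ``start``/``end`` are 0-based half-open base-pair coordinates on the
    top strand regardless of the coding strand.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    is_tr: bool = False
    tr_family: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.is_tr and self.tr_family is not None:
            raise ValueError(f"{self.gene_id}: tr_family set on a non-regulator gene")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the transcription start side."""
        return self.start if self.strand == "+" else self.end


@dataclass
class Replicon:
    replicon_id: str
    length: int
    genes: list[GeneRecord]
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"{g.gene_id}: end {g.end} exceeds replicon length {self.length}"
                )


@dataclass
class GenomeAnnotation:
    """Ordered collection of replicons, each with its genes sorted by start."""

    replicons: list[Replicon]

    def iter_genes(self) -> Iterator[GeneRecord]:
        for rep in self.replicons:
            yield from rep.genes

    def get_replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise KeyError(replicon_id)

    @property
    def n_genes(self) -> int:
        return sum(len(r.genes) for r in self.replicons)


def _harvest_ec_numbers(feature) -> list[str]:
    """EC numbers from the EC_number qualifier plus patterns in the product text."""
    ecs: list[str] = []
    for ec in feature.qualifiers.get("EC_number", []):
        ec = ec.strip()
        if ec and ec not in ecs:
            ecs.append(ec)
    product = feature.qualifiers.get("product", [""])[0]
    for match in EC_PATTERN.finditer(product):
        ec = match.group(1)
        if ec not in ecs:
            ecs.append(ec)
    return ecs


def read_annotated_genome(path: str | Path, keep_sequence: bool = True) -> GenomeAnnotation:
    """Parse a GenBank flat file into a :class:`GenomeAnnotation`.

    One :class:`GeneRecord` is produced per CDS feature; pseudo-genes and
    non-CDS features are ignored.  Compound (``join``) locations are
    flattened to their outer span, which is sufficient for the orientation
    and intergenic-distance arithmetic the screen performs.

    Parameters
    ----------
    path:
        Readable GenBank flat file with at least one record.
    keep_sequence:
        Retain the nucleotide sequence (needed for promoter sequence
        extraction) when the record carries one.
    """
    path = Path(path)
    replicons: list[Replicon] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        genes: list[GeneRecord] = []
        for idx, feature in enumerate(record.features):
            if feature.type != "CDS":
                continue
            if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
                continue
            loc = feature.location
            if loc is None:
                continue
            start, end = int(loc.start), int(loc.end)
            if len(getattr(loc, "parts", [loc])) > 1:
                logger.warning(
                    "%s: compound location for feature %d flattened to outer span [%d, %d)",
                    record.id, idx, start, end,
                )
            strand = "-" if loc.strand == -1 else "+"
            locus = feature.qualifiers.get(
                "locus_tag", feature.qualifiers.get("gene", [f"{record.id}_cds{idx}"])
            )[0]
            genes.append(
                GeneRecord(
                    gene_id=locus,
                    replicon_id=record.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=feature.qualifiers.get("product", [""])[0],
                    ec_numbers=_harvest_ec_numbers(feature),
                )
            )
        if not genes:
            logger.warning("%s: record contains no CDS features", record.id)
        seq = None
        if keep_sequence:
            try:
                seq = str(record.seq)
            except Exception:  # undefined sequence (e.g. CONTIG-only record)
                seq = None
        replicons.append(
            Replicon(
                replicon_id=record.id,
                length=len(record) if len(record) else max((g.end for g in genes), default=0),
                genes=genes,
                sequence=seq,
            )
        )
    if n_records == 0:
        raise ValueError(f"{path}: no GenBank records found")
    return GenomeAnnotation(replicons=replicons)


CANDIDATE_COLUMNS = [
    "tr_id",
    "tr_family",
    "replicon_id",
    "promoter_start",
    "promoter_end",
    "promoter_length",
    "operon_genes",
    "n_catalytic",
    "status",
    "reason",
    "ligands",
]


def write_candidates(candidates, path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write candidate systems as a TSV table (one row per candidate).

    Ligands serialise as ``compound:consumed_by:produced_by`` triples joined
    by ``;`` in rank order.  Optionally also writes promoter intervals as a
    6-column-free BED file (chrom, start, end, name).
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for cand in candidates:
            pair = cand.pair
            rep, pstart, pend = pair.promoter_interval
            writer.writerow(
                [
                    pair.tr.gene_id,
                    pair.tr.tr_family or "unknown",
                    rep,
                    pstart,
                    pend,
                    pend - pstart,
                    ";".join(g.gene_id for g in pair.operon.genes),
                    pair.operon.n_catalytic,
                    cand.status,
                    cand.reason,
                    ";".join(
                        f"{l.compound}:{l.consumed_by}:{l.produced_by}" for l in cand.ligands
                    ),
                ]
            )
    if bed_path is not None:
        with Path(bed_path).open("w") as fh:
            for cand in candidates:
                rep, pstart, pend = cand.pair.promoter_interval
                fh.write(f"{rep}\t{pstart}\t{pend}\t{cand.pair.tr.gene_id}\n")


def read_candidates_table(path: str | Path) -> list[dict]:
    """Read a candidate TSV back into a list of typed row dicts."""
    rows = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            row["promoter_start"] = int(row["promoter_start"])
            row["promoter_end"] = int(row["promoter_end"])
            row["promoter_length"] = int(row["promoter_length"])
            row["n_catalytic"] = int(row["n_catalytic"])
            row["operon_genes"] = row["operon_genes"].split(";") if row["operon_genes"] else []
            ligands = []
            if row["ligands"]:
                for item in row["ligands"].split(";"):
                    compound, consumed, produced = item.rsplit(":", 2)
                    ligands.append((compound, int(consumed), int(produced)))
            row["ligands"] = ligands
            rows.append(row)
    return rows
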