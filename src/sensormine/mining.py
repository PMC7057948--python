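"""Detection of divergent regulator-operon arrangements.

The screen looks for the genetic architecture typical of LysR-type
transcriptional regulators: a TR gene transcribed divergently from a
metabolic operon, the two sharing a compact intergenic region that
contains both promoters.  Operons are called as maximal runs of
co-directional genes separated by short gaps; a divergent pair is a TR
whose 5' end faces the 5' end of an operon's first gene across an
intergenic region no wider than ``max_intergenic``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .genome_io import GeneRecord, GenomeAnnotation

logger = logging.getLogger(__name__)

#: default operon gap: co-transcribed prokaryotic genes are rarely separated
#: by more than ~150 bp.
DEFAULT_MAX_GAP = 150
#: default ceiling on the TR-operon intergenic region; divergent promoters
#: are compact (the benzoate exemplar is 146 bp).
DEFAULT_MAX_INTERGENIC = 500

#: (pattern, family) pairs applied case-insensitively to product text.
#: Family tokens come first so e.g. "LysR family transcriptional regulator"
#: is assigned its family rather than the generic match.
DEFAULT_TR_LEXICON: list[tuple[str, str]] = [
    (r"\blysr\b", "LysR"),
    (r"\bmarr\b", "MarR"),
    (r"\basnc\b", "AsnC"),
    (r"\bmocr\b", "MocR"),
    (r"\biclr\b", "IclR"),
    (r"\btetr\b", "TetR"),
    (r"\barac\b", "AraC"),
    (r"\bgntr\b", "GntR"),
    (r"\blaci\b", "LacI"),
    (r"\bxre\b", "XRE"),
    (r"sigma[- ]?54[- ]dependent", "sigma54"),
    (r"transcriptional\s+(regulator|activator|repressor)", ""),
    (r"transcription\s+(factor|regulator|activator|repressor)", ""),
]

#: catalytic-product heuristic: enzyme names overwhelmingly end in "-ase".
CATALYTIC_PATTERN = re.compile(
    r"[a-z]ase\b|dehydrogenase|decarboxylase|transferase|hydrolase|isomerase|"
    r"ligase|oxidase|reductase|synthase|kinase|lyase",
    re.IGNORECASE,
)


def is_catalytic(gene: GeneRecord) -> bool:
    """A gene counts as catalytic if it carries an EC number or an
    enzyme-like product name.  TR genes never count, even when they carry
    an EC number, so a regulator cannot satisfy the operon filter itself."""
    if gene.is_tr:
        return False
    if gene.ec_numbers:
        return True
    return bool(CATALYTIC_PATTERN.search(gene.product))


@dataclass
class Operon:
    """Maximal run of co-directional genes, ordered in transcription
    direction (ascending start on '+', descending on '-')."""

    replicon_id: str
    strand: str
    genes: list[GeneRecord]
    n_catalytic: int = 0

    def __post_init__(self) -> None:
        if any(g.strand != self.strand for g in self.genes):
            raise ValueError("operon members must share the operon strand")
        self.n_catalytic = sum(is_catalytic(g) for g in self.genes)

    @property
    def first_gene(self) -> GeneRecord:
        """The promoter-proximal gene (first in transcription order)."""
        return self.genes[0]

    @property
    def span(self) -> tuple[int, int]:
        starts = [g.start for g in self.genes]
        ends = [g.end for g in self.genes]
        return min(starts), max(ends)


@dataclass
class DivergentPair:
    """A TR gene head-to-head with an operon across a shared intergenic
    region (the candidate bidirectional promoter)."""

    tr: GeneRecord
    operon: Operon
    promoter_interval: tuple[str, int, int]

    def __post_init__(self) -> None:
        if self.tr.strand == self.operon.strand:
            raise ValueError("divergent pair requires opposite strands")
        _, start, end = self.promoter_interval
        if end < start:
            raise ValueError("negative promoter interval")

    @property
    def intergenic_length(self) -> int:
        _, start, end = self.promoter_interval
        return end - start


def detect_tr_genes(
    annotation: GenomeAnnotation,
    vocabulary: Optional[list[tuple[str, str]]] = None,
) -> GenomeAnnotation:
    """Flag transcriptional regulators by product-text keyword matching.

    ``is_tr`` is set iff any lexicon pattern matches the product;
    ``tr_family`` is the first matching family token, else ``"unknown"``.
    The annotation is modified in place and returned.
    """
    lexicon = vocabulary if vocabulary is not None else DEFAULT_TR_LEXICON
    if not lexicon:
        raise ValueError("TR vocabulary must be non-empty")
    compiled = [(re.compile(pat, re.IGNORECASE), fam) for pat, fam in lexicon]
    for gene in annotation.iter_genes():
        family = None
        matched = False
        for pattern, fam in compiled:
            if pattern.search(gene.product):
                matched = True
                if fam and family is None:
                    family = fam
        gene.is_tr = matched
        gene.tr_family = (family or "unknown") if matched else None
    return annotation


def infer_operons(annotation: GenomeAnnotation, max_gap: int = DEFAULT_MAX_GAP) -> list[Operon]:
    """Call operons as maximal same-strand runs with intergenic gaps
    <= ``max_gap``.

    TR genes are excluded from operon membership and break runs (a
    regulator gene marks a transcription-unit boundary).  Single-gene runs
    are returned; the >=2-catalytic-genes rule is applied downstream.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    operons: list[Operon] = []
    for rep in annotation.replicons:
        run: list[GeneRecord] = []
        for gene in rep.genes:
            if gene.is_tr:
                if run:
                    operons.append(_make_operon(rep.replicon_id, run))
                run = []
                continue
            if run and (gene.strand != run[-1].strand or gene.start - run[-1].end > max_gap):
                operons.append(_make_operon(rep.replicon_id, run))
                run = []
            run.append(gene)
        if run:
            operons.append(_make_operon(rep.replicon_id, run))
    return operons


def _make_operon(replicon_id: str, run: list[GeneRecord]) -> Operon:
    strand = run[0].strand
    genes = sorted(run, key=lambda g: g.start, reverse=(strand == "-"))
    return Operon(replicon_id=replicon_id, strand=strand, genes=genes)


def find_divergent_candidates(
    annotation: GenomeAnnotation,
    operons: list[Operon],
    max_intergenic: int = DEFAULT_MAX_INTERGENIC,
) -> list[DivergentPair]:
    """Pair each TR with the nearest head-to-head operon on the opposite
    strand.

    A '-'-strand TR transcribes leftward, so its promoter side is its high
    coordinate and an eligible operon sits on the '+' strand to its right;
    mirror-image for a '+'-strand TR.  Convergent and co-directional
    arrangements never qualify.  Pairs whose intergenic region is negative
    (overlapping genes), wider than ``max_intergenic``, or interrupted by
    another CDS are rejected.
    """
    by_replicon: dict[str, list[Operon]] = {}
    for op in operons:
        by_replicon.setdefault(op.replicon_id, []).append(op)

    pairs: list[DivergentPair] = []
    for rep in annotation.replicons:
        rep_operons = by_replicon.get(rep.replicon_id, [])
        for tr in rep.genes:
            if not tr.is_tr:
                continue
            best: Optional[tuple[int, Operon, int, int]] = None
            for op in rep_operons:
                if op.strand == tr.strand:
                    continue
                first = op.first_gene
                if tr.strand == "-":
                    # TR 5' end at tr.end; operon must start to the right
                    start, end = tr.end, first.start
                else:
                    # TR 5' end at tr.start; operon first gene ends to the left
                    start, end = first.end, tr.start
                gap = end - start
                if gap < 0:
                    if first.start < tr.end and first.end > tr.start:
                        logger.info(
                            "rejecting %s / %s: genes overlap (intergenic %d bp)",
                            tr.gene_id, first.gene_id, gap,
                        )
                    continue
                if gap > max_intergenic:
                    continue
                if _interval_hits_cds(rep.genes, start, end, exclude={tr.gene_id, first.gene_id}):
                    continue
                if best is None or gap < best[0]:
                    best = (gap, op, start, end)
            if best is not None:
                gap, op, start, end = best
                pairs.append(
                    DivergentPair(
                        tr=tr,
                        operon=op,
                        promoter_interval=(rep.replicon_id, start, end),
                    )
                )
    pairs.sort(key=lambda p: (p.promoter_interval[0], p.promoter_interval[1], p.tr.gene_id))
    return pairs


def _interval_hits_cds(genes: list[GeneRecord], start: int, end: int, exclude: set[str]) -> bool:
    if end <= start:
        return False
    return any(
        g.start < end and g.end > start for g in genes if g.gene_id not in exclude
    )


@dataclass
class PromoterRegion:
    replicon_id: str
    start: int
    end: int
    sequence: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_promoter_region(pair: DivergentPair, annotation: GenomeAnnotation) -> PromoterRegion:
    """Return the shared intergenic interval, with its sequence reported on
    the operon's coding strand when the record carries sequence."""
    rep_id, start, end = pair.promoter_interval
    rep = annotation.get_replicon(rep_id)
    if start < 0 or end > rep.length:
        raise ValueError(
            f"promoter interval [{start}, {end}) outside replicon {rep_id} "
            f"of length {rep.length}"
        )
    if end == start:
        logger.warning("%s: zero-length intergenic region (abutting genes)", pair.tr.gene_id)
    seq = None
    if rep.sequence is not None:
        seq = rep.sequence[start:end]
        if pair.operon.strand == "-":
            seq = str(Seq(seq).reverse_complement())
    return PromoterRegion(replicon_id=rep_id, start=start, end=end, sequence=seq)
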