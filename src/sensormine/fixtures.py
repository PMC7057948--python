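"""Synthetic test-data generators.

Two generators make the whole pipeline testable without any downloads:

* :func:`generate_toy_genome` writes a GenBank record containing planted
  divergent TR-operon systems (each operon's EC numbers form a linear toy
  pathway in a companion reaction-KB file) plus decoy arrangements that a
  correct screen must reject, together with a JSON ground-truth manifest.

* :func:`simulate_plate_timecourse` emulates a plate-reader run: logistic
  growth, constant medium autofluorescence, and a reporter signal whose
  OD-normalised value follows the Hill dose-response law at each well's
  inducer concentration.  Optional multiplicative log-normal noise models
  signal-proportional measurement error.

Both are deterministic: the same spec and seed reproduce the artifacts
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .doseresponse import PlateTimeCourse, hill
from .ligand_inference import ReactionEntry, ReactionKB, write_reaction_kb

TR_FAMILIES = ["LysR", "MarR", "AsnC", "MocR", "IclR", "TetR", "AraC", "GntR"]
CATALYTIC_NAMES = ["dehydrogenase", "decarboxylase", "transferase", "hydrolase", "isomerase"]

GENE_LEN = 900          # bp per toy CDS
INTRA_OPERON_GAP = 80   # bp between operon members (< default max_gap)
CASSETTE_SPACER = 1500  # bp between cassettes (> default max_intergenic)


@dataclass
class PlantSpec:
    """Layout specification for a planted toy genome."""

    n_systems: int = 3
    n_decoys: int = 4
    intergenic_lengths: tuple[int, int] = (80, 300)
    operon_sizes: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_systems < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        if self.intergenic_lengths[0] > self.intergenic_lengths[1]:
            raise ValueError("empty intergenic-length range")
        if not (2 <= self.operon_sizes[0] <= self.operon_sizes[1]):
            raise ValueError("operon sizes must be >= 2 and form a non-empty range")


@dataclass
class _Cassette:
    features: list[SeqFeature]
    length: int


def _tr_feature(start: int, end: int, strand: int, locus: str, family: str) -> SeqFeature:
    return SeqFeature(
        FeatureLocation(start, end, strand=strand),
        type="CDS",
        qualifiers={
            "locus_tag": [locus],
            "product": [f"{family} family transcriptional regulator"],
        },
    )


def _enzyme_feature(start: int, end: int, strand: int, locus: str, name: str,
                    ec: Optional[str]) -> SeqFeature:
    quals = {"locus_tag": [locus], "product": [name]}
    if ec is not None:
        quals["EC_number"] = [ec]
    return SeqFeature(FeatureLocation(start, end, strand=strand), type="CDS", qualifiers=quals)


def _planted_cassette(idx: int, rng: np.random.Generator, spec: PlantSpec,
                      kb: ReactionKB, manifest_systems: list[dict]) -> _Cassette:
    """One TR divergently opposed to a linear-pathway operon.

    Orientation 'right': TR on '-' with the operon on '+' downstream of the
    shared intergenic region; 'left' is the mirror image.
    """
    n_genes = int(rng.integers(spec.operon_sizes[0], spec.operon_sizes[1] + 1))
    gap = int(rng.integers(spec.intergenic_lengths[0], spec.intergenic_lengths[1] + 1))
    family = TR_FAMILIES[int(rng.integers(len(TR_FAMILIES)))]
    rightward = bool(rng.integers(2))
    tr_id = f"TOY_TR{idx:03d}"

    compounds = [f"cpd_s{idx}_{j}" for j in range(n_genes + 1)]
    ecs = [f"9.{idx + 1}.{j + 1}.1" for j in range(n_genes)]
    for j, ec in enumerate(ecs):
        subs = {compounds[j]}
        prods = {compounds[j + 1]}
        if j % 2 == 1:
            subs.add("nad+")       # blacklisted cofactors exercise removal
            prods.add("nadh")
        else:
            prods.add("h2o")
        kb.entries.setdefault(ec, []).append(
            ReactionEntry(ec=ec, substrates=frozenset(subs), products=frozenset(prods))
        )

    features: list[SeqFeature] = []
    operon_ids = [f"TOY_G{idx:03d}_{j}" for j in range(n_genes)]
    if rightward:
        tr_start, tr_end = 0, GENE_LEN
        features.append(_tr_feature(tr_start, tr_end, -1, tr_id, family))
        pos = tr_end + gap
        for j in range(n_genes):
            name = f"toy pathway {CATALYTIC_NAMES[j % len(CATALYTIC_NAMES)]} {j}"
            features.append(_enzyme_feature(pos, pos + GENE_LEN, +1, operon_ids[j], name, ecs[j]))
            pos += GENE_LEN + INTRA_OPERON_GAP
        length = pos
        promoter = (tr_end, tr_end + gap)
    else:
        # operon on '-' (transcribed leftward), TR on '+' to its right
        pos = 0
        for j in reversed(range(n_genes)):
            name = f"toy pathway {CATALYTIC_NAMES[j % len(CATALYTIC_NAMES)]} {j}"
            features.append(_enzyme_feature(pos, pos + GENE_LEN, -1, operon_ids[j], name, ecs[j]))
            pos += GENE_LEN + INTRA_OPERON_GAP
        first_gene_end = pos - INTRA_OPERON_GAP
        tr_start = first_gene_end + gap
        features.append(_tr_feature(tr_start, tr_start + GENE_LEN, +1, tr_id, family))
        length = tr_start + GENE_LEN
        promoter = (first_gene_end, tr_start)

    manifest_systems.append(
        {
            "tr_id": tr_id,
            "tr_family": family,
            "promoter_offset": list(promoter),  # within-cassette; shifted later
            "operon_genes": operon_ids,
            "ecs": ecs,
            "entry_compound": compounds[0],
        }
    )
    return _Cassette(features=features, length=length)


def _decoy_cassette(idx: int, kind: str, rng: np.random.Generator,
                    kb: ReactionKB, manifest_decoys: list[dict]) -> _Cassette:
    family = TR_FAMILIES[int(rng.integers(len(TR_FAMILIES)))]
    tr_id = f"TOY_DTR{idx:03d}"
    features: list[SeqFeature] = []
    if kind == "convergent":
        # TR 5' end faces away; enzyme genes approach it 3'-to-3'
        features.append(_tr_feature(0, GENE_LEN, +1, tr_id, family))
        pos = GENE_LEN + 120
        for j in range(2):
            features.append(
                _enzyme_feature(pos, pos + GENE_LEN, -1, f"TOY_DG{idx:03d}_{j}",
                                f"decoy {CATALYTIC_NAMES[j]}", None)
            )
            pos += GENE_LEN + INTRA_OPERON_GAP
        length = pos
    elif kind == "codirectional":
        features.append(_tr_feature(0, GENE_LEN, +1, tr_id, family))
        pos = GENE_LEN + 120
        for j in range(2):
            features.append(
                _enzyme_feature(pos, pos + GENE_LEN, +1, f"TOY_DG{idx:03d}_{j}",
                                f"decoy {CATALYTIC_NAMES[j]}", None)
            )
            pos += GENE_LEN + INTRA_OPERON_GAP
        length = pos
    elif kind == "single_gene":
        # genuinely divergent, but the operon has only one catalytic gene
        ec = f"8.{idx + 1}.1.1"
        kb.entries.setdefault(ec, []).append(
            ReactionEntry(
                ec=ec,
                substrates=frozenset({f"decoy_s{idx}_in"}),
                products=frozenset({f"decoy_s{idx}_out"}),
            )
        )
        features.append(_tr_feature(0, GENE_LEN, -1, tr_id, family))
        gene_start = GENE_LEN + 150
        features.append(
            _enzyme_feature(gene_start, gene_start + GENE_LEN, +1,
                            f"TOY_DG{idx:03d}_0", "decoy lone hydrolase", ec)
        )
        length = gene_start + GENE_LEN
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    manifest_decoys.append({"kind": kind, "tr_id": tr_id})
    return _Cassette(features=features, length=length)


def generate_toy_genome(spec: PlantSpec, out_dir: str | Path) -> dict:
    """Write ``toy_genome.gbk``, ``toy_kb.tsv`` and ``manifest.json`` into
    ``out_dir`` and return the manifest dict.

    The manifest records, per planted system, the TR locus tag, the
    absolute promoter interval, the operon gene ids and the true entry
    compound — the ground truth against which mining recall is scored.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    kb = ReactionKB()
    systems: list[dict] = []
    decoys: list[dict] = []
    cassettes: list[_Cassette] = []
    for i in range(spec.n_systems):
        cassettes.append(_planted_cassette(i, rng, spec, kb, systems))
    decoy_kinds = ["convergent", "codirectional", "single_gene"]
    for d in range(spec.n_decoys):
        cassettes.append(_decoy_cassette(d, decoy_kinds[d % 3], rng, kb, decoys))
    order = rng.permutation(len(cassettes))

    features: list[SeqFeature] = []
    offset = CASSETTE_SPACER
    system_by_first_feature: dict[int, dict] = {}
    for pos_in_layout, cass_idx in enumerate(order):
        cass = cassettes[cass_idx]
        for feat in cass.features:
            features.append(
                SeqFeature(
                    FeatureLocation(
                        int(feat.location.start) + offset,
                        int(feat.location.end) + offset,
                        strand=feat.location.strand,
                    ),
                    type="CDS",
                    qualifiers=feat.qualifiers,
                )
            )
        if cass_idx < spec.n_systems:
            sys_entry = systems[cass_idx]
            p0, p1 = sys_entry.pop("promoter_offset")
            sys_entry["promoter_start"] = p0 + offset
            sys_entry["promoter_end"] = p1 + offset
        offset += cass.length + CASSETTE_SPACER

    total_len = offset
    seq = "".join(rng.choice(list("ACGT"), size=total_len))
    features.sort(key=lambda f: int(f.location.start))
    record = SeqRecord(
        Seq(seq),
        id="toygenome",
        name="toygenome",
        description="synthetic chromosome with planted divergent TR-operon systems",
        features=features,
        annotations={"molecule_type": "DNA", "topology": "linear", "date": "01-JAN-2020"},
    )
    gbk_path = out_dir / "toy_genome.gbk"
    SeqIO.write([record], str(gbk_path), "genbank")
    kb_path = out_dir / "toy_kb.tsv"
    write_reaction_kb(kb, kb_path)

    for entry in systems:
        entry["replicon_id"] = "toygenome"
    manifest = {
        "spec": {
            "n_systems": spec.n_systems,
            "n_decoys": spec.n_decoys,
            "intergenic_lengths": list(spec.intergenic_lengths),
            "operon_sizes": list(spec.operon_sizes),
            "seed": spec.seed,
        },
        "replicon_id": "toygenome",
        "replicon_length": total_len,
        "systems": systems,
        "decoys": decoys,
        "genome_path": str(gbk_path),
        "kb_path": str(kb_path),
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# plate-reader simulation


@dataclass
class SimSpec:
    """Specification of one simulated dose-response plate run.

    ``hill`` is the ground truth (b_min, b_max, K_m, h); defaults are the
    beta-alanine-sensor regime (8-fold dynamic range, K_m = 201 uM,
    h = 0.75, basal output 100 AFU/OD).  Twelve log-spaced concentrations
    spanning 0.01x-100x K_m (plus uninduced wells) are used unless
    ``concentrations`` is given.  Sampling every 5 min over 6 h matches a
    standard kinetic plate-reader protocol.
    """

    hill: tuple[float, float, float, float] = (100.0, 800.0, 201e-6, 0.75)
    concentrations: Optional[Sequence[float]] = None
    noise_cv: float = 0.0
    n_replicates: int = 3
    od0: float = 0.05
    od_max: float = 1.5
    growth_rate: float = 0.02     # per minute
    sampling_interval: float = 5  # minutes
    duration: float = 360         # minutes
    blank_od: float = 0.04
    blank_fl: float = 100.0
    n_blanks: int = 3
    system_id: str = "sim"
    inducer: str = "ligand"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def concentration_grid(self) -> np.ndarray:
        if self.concentrations is not None:
            return np.asarray(self.concentrations, dtype=float)
        km = self.hill[2]
        return np.concatenate([[0.0], np.geomspace(0.01 * km, 100 * km, 12)])


def _logistic_od(t: np.ndarray, od0: float, od_max: float, rate: float) -> np.ndarray:
    e = np.exp(rate * t)
    return od_max * od0 * e / (od_max + od0 * (e - 1.0))


def simulate_plate_timecourse(spec: SimSpec) -> list[PlateTimeCourse]:
    """Simulate raw plate-reader wells (including blanks) for one system.

    The OD-normalised reporter truth in each well is the Hill response at
    that well's concentration, held constant over the course; raw
    fluorescence is truth x biomass plus medium autofluorescence, with
    multiplicative log-normal noise of coefficient of variation
    ``noise_cv`` applied to the signal component.  ``noise_cv = 0`` makes
    normalisation + window extraction + fitting the exact inverse of the
    generator.
    """
    rng = np.random.default_rng(spec.seed)
    b_min, b_max, km, h = spec.hill
    times = np.arange(0.0, spec.duration + spec.sampling_interval / 2, spec.sampling_interval)
    od_growth = _logistic_od(times, spec.od0, spec.od_max, spec.growth_rate)
    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    else:
        sigma = 0.0

    courses: list[PlateTimeCourse] = []
    well = 0
    for conc in spec.concentration_grid():
        truth = float(hill(conc, b_max, km, h, b_min))
        for rep in range(spec.n_replicates):
            signal = truth * od_growth
            if sigma > 0:
                factors = np.exp(rng.normal(-sigma**2 / 2, sigma, size=times.shape))
                signal = signal * factors
            courses.append(
                PlateTimeCourse(
                    well_id=f"W{well:03d}",
                    system_id=spec.system_id,
                    inducer=spec.inducer if conc > 0 else "none",
                    concentration=float(conc),
                    times=times,
                    fluorescence=signal + spec.blank_fl,
                    absorbance=od_growth + spec.blank_od,
                    is_blank=False,
                    replicate=rep,
                )
            )
            well += 1
    for b in range(spec.n_blanks):
        courses.append(
            PlateTimeCourse(
                well_id=f"B{b:03d}",
                system_id=spec.system_id,
                inducer="none",
                concentration=0.0,
                times=times,
                fluorescence=np.full_like(times, spec.blank_fl),
                absorbance=np.full_like(times, spec.blank_od),
                is_blank=True,
                replicate=b,
            )
        )
    return courses
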