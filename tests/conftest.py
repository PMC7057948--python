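"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import nnls

from sensormine import (
    PlantSpec,
    generate_toy_genome,
    load_reaction_kb,
    read_annotated_genome,
)
from sensormine.genome_io import GeneRecord, GenomeAnnotation, Replicon

#: published dose-response parameters of six characterised biosensors
#: (dynamic range mu in fold, K_m in molar, Hill coefficient h)
SENSOR_PARAMS = {
    "NahR_salicylate": (650.8, 2.12e-6, 0.66),
    "BenM_benzoate": (74.1, 12.6e-6, 1.64),
    "OapR_beta_alanine": (8.0, 201e-6, 0.75),
    "AcoR_acetoin": (11.1, 1.23e-6, 1.36),
    "TtdR_tartrate": (370.6, 61.5e-3, 0.80),
    "SauR_sulfonatoacetate": (395.4, 7.3e-3, 0.57),
}


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A planted toy genome (3 systems, 4 decoys), parsed, with its KB."""
    out = tmp_path_factory.mktemp("toy_genome")
    manifest = generate_toy_genome(PlantSpec(n_systems=3, n_decoys=4, seed=7), out)
    annotation = read_annotated_genome(manifest["genome_path"])
    kb = load_reaction_kb(manifest["kb_path"])
    return manifest, annotation, kb


def make_annotation(genes: list[GeneRecord], length: int = 100_000,
                    replicon_id: str = "chr") -> GenomeAnnotation:
    """Assemble a single-replicon annotation from hand-written gene records."""
    return GenomeAnnotation(replicons=[
        Replicon(replicon_id=replicon_id, length=length, genes=list(genes))
    ])


def gene(gene_id: str, start: int, end: int, strand: str, product: str = "",
         ec: list[str] | None = None) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id, replicon_id="chr", start=start, end=end, strand=strand,
        product=product, ec_numbers=ec or [],
    )


def grid_search_sse(I: np.ndarray, rfp: np.ndarray, n_km: int = 40, n_h: int = 40) -> float:
    """Independent coarse-grid Hill SSE oracle.

    Exhaustive grid over (K_m, h) with the conditionally-linear pair
    (b_max, b_min) solved in closed form at every node by non-negative
    least squares.  Returns the smallest SSE found.
    """
    pos = I[I > 0]
    best = np.inf
    for km in np.geomspace(pos.min() * 1e-2, pos.max() * 1e2, n_km):
        for h in np.geomspace(0.1, 10.0, n_h):
            shape = I**h / (km**h + I**h)
            design = np.column_stack([shape, np.ones_like(I)])
            coef, _ = nnls(design, rfp)
            sse = float(np.sum((rfp - design @ coef) ** 2))
            if sse < best:
                best = sse
    return best


def brute_force_sources(reactions, blacklist) -> set[str]:
    """Enumerate pathway entry compounds by direct definition: consumed by
    at least one reaction, produced by none (reversible reactions produce
    their substrates too)."""
    consumed, produced = set(), set()
    for rxn in reactions:
        subs = set(rxn.substrates) - set(blacklist)
        prods = set(rxn.products) - set(blacklist)
        if not subs or not prods:
            continue
        consumed |= subs
        produced |= prods
        if rxn.reversible:
            consumed |= prods
            produced |= subs
    return {c for c in consumed if c not in produced}
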