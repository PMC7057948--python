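"""Cross-reactivity matrices, hit calling and orthogonality reporting.

Every (system, compound) measurement is reduced to a relative induction

    rel% = 100 * (FL_compound - FL_uninduced) / (FL_primary - FL_uninduced)

where FL is OD-normalised fluorescence and FL_primary is the response to
the system's own (primary) effector.  A compound is a cross-reactivity hit
for a non-cognate system when rel >= 5% AND its absolute fold induction is
>= 5; a system is orthogonal when every non-cognate compound stays
strictly below 5% relative induction.  Negative values (repression) are
reported as-is, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_REL_THRESHOLD = 5.0   # percent, hit rule uses >=
DEFAULT_FOLD_THRESHOLD = 5.0  # fold, hit rule uses >=


@dataclass
class InductionMeasurement:
    """Normalised fluorescence of one system with one test compound, its
    uninduced control and its primary-effector control, all at the same
    post-induction time."""

    system_id: str
    compound_id: str
    fl_compound: float
    fl_uninduced: float
    fl_primary: float

    def __post_init__(self) -> None:
        if self.fl_primary == self.fl_uninduced:
            raise ValueError(
                f"{self.system_id}/{self.compound_id}: FL_primary equals FL_uninduced, "
                "relative induction undefined"
            )


@dataclass
class Hit:
    system_id: str
    compound_id: str
    rel: float
    fold: float


@dataclass
class CrossReactivityMatrix:
    """systems x compounds relative-induction and fold matrices.

    ``rel`` and ``fold`` are DataFrames indexed by system and compound;
    missing combinations are NaN (absent, not zero)."""

    systems: list[str]
    compounds: list[str]
    rel: pd.DataFrame
    fold: pd.DataFrame
    primary_map: dict[str, str]
    hits: Optional[pd.DataFrame] = None
    orthogonal_systems: Optional[set[str]] = None


def relative_induction(fl_compound: float, fl_uninduced: float, fl_primary: float) -> float:
    """Relative induction in percent; may be negative (repression) or
    exceed 100 (super-induction)."""
    denom = fl_primary - fl_uninduced
    if denom == 0:
        raise ValueError("FL_primary equals FL_uninduced: relative induction undefined")
    return 100.0 * (fl_compound - fl_uninduced) / denom


def build_matrix(
    measurements: Sequence[InductionMeasurement],
    primary_map: dict[str, str],
) -> CrossReactivityMatrix:
    """Assemble the rel/fold matrices from long-format measurements.

    Each (system, compound) pair may appear at most once and FL_primary
    must be consistent within a system; every system needs a measurement
    of its own primary compound (this is what anchors the 100% diagonal).
    """
    seen: set[tuple[str, str]] = set()
    primary_fl: dict[str, float] = {}
    for m in measurements:
        key = (m.system_id, m.compound_id)
        if key in seen:
            raise ValueError(f"duplicate measurement for {key}")
        seen.add(key)
        prev = primary_fl.setdefault(m.system_id, m.fl_primary)
        if prev != m.fl_primary:
            raise ValueError(f"{m.system_id}: inconsistent FL_primary values")

    systems = sorted({m.system_id for m in measurements})
    compounds = sorted({m.compound_id for m in measurements})
    for sys_id in systems:
        if sys_id not in primary_map:
            raise ValueError(f"{sys_id}: no primary compound assigned")
        if (sys_id, primary_map[sys_id]) not in seen:
            raise ValueError(f"{sys_id}: primary-effector measurement missing")

    rel = pd.DataFrame(np.nan, index=systems, columns=compounds)
    fold = pd.DataFrame(np.nan, index=systems, columns=compounds)
    for m in measurements:
        rel.loc[m.system_id, m.compound_id] = relative_induction(
            m.fl_compound, m.fl_uninduced, m.fl_primary
        )
        if m.fl_uninduced > 0:
            fold.loc[m.system_id, m.compound_id] = m.fl_compound / m.fl_uninduced
        else:
            logger.warning(
                "%s/%s: non-positive uninduced fluorescence, fold undefined",
                m.system_id, m.compound_id,
            )
    return CrossReactivityMatrix(
        systems=systems, compounds=compounds, rel=rel, fold=fold, primary_map=dict(primary_map)
    )


def classify_hits(
    matrix: CrossReactivityMatrix,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> list[Hit]:
    """Off-diagonal (non-cognate) pairs passing BOTH the relative (>=) and
    absolute-fold (>=) thresholds, sorted by relative induction descending.
    Also fills ``matrix.hits`` with the boolean hit mask."""
    hits: list[Hit] = []
    hit_mask = pd.DataFrame(False, index=matrix.systems, columns=matrix.compounds)
    for sys_id in matrix.systems:
        primary = matrix.primary_map[sys_id]
        for compound in matrix.compounds:
            if compound == primary:
                continue
            rel = matrix.rel.loc[sys_id, compound]
            fold = matrix.fold.loc[sys_id, compound]
            if np.isnan(rel) or np.isnan(fold):
                continue
            if rel >= rel_threshold and fold >= fold_threshold:
                hit_mask.loc[sys_id, compound] = True
                hits.append(Hit(sys_id, compound, float(rel), float(fold)))
    matrix.hits = hit_mask
    hits.sort(key=lambda h: -h.rel)
    return hits


def orthogonality_report(
    matrix: CrossReactivityMatrix, threshold: float = DEFAULT_REL_THRESHOLD
) -> set[str]:
    """Systems whose every measured non-cognate relative induction is
    strictly below ``threshold`` percent.  Also fills
    ``matrix.orthogonal_systems``."""
    orthogonal: set[str] = set()
    for sys_id in matrix.systems:
        primary = matrix.primary_map[sys_id]
        off_diag = matrix.rel.loc[sys_id].drop(labels=[primary], errors="ignore").dropna()
        if (off_diag < threshold).all():
            orthogonal.add(sys_id)
    matrix.orthogonal_systems = orthogonal
    return orthogonal


# ---------------------------------------------------------------------------
# I/O

MEASUREMENT_COLUMNS = ["system", "compound", "FL_compound", "FL_uninduced", "FL_primary"]


def read_induction_table(path: str | Path) -> list[InductionMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        InductionMeasurement(
            system_id=str(r["system"]),
            compound_id=str(r["compound"]),
            fl_compound=float(r["FL_compound"]),
            fl_uninduced=float(r["FL_uninduced"]),
            fl_primary=float(r["FL_primary"]),
        )
        for _, r in df.iterrows()
    ]


def write_matrix(matrix: CrossReactivityMatrix, rel_path: str | Path,
                 fold_path: str | Path | None = None) -> None:
    matrix.rel.to_csv(rel_path, sep="\t", index_label="system")
    if fold_path is not None:
        matrix.fold.to_csv(fold_path, sep="\t", index_label="system")


def write_hits(hits: Sequence[Hit], path: str | Path) -> None:
    pd.DataFrame(
        [(h.system_id, h.compound_id, h.rel, h.fold) for h in hits],
        columns=["system", "compound", "relative_induction_pct", "fold_induction"],
    ).to_csv(path, sep="\t", index=False)


def plot_heatmap(matrix: CrossReactivityMatrix, path: str | Path) -> None:
    """Write the relative-induction heat map (systems x compounds)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.4 * len(matrix.compounds) + 2,
                                    0.4 * len(matrix.systems) + 2))
    im = ax.imshow(matrix.rel.to_numpy(), cmap="viridis", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(matrix.compounds)), matrix.compounds, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.systems)), matrix.systems, fontsize=7)
    fig.colorbar(im, ax=ax, label="relative induction (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
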