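"""Plate-reader normalisation, Hill dose-response fitting and derived
biosensor parameters.

Workflow: raw fluorescence/absorbance time courses are blank-corrected and
OD-normalised; the absolute normalised fluorescence (AFU/OD) at the minimal
induction interval (default 80 min after inducer addition, before inducer
catabolism distorts the signal) is read off per well; the resulting
dose-response points are fit by non-linear least squares to the Hill
function

    RFP(I) = b_max * I^h / (K_m^h + I^h) + b_min

with b_max the maximal reporter output, b_min the basal output, K_m the
inducer concentration giving half-maximal output, and h the Hill
coefficient.  The dynamic range is mu = b_max / b_min with standard
deviation propagated as

    sigma_mu = mu * sqrt((sigma_bmax/b_max)^2 + (sigma_bmin/b_min)^2),

sigma_bmax taken from the fit covariance and sigma_bmin from the spread of
uninduced replicates.

Concentrations are molar throughout; fluorescence is in arbitrary units
per OD600 (AFU/OD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DEFAULT_T_WINDOW = 80.0  # minutes; minimal induction interval
DEFAULT_OD_FLOOR = 0.01  # corrected-OD mask threshold
CELL_DENSITY_G_PER_ML = 1.105  # wet cell pellet density


class FitError(ValueError):
    """Raised when a dataset cannot be fit at all (bad inputs)."""


class DynamicRangeUndefinedError(ValueError):
    """Raised when b_min <= 0 makes the dynamic range undefined (reported
    as 'ND' at the table level)."""


@dataclass
class PlateTimeCourse:
    """One well's fluorescence/absorbance time course.

    ``times`` are minutes from inducer addition.  ``normalized`` is filled
    by :func:`normalize_measurements`; masked time points are NaN.
    """

    well_id: str
    system_id: str
    inducer: str
    concentration: float
    times: np.ndarray
    fluorescence: np.ndarray
    absorbance: np.ndarray
    is_blank: bool = False
    replicate: int = 0
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.well_id}: times must be strictly increasing")
        if len(self.fluorescence) != len(self.times) or len(self.absorbance) != len(self.times):
            raise ValueError(f"{self.well_id}: series lengths differ from time grid")
        if self.is_blank and self.inducer != "none":
            raise ValueError(f"{self.well_id}: blank wells must have inducer 'none'")


@dataclass
class DoseResponseDataset:
    """Dose-response points (inducer molarity vs AFU/OD) for one system."""

    system_id: str
    concentrations: np.ndarray
    rfp: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if np.any(self.concentrations < 0):
            raise ValueError("inducer concentrations must be >= 0")
        if not np.any(self.concentrations == 0):
            raise ValueError("dataset needs at least one uninduced (I = 0) point")

    @property
    def b_min_obs(self) -> float:
        """Mean normalised fluorescence of the uninduced wells."""
        return float(np.mean(self.rfp[self.concentrations == 0]))

    @property
    def uninduced_sd(self) -> float:
        """Replicate standard deviation of the uninduced wells (ddof=1)."""
        vals = self.rfp[self.concentrations == 0]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def n_distinct_nonzero(self) -> int:
        return len(np.unique(self.concentrations[self.concentrations > 0]))


@dataclass
class HillFitResult:
    b_max: float
    b_max_sd: float
    b_min: float
    b_min_sd: float
    K_m: float
    K_m_sd: float
    h: float
    h_sd: float
    mu: float = np.nan
    mu_sd: float = np.nan
    converged: bool = False
    degenerate: bool = False
    sse: float = np.nan


@dataclass
class IntracellularSample:
    """Pellet/extract record for the intracellular-concentration formula."""

    pellet_wet_mass_g: float
    v_solvent_ml: float
    c_extract_molar: float
    cell_density_g_per_ml: float = CELL_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        for name in ("pellet_wet_mass_g", "c_extract_molar", "cell_density_g_per_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_solvent_ml < 0:
            raise ValueError("v_solvent_ml must be >= 0")

    @property
    def v_pellet_ml(self) -> float:
        return self.pellet_wet_mass_g / self.cell_density_g_per_ml


def hill(I, b_max, K_m, h, b_min):
    """Hill dose-response function; accepts scalars or arrays, I >= 0."""
    I = np.asarray(I, dtype=float)
    with np.errstate(divide="ignore"):
        result = b_max * I**h / (K_m**h + I**h) + b_min
    return result


def normalize_measurements(
    courses: Sequence[PlateTimeCourse], od_floor: float = DEFAULT_OD_FLOOR
) -> list[PlateTimeCourse]:
    """Blank-correct and OD-normalise every non-blank well.

    Per time point: normalised = (FL - mean blank FL) / (OD - mean blank
    OD).  Time points whose corrected OD is <= ``od_floor`` are masked
    (NaN) because the ratio is numerically unstable at negligible biomass.
    """
    blanks = [c for c in courses if c.is_blank]
    if not blanks:
        raise ValueError("no blank (medium-only) wells present; cannot blank-correct")
    grid = blanks[0].times
    for b in blanks[1:]:
        if not np.array_equal(b.times, grid):
            raise ValueError("blank wells must share a common time grid")
    blank_fl = np.mean([b.fluorescence for b in blanks], axis=0)
    blank_od = np.mean([b.absorbance for b in blanks], axis=0)

    out: list[PlateTimeCourse] = []
    for course in courses:
        if course.is_blank:
            out.append(course)
            continue
        if not np.array_equal(course.times, grid):
            raise ValueError(f"{course.well_id}: time grid differs from blank wells")
        corrected_od = course.absorbance - blank_od
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = (course.fluorescence - blank_fl) / corrected_od
        norm = np.where(corrected_od <= od_floor, np.nan, norm)
        if np.all(np.isnan(norm)):
            raise ValueError(f"{course.well_id}: every time point masked (OD <= {od_floor})")
        out.append(replace(course, normalized=norm))
    return out


def extract_induction_window(
    course: PlateTimeCourse, t_window: float = DEFAULT_T_WINDOW
) -> tuple[float, float]:
    """Return (inducer concentration, normalised fluorescence) at the
    sample time nearest ``t_window``.

    The nearest recorded sample is used rather than interpolation; it must
    lie within half the sampling interval of the requested window.
    """
    if course.normalized is None:
        raise ValueError(f"{course.well_id}: normalise before window extraction")
    dt = float(np.median(np.diff(course.times)))
    idx = int(np.argmin(np.abs(course.times - t_window)))
    if abs(course.times[idx] - t_window) > dt / 2 + 1e-9:
        raise ValueError(
            f"{course.well_id}: no sample within {dt / 2:.1f} min of t = {t_window} min"
        )
    value = course.normalized[idx]
    if np.isnan(value):
        raise ValueError(f"{course.well_id}: sample at window time is masked")
    return course.concentration, float(value)


def build_dose_response(
    courses: Sequence[PlateTimeCourse], t_window: float = DEFAULT_T_WINDOW
) -> list[DoseResponseDataset]:
    """Group normalised wells by system and extract the induction-window
    point from each, yielding one dataset per system."""
    by_system: dict[str, list[PlateTimeCourse]] = {}
    for course in courses:
        if course.is_blank:
            continue
        by_system.setdefault(course.system_id, []).append(course)
    datasets = []
    for system_id in sorted(by_system):
        points = [
            (*extract_induction_window(c, t_window), c.replicate) for c in by_system[system_id]
        ]
        conc, rfp, rep = zip(*points)
        datasets.append(
            DoseResponseDataset(
                system_id=system_id,
                concentrations=np.array(conc),
                rfp=np.array(rfp),
                replicate=np.array(rep),
            )
        )
    return datasets


def _initial_km(I: np.ndarray, rfp: np.ndarray, b_min0: float, b_max0: float) -> float:
    """Pick the starting K_m from a log-spaced grid over the observed
    concentrations, scoring each node's SSE at h = 1."""
    pos = I[I > 0]
    grid = np.geomspace(pos.min(), pos.max(), 25)
    best_km, best_sse = grid[0], np.inf
    for km in grid:
        sse = float(np.sum((rfp - hill(I, b_max0, km, 1.0, b_min0)) ** 2))
        if sse < best_sse:
            best_km, best_sse = km, sse
    return float(best_km)


def fit_hill(
    dataset: DoseResponseDataset,
    h_bounds: tuple[float, float] = (0.1, 10.0),
    km_bounds: Optional[tuple[float, float]] = None,
    maxfev: int = 20000,
) -> HillFitResult:
    """Non-linear least-squares fit of the Hill function to a dose-response
    dataset.

    Initialisation: b_min at the uninduced mean, b_max at max(RFP) - b_min,
    K_m at the best node of a log-spaced grid over the observed
    concentrations, h at 1.  K_m is bounded to [min I>0 / 100, max I * 100]
    unless overridden.  Parameter standard deviations come from the fit
    covariance.  Optimiser failure yields ``converged=False``, never an
    exception.
    """
    I, rfp = dataset.concentrations, dataset.rfp
    if not np.all(np.isfinite(rfp)):
        raise FitError(f"{dataset.system_id}: non-finite fluorescence values")
    if dataset.n_distinct_nonzero < 4:
        raise FitError(
            f"{dataset.system_id}: need >= 4 distinct non-zero concentrations, "
            f"have {dataset.n_distinct_nonzero}"
        )
    pos = I[I > 0]
    if km_bounds is None:
        km_bounds = (pos.min() * 1e-2, pos.max() * 1e2)

    degenerate = bool(np.ptp(rfp) == 0)
    b_min0 = dataset.b_min_obs
    b_max0 = max(float(np.max(rfp)) - b_min0, 1e-9)
    p0 = [b_max0, _initial_km(I, rfp, b_min0, b_max0), 1.0, max(b_min0, 0.0)]
    lower = [1e-12, km_bounds[0], h_bounds[0], 0.0]
    upper = [np.inf, km_bounds[1], h_bounds[1], np.inf]
    p0 = np.clip(p0, lower, upper)

    try:
        popt, pcov = curve_fit(
            hill, I, rfp, p0=p0, bounds=(lower, upper), maxfev=maxfev, method="trf"
        )
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, ValueError) as exc:
        logger.warning("%s: Hill fit failed: %s", dataset.system_id, exc)
        nan = float("nan")
        return HillFitResult(nan, nan, nan, nan, nan, nan, nan, nan, converged=False,
                             degenerate=degenerate)

    b_max, K_m, h, b_min = (float(v) for v in popt)
    with np.errstate(invalid="ignore"):
        sds = np.sqrt(np.diag(pcov))
    b_max_sd, K_m_sd, h_sd, b_min_sd = (float(v) for v in sds)
    sse = float(np.sum((rfp - hill(I, *popt)) ** 2))
    result = HillFitResult(
        b_max=b_max, b_max_sd=b_max_sd,
        b_min=b_min, b_min_sd=b_min_sd,
        K_m=K_m, K_m_sd=K_m_sd,
        h=h, h_sd=h_sd,
        converged=bool(converged),
        degenerate=degenerate,
        sse=sse,
    )
    if b_min > 0:
        result.mu, result.mu_sd = _propagate_mu(b_max, b_max_sd, b_min, b_min_sd)
    return result


def _propagate_mu(b_max, b_max_sd, b_min, b_min_sd) -> tuple[float, float]:
    mu = b_max / b_min
    mu_sd = mu * np.sqrt((b_max_sd / b_max) ** 2 + (b_min_sd / b_min) ** 2)
    return float(mu), float(mu_sd)


def dynamic_range(fit: HillFitResult, b_min_sd: float) -> tuple[float, float]:
    """Dynamic range mu = b_max / b_min with propagated standard deviation.

    ``b_min_sd`` is the replicate standard deviation of the uninduced
    normalised fluorescence (not the covariance-derived value), matching
    how basal-level uncertainty is measured experimentally.
    """
    if not fit.b_min > 0:
        raise DynamicRangeUndefinedError(
            f"b_min = {fit.b_min!r} <= 0: dynamic range undefined (ND)"
        )
    return _propagate_mu(fit.b_max, fit.b_max_sd, fit.b_min, b_min_sd)


def relative_response(
    dataset: DoseResponseDataset, fit: Optional[HillFitResult] = None
) -> np.ndarray:
    """Dose-response points rescaled to a 0-100% axis.

    rel(I) = 100 * (RFP(I) - RFP_uninduced) / b_max.  When no converged fit
    with a defined b_max is available, the observed response at the highest
    tested concentration is set to 100% instead.

    Returns an array of (I, percent) rows.
    """
    uninduced = dataset.b_min_obs
    if fit is not None and fit.converged and fit.b_max > 0:
        scale = fit.b_max
    else:
        top = np.max(dataset.concentrations)
        top_mean = float(np.mean(dataset.rfp[dataset.concentrations == top]))
        scale = top_mean - uninduced
        if scale == 0:
            raise ValueError(f"{dataset.system_id}: flat response, cannot rescale")
    percent = 100.0 * (dataset.rfp - uninduced) / scale
    return np.column_stack([dataset.concentrations, percent])


def fold_induction(induced_norm: float, uninduced_norm: float) -> float:
    """Fold induction: ratio of induced to uninduced normalised output."""
    if uninduced_norm <= 0:
        raise ValueError(f"uninduced normalised fluorescence must be > 0, got {uninduced_norm}")
    return induced_norm / uninduced_norm


def intracellular_concentration(sample: IntracellularSample) -> float:
    """Intracellular molar concentration from the extract concentration.

    C_intracellular = ((V_pellet + V_solvent) / V_pellet) * C_extract, with
    V_pellet obtained from the wet pellet mass via the cell density.
    """
    v_pellet = sample.v_pellet_ml
    return (v_pellet + sample.v_solvent_ml) / v_pellet * sample.c_extract_molar


# ---------------------------------------------------------------------------
# plate-table I/O (long format)

PLATE_COLUMNS = [
    "well", "system", "inducer", "concentration_M", "time_min",
    "fluorescence", "od600", "is_blank", "replicate",
]


def write_plate_table(courses: Sequence[PlateTimeCourse], path: str | Path) -> None:
    rows = []
    for c in courses:
        for t, fl, od in zip(c.times, c.fluorescence, c.absorbance):
            rows.append(
                (c.well_id, c.system_id, c.inducer, c.concentration, t, fl, od,
                 int(c.is_blank), c.replicate)
            )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_plate_table(path: str | Path) -> list[PlateTimeCourse]:
    df = pd.read_csv(path, sep="\t")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    courses = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        first = grp.iloc[0]
        courses.append(
            PlateTimeCourse(
                well_id=str(well),
                system_id=str(first["system"]),
                inducer=str(first["inducer"]),
                concentration=float(first["concentration_M"]),
                times=grp["time_min"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                absorbance=grp["od600"].to_numpy(),
                is_blank=bool(first["is_blank"]),
                replicate=int(first["replicate"]),
            )
        )
    return courses


def plot_dose_response(
    dataset: DoseResponseDataset, fit: Optional[HillFitResult], path: str | Path
) -> None:
    """Write a dose-response scatter with the fitted Hill curve overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pos = dataset.concentrations > 0
    ax.scatter(dataset.concentrations[pos], dataset.rfp[pos], color="k", zorder=3)
    if fit is not None and fit.converged:
        grid = np.geomspace(
            dataset.concentrations[pos].min(), dataset.concentrations[pos].max(), 200
        )
        ax.plot(grid, hill(grid, fit.b_max, fit.K_m, fit.h, fit.b_min), color="tab:red")
        ax.axvline(fit.K_m, ls=":", color="grey")
    ax.set_xscale("log")
    ax.set_xlabel("inducer (M)")
    ax.set_ylabel("normalised fluorescence (AFU/OD)")
    ax.set_title(dataset.system_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
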