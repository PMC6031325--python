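"""Sub-compartment detection from two-channel ratio profiles.

This is the core statistic of the package.  Along each filament the two
intensity vectors I_RBP1 and I_RBP2 are turned into a mean-normalized ratio
profile; a sub-compartment is a maximal contiguous stretch where that
normalized ratio deviates from unity by more than a threshold (20% by
default) in either direction.  Each detected compartment carries its length
L, its relative enrichment (percent excess of the maximal dominant-over-other
normalized ratio), and an attribution: does the deviation reflect
*enrichment* of the dominant protein, or *exclusion* of the coexisting one?

Normalization uses the geometric mean of the ratio, and optional smoothing is
a geometric (log-domain) moving average.  Both choices make channel swap an
exact algebraic symmetry: swapping I1 and I2 maps the normalized ratio to its
reciprocal, so every RBP1-dominant compartment maps to an RBP2-dominant one
with identical boundaries and enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .datatypes import ProfilePair

__all__ = [
    "RatioProfile",
    "Compartment",
    "CellAnalysis",
    "ratio_profile",
    "ratio_profiles_pooled",
    "detect_compartments",
    "attribute_compartment",
    "analyze_cell",
    "summarize",
    "compare_groups",
    "ENRICHMENT_OF_DOMINANT",
    "EXCLUSION_OF_OTHER",
]

ENRICHMENT_OF_DOMINANT = "enrichment_of_dominant"
EXCLUSION_OF_OTHER = "exclusion_of_other"


@dataclass
class RatioProfile:
    """Mean-normalized I_RBP1 / I_RBP2 ratio along one profile.

    ``r`` is the raw epsilon-guarded ratio, ``n`` the ratio divided by its
    geometric mean (so gmean(n) = 1 when normalized per profile); the
    epsilons actually used are kept for downstream log computations.
    """

    positions_um: np.ndarray
    r: np.ndarray
    n: np.ndarray
    epsilon1: float
    epsilon2: float
    step_um: float
    path_id: int
    mean_i1: float
    mean_i2: float

    def __post_init__(self) -> None:
        if np.any(self.n <= 0):
            raise ValueError("normalized ratio must be strictly positive")


@dataclass
class Compartment:
    """One detected sub-compartment on one filament path."""

    path_id: int
    dominant_channel: str  # "RBP1" or "RBP2"
    start_um: float
    end_um: float
    enrichment_pct: float
    argmax_um: float
    attribution: str | None = None
    cell_id: str | None = None

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass
class CellAnalysis:
    """All compartments of one cell plus the analyzed-length bookkeeping."""

    cell_id: str
    total_analyzed_length_um: float
    compartments: list[Compartment] = field(default_factory=list)
    min_total_length_um: float = 500.0

    @property
    def qc_pass(self) -> bool:
        """Whether enough network length was analyzed (>= 0.5 mm by default)."""
        return self.total_analyzed_length_um >= self.min_total_length_um

    def counts_by_channel(self) -> dict[str, int]:
        out = {"RBP1": 0, "RBP2": 0}
        for c in self.compartments:
            out[c.dominant_channel] += 1
        return out

    def mean_enrichment_pct(self) -> float:
        if not self.compartments:
            return float("nan")
        return float(np.mean([c.enrichment_pct for c in self.compartments]))


# ---------------------------------------------------------------------------
# ratio profiles
# ---------------------------------------------------------------------------


def _guarded_ratio(
    i1: np.ndarray, i2: np.ndarray, epsilon_frac: float
) -> tuple[np.ndarray, float, float]:
    eps1 = epsilon_frac * float(np.mean(i1))
    eps2 = epsilon_frac * float(np.mean(i2))
    den = i2 + eps2
    if np.any(den == 0):
        pos = int(np.flatnonzero(den == 0)[0])
        raise ZeroDivisionError(
            f"zero denominator intensity at sample {pos}; "
            "use epsilon_frac > 0 for profiles with empty stretches"
        )
    return (i1 + eps1) / den, eps1, eps2


def ratio_profile(
    p: ProfilePair,
    epsilon_frac: float = 0.01,
    reference: tuple[float, float, float] | None = None,
) -> RatioProfile:
    """Compute the normalized ratio profile of one :class:`ProfilePair`.

    ``reference``, if given, is (epsilon1, epsilon2, log_gmean_r) computed
    over a pooled set of profiles (one cell), so that all profiles of a cell
    share one normalization; otherwise the profile normalizes itself.
    """
    if len(p) == 0:
        raise ValueError("empty profile")
    if epsilon_frac < 0:
        raise ValueError("epsilon_frac must be >= 0")
    if reference is None:
        r, eps1, eps2 = _guarded_ratio(p.i_rbp1, p.i_rbp2, epsilon_frac)
        log_gmean = float(np.mean(np.log(r)))
    else:
        eps1, eps2, log_gmean = reference
        den = p.i_rbp2 + eps2
        if np.any(den == 0):
            pos = int(np.flatnonzero(den == 0)[0])
            raise ZeroDivisionError(f"zero denominator intensity at sample {pos}")
        r = (p.i_rbp1 + eps1) / den
    n = r / np.exp(log_gmean)
    return RatioProfile(
        positions_um=p.positions_um,
        r=r,
        n=n,
        epsilon1=eps1,
        epsilon2=eps2,
        step_um=p.step_um,
        path_id=p.path_id,
        mean_i1=float(np.mean(p.i_rbp1)),
        mean_i2=float(np.mean(p.i_rbp2)),
    )


def ratio_profiles_pooled(
    profiles: list[ProfilePair], epsilon_frac: float = 0.01
) -> list[RatioProfile]:
    """Ratio profiles for one cell, normalized over the pooled network.

    The channel means (for the epsilon guard, and for the attribution test's
    mean(I) terms) and the geometric-mean normalizer are computed over the
    concatenation of all profiles, mirroring an analysis in which the whole
    traced network of a cell is recorded in two long intensity vectors.
    """
    if not profiles:
        raise ValueError("no profiles given")
    i1 = np.concatenate([p.i_rbp1 for p in profiles])
    i2 = np.concatenate([p.i_rbp2 for p in profiles])
    r, eps1, eps2 = _guarded_ratio(i1, i2, epsilon_frac)
    log_gmean = float(np.mean(np.log(r)))
    m1 = float(np.mean(i1))
    m2 = float(np.mean(i2))
    out = []
    for p in profiles:
        rp = ratio_profile(p, epsilon_frac, reference=(eps1, eps2, log_gmean))
        rp.mean_i1 = m1
        rp.mean_i2 = m2
        out.append(rp)
    return out


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def smooth_ratio(n: np.ndarray, window: int) -> np.ndarray:
    """Geometric moving average (uniform window in log space, edge-replicated)."""
    if window <= 1:
        return n
    return np.exp(uniform_filter1d(np.log(n), size=int(window), mode="nearest"))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_compartments(
    rp: RatioProfile,
    threshold: float = 0.20,
    min_run_samples: int = 5,
    smoothing_window: int = 5,
) -> list[Compartment]:
    """Detect sub-compartments as maximal supra-threshold runs.

    An RBP1-dominant compartment is a maximal contiguous run of samples with
    smoothed normalized ratio n > 1 + threshold (strictly); an RBP2-dominant
    one a run with n < 1/(1 + threshold).  Runs shorter than
    ``min_run_samples`` are discarded.  Each compartment spans half a step
    beyond its first and last sample (so L = run length x step), and its
    enrichment is the percent excess of the maximal dominant-over-other
    smoothed ratio within the run.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_run_samples < 1:
        raise ValueError("min_run_samples must be >= 1")
    ns = smooth_ratio(rp.n, smoothing_window)
    half = rp.step_um / 2.0
    out: list[Compartment] = []
    for dominant, vals in (("RBP1", ns), ("RBP2", 1.0 / ns)):
        for first, last in _runs(vals > 1.0 + threshold):
            if last - first + 1 < min_run_samples:
                continue
            seg = vals[first : last + 1]
            k = int(np.argmax(seg))
            out.append(
                Compartment(
                    path_id=rp.path_id,
                    dominant_channel=dominant,
                    start_um=float(rp.positions_um[first] - half),
                    end_um=float(rp.positions_um[last] + half),
                    enrichment_pct=float((seg[k] - 1.0) * 100.0),
                    argmax_um=float(rp.positions_um[first + k]),
                )
            )
    out.sort(key=lambda c: (c.start_um, c.dominant_channel))
    return out


# ---------------------------------------------------------------------------
# attribution: enrichment of the dominant vs exclusion of the other
# ---------------------------------------------------------------------------


def attribute_compartment(
    c: Compartment,
    p: ProfilePair,
    rp: RatioProfile | None = None,
    epsilon_frac: float = 0.01,
) -> str:
    """Decide whether a compartment reflects enrichment or exclusion.

    At the position of maximal dominant-over-other ratio, the signed log
    deviations of the two channels from their profile means are compared:

        log(I_dom / mean(I_dom)) + log(I_other / mean(I_other)) > 0

    i.e. the dominant channel's excess outweighs the other channel's deficit
    -> the compartment is attributed to *enrichment of the dominant* protein;
    otherwise to *exclusion of the other*.  The sum of log deviations is
    symmetric in the two channels, so channel swap preserves the attribution.
    """
    if rp is not None:
        eps1, eps2 = rp.epsilon1, rp.epsilon2
        m1, m2 = rp.mean_i1, rp.mean_i2
    else:
        eps1 = epsilon_frac * float(np.mean(p.i_rbp1))
        eps2 = epsilon_frac * float(np.mean(p.i_rbp2))
        m1 = float(np.mean(p.i_rbp1))
        m2 = float(np.mean(p.i_rbp2))
    k = int(np.argmin(np.abs(p.positions_um - c.argmax_um)))
    i1 = p.i_rbp1[k] + eps1
    i2 = p.i_rbp2[k] + eps2
    if i1 <= 0 or i2 <= 0 or m1 <= 0 or m2 <= 0:
        raise ZeroDivisionError(
            f"zero intensity at argmax (sample {k}); use epsilon_frac > 0"
        )
    value = np.log(i1 / (m1 + eps1)) + np.log(i2 / (m2 + eps2))
    c.attribution = ENRICHMENT_OF_DOMINANT if value > 0 else EXCLUSION_OF_OTHER
    return c.attribution


# ---------------------------------------------------------------------------
# per-cell orchestration and summaries
# ---------------------------------------------------------------------------


def analyze_cell(
    cell_id: str,
    profiles: list[ProfilePair],
    threshold: float = 0.20,
    min_run_samples: int = 5,
    smoothing_window: int = 5,
    epsilon_frac: float = 0.01,
    min_total_length_um: float = 500.0,
) -> CellAnalysis:
    """Full per-cell chain: pooled normalization -> detection -> attribution."""
    rps = ratio_profiles_pooled(profiles, epsilon_frac=epsilon_frac)
    comps: list[Compartment] = []
    for p, rp in zip(profiles, rps):
        for c in detect_compartments(
            rp,
            threshold=threshold,
            min_run_samples=min_run_samples,
            smoothing_window=smoothing_window,
        ):
            attribute_compartment(c, p, rp=rp)
            c.cell_id = cell_id
            comps.append(c)
    total = float(sum(p.extent_um for p in profiles))
    return CellAnalysis(
        cell_id=cell_id,
        total_analyzed_length_um=total,
        compartments=comps,
        min_total_length_um=min_total_length_um,
    )


def summarize(cells: list[CellAnalysis]) -> dict:
    """Pool compartment statistics over cells.

    Returns per-cell and pooled distributions of compartment length and
    relative enrichment, counts per dominant channel, attribution fractions,
    and a QC flag for cells with less analyzed length than required.
    """
    if not cells:
        raise ValueError("summarize needs at least one cell")
    all_comps = [c for cell in cells for c in cell.compartments]
    lengths = np.array([c.length_um for c in all_comps])
    enrich = np.array([c.enrichment_pct for c in all_comps])
    attr = [c.attribution for c in all_comps]
    n = len(all_comps)

    def _stats(x: np.ndarray) -> dict:
        if len(x) == 0:
            return {"n": 0, "mean": None, "median": None, "min": None, "max": None}
        return {
            "n": int(len(x)),
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }

    by_channel = {"RBP1": 0, "RBP2": 0}
    for c in all_comps:
        by_channel[c.dominant_channel] += 1
    attribution_counts = {
        ENRICHMENT_OF_DOMINANT: sum(a == ENRICHMENT_OF_DOMINANT for a in attr),
        EXCLUSION_OF_OTHER: sum(a == EXCLUSION_OF_OTHER for a in attr),
    }
    per_cell = []
    for cell in cells:
        per_cell.append(
            {
                "cell_id": cell.cell_id,
                "total_analyzed_length_um": cell.total_analyzed_length_um,
                "qc_pass": cell.qc_pass,
                "n_compartments": len(cell.compartments),
                "mean_enrichment_pct": (
                    None
                    if not cell.compartments
                    else float(np.mean([c.enrichment_pct for c in cell.compartments]))
                ),
                "counts_by_channel": cell.counts_by_channel(),
            }
        )
    return {
        "n_cells": len(cells),
        "n_compartments": n,
        "length_um": _stats(lengths),
        "enrichment_pct": _stats(enrich),
        "counts_by_channel": by_channel,
        "attribution_counts": attribution_counts,
        "attribution_fraction_exclusion": (
            None if n == 0 else attribution_counts[EXCLUSION_OF_OTHER] / n
        ),
        "cells": per_cell,
        "qc_all_cells_pass": all(cell.qc_pass for cell in cells),
    }


def compartments_table(cells: list[CellAnalysis]) -> pd.DataFrame:
    """Flat per-compartment table (one row per detected compartment)."""
    rows = []
    for cell in cells:
        for c in cell.compartments:
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "path_id": c.path_id,
                    "dominant_channel": c.dominant_channel,
                    "start_um": c.start_um,
                    "end_um": c.end_um,
                    "length_um": c.length_um,
                    "enrichment_pct": c.enrichment_pct,
                    "argmax_um": c.argmax_um,
                    "attribution": c.attribution,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "path_id",
            "dominant_channel",
            "start_um",
            "end_um",
            "length_um",
            "enrichment_pct",
            "argmax_um",
            "attribution",
        ],
    )


def compare_groups(cells_a: list[CellAnalysis], cells_b: list[CellAnalysis]) -> dict:
    """Two-tailed two-sample t-test on per-cell mean compartment enrichment.

    A reporting convenience for contrasting conditions; cells without any
    compartment contribute no observation.
    """
    a = np.array(
        [c.mean_enrichment_pct() for c in cells_a if c.compartments], dtype=float
    )
    b = np.array(
        [c.mean_enrichment_pct() for c in cells_b if c.compartments], dtype=float
    )
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 cells with compartments")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-zero variance groups trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    degenerate = bool(np.isnan(t))
    return {
        "t": None if degenerate else float(t),
        "df": int(df),
        "p": None if degenerate else float(p),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "degenerate_variance": degenerate,
    }
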