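"""Thin-filament and sarcomere lengths from fitted units, and group statistics.

Thin filament length (TF) is half the fitted plateau width plus the
half-width-at-half-maximum of the flank Gaussian:

    TF = W/2 + sqrt(2 ln 2) * sigma_bar,    sigma_bar = (sigma_L + sigma_R)/2

Sarcomere length (SL) is the distance between adjacent fitted unit centres
(Z-disk to Z-disk).  Measurements are filtered to an SL window before group
comparison (default 1.85-2.2 um, closed interval), and TF is regressed on SL
over the wider 1.6-2.6 um window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profile_fit import HWHM_FACTOR, SarcomereUnitFit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilamentMeasurement:
    """One thin-filament length measurement with its local sarcomere length."""

    tf_length: float  # um
    sl: float         # um (mean of the flanking centre-to-centre spacings)
    unit_index: int
    fish_id: str = ""
    genotype: str = ""
    qc_pass: bool = True


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    sl_range: tuple[float, float]


@dataclass(frozen=True)
class GroupComparison:
    group_means: dict          # genotype -> (mean um, sem um, n)
    percent_of_control: dict   # genotype -> %
    difference_p: dict         # genotype -> Holm-adjusted Welch p vs control
    sl_window: tuple[float, float]
    control: str


def thin_filament_length(fit: SarcomereUnitFit) -> float:
    """TF = W/2 + HWHM of the flank Gaussian (mean of the two flank sigmas)."""
    if not fit.converged:
        raise ValueError("cannot measure thin filament length from a non-converged fit")
    sigma_bar = 0.5 * (fit.sigma_left + fit.sigma_right)
    return fit.rect_width / 2.0 + HWHM_FACTOR * sigma_bar


def sarcomere_length(fits: Sequence[SarcomereUnitFit]) -> list[tuple[int, float]]:
    """Centre-to-centre spacing of consecutive converged fits.

    Returns one (pair index, SL) per adjacent pair.  Input must be ordered by
    centre position.
    """
    conv = [f for f in fits if f.converged]
    centers = [f.center for f in conv]
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise ValueError("fits must be ordered by increasing center position")
    if len(conv) < 2:
        return []
    return [(i, centers[i + 1] - centers[i]) for i in range(len(centers) - 1)]


def measurements_from_fits(fits: Sequence[SarcomereUnitFit], fish_id: str = "",
                           genotype: str = "") -> list[FilamentMeasurement]:
    """Attach TF and local SL to every converged fit on one profile.

    Each unit's SL is the mean of its left and right centre spacings when
    both exist, else the single available one; units with no converged
    neighbour carry no SL and fail QC.
    """
    conv = [f for f in fits if f.converged]
    sls = dict(sarcomere_length(conv))
    out = []
    for i, f in enumerate(conv):
        neigh = [sls[j] for j in (i - 1, i) if j in sls]
        if not neigh:
            continue
        sl = float(np.mean(neigh))
        tf = thin_filament_length(f)
        out.append(FilamentMeasurement(tf_length=tf, sl=sl, unit_index=i,
                                       fish_id=fish_id, genotype=genotype,
                                       qc_pass=tf < sl))
    return out


def filter_by_sl(measurements: Iterable[FilamentMeasurement],
                 lo: float = 1.85, hi: float = 2.2) -> list[FilamentMeasurement]:
    """Keep QC-passing measurements with lo <= SL <= hi (closed interval)."""
    return [m for m in measurements if m.qc_pass and lo <= m.sl <= hi]


def regress_tf_vs_sl(measurements: Iterable[FilamentMeasurement],
                     sl_range: tuple[float, float] = (1.6, 2.6)) -> RegressionResult | None:
    """OLS line of TF on SL over the given SL window; None if n < 3."""
    lo, hi = min(sl_range), max(sl_range)
    pts = [(m.sl, m.tf_length) for m in measurements if m.qc_pass and lo <= m.sl <= hi]
    if len(pts) < 3:
        logger.warning("regression skipped: only %d points in SL range", len(pts))
        return None
    sl = np.array([p[0] for p in pts])
    tf = np.array([p[1] for p in pts])
    if np.ptp(sl) == 0:
        logger.warning("regression skipped: no SL spread")
        return None
    res = stats.linregress(sl, tf)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, n=len(pts), sl_range=(lo, hi))


def compare_groups(measurements_by_genotype: Mapping[str, Sequence[FilamentMeasurement]],
                   control: str,
                   sl_window: tuple[float, float] = (1.85, 2.2)) -> GroupComparison:
    """Per-genotype mean TF in the SL window and Welch tests vs the control.

    percent_of_control = 100 * mean_g / mean_control (exactly 100 for the
    control).  Mutant-vs-control two-sided Welch p-values are Holm-corrected
    across contrasts.
    """
    if control not in measurements_by_genotype:
        raise ValueError(f"control group {control!r} missing")
    lo, hi = min(sl_window), max(sl_window)
    tf_by_g = {g: np.array([m.tf_length for m in filter_by_sl(ms, lo, hi)])
               for g, ms in measurements_by_genotype.items()}
    if tf_by_g[control].size == 0:
        raise ValueError("control group has no measurements in the SL window")
    means = {g: (float(v.mean()) if v.size else float("nan"),
                 float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
                 int(v.size))
             for g, v in tf_by_g.items()}
    ctrl_mean = means[control][0]
    percent = {g: 100.0 if g == control else 100.0 * means[g][0] / ctrl_mean
               for g in tf_by_g}
    contrasts = [g for g in tf_by_g if g != control and tf_by_g[g].size >= 2]
    raw_p = [float(stats.ttest_ind(tf_by_g[g], tf_by_g[control], equal_var=False).pvalue)
             for g in contrasts]
    if raw_p:
        adj = multipletests(raw_p, method="holm")[1]
        diff_p = {g: float(p) for g, p in zip(contrasts, adj)}
    else:
        diff_p = {}
    return GroupComparison(group_means=means, percent_of_control=percent,
                           difference_p=diff_p, sl_window=(lo, hi), control=control)


# ---------------------------------------------------------------------------
# tabulation helpers

def measurements_to_frame(measurements: Iterable[FilamentMeasurement]):
    import pandas as pd

    return pd.DataFrame([{"fish_id": m.fish_id, "genotype": m.genotype,
                          "unit_index": m.unit_index, "tf_um": m.tf_length,
                          "sl_um": m.sl, "qc_pass": m.qc_pass}
                         for m in measurements],
                        columns=["fish_id", "genotype", "unit_index",
                                 "tf_um", "sl_um", "qc_pass"])


def frame_to_measurements(df) -> list[FilamentMeasurement]:
    return [FilamentMeasurement(tf_length=r.tf_um, sl=r.sl_um,
                                unit_index=int(r.unit_index), fish_id=str(r.fish_id),
                                genotype=str(r.genotype), qc_pass=bool(r.qc_pass))
            for r in df.itertuples(index=False)]


def comparison_to_frame(comp: GroupComparison):
    import pandas as pd

    rows = []
    for g, (mean, sem, n) in comp.group_means.items():
        rows.append({"genotype": g, "mean_tf_um": mean, "sem_tf_um": sem, "n": n,
                     "percent_of_control": comp.percent_of_control[g],
                     "p_holm_vs_control": comp.difference_p.get(g, float("nan")),
                     "sl_lo_um": comp.sl_window[0], "sl_hi_um": comp.sl_window[1]})
    return pd.DataFrame(rows)
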