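"""mRNA kinetics: percent-remaining from ddCt, half-life from a quadratic
decay fit (with a log-linear alternative), and polysome fraction
distributions from Ct values."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: default polysome gradient fraction grouping: 1-2 free RNP, 3-5 monosome
#: (40S/60S/80S), 7-9 low-molecular-weight polysomes, 10-12 high-molecular-
#: weight polysomes
POLYSOME_GROUPS = {
    1: "free", 2: "free",
    3: "monosome", 4: "monosome", 5: "monosome",
    6: "other",
    7: "LMW polysome", 8: "LMW polysome", 9: "LMW polysome",
    10: "HMW polysome", 11: "HMW polysome", 12: "HMW polysome",
}


@dataclass(frozen=True)
class HalfLifeEstimate:
    gene_id: Optional[str]
    coefficients: tuple          # (a0, a1, a2) of percent(t) = a0 + a1 t + a2 t^2
    half_life: Optional[float]   # hours; None when 50% is not reached in range


def percent_remaining(series: pd.DataFrame) -> pd.DataFrame:
    """Percent mRNA remaining per time point by the ddCt method.

    ``series`` is long-format with columns time_h, replicate, ct_target,
    ct_reference.  Per replicate, dCt_t = Ct_target - Ct_reference and
    ddCt_t = dCt_t - dCt_0 (each replicate paired with its own t = 0);
    percent_t = 100 * 2^(-ddCt); replicates are averaged on the percent
    scale.  A replicate without a t = 0 measurement is an error.
    """
    rows = []
    for rep, grp in series.groupby("replicate"):
        grp = grp.sort_values("time_h")
        dct = grp["ct_target"].to_numpy() - grp["ct_reference"].to_numpy()
        t = grp["time_h"].to_numpy(dtype=float)
        at0 = np.flatnonzero(t == 0.0)
        if at0.size == 0:
            raise ValueError(f"replicate {rep!r} has no t=0 measurement")
        ddct = dct - dct[at0[0]]
        for time, pct in zip(t, 100.0 * np.power(2.0, -ddct)):
            rows.append((rep, time, pct))
    per_rep = pd.DataFrame(rows, columns=["replicate", "time_h", "percent"])
    return (per_rep.groupby("time_h", as_index=False)["percent"].mean()
            .sort_values("time_h").reset_index(drop=True))


def fit_decay_halflife(times: Sequence[float], percents: Sequence[float],
                       gene_id: Optional[str] = None,
                       max_extrapolation: float = 1.25) -> HalfLifeEstimate:
    """Least-squares quadratic fit of percent(t); half-life is the smallest
    50%-crossing of the fitted curve, or ``None`` ("not reached") when the
    curve never crosses 50%.

    The crossing is accepted up to ``max_extrapolation`` times the last
    measured time point: a transcript whose half-life equals the assay span
    has its fitted crossing marginally beyond the last sample, and reporting
    it beats an artificial "not reached".
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(percents, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    a2, a1, a0 = np.polyfit(t, y, 2)
    # roots of a2 x^2 + a1 x + (a0 - 50) = 0 within the accepted range
    if abs(a2) < 1e-12:
        roots = [] if abs(a1) < 1e-12 else [(50.0 - a0) / a1]
    else:
        roots = np.roots([a2, a1, a0 - 50.0])
        roots = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
    in_range = [r for r in roots
                if -1e-9 <= r <= t.max() * max_extrapolation + 1e-9]
    half_life = float(min(in_range)) if in_range else None
    if half_life is not None:
        half_life = max(half_life, 0.0)
    return HalfLifeEstimate(gene_id, (float(a0), float(a1), float(a2)), half_life)


def fit_halflife_linear_log(times: Sequence[float], percents: Sequence[float],
                            gene_id: Optional[str] = None) -> HalfLifeEstimate:
    """Alternative estimator: linear fit of log2(percent) vs time; half-life
    is -1/slope (None when the slope is non-negative)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(percents, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y <= 0):
        raise ValueError("percents must be positive for the log fit")
    slope, intercept = np.polyfit(t, np.log2(y), 1)
    half_life = None if slope >= 0 else float(-1.0 / slope)
    return HalfLifeEstimate(gene_id, (float(intercept), float(slope), 0.0),
                            half_life)


def polysome_distribution(ct_by_fraction: Sequence[float],
                          groups: dict = POLYSOME_GROUPS) -> pd.DataFrame:
    """Percent distribution of a transcript across gradient fractions by the
    dCt method: weight_i = 2^(-Ct_i), percent_i = 100 * weight / sum."""
    ct = np.asarray(ct_by_fraction, dtype=float)
    if ct.size != len(groups):
        raise ValueError(f"expected {len(groups)} fractions, got {ct.size}")
    if np.any(np.isnan(ct)):
        raise ValueError("missing fraction measurement")
    w = np.power(2.0, -(ct - ct.min()))      # shift for numerical stability
    pct = 100.0 * w / w.sum()
    return pd.DataFrame({
        "fraction_index": np.arange(1, ct.size + 1),
        "group": [groups[i] for i in range(1, ct.size + 1)],
        "percent": pct,
    })
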