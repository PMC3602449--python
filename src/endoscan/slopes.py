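"""Per-subject FEV1 decline rates by ordinary least squares.

Each subject's visits (month, FEV1) are fitted with a straight line;
the slope ES_i (ml/month) becomes the derived phenotype of every
downstream association model, and the intercept estimates baseline
FEV1.  Subjects with a single visit cannot define a slope and are
dropped with a log entry rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import LongitudinalPhenotype

log = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """All visit months identical: the slope is unidentifiable."""


@dataclass(frozen=True)
class SlopeEstimate:
    subject: str
    es: float        # ml/month
    u0: float        # ml, fitted baseline
    r2: float        # NaN when residual and total variance are both 0
    n_visits: int


def estimate_slope(months, fev1, subject: str = "") -> SlopeEstimate:
    """OLS line through one subject's visits.

    With exactly two visits the slope is the finite difference and R2
    is 1 by construction; R2 is NaN for a perfectly flat series (zero
    total and residual variance).
    """
    x = np.asarray(months, dtype=float)
    y = np.asarray(fev1, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("months and fev1 must be equal-length 1-D, length >= 2")
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"all visit months identical for {subject!r}")
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    es = float(((x - xbar) * (y - ybar)).sum() / sxx)
    u0 = float(ybar - es * xbar)
    resid = y - (u0 + es * x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    if ss_tot == 0.0:
        r2 = np.nan if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return SlopeEstimate(subject=subject, es=es, u0=u0, r2=r2, n_visits=len(x))


def estimate_all_slopes(pheno: LongitudinalPhenotype
                        ) -> tuple[pd.DataFrame, dict]:
    """Fit every subject; returns (slopes frame, cohort summary).

    The frame has columns subject/es/u0/r2/n_visits, one row per
    retained subject.  The summary reports the mean and SD of ES and
    the mean and median per-subject R2 (NaN R2 excluded).
    """
    rows = []
    dropped = []
    for subject, grp in pheno.records.groupby("subject", sort=False):
        if len(grp) < 2 or grp["month"].nunique() < 2:
            dropped.append(subject)
            continue
        rows.append(estimate_slope(grp["month"].to_numpy(),
                                   grp["fev1"].to_numpy(), subject=str(subject)))
    if dropped:
        log.info("dropped %d subject(s) with <2 distinct visit months: %s",
                 len(dropped), dropped[:10])
    if not rows:
        raise ValueError("no subject has >= 2 visits; empty cohort")
    df = pd.DataFrame([r.__dict__ for r in rows])
    r2 = df["r2"].to_numpy(dtype=float)
    summary = {
        "n_subjects": len(df),
        "n_dropped": len(dropped),
        "es_mean": float(df["es"].mean()),
        "es_sd": float(df["es"].std(ddof=1)) if len(df) > 1 else np.nan,
        "r2_mean": float(np.nanmean(r2)),
        "r2_median": float(np.nanmedian(r2)),
    }
    return df, summary
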