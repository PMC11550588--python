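"""Deeks' funnel-plot asymmetry test for small-study effects in DTA meta-analysis.

Conventional funnel-plot tests (Egger, Begg) behave badly for diagnostic
odds ratios because the DOR's variance is driven by the case/control split
rather than total sample size.  Deeks' test regresses ln(DOR) on the inverse
square root of the effective sample size

    ESS = 4 * n1 * n0 / (n1 + n0)

by weighted least squares with weights ESS; a non-zero slope indicates that
small studies report systematically different accuracy, the usual footprint
of publication bias.  Significance is conventionally judged at alpha = 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .dta_core import Study2x2Record, apply_continuity_correction

DEEKS_ALPHA = 0.1


@dataclass
class DeeksResult:
    slope: float
    intercept: float
    slope_p: float
    ess_per_study: list[float]
    biased: bool
    n_studies: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_p": self.slope_p,
            "biased": self.biased,
            "n_studies": self.n_studies,
        }


def effective_sample_size(n1: float, n0: float) -> float:
    """ESS = 4·n1·n0/(n1+n0): the size of a balanced study of equal information."""
    return 4.0 * n1 * n0 / (n1 + n0)


def deeks_test(
    studies: Sequence[Study2x2Record], *, alpha: float = DEEKS_ALPHA
) -> DeeksResult:
    """Deeks' regression of ln(DOR) on 1/sqrt(ESS), weights ESS.

    Counts go through the zero-cell continuity correction first.  The slope
    p-value is two-sided from a t distribution on K−2 degrees of freedom.
    """
    if len(studies) < 4:
        raise ValueError(f"Deeks' test requires at least 4 studies, got {len(studies)}")
    ln_dor, inv_sqrt_ess, ess = [], [], []
    for rec in studies:
        rec = apply_continuity_correction(rec)
        ln_dor.append(math.log((rec.tp * rec.tn) / (rec.fp * rec.fn)))
        e = effective_sample_size(rec.n_diseased, rec.n_nondiseased)
        ess.append(e)
        inv_sqrt_ess.append(1.0 / math.sqrt(e))
    x = np.asarray(inv_sqrt_ess)
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in 1/sqrt(ESS); regression is degenerate")
    X = sm.add_constant(x)
    res = sm.WLS(np.asarray(ln_dor), X, weights=np.asarray(ess)).fit()
    slope_p = float(res.pvalues[1])
    return DeeksResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_p=slope_p,
        ess_per_study=ess,
        biased=bool(slope_p < alpha),
        n_studies=len(studies),
    )


def funnel_coordinates(studies: Sequence[Study2x2Record]) -> list[dict]:
    """Funnel-plot coordinates (1/sqrt(ESS) vs DOR) for plotting exports."""
    out = []
    for rec in studies:
        rec = apply_continuity_correction(rec)
        ess = effective_sample_size(rec.n_diseased, rec.n_nondiseased)
        out.append(
            {
                "study_id": rec.study_id,
                "inv_sqrt_ess": 1.0 / math.sqrt(ess),
                "dor": (rec.tp * rec.tn) / (rec.fp * rec.fn),
            }
        )
    return out
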