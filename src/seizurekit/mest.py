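"""Maximal electroshock threshold (MEST) staircase analysis.

The up-and-down staircase steps the stimulation current one ladder step
down after tonic hind-limb extension and one step up after its absence.
Each animal contributes one observed outcome; monotonicity of the
stimulus-response relation lets the outcome be imputed across the rest
of the ladder (extension propagates upward as assumed extension, lack of
extension downward as assumed lack).  The per-current extension
probability — responders over animals tested, observed and assumed both
counting — is fitted with the Boltzmann sigmoid

    P(I) = 1 / (1 + exp((EC50 - I) / Slope))

whose EC50 is the seizure-threshold estimate.  Group EC50s are compared
with a normal-reference test on the fitted standard errors, Bonferroni
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .types import (
    ASSUMED_EXT,
    ASSUMED_NO,
    OBSERVED_EXT,
    OBSERVED_NO,
    UNTESTED,
    StaircaseTable,
)

__all__ = [
    "next_current",
    "impute_outcomes",
    "probability_curve",
    "BoltzmannThreshold",
    "BoltzmannFit",
    "fit_boltzmann",
    "compare_ec50",
]


def next_current(ladder: Sequence[float], previous_outcome: str, previous_index: int
                 ) -> Tuple[int, bool]:
    """Staircase rule: one step down after extension, one step up after none.

    Returns ``(index, clipped)``; ``clipped`` is True when the step ran off
    a ladder end and was held at the boundary.
    """
    if not 0 <= previous_index < len(ladder):
        raise ValueError("previous_index: outside the ladder")
    if previous_outcome == "extension":
        idx = previous_index - 1
    elif previous_outcome == "no_extension":
        idx = previous_index + 1
    else:
        raise ValueError("previous_outcome: must be 'extension' or 'no_extension'")
    clipped = idx < 0 or idx > len(ladder) - 1
    return min(max(idx, 0), len(ladder) - 1), clipped


def impute_outcomes(table: StaircaseTable) -> StaircaseTable:
    """Fill the animal x ladder matrix with observed and assumed outcomes.

    Extension at a current implies (assumed) extension at all higher
    currents; lack of extension implies assumed lack at all lower currents.
    Remaining cells stay untested.  Idempotent.
    """
    records = table.records
    dup = records["animal_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"records: conflicting duplicate observations for animals "
            f"{sorted(records.loc[dup, 'animal_id'].unique())}"
        )
    ladder = list(table.ladder)
    rows = {}
    for _, rec in records.iterrows():
        current = float(rec["current_ma"])
        if current not in ladder:
            raise ValueError(f"records: current {current} mA not on the ladder")
        j = ladder.index(current)
        row = [UNTESTED] * len(ladder)
        if rec["outcome"] == "extension":
            row[j] = OBSERVED_EXT
            for k in range(j + 1, len(ladder)):
                row[k] = ASSUMED_EXT
        elif rec["outcome"] == "no_extension":
            row[j] = OBSERVED_NO
            for k in range(j):
                row[k] = ASSUMED_NO
        else:
            raise ValueError(f"records: unknown outcome {rec['outcome']!r}")
        rows[rec["animal_id"]] = row
    imputed = pd.DataFrame.from_dict(rows, orient="index", columns=ladder)
    imputed.index.name = "animal_id"
    return replace(table, imputed=imputed)


def probability_curve(table: StaircaseTable) -> pd.DataFrame:
    """Per-current extension probability from an imputed staircase table.

    Returns a DataFrame ``(current_ma, n_responders, n_tested, p)`` over the
    currents with at least one tested (observed or assumed) cell.  The curve
    is non-decreasing in current by construction of the imputation.
    """
    if table.imputed is None:
        table = impute_outcomes(table)
    imputed = table.imputed
    rows = []
    for current in imputed.columns:
        col = imputed[current]
        tested = int((col != UNTESTED).sum())
        if tested == 0:
            continue
        responders = int(col.isin([OBSERVED_EXT, ASSUMED_EXT]).sum())
        rows.append((float(current), responders, tested, responders / tested))
    return pd.DataFrame(rows, columns=["current_ma", "n_responders", "n_tested", "p"])


def _boltzmann(I, ec50, slope):
    return 1.0 / (1.0 + np.exp((ec50 - I) / slope))


class BoltzmannThreshold(BaseEstimator):
    """Boltzmann sigmoid fit of an extension-probability curve.

    Parameters
    ----------
    weighted : bool
        Weight each probability point by the number of animals tested at
        that current (weighted least squares); ``False`` gives each point
        equal weight.
    method : {"wls", "mle"}
        "wls" (default) minimizes (weighted) squared error on the
        aggregated probability points; "mle" maximizes the per-animal
        binomial likelihood instead.

    Attributes
    ----------
    ec50_ : float
        Current (mA) with 50% extension probability.
    slope_ : float
        Sigmoid slope parameter (mA).
    se_ec50_, se_slope_ : float
        Standard errors from the fit covariance (NaN for "mle" when the
        Hessian is not available).
    fitted_probabilities_ : ndarray
        Model probabilities at the fitted currents.
    """

    def __init__(self, weighted: bool = True, method: str = "wls"):
        self.weighted = weighted
        self.method = method

    def fit(self, current_ma: np.ndarray, p: np.ndarray, n_tested: np.ndarray = None
            ) -> "BoltzmannThreshold":
        I = np.asarray(current_ma, dtype=float).ravel()
        p = np.asarray(p, dtype=float).ravel()
        n = (np.ones_like(I) if n_tested is None
             else np.asarray(n_tested, dtype=float).ravel())
        if I.size != p.size or I.size != n.size:
            raise ValueError("current_ma/p/n_tested: lengths differ")
        if I.size < 3:
            raise ValueError("curve: need >= 3 tested currents to fit a two-parameter sigmoid")
        if np.all(p <= 0) or np.all(p >= 1):
            raise ValueError(
                "curve: degenerate probability curve (all 0 or all 1) — the ladder "
                "does not bracket the threshold"
            )

        # initial guess: interpolate the 50% crossing; slope from the ladder span
        order = np.argsort(I)
        Io, po = I[order], p[order]
        ec50_0 = float(np.interp(0.5, po, Io)) if po[0] <= 0.5 <= po[-1] else float(np.median(Io))
        slope_0 = max((Io[-1] - Io[0]) / 8.0, 1e-3)

        if self.method == "wls":
            sigma = 1.0 / np.sqrt(n) if self.weighted else np.ones_like(n)
            popt, pcov = optimize.curve_fit(
                _boltzmann, I, p, p0=[ec50_0, slope_0], sigma=sigma,
                bounds=([Io[0] - 3 * (Io[-1] - Io[0]), 1e-4],
                        [Io[-1] + 3 * (Io[-1] - Io[0]), 10 * (Io[-1] - Io[0])]),
                maxfev=20_000,
            )
            self.ec50_, self.slope_ = float(popt[0]), float(popt[1])
            se = np.sqrt(np.diag(pcov))
            self.se_ec50_, self.se_slope_ = float(se[0]), float(se[1])
        elif self.method == "mle":
            k = np.round(p * n)

            def nll(theta):
                q = np.clip(_boltzmann(I, theta[0], np.exp(theta[1])), 1e-12, 1 - 1e-12)
                return -np.sum(k * np.log(q) + (n - k) * np.log(1 - q))

            res = optimize.minimize(nll, x0=[ec50_0, np.log(slope_0)], method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
            self.ec50_, self.slope_ = float(res.x[0]), float(np.exp(res.x[1]))
            self.se_ec50_ = self.se_slope_ = float("nan")
        else:
            raise ValueError("method: must be 'wls' or 'mle'")

        self.fitted_probabilities_ = _boltzmann(I, self.ec50_, self.slope_)
        self.currents_ = I
        return self

    def predict_proba(self, current_ma: np.ndarray) -> np.ndarray:
        """Extension probability at the given currents under the fitted sigmoid."""
        return _boltzmann(np.asarray(current_ma, dtype=float), self.ec50_, self.slope_)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann threshold parameters with standard errors."""

    ec50: float  # mA
    slope: float  # mA
    se_ec50: float
    se_slope: float
    currents: Tuple[float, ...]
    fitted_probabilities: Tuple[float, ...]

    def probability(self, current_ma) -> np.ndarray:
        return _boltzmann(np.asarray(current_ma, dtype=float), self.ec50, self.slope)


def fit_boltzmann(curve: pd.DataFrame, weighted: bool = True, method: str = "wls"
                  ) -> BoltzmannFit:
    """Fit the Boltzmann sigmoid to a probability curve DataFrame.

    ``curve`` must carry columns ``current_ma``, ``p`` and (for weighting)
    ``n_tested`` as produced by :func:`probability_curve`.
    """
    n = curve["n_tested"].to_numpy() if "n_tested" in curve else None
    est = BoltzmannThreshold(weighted=weighted, method=method).fit(
        curve["current_ma"].to_numpy(), curve["p"].to_numpy(), n
    )
    return BoltzmannFit(
        ec50=est.ec50_, slope=est.slope_, se_ec50=est.se_ec50_, se_slope=est.se_slope_,
        currents=tuple(est.currents_), fitted_probabilities=tuple(est.fitted_probabilities_),
    )


def compare_ec50(fit_a: BoltzmannFit, fit_b: BoltzmannFit, n_comparisons: int = 1
                 ) -> Tuple[float, float]:
    """Two-sided EC50 difference test with Bonferroni correction.

    ``t = (EC50_a - EC50_b) / sqrt(se_a^2 + se_b^2)`` against the standard
    normal reference; the p-value is multiplied by ``n_comparisons`` and
    capped at 1.
    """
    if not (fit_a.se_ec50 > 0 and fit_b.se_ec50 > 0):
        raise ValueError("se_ec50: both fits need positive standard errors")
    t = (fit_a.ec50 - fit_b.ec50) / np.hypot(fit_a.se_ec50, fit_b.se_ec50)
    p = 2.0 * stats.norm.sf(abs(t)) * n_comparisons
    return float(t), float(min(p, 1.0))
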