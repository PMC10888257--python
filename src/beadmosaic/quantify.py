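"""Poisson-corrected variant-allele-frequency (VAF) estimation.

In bead-emulsion digital PCR each bead is a partition seeded by a Poisson
number of single molecules. The observed positive fraction ``p = m/(m+w)``
therefore underestimates the per-molecule mutant frequency; the standard
partition correction is

    lambda = -ln(1 - p)

which is exact under Poisson seeding and reduces to ``p`` for small ``p``.
A sample with zero mutant partitions is reported as ``lambda = 0`` with a
non-zero upper confidence bound: at low VAF, zeros are expected
non-detections (probability ``exp(-N * VAF)`` with ``N`` assayed molecules),
not evidence of true absence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def poisson_correct(m: int, w: int) -> float:
    """Partition-corrected VAF ``lambda = -ln(1 - m/(m+w))``.

    ``m`` and ``w`` are mutant and wild-type positive bead counts. A
    saturated sample (``m > 0, w = 0``) has infinite lambda and raises
    rather than silently capping.
    """
    if m < 0 or w < 0:
        raise ValueError("counts must be non-negative")
    if m + w == 0:
        raise ValueError("no positive beads: lambda undefined")
    if m > 0 and w == 0:
        raise ValueError("saturated sample (no wild-type beads): "
                         "lambda is infinite")
    return -math.log1p(-(m / (m + w)))


@dataclass
class VAFEstimate:
    """One sample's mutant/wild-type counts and corrected VAF with CI."""

    m: int
    w: int
    raw_fraction: float
    lam: float
    n_molecules: int
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.lam <= self.ci_high):
            raise ValueError("confidence interval does not bracket lambda")


def _clopper_pearson(m: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    low = 0.0 if m == 0 else float(sps.beta.ppf(alpha / 2, m, n - m + 1))
    high = 1.0 if m == n else float(sps.beta.ppf(1 - alpha / 2, m + 1, n - m))
    return low, high


def estimate_vaf(calls=None, *, m: int | None = None, w: int | None = None,
                 n_molecules: int = 100_000, ci_level: float = 0.95,
                 qc=None, override_qc: bool = False) -> VAFEstimate:
    """Poisson-corrected VAF with an exact binomial (Clopper-Pearson) CI.

    Accepts either a genotype call set (anything with ``n_mut``/``n_wt``
    attributes) or explicit ``m``/``w`` counts. The CI is computed on the
    raw positive fraction and transformed through the Poisson correction
    (monotone, so coverage is preserved). If a failed QC result is passed,
    estimation refuses unless ``override_qc`` is set (and logged).
    """
    if calls is not None:
        summary = getattr(calls, "summary", calls)
        m, w = int(summary.n_mut), int(summary.n_wt)
    if m is None or w is None:
        raise ValueError("provide either calls or both m and w")
    if qc is not None and not qc.passed:
        if not override_qc:
            raise ValueError(f"experiment failed QC: {qc.reasons}; "
                             "pass override_qc=True to force estimation")
        logger.warning("estimating VAF despite failed QC: %s", qc.reasons)
    lam = poisson_correct(m, w)
    n = m + w
    p_low, p_high = _clopper_pearson(m, n, ci_level)
    ci_low = -math.log1p(-p_low)
    ci_high = math.inf if p_high >= 1.0 else -math.log1p(-p_high)
    return VAFEstimate(m=m, w=w, raw_fraction=m / n, lam=lam,
                       n_molecules=n_molecules, ci_low=ci_low,
                       ci_high=ci_high, ci_level=ci_level)


def detection_probability(vaf, n_molecules):
    """Probability of observing >= 1 mutant among ``n_molecules`` molecules.

    ``1 - exp(-N * vaf)``: the Poisson detection limit. At VAF 1e-5 with
    1e5 assayed molecules this is ``1 - 1/e ~= 63%`` — zeros at such
    frequencies are common even when the mutation is present.
    """
    vaf = np.asarray(vaf, dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("vaf must lie in [0, 1]")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    out = -np.expm1(-n_molecules * vaf)
    return float(out) if out.ndim == 0 else out


@dataclass
class DilutionSeries:
    """Spike-in validation series: replicate counts per expected fraction.

    ``data`` columns: expected_fraction, replicate, m, w. Expected fractions
    must be strictly decreasing across points with >= 1 replicate each.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"expected_fraction", "replicate", "m", "w"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dilution series missing columns: {sorted(missing)}")
        fracs = self.data["expected_fraction"].unique()
        if len(fracs) == 0:
            raise ValueError("empty dilution series")
        if not np.all(np.diff(fracs) < 0):
            raise ValueError("expected fractions must be strictly decreasing")
        if np.any((fracs <= 0) | (fracs >= 1)):
            raise ValueError("expected fractions must lie in (0, 1)")

    @property
    def expected_fractions(self) -> np.ndarray:
        return self.data["expected_fraction"].unique()

    def corrected(self) -> pd.DataFrame:
        """Per-replicate Poisson-corrected VAF (``lam`` column added)."""
        out = self.data.copy()
        out["lam"] = [poisson_correct(int(m), int(w))
                      for m, w in zip(out["m"], out["w"])]
        return out


def validate_dilution(series: DilutionSeries) -> dict:
    """Accuracy check of a serial-dilution experiment.

    Computes Pearson's r between the expected spike-in fractions and the
    observed Poisson-corrected VAFs across all replicates, plus per-point
    medians (the summary a validation figure would show).
    """
    if len(series.expected_fractions) < 3:
        raise ValueError("need >= 3 distinct expected fractions")
    obs = series.corrected()
    r, p = sps.pearsonr(obs["expected_fraction"], obs["lam"])
    medians = (obs.groupby("expected_fraction", sort=False)["lam"]
               .median().rename("median_lam").reset_index())
    return {"pearson_r": float(r), "p_value": float(p), "medians": medians}
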