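"""Dye-switch genotype calling from per-bead intensities.

Each probing round assigns every bead a 2-digit code over (ch1, ch2):
00 empty, 10 ch1-positive, 01 ch2-positive, 11 both. The dye-switch round
swaps fluorophores between alleles, so a true wild-type bead reads 10 then
01 (combined code 1001) and a true mutant 01 then 10 (0110). Beads
fluorescing in both channels of one round carried both a mutant and a
wild-type molecule (code contains 11) and are eliminated as MULTI; any
other combined code is a channel artefact and called INCONSISTENT. Both are
excluded from mutation counting, numerator and denominator alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from beadmosaic.images import INTENSITY_COLUMNS

logger = logging.getLogger(__name__)

ROUND_CHANNELS = {
    "scan1": ("ch1_scan1", "ch2_scan1"),
    "dyeswitch": ("ch1_dyeswitch", "ch2_dyeswitch"),
}

#: component code order; 00 first so that exact responsibility ties resolve
#: conservatively toward "empty"
CODES = ("00", "10", "01", "11")

CLASS_WT = "WT"
CLASS_MUT = "MUT"
CLASS_EMPTY = "EMPTY"
CLASS_MULTI = "MULTI"
CLASS_INCONSISTENT = "INCONSISTENT"


def normalize_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Log-transform and robustly standardize the intensity columns.

    Each channel/round column is mapped through log10 (values at or below
    zero are clipped to the column's smallest positive entry) and then
    centred on the median and scaled by 1.4826*MAD. The transform is
    monotone per channel and invariant to rescaling a channel's gain.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 beads to normalize")
    out = table.copy()
    for col in INTENSITY_COLUMNS:
        x = out[col].to_numpy(float)
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError(f"column {col!r} has no positive intensities")
        lx = np.log10(np.clip(x, pos.min(), None))
        med = np.median(lx)
        mad = np.median(np.abs(lx - med))
        if mad == 0:
            raise ValueError(f"zero spread in channel {col!r}")
        out[col] = (lx - med) / (1.4826 * mad)
    return out


def _threshold_codes(x: np.ndarray, min_separation: float) -> np.ndarray:
    """Per-channel threshold grid -> quadrant index 0..3.

    Normalization anchors the (always-majority) empty-bead background at
    z = 0, so "positive in a channel" means more than ``min_separation``
    robust z-units above it. Values far *below* background (e.g. beads
    hanging over the image edge in one round) are low, not a cluster of
    their own.
    """
    hi = x > min_separation
    return hi[:, 0].astype(int) + 2 * hi[:, 1].astype(int)


def _quadrant_init(x: np.ndarray, quad: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full GMM initialization (weights, means, precisions) from the
    threshold-grid quadrants.

    One component per quadrant, centred on the quadrant members (nominal
    corner positions for unpopulated quadrants) with tight diagonal
    covariances, so EM cannot let a rare cluster's component drift onto
    the dominant empty-bead blob before the first E-step.
    """
    lo = np.array([x[:, 0].min(), x[:, 1].min()])
    hi = np.array([x[:, 0].max(), x[:, 1].max()])
    corners = np.array([lo, [hi[0], lo[1]], [lo[0], hi[1]], hi])
    means = corners.copy()
    weights = np.full(4, 1.0 / len(x))
    precisions = np.empty((4, 2, 2))
    for q in range(4):
        members = x[quad == q]
        if len(members):
            means[q] = members.mean(axis=0)
            weights[q] = len(members) / len(x)
            var = members.var(axis=0) + 1e-2
        else:
            var = np.array([1.0, 1.0])
        precisions[q] = np.diag(1.0 / var)
    weights /= weights.sum()
    return weights, means, precisions


@dataclass
class ClusterModel:
    """Per-round cluster assignment result."""

    codes: pd.Series  # 2-digit code per bead
    confident: pd.Series  # max responsibility >= conf_min
    responsibilities: pd.DataFrame  # per-code posterior, columns = CODES
    method: str  # "gmm" or "threshold" (fallback)


def fit_cluster_model(table: pd.DataFrame, round_name: str,
                      conf_min: float = 0.95, min_separation: float = 5.0,
                      method: str = "gmm", seed: int = 0) -> ClusterModel:
    """Assign each bead a 2-digit cluster code for one probing round.

    A 4-component full-covariance Gaussian mixture is fitted on the
    normalized (ch1, ch2) plane. Components are initialized at the
    centroids of the per-channel threshold-grid quadrants (nominal corners
    for unpopulated quadrants) so that rare clusters — e.g. a handful of
    mutant beads at low VAF — are not absorbed into the dominant empty
    component. Each component maps to a code digit per channel: 1 iff its
    mean lies more than ``min_separation`` robust z-units above the
    background (the normalization anchors the majority empty-bead
    population at z = 0). Beads whose
    summed per-code responsibility falls below ``conf_min`` are flagged
    unconfident (downstream: INCONSISTENT). A degenerate fit falls back to
    the plain threshold grid, logged.
    """
    if round_name not in ROUND_CHANNELS:
        raise ValueError(f"unknown round {round_name!r}")
    cols = ROUND_CHANNELS[round_name]
    x = table[list(cols)].to_numpy(float)
    if len(x) < 8:
        raise ValueError("need >= 8 beads to fit the cluster model")
    index = pd.Index(table["bead_id"], name="bead_id")
    quad = _threshold_codes(x, min_separation)

    if method == "threshold":
        return _threshold_model(quad, index)
    if method != "gmm":
        raise ValueError(f"unknown method {method!r}")

    try:
        import warnings as _warnings
        weights0, means0, precisions0 = _quadrant_init(x, quad)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            gmm = GaussianMixture(n_components=4, covariance_type="full",
                                  weights_init=weights0, means_init=means0,
                                  precisions_init=precisions0,
                                  reg_covar=1e-4, random_state=seed,
                                  max_iter=200)
            gmm.fit(x)
            resp_comp = gmm.predict_proba(x)
        comp_codes = _map_components(gmm.means_, min_separation)
    except (ValueError, np.linalg.LinAlgError) as err:
        logger.warning("GMM fit degenerate (%s); falling back to threshold "
                       "grid for round %s", err, round_name)
        return _threshold_model(quad, index)

    resp = np.zeros((len(x), 4))
    for comp, code_idx in enumerate(comp_codes):
        resp[:, code_idx] += resp_comp[:, comp]
    best = resp.argmax(axis=1)  # ties resolve to the lowest index: 00 first
    conf = resp[np.arange(len(x)), best]
    codes = pd.Series([CODES[i] for i in best], index=index, name="code")
    responsibilities = pd.DataFrame(resp, index=index, columns=list(CODES))
    return ClusterModel(codes=codes,
                        confident=pd.Series(conf >= conf_min, index=index,
                                            name="confident"),
                        responsibilities=responsibilities, method="gmm")


def _map_components(means: np.ndarray, min_separation: float) -> np.ndarray:
    """Map mixture components to codes: high iff the component mean sits
    more than ``min_separation`` z-units above the background (z = 0)."""
    hi = means > min_separation
    return hi[:, 0].astype(int) + 2 * hi[:, 1].astype(int)


def _threshold_model(quad: np.ndarray, index: pd.Index) -> ClusterModel:
    resp = np.zeros((len(quad), 4))
    resp[np.arange(len(quad)), quad] = 1.0
    codes = pd.Series([CODES[q] for q in quad], index=index, name="code")
    return ClusterModel(codes=codes,
                        confident=pd.Series(True, index=index, name="confident"),
                        responsibilities=pd.DataFrame(resp, index=index,
                                                      columns=list(CODES)),
                        method="threshold")


@dataclass
class CountSummary:
    """Bead class tallies for one experiment."""

    n_beads: int
    n_wt: int
    n_mut: int
    n_empty: int
    n_multi: int
    n_inconsistent: int

    def __post_init__(self) -> None:
        total = (self.n_wt + self.n_mut + self.n_empty + self.n_multi
                 + self.n_inconsistent)
        if total != self.n_beads:
            raise ValueError("class counts do not sum to n_beads")

    @property
    def positive_fraction(self) -> float:
        return (self.n_beads - self.n_empty) / self.n_beads


@dataclass
class GenotypeCallSet:
    """Per-bead combined dye-switch codes and class labels."""

    calls: pd.DataFrame  # bead_id, code_scan1, code_dyeswitch, code, class
    summary: CountSummary

    @property
    def n_wt(self) -> int:
        return self.summary.n_wt

    @property
    def n_mut(self) -> int:
        return self.summary.n_mut


def _classify_code(code1: str, code2: str, confident: bool) -> str:
    if not confident:
        return CLASS_INCONSISTENT
    if code1 == "11" or code2 == "11":
        return CLASS_MULTI
    combined = code1 + code2
    if combined == "1001":
        return CLASS_WT
    if combined == "0110":
        return CLASS_MUT
    if combined == "0000":
        return CLASS_EMPTY
    return CLASS_INCONSISTENT


def call_genotypes(round1: ClusterModel, round2: ClusterModel) -> GenotypeCallSet:
    """Combine the two rounds into 4-digit codes and final classes.

    The dye switch is mandatory: both rounds must be present and cover the
    same beads. Combined code = scan1 digits then dye-switch digits, digit
    order (ch1, ch2) within a round.
    """
    if round1 is None or round2 is None:
        raise ValueError("dye-switch confirmation is mandatory: need both rounds")
    if not round1.codes.index.equals(round2.codes.index):
        raise ValueError("rounds cover different bead ids")
    conf = round1.confident.to_numpy() & round2.confident.to_numpy()
    c1 = round1.codes.to_numpy()
    c2 = round2.codes.to_numpy()
    classes = [_classify_code(a, b, ok) for a, b, ok in zip(c1, c2, conf)]
    calls = pd.DataFrame({
        "bead_id": round1.codes.index,
        "code_scan1": c1,
        "code_dyeswitch": c2,
        "code": np.char.add(c1.astype(str), c2.astype(str)),
        "class": classes,
        "confidence": np.minimum(
            round1.responsibilities.max(axis=1).to_numpy(),
            round2.responsibilities.max(axis=1).to_numpy()),
    })
    counts = calls["class"].value_counts()
    summary = CountSummary(
        n_beads=len(calls),
        n_wt=int(counts.get(CLASS_WT, 0)),
        n_mut=int(counts.get(CLASS_MUT, 0)),
        n_empty=int(counts.get(CLASS_EMPTY, 0)),
        n_multi=int(counts.get(CLASS_MULTI, 0)),
        n_inconsistent=int(counts.get(CLASS_INCONSISTENT, 0)),
    )
    return GenotypeCallSet(calls=calls, summary=summary)


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    positive_fraction: float = float("nan")


def qc_experiment(summary: CountSummary, max_positive: float = 0.30,
                  target_positive: float = 0.10) -> QCResult:
    """Experiment-level QC on the bead class tallies.

    Experiments with more than ``max_positive`` positive beads are failed
    (too many beads seeded with more than one molecule would underestimate
    the mutation count — such runs are discarded and repeated), as are
    experiments with no called WT or mutant bead at all. A positive
    fraction more than 3x away from the ~10% seeding target draws a
    warning.
    """
    if summary.n_beads == 0:
        raise ValueError("empty experiment")
    pf = summary.positive_fraction
    reasons: list[str] = []
    warns: list[str] = []
    if pf > max_positive:
        reasons.append(
            f"positive fraction {pf:.2f} exceeds {max_positive:.2f}: "
            "discard and repeat (multi-seeded beads underestimate mutations)")
    if summary.n_wt + summary.n_mut == 0:
        reasons.append("no WT or mutant bead called: no signal")
    if pf > 0 and (pf > 3 * target_positive or pf < target_positive / 3):
        warns.append(f"positive fraction {pf:.3f} deviates >3x from the "
                     f"{target_positive:.2f} seeding target")
    return QCResult(passed=not reasons, reasons=reasons, warnings=warns,
                    positive_fraction=pf)
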