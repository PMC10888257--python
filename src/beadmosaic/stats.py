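"""Spatial and cohort mosaicism statistics.

Testis maps (6 slices x 32 pieces by default) are summarized by the
MaxVAF/IQR ratio: the highest per-piece VAF relative to the interquartile
range across pieces. Under uniform mutation spread the ratio is near 1;
focal sub-clonal expansions (symmetric self-renewal of mutant spermatogonial
stem cells) drive it to tens or hundreds.

Sperm cohorts are tested for the paternal-age effect with Spearman's rank
correlation between donor age and VAF, and two variants are compared with a
two-sided Mann-Whitney U test (tie-corrected normal approximation with a
Z-score, plus an exact small-sample mode).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from beadmosaic.quantify import poisson_correct


def _lam_column(df: pd.DataFrame) -> np.ndarray:
    """Poisson-corrected VAF per row from m and n_molecules (NaN-safe)."""
    lam = np.full(len(df), np.nan)
    for i, (m, n) in enumerate(zip(df["m"], df["n_molecules"])):
        if pd.notna(m):
            lam[i] = poisson_correct(int(m), int(n) - int(m))
    return lam


@dataclass
class TestisMap:
    """Per-piece mutant counts for one dissected testis.

    ``data`` columns: slice (1..n_slices), piece (1..pieces_per_slice),
    m (mutant molecule count; NaN for pieces not available), n_molecules.
    """

    __test__ = False  # name looks like a test class to pytest; it is not

    data: pd.DataFrame
    n_slices: int = 6
    pieces_per_slice: int = 32
    locus: str | None = None

    def __post_init__(self) -> None:
        required = {"slice", "piece", "m", "n_molecules"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"testis map missing columns: {sorted(missing)}")
        addr = list(zip(self.data["slice"], self.data["piece"]))
        if len(set(addr)) != len(addr):
            raise ValueError("duplicate (slice, piece) addresses")
        if (self.data["slice"].min() < 1 or self.data["slice"].max() > self.n_slices
                or self.data["piece"].min() < 1
                or self.data["piece"].max() > self.pieces_per_slice):
            raise ValueError("piece address outside the dissection grid")

    @property
    def n_pieces(self) -> int:
        return len(self.data)

    def lam(self) -> np.ndarray:
        """Per-piece corrected VAF; NaN where the piece is not available."""
        return _lam_column(self.data)


@dataclass
class TestisSummary:
    """The per-testis summary row: mean/median/IQR/max VAF and MaxVAF/IQR."""

    mean_vaf: float
    median_vaf: float
    iqr: float
    max_vaf: float
    max_over_iqr: float  # NaN when IQR == 0 (uniform map)
    n: int


def summarize_testis(testis: TestisMap | np.ndarray) -> TestisSummary:
    """Summary statistics over the non-NA pieces of a testis map.

    Quantiles use linear interpolation (type 7). ``max_over_iqr`` is NaN for
    a zero IQR: a perfectly uniform map is the no-expansion null, not an
    infinite expansion signal.
    """
    vals = testis.lam() if isinstance(testis, TestisMap) else np.asarray(testis, float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise ValueError("need >= 4 non-NA pieces to summarize a testis map")
    q25, q75 = np.percentile(vals, [25, 75])
    iqr = float(q75 - q25)
    max_vaf = float(vals.max())
    ratio = max_vaf / iqr if iqr > 0 else math.nan
    return TestisSummary(mean_vaf=float(vals.mean()),
                         median_vaf=float(np.median(vals)),
                         iqr=iqr, max_vaf=max_vaf, max_over_iqr=ratio,
                         n=int(vals.size))


@dataclass
class DonorCohort:
    """Sperm-donor cohort for one locus.

    ``data`` columns: donor_id, age (years), m (mutant count), n_molecules.
    """

    data: pd.DataFrame
    locus: str | None = None
    age_range: tuple[float, float] = (18.0, 80.0)

    def __post_init__(self) -> None:
        required = {"donor_id", "age", "m", "n_molecules"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort missing columns: {sorted(missing)}")
        if self.data["donor_id"].duplicated().any():
            raise ValueError("one record per donor per locus")
        lo, hi = self.age_range
        if ((self.data["age"] < lo) | (self.data["age"] > hi)).any():
            raise ValueError(f"donor age outside declared range {self.age_range}")

    @property
    def n_donors(self) -> int:
        return len(self.data)

    def lam(self) -> np.ndarray:
        return _lam_column(self.data)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "t-approx" or "exact-permutation"


@dataclass
class MannWhitneyResult:
    u: float  # larger of the two U statistics (max n_a * n_b)
    z: float  # tie- and continuity-corrected normal deviate, >= 0
    p_value: float
    n_a: int
    n_b: int
    method: str  # "normal-approx" or "exact"


@dataclass
class PositivityResult:
    n_positive: int
    n: int
    fraction: float
    percent: int  # rounded, as reported


def _spearman_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    return float(np.corrcoef(x_ranks, y_ranks)[0, 1])


def age_trend(cohort: DonorCohort, method: str = "auto",
              exact_max_n: int = 8) -> SpearmanResult:
    """Spearman rank correlation between donor age and corrected VAF.

    Ties get average ranks. The two-sided p-value uses the t approximation
    (the conventional large-sample test) or, for ``method="exact"`` (default
    for n <= ``exact_max_n``), full enumeration of the permutation null.
    """
    ages = cohort.data["age"].to_numpy(float)
    lam = cohort.lam()
    n = len(ages)
    if n < 5:
        raise ValueError("need >= 5 donors for the age trend")
    if np.unique(ages).size == 1 or np.unique(lam).size == 1:
        raise ValueError("constant ages or constant VAFs: rho undefined")
    if method == "auto":
        method = "exact" if n <= exact_max_n else "t-approx"

    rx = sps.rankdata(ages)
    ry = sps.rankdata(lam)
    rho = _spearman_rho(rx, ry)
    if method == "t-approx":
        # matches the standard two-sided t test on rho with n-2 df
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
        p = 2 * sps.t.sf(abs(t), n - 2)
        return SpearmanResult(rho=rho, p_value=min(1.0, float(p)), n=n,
                              method="t-approx")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_spearman_rho(rx, np.array(perm))) >= target:
            count += 1
    return SpearmanResult(rho=rho, p_value=count / total, n=n,
                          method="exact-permutation")


def _mwu_from_values(a: np.ndarray, b: np.ndarray) -> tuple[float, float, np.ndarray]:
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r_a = ranks[:len(a)].sum()
    u_a = r_a - len(a) * (len(a) + 1) / 2
    u_b = len(a) * len(b) - u_a
    return u_a, u_b, ranks


def compare_variants(cohort_a: DonorCohort | np.ndarray,
                     cohort_b: DonorCohort | np.ndarray,
                     method: str = "auto", exact_max_n: int = 14
                     ) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two cohorts' VAFs.

    Reports the larger of the two U statistics and a Z-score from the
    normal approximation with average-rank tie correction and a 0.5
    continuity correction. ``method="exact"`` (default when the combined
    sample is <= ``exact_max_n``) enumerates all rank splits instead; it is
    exact under ties as well because it permutes the observed values.
    """
    a = cohort_a.lam() if isinstance(cohort_a, DonorCohort) else np.asarray(cohort_a, float)
    b = cohort_b.lam() if isinstance(cohort_b, DonorCohort) else np.asarray(cohort_b, float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both cohorts must be non-empty")
    u_a, u_b, ranks = _mwu_from_values(a, b)
    u = max(u_a, u_b)
    mu = n_a * n_b / 2.0
    if method == "auto":
        method = "exact" if n_a + n_b <= exact_max_n else "normal-approx"

    if method == "exact":
        combined = np.concatenate([a, b])
        allranks = sps.rankdata(combined)
        target = abs(u_a - mu) - 1e-12
        count = 0
        total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            total += 1
            r = allranks[list(idx)].sum()
            u_perm = r - n_a * (n_a + 1) / 2
            if abs(u_perm - mu) >= target:
                count += 1
        p = count / total
        z = _mwu_z(u, mu, n_a, n_b, ranks)
        return MannWhitneyResult(u=float(u), z=z, p_value=p,
                                 n_a=n_a, n_b=n_b, method="exact")
    if method != "normal-approx":
        raise ValueError(f"unknown method {method!r}")
    z = _mwu_z(u, mu, n_a, n_b, ranks)
    p = min(1.0, 2 * float(sps.norm.sf(z)))
    return MannWhitneyResult(u=float(u), z=z, p_value=p,
                             n_a=n_a, n_b=n_b, method="normal-approx")


def _mwu_z(u: float, mu: float, n_a: int, n_b: int, ranks: np.ndarray) -> float:
    n = n_a + n_b
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    return max(0.0, float(z))


def positivity_rate(cohort: DonorCohort) -> PositivityResult:
    """Fraction of donors with at least one mutant molecule observed."""
    if cohort.n_donors == 0:
        raise ValueError("empty cohort")
    m = cohort.data["m"]
    positive = int(((m > 0) & m.notna()).sum())
    frac = positive / cohort.n_donors
    return PositivityResult(n_positive=positive, n=cohort.n_donors,
                            fraction=frac, percent=round(100 * frac))


#: VAF bin edges for the testis heat map, spanning 0 .. >1e-3 on a log-like scale
HEATMAP_BINS = (0.0, 1e-6, 1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 1.0)


def render_testis_heatmap(testis: TestisMap, path, cmap: str = "viridis"):
    """Render the dissection grid as one colour-coded panel per slice.

    Pieces are coloured by corrected VAF on a banded quasi-log scale from 0
    to >1e-3; not-available pieces are greyed out. Writes PNG or SVG by file
    suffix and returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colors

    lam = testis.lam()
    grid = np.full((testis.n_slices, testis.pieces_per_slice), np.nan)
    for (s, p), v in zip(zip(testis.data["slice"], testis.data["piece"]), lam):
        grid[int(s) - 1, int(p) - 1] = v

    ncols = 8 if testis.pieces_per_slice % 8 == 0 else testis.pieces_per_slice
    nrows = testis.pieces_per_slice // ncols
    norm = colors.BoundaryNorm(HEATMAP_BINS, ncolors=256)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.7")

    fig, axes = plt.subplots(1, testis.n_slices,
                             figsize=(2.2 * testis.n_slices, 2.2 * nrows / 2))
    axes = np.atleast_1d(axes)
    for s, ax in enumerate(axes):
        panel = np.ma.masked_invalid(grid[s].reshape(nrows, ncols))
        im = ax.imshow(panel, cmap=cm, norm=norm, interpolation="nearest")
        ax.set_title(f"slice {s + 1}", fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, fraction=0.02, label="VAF (banded scale)")
    if testis.locus:
        fig.suptitle(testis.locus)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
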