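"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: bead-array image
sets (two probing rounds x three channels, with dye-switch channel
swapping and an inter-round shift), testis dissection maps (6 slices x 32
pieces) with focal sub-clonal expansions over a log-normal background,
sperm-donor cohorts with an age-dependent VAF trend, and serial-dilution
spike-in series.

Bead classes follow Poisson single-molecule seeding: each bead captures
``Poisson(rate * vaf)`` mutant and ``Poisson(rate * (1 - vaf))`` wild-type
molecules independently, so at the default seeding rate of
``-ln(0.9) ~= 0.105`` about 10% of beads are positive and most positives
carry exactly one molecule. Beads with both alleles aboard are MIXED and
should be eliminated by the dye-switch analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from skimage.draw import disk

from beadmosaic.images import BeadImageSet, PAGE_ORDER
from beadmosaic.quantify import DilutionSeries
from beadmosaic.stats import TestisMap, DonorCohort

CLASS_EMPTY = "EMPTY"
CLASS_WT = "WT"
CLASS_MUT = "MUT"
CLASS_MIXED = "MIXED"

#: expected ~10% positive beads: the low molecule-to-bead input ratio used
#: so that most positive beads carry a single molecule
DEFAULT_SEEDING_RATE = -math.log(0.9)


class PlacementError(RuntimeError):
    """Raised when non-overlapping bead placement cannot be achieved."""


@dataclass
class SimConfig:
    """Parameters of one simulated bead-array experiment.

    Desk-scale defaults: 10,000 beads in a 2048x2048 field and 1e5
    effective assayed molecules stand in for the production scale of
    ~6e6 beads (a 1024x1024 field cannot hold 10,000 non-overlapping
    beads of this radius: it is past the random-packing limit).
    ``true_vaf`` defaults to the 1:100 spike-in level so a default field
    contains a visible mutant population.
    """

    seed: int = 0
    image_size: tuple[int, int] = (2048, 2048)
    n_beads: int = 10_000
    bead_radius: int = 4
    seeding_rate: float = DEFAULT_SEEDING_RATE
    true_vaf: float = 1e-2
    channel_gains: dict = field(default_factory=lambda: {"ch1": 1000.0,
                                                         "ch2": 1000.0})
    background: float = 100.0
    brightfield_gain: float = 600.0
    noise_sd: float = 20.0
    shift: tuple[int, int] = (12, -7)  # (dy, dx) applied to the dyeswitch round
    n_molecules: int = 100_000

    def __post_init__(self) -> None:
        if self.n_beads <= 0:
            raise ValueError("n_beads must be positive")
        if not (0.0 <= self.true_vaf <= 1.0):
            raise ValueError("true_vaf must lie in [0, 1]")
        if self.seeding_rate <= 0:
            raise ValueError("seeding_rate must be positive")
        if self.bead_radius < 1:
            raise ValueError("bead_radius must be >= 1 pixel")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image size must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["shift"] = list(self.shift)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        if "shift" in d:
            d["shift"] = tuple(d["shift"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    bead_classes: np.ndarray | None = None  # per-bead class label
    bead_centers: np.ndarray | None = None  # (n, 2) float (y, x), scan1 frame
    shift: tuple[int, int] | None = None
    piece_vaf: pd.DataFrame | None = None  # per-piece true VAF (testis)
    donor_vaf: pd.DataFrame | None = None  # per-donor true VAF (cohort)


def draw_bead_classes(rng: np.random.Generator, n_beads: int,
                      seeding_rate: float, true_vaf: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson single-molecule seeding of beads.

    Returns (class labels, mutant molecule counts, wild-type molecule
    counts). MIXED means at least one molecule of each allele landed on
    the bead.
    """
    n_mut = rng.poisson(seeding_rate * true_vaf, size=n_beads)
    n_wt = rng.poisson(seeding_rate * (1.0 - true_vaf), size=n_beads)
    classes = np.full(n_beads, CLASS_EMPTY, dtype=object)
    classes[(n_wt > 0) & (n_mut == 0)] = CLASS_WT
    classes[(n_mut > 0) & (n_wt == 0)] = CLASS_MUT
    classes[(n_mut > 0) & (n_wt > 0)] = CLASS_MIXED
    return classes, n_mut, n_wt


def _place_beads(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Rejection-sample non-overlapping bead centres on a grid hash."""
    h, w = config.image_size
    r = config.bead_radius
    # non-overlap plus a 2 px guard so adjacent beads stay 4-connectivity
    # separable in the segmentation mask
    min_dist = 2 * r + 3
    if h < 2 * r + 2 or w < 2 * r + 2:
        raise PlacementError("image too small for even one bead")
    cell = min_dist
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    centers = np.empty((config.n_beads, 2))
    placed = 0
    max_attempts = 10 * config.n_beads
    attempts = 0
    while placed < config.n_beads:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {placed}/{config.n_beads} beads after "
                f"{max_attempts} attempts: bead density too high")
        attempts += 1
        y = rng.uniform(r, h - 1 - r)
        x = rng.uniform(r, w - 1 - r)
        cy, cx = int(y // cell), int(x // cell)
        ok = True
        for ny in range(cy - 1, cy + 2):
            for nx in range(cx - 1, cx + 2):
                for (py, px) in grid.get((ny, nx), ()):
                    if (y - py) ** 2 + (x - px) ** 2 < min_dist ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers[placed] = (y, x)
            grid.setdefault((cy, cx), []).append((y, x))
            placed += 1
    return centers


def _render_round(config: SimConfig, centers: np.ndarray,
                  classes: np.ndarray, dyeswitch: bool,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Render brightfield + two fluorescence channels for one round.

    Dye-switch contract: in scan1 a WT bead is bright in ch1 and a mutant
    in ch2; the dye-switch round swaps them. MIXED beads are bright in
    both channels of every round.
    """
    h, w = config.image_size
    shape = (h, w)
    bf = np.full(shape, config.background)
    ch1 = np.full(shape, config.background)
    ch2 = np.full(shape, config.background)
    g1 = config.channel_gains["ch1"]
    g2 = config.channel_gains["ch2"]
    for (y, x), cls in zip(centers, classes):
        rr, cc = disk((y, x), config.bead_radius + 0.5, shape=shape)
        bf[rr, cc] = config.brightfield_gain
        if cls == CLASS_EMPTY:
            continue
        wt_bright = (cls in (CLASS_WT, CLASS_MIXED))
        mut_bright = (cls in (CLASS_MUT, CLASS_MIXED))
        if dyeswitch:
            wt_bright, mut_bright = mut_bright, wt_bright
        if wt_bright:
            ch1[rr, cc] = g1
        if mut_bright:
            ch2[rr, cc] = g2
    if config.noise_sd > 0:
        bf = bf + rng.normal(0, config.noise_sd, shape)
        ch1 = ch1 + rng.normal(0, config.noise_sd, shape)
        ch2 = ch2 + rng.normal(0, config.noise_sd, shape)
    return {"brightfield": bf, "ch1": ch1, "ch2": ch2}


def simulate_bead_image_set(config: SimConfig) -> tuple[BeadImageSet, GroundTruth]:
    """Simulate a two-round, three-channel bead-array field.

    Beads are uniform bright disks placed without overlap (rejection
    sampling; raises :class:`PlacementError` if the density makes placement
    impossible within 10x ``n_beads`` attempts). The dye-switch round is
    the same field translated by ``config.shift`` with allele/channel
    assignments swapped, plus fresh additive Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    centers = _place_beads(rng, config)
    classes, _, _ = draw_bead_classes(rng, config.n_beads,
                                      config.seeding_rate, config.true_vaf)
    round1 = _render_round(config, centers, classes, dyeswitch=False, rng=rng)
    dy, dx = config.shift
    shifted_centers = centers + np.array([dy, dx])
    round2 = _render_round(config, shifted_centers, classes, dyeswitch=True,
                           rng=rng)
    images = {("scan1", ch): round1[ch] for ch in round1}
    images.update({("dyeswitch", ch): round2[ch] for ch in round2})
    truth = GroundTruth(bead_classes=classes, bead_centers=centers,
                        shift=(dy, dx))
    return BeadImageSet(images), truth


def simulate_testis_map(n_slices: int = 6, pieces_per_slice: int = 32,
                        background_vaf_mu: float = math.log(2.3e-5),
                        background_vaf_sigma: float = 1.0,
                        clusters: list[tuple[int, int, float]] | None = None,
                        n_molecules: int = 100_000,
                        na_pieces: list[tuple[int, int]] | None = None,
                        seed: int = 0, locus: str | None = None
                        ) -> tuple[TestisMap, GroundTruth]:
    """Simulate per-piece mutant counts for a dissected testis.

    The per-piece background VAF is log-normal (defaults match a testis
    whose median piece VAF is ~2.3e-5); each ``(slice, piece, amplitude)``
    cluster multiplies that piece's VAF by ``amplitude`` (>= 1), emulating
    a focal sub-clonal expansion. Mutant counts are binomial draws of
    ``n_molecules`` molecules at the piece VAF. ``na_pieces`` lists
    dissected pieces with no usable measurement.
    """
    clusters = clusters or []
    na = set(na_pieces or [])
    rng = np.random.default_rng(seed)
    for s, p, amp in clusters:
        if not (1 <= s <= n_slices and 1 <= p <= pieces_per_slice):
            raise ValueError(f"cluster address ({s}, {p}) outside grid")
        if amp < 1:
            raise ValueError("cluster amplitude must be >= 1")
    rows = []
    truth_rows = []
    amp_map = {(s, p): a for s, p, a in clusters}
    for s in range(1, n_slices + 1):
        for p in range(1, pieces_per_slice + 1):
            vaf = math.exp(rng.normal(background_vaf_mu, background_vaf_sigma))
            vaf = min(1.0, vaf * amp_map.get((s, p), 1.0))
            m = np.nan if (s, p) in na else rng.binomial(n_molecules, vaf)
            rows.append({"slice": s, "piece": p, "m": m,
                         "n_molecules": n_molecules})
            truth_rows.append({"slice": s, "piece": p, "true_vaf": vaf})
    data = pd.DataFrame(rows)
    tmap = TestisMap(data=data, n_slices=n_slices,
                     pieces_per_slice=pieces_per_slice, locus=locus)
    return tmap, GroundTruth(piece_vaf=pd.DataFrame(truth_rows))


# ACH-like cohort defaults, calibrated once by Monte Carlo so that the
# population Spearman rho between age and observed VAF is ~0.3 at n = 56
# with 1e5 molecules (see docs/methods.md).
DEFAULT_LOG_VAF_INTERCEPT = math.log(2.9e-5) - 0.03 * 42.0
DEFAULT_LOG_VAF_SLOPE = 0.03  # per year
DEFAULT_DISPERSION = 0.7  # sd of log-VAF around the age trend


def simulate_sperm_cohort(n_donors: int = 56,
                          age_range: tuple[float, float] = (25.0, 59.0),
                          log_vaf_intercept: float = DEFAULT_LOG_VAF_INTERCEPT,
                          log_vaf_slope: float = DEFAULT_LOG_VAF_SLOPE,
                          dispersion: float = DEFAULT_DISPERSION,
                          n_molecules: int = 100_000, seed: int = 0,
                          locus: str | None = None
                          ) -> tuple[DonorCohort, GroundTruth]:
    """Simulate a sperm-donor cohort with an age-dependent mutation load.

    Donor ages are uniform over ``age_range``; each donor's true VAF is
    ``exp(intercept + slope * age + N(0, dispersion))`` and the observed
    mutant count is a binomial draw of ``n_molecules`` molecules. This
    generative model is a stand-in for real per-donor data: it reproduces
    the scale, trend strength, and zero-inflation of an ACH-like cohort,
    not any particular donor.
    """
    if n_donors < 3:
        raise ValueError("need >= 3 donors")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n_donors)
    log_vaf = (log_vaf_intercept + log_vaf_slope * ages
               + rng.normal(0, dispersion, size=n_donors))
    true_vaf = np.minimum(1.0, np.exp(log_vaf))
    m = rng.binomial(n_molecules, true_vaf)
    data = pd.DataFrame({
        "donor_id": [f"D{i:03d}" for i in range(n_donors)],
        "age": ages,
        "m": m,
        "n_molecules": n_molecules,
    })
    cohort = DonorCohort(data=data, locus=locus,
                         age_range=(age_range[0] - 1e-9, age_range[1] + 1e-9))
    truth = GroundTruth(donor_vaf=pd.DataFrame({
        "donor_id": data["donor_id"], "age": ages, "true_vaf": true_vaf}))
    return cohort, truth


def simulate_dilution_series(expected_fractions=(1e-2, 1e-3, 1e-4),
                             replicates: int = 3, n_molecules: int = 100_000,
                             seed: int = 0) -> DilutionSeries:
    """Simulate a mutant spike-in dilution series.

    Defaults reproduce the 1 mutant : 100 / 1,000 / 10,000 wild-type
    validation design. Per replicate, the mutant count is
    ``Binomial(n_molecules, fraction)`` and wild-type the remainder.
    """
    fracs = list(expected_fractions)
    if not fracs:
        raise ValueError("expected_fractions must be non-empty")
    if any(not (0 < f < 1) for f in fracs):
        raise ValueError("fractions must lie in (0, 1)")
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fracs:
        for rep in range(replicates):
            m = int(rng.binomial(n_molecules, f))
            rows.append({"expected_fraction": f, "replicate": rep,
                         "m": m, "w": n_molecules - m})
    return DilutionSeries(pd.DataFrame(rows))
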