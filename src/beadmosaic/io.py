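"""Pipeline configuration, table IO, and the end-to-end runner.

Canonical formats: TSV (tab-delimited, UTF-8, header row) for tables, YAML
for configuration, JSON for reports/manifests. All randomness flows from
one global seed through :class:`numpy.random.SeedSequence` spawning, so a
fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from beadmosaic import images as im
from beadmosaic import genotyping as gt
from beadmosaic import quantify as qt
from beadmosaic import stats as st
from beadmosaic import simulate as sim

logger = logging.getLogger(__name__)

BEAD_TABLE_SCHEMA = {
    "bead_id": "int", "y": "float", "x": "float", "area": "float",
    "ch1_scan1": "float", "ch2_scan1": "float",
    "ch1_dyeswitch": "float", "ch2_dyeswitch": "float",
}
CALLS_SCHEMA = {
    "bead_id": "int", "code_scan1": "str", "code_dyeswitch": "str",
    "code": "str", "class": "str", "confidence": "float",
}
COHORT_SCHEMA = {"donor_id": "str", "age": "float", "m": "float",
                 "n_molecules": "int"}
TESTIS_SCHEMA = {"slice": "int", "piece": "int", "m": "float",
                 "n_molecules": "int"}
DILUTION_SCHEMA = {"expected_fraction": "float", "replicate": "int",
                   "m": "int", "w": "int"}

_DTYPES = {"int": "int64", "float": "float64", "str": "object"}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and reason."""

    def __init__(self, stage: str, reason: str, path=None):
        self.stage = stage
        self.reason = reason
        self.path = path
        loc = f" (input: {path})" if path else ""
        super().__init__(f"stage {stage!r} failed{loc}: {reason}")


def read_table(path, schema: dict[str, str]) -> pd.DataFrame:
    """Read and validate a TSV table against a column->type schema."""
    df = pd.read_csv(path, sep="\t")
    for col, kind in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        if kind == "str":
            df[col] = df[col].astype(str)
            continue
        try:
            df[col] = df[col].astype(_DTYPES[kind])
        except (ValueError, TypeError) as err:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()]
            row = int(bad.index[0]) if len(bad) else "?"
            raise SchemaError(
                f"{path}: column {col!r} is not {kind} (first bad row "
                f"{row}): {err}") from err
    return df


def write_table(df: pd.DataFrame, path, schema: dict[str, str] | None = None
                ) -> None:
    """Write a table as TSV with a fixed column order when a schema is given."""
    if schema is not None:
        missing = set(schema) - set(df.columns)
        if missing:
            raise SchemaError(f"cannot write {path}: missing columns "
                              f"{sorted(missing)}")
        df = df[list(schema)]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class LocusConfig:
    """Per-locus settings: one mutation site screened in the experiment."""

    label: str
    true_vaf: float = 1e-2  # bead-level mutant fraction for the image demo
    cohort: dict = field(default_factory=dict)  # simulate_sperm_cohort kwargs
    testis: dict = field(default_factory=dict)  # simulate_testis_map kwargs


def _default_loci() -> list[LocusConfig]:
    return [
        LocusConfig(label="c.1138G>A", true_vaf=0.05,
                    testis={"clusters": [[2, 7, 20.0]]}),
        LocusConfig(label="c.1948A>G", true_vaf=0.02,
                    cohort={"log_vaf_intercept":
                            sim.DEFAULT_LOG_VAF_INTERCEPT - math.log(10)},
                    testis={"background_vaf_mu": math.log(4e-6),
                            "clusters": [[5, 12, 300.0]]}),
    ]


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    The default demo simulates a small two-locus experiment (an ACH-like
    and a TDII-like FGFR3 site) at desk scale.
    """

    seed: int = 0
    n_molecules: int = 100_000
    loci: list[LocusConfig] = field(default_factory=_default_loci)
    sim: dict = field(default_factory=lambda: {"image_size": (512, 512),
                                               "n_beads": 600})
    max_positive: float = 0.30
    heatmap_format: str = "png"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"] = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in d["sim"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "loci" in d:
            loci = []
            for entry in d["loci"]:
                lk = set(LocusConfig.__dataclass_fields__)
                bad = set(entry) - lk
                if bad:
                    raise ValueError(f"unknown locus config keys: {sorted(bad)}")
                loci.append(LocusConfig(**entry))
            d["loci"] = loci
        if "sim" in d and "image_size" in d["sim"]:
            d["sim"] = dict(d["sim"])
            d["sim"]["image_size"] = tuple(d["sim"]["image_size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _summary_dict(obj) -> dict:
    return {k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in dataclasses.asdict(obj).items()}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> call-beads -> classify -> VAF -> statistics.

    Writes, per locus: the image set (TIFF), bead table and genotype calls
    (TSV), QC report (JSON), testis map (TSV) and heat map, cohort table
    (TSV); plus a cross-locus comparison and a manifest recording the seed,
    package versions, and per-stage status. Any stage failure aborts with
    :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    locus_seeds = root_ss.spawn(len(config.loci))
    manifest: dict = {
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
        "loci": {},
    }
    cohorts: dict[str, st.DonorCohort] = {}

    for locus, ss in zip(config.loci, locus_seeds):
        tag = locus.label.replace(">", "-").replace(".", "_")
        res: dict = {}
        img_ss, testis_ss, cohort_ss, gmm_ss = ss.spawn(4)

        t0 = time.perf_counter()
        sim_cfg = sim.SimConfig(seed=_child_seed(img_ss),
                                true_vaf=locus.true_vaf,
                                n_molecules=config.n_molecules, **config.sim)
        image_set, truth = sim.simulate_bead_image_set(sim_cfg)
        tiff_path = out / f"{tag}.images.tiff"
        image_set.save_tiff(tiff_path)
        _stage(manifest, f"{locus.label}/simulate", t0)

        t0 = time.perf_counter()
        try:
            reg = im.register_rounds(image_set[("scan1", "brightfield")],
                                     image_set[("dyeswitch", "brightfield")])
            if not reg.accepted:
                raise StageError("register", f"shift {reg.shift} exceeds "
                                 f"{reg.max_shift} px: image pair discarded",
                                 tiff_path)
            mask1 = im.segment_beads(image_set[("scan1", "brightfield")],
                                     bead_radius=sim_cfg.bead_radius)
            mask2 = im.segment_beads(image_set[("dyeswitch", "brightfield")],
                                     bead_radius=sim_cfg.bead_radius)
            _, matched = im.propagate_mask(mask1, reg, mask2)
            table = im.extract_bead_table(image_set, mask1, reg, matched)
            if table.empty:
                raise StageError("call-beads", "no matched beads", tiff_path)
        except ValueError as err:
            raise StageError("call-beads", str(err), tiff_path) from err
        table_path = out / f"{tag}.beads.tsv"
        write_table(table, table_path, BEAD_TABLE_SCHEMA)
        _stage(manifest, f"{locus.label}/call-beads", t0)

        t0 = time.perf_counter()
        try:
            norm = gt.normalize_intensities(table)
            gmm_seed = _child_seed(gmm_ss)
            r1 = gt.fit_cluster_model(norm, "scan1", seed=gmm_seed)
            r2 = gt.fit_cluster_model(norm, "dyeswitch", seed=gmm_seed)
            calls = gt.call_genotypes(r1, r2)
        except ValueError as err:
            raise StageError("classify", str(err), table_path) from err
        write_table(calls.calls, out / f"{tag}.calls.tsv", CALLS_SCHEMA)
        qc = gt.qc_experiment(calls.summary, max_positive=config.max_positive)
        qc_path = out / f"{tag}.qc.json"
        qc_path.write_text(json.dumps(dataclasses.asdict(qc), indent=2))
        _stage(manifest, f"{locus.label}/classify", t0)
        if not qc.passed:
            manifest["stages"].append({"stage": f"{locus.label}/qc",
                                       "status": "fail",
                                       "reasons": qc.reasons})
            raise StageError("qc", "; ".join(qc.reasons), qc_path)

        t0 = time.perf_counter()
        est = qt.estimate_vaf(calls, n_molecules=config.n_molecules)
        res["vaf"] = _summary_dict(est)
        res["qc"] = dataclasses.asdict(qc)
        _stage(manifest, f"{locus.label}/vaf", t0)

        t0 = time.perf_counter()
        tmap, _ = sim.simulate_testis_map(seed=_child_seed(testis_ss),
                                          n_molecules=config.n_molecules,
                                          locus=locus.label, **locus.testis)
        write_table(tmap.data, out / f"{tag}.testis.tsv", TESTIS_SCHEMA)
        res["testis_summary"] = _summary_dict(st.summarize_testis(tmap))
        st.render_testis_heatmap(
            tmap, out / f"{tag}.testis.{config.heatmap_format}")
        _stage(manifest, f"{locus.label}/testis-stats", t0)

        t0 = time.perf_counter()
        cohort, _ = sim.simulate_sperm_cohort(seed=_child_seed(cohort_ss),
                                              n_molecules=config.n_molecules,
                                              locus=locus.label,
                                              **locus.cohort)
        write_table(cohort.data, out / f"{tag}.cohort.tsv", COHORT_SCHEMA)
        trend = st.age_trend(cohort)
        pos = st.positivity_rate(cohort)
        res["age_trend"] = dataclasses.asdict(trend)
        res["positivity"] = dataclasses.asdict(pos)
        cohorts[locus.label] = cohort
        _stage(manifest, f"{locus.label}/cohort-stats", t0)

        manifest["loci"][locus.label] = res

    if len(cohorts) >= 2:
        labels = list(cohorts)
        mwu = st.compare_variants(cohorts[labels[0]], cohorts[labels[1]])
        manifest["comparison"] = {"a": labels[0], "b": labels[1],
                                  **dataclasses.asdict(mwu)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage(manifest: dict, name: str, t0: float) -> None:
    dt = time.perf_counter() - t0
    logger.info("stage %s done in %.2fs", name, dt)
    manifest["stages"].append({"stage": name, "status": "ok",
                               "seconds": round(dt, 3)})


def _versions() -> dict:
    import beadmosaic
    import scipy
    import skimage
    import sklearn
    return {"beadmosaic": beadmosaic.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__}
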