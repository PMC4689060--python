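"""End-to-end pipeline: simulate → intensity → exposure → mvpa → fit → report.

Stages communicate through files in one output directory; a JSON run
manifest records a config hash and per-stage input/output checksums, so a
re-run with identical config and seeds reproduces identical checksums and
unchanged stages are skipped. A single root seed is fanned out to named
per-stage streams, so changing one stage's seed leaves the others
untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .accelerometry import process_series
from .association import (basic_models_table, fit_basic_models,
                          run_pattern_analysis, pattern_plot, STRATA)
from .city import (CityConfig, generate_density_raster, generate_point_layer,
                   generate_street_network)
from .cohort import CohortConfig, EpochConfig, generate_cohort, \
    generate_epoch_counts
from .exposure import (BlurSpec, ExposureConfig, build_exposure_matrix,
                       exposure_summary, layer_surfaces)
from .intensity import kernel_intensity_surface

logger = logging.getLogger(__name__)

STAGES = ["simulate", "intensity", "exposure", "mvpa", "fit", "report"]


def stage_seed(root_seed: int, name: str) -> int:
    """Named per-stage seed stream derived from one root seed."""
    return int((zlib.crc32(name.encode()) ^ (root_seed * 2654435761)) % 2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "scratch/run"
    seed: int = 0
    city: CityConfig = field(default_factory=CityConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    n_days: int = 4
    layers: list = field(default_factory=lambda: ["intersections", "transit",
                                                  "open_space"])
    strata: list = field(default_factory=lambda: list(STRATA))
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        d = self.exposure.distances_m
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("distances must be positive and strictly increasing")
        from .exposure import MEASURES
        if not set(self.exposure.measures) <= set(MEASURES):
            raise ValueError("unknown intensity measure requested")
        self.strata = [tuple(s) for s in self.strata]
        # fan the root seed out to the stage streams
        self.city.seed = stage_seed(self.seed, "simulate.city")
        self.cohort.seed = stage_seed(self.seed, "simulate.cohort")
        self.epochs.seed = stage_seed(self.seed, "simulate.epochs")
        if self.exposure.blur is not None:
            self.exposure.blur.seed = stage_seed(self.seed, "exposure.blur")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, sub in (("city", CityConfig), ("cohort", CohortConfig),
                         ("epochs", EpochConfig)):
            if key in raw:
                kw[key] = sub(**raw.pop(key))
        if "exposure" in raw:
            exp = raw.pop("exposure")
            if "blur" in exp and exp["blur"] is not None:
                exp["blur"] = BlurSpec(**exp["blur"])
            kw["exposure"] = ExposureConfig(**exp)
        kw.update(raw)
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


STAGE_FILES = {
    "simulate": ["network.geojson", "density.asc", "cohort.csv", "truth.json",
                 "epochs.csv"],
    "intensity": ["bandwidths.json"],
    "exposure": ["exposures.csv", "exposure_summary.csv"],
    "mvpa": ["mvpa.csv", "day_summaries.csv"],
    "fit": ["basic_models.csv"],
    "report": ["pattern.csv"],
}

STAGE_INPUTS = {
    "simulate": [],
    "intensity": ["simulate"],
    "exposure": ["simulate", "intensity"],
    "mvpa": ["simulate"],
    "fit": ["mvpa"],
    "report": ["exposure", "fit"],
}


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = {"config_hash": config.config_hash(), "stages": {},
                         "warnings": 0}
        if self.manifest_path.exists():
            try:
                prev = json.loads(self.manifest_path.read_text())
                if prev.get("config_hash") == self.manifest["config_hash"]:
                    self.manifest["stages"] = prev.get("stages", {})
            except (json.JSONDecodeError, OSError):
                pass
        self._cache: dict = {}

    # --- manifest bookkeeping -------------------------------------------

    def _files(self, stage) -> list[Path]:
        names = list(STAGE_FILES[stage])
        if stage == "simulate":
            names += [f"layer_{k}.geojson" for k in self.config.layers]
        if stage == "intensity":
            for k in self.config.layers:
                for fam in ("fixed", "mse_cv", "lscv"):
                    names += [f"surface_{k}_{fam}.asc",
                              f"surface_{k}_{fam}.asc.json"]
        return [self.out / n for n in names]

    def _input_state(self, stage) -> dict:
        state = {}
        for dep in STAGE_INPUTS[stage]:
            rec = self.manifest["stages"].get(dep)
            if rec is None or rec.get("status") != "done":
                raise RuntimeError(f"stage {stage!r} requires {dep!r}")
            state[dep] = rec["outputs"]
        return state

    def _up_to_date(self, stage) -> bool:
        rec = self.manifest["stages"].get(stage)
        if rec is None or rec.get("status") != "done":
            return False
        try:
            if rec.get("inputs") != self._input_state(stage):
                return False
        except RuntimeError:
            return False
        for f in self._files(stage):
            if not f.exists() or _sha256(f) != rec["outputs"].get(f.name):
                return False
        return True

    def _finish(self, stage) -> None:
        outputs = {}
        for f in self._files(stage):
            if not f.exists():
                raise RuntimeError(f"stage {stage!r} did not produce {f.name}")
            outputs[f.name] = _sha256(f)
        self.manifest["stages"][stage] = {
            "status": "done", "inputs": self._input_state(stage),
            "outputs": outputs,
            "timestamp": pd.Timestamp.now().isoformat()}
        self._save_manifest()

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    # --- stages ---------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        network = generate_street_network(cfg.city)
        density = generate_density_raster(cfg.city)
        layers = {k: generate_point_layer(k, density, network, cfg.city)
                  for k in cfg.layers}
        # the generative truth exposure: the fixed-bandwidth open-space
        # kernel intensity at the (unblurred) home, centered at its window
        # mean so the exposure coefficient acts on deviations and the
        # intercept keeps its typical-child meaning
        truth_kind = "open_space" if "open_space" in layers else cfg.layers[-1]
        from .intensity import bw_fixed
        truth_surf = kernel_intensity_surface(
            layers[truth_kind], bw_fixed(500.0),
            cell_size_m=cfg.exposure.cell_size_m)
        surf_mean = float(np.nanmean(truth_surf.values))
        cohort, truth = generate_cohort(
            cfg.cohort, density,
            truth_exposure_fn=lambda x, y: truth_surf.value_at(x, y) - surf_mean)
        series = []
        for row in cohort.itertuples():
            series.append(generate_epoch_counts(
                row.child_id, row.mvpa_min_per_day, cfg.n_days, cfg.epochs))
        mio.write_network_geojson(network, self.out / "network.geojson")
        mio.write_density(density, self.out / "density.asc")
        for k, pat in layers.items():
            mio.write_points_geojson(pat, self.out / f"layer_{k}.geojson")
        cohort.to_csv(self.out / "cohort.csv", index=False)
        (self.out / "truth.json").write_text(json.dumps(_jsonable(
            {"true_beta": truth.true_beta, "gamma_shape": truth.gamma_shape,
             "exposure": truth.exposure, "seed": truth.seed,
             "linear_predictor": truth.linear_predictor})))
        mio.write_epochs_csv(series, self.out / "epochs.csv")
        self._cache.update(network=network, density=density, layers=layers,
                           cohort=cohort, series=series)

    def _load_simulate(self):
        c = self._cache
        if "network" not in c:
            c["network"] = mio.read_network_geojson(self.out / "network.geojson")
            c["density"] = mio.read_density(self.out / "density.asc")
            c["layers"] = {k: mio.read_points_geojson(
                self.out / f"layer_{k}.geojson") for k in self.config.layers}
            c["cohort"] = pd.read_csv(self.out / "cohort.csv")
        return c

    def stage_intensity(self) -> None:
        c = self._load_simulate()
        bws, surfs = {}, {}
        meta = {}
        for kind, pat in c["layers"].items():
            bws[kind], surfs[kind] = layer_surfaces(pat, self.config.exposure)
            for fam, surf in surfs[kind].items():
                mio.write_surface(surf, self.out / f"surface_{kind}_{fam}.asc")
            meta[kind] = {fam: mio._bw_to_json(bw)
                          for fam, bw in bws[kind].items()}
        (self.out / "bandwidths.json").write_text(json.dumps(meta))
        self._cache.update(bandwidths=bws, surfaces=surfs)

    def _load_intensity(self):
        c = self._cache
        if "surfaces" not in c:
            c["surfaces"], c["bandwidths"] = {}, {}
            for kind in self.config.layers:
                c["surfaces"][kind] = {}
                c["bandwidths"][kind] = {}
                for fam in ("fixed", "mse_cv", "lscv"):
                    s = mio.read_surface(self.out / f"surface_{kind}_{fam}.asc")
                    c["surfaces"][kind][fam] = s
                    c["bandwidths"][kind][fam] = s.bandwidth
        return c

    def stage_exposure(self) -> None:
        c = self._load_intensity()
        self._load_simulate()
        exposures = build_exposure_matrix(
            c["cohort"], c["layers"], c["network"], c["density"],
            config=self.config.exposure, surfaces=c["surfaces"],
            bandwidths=c["bandwidths"])
        exposures.to_csv(self.out / "exposures.csv", index=False)
        exposure_summary(exposures).to_csv(
            self.out / "exposure_summary.csv", index=False)
        self._cache["exposures"] = exposures

    def stage_mvpa(self) -> None:
        c = self._cache
        series = c.get("series")
        if series is None:
            series = mio.read_epochs_csv(self.out / "epochs.csv")
        days_all, outcomes = [], []
        for s in series:
            days, hab = process_series(s)
            days["child_id"] = s.child_id
            days_all.append(days)
            outcomes.append(hab.__dict__)
        pd.concat(days_all).to_csv(self.out / "day_summaries.csv", index=False)
        pd.DataFrame(outcomes).to_csv(self.out / "mvpa.csv", index=False)

    def _analysis_cohort(self) -> pd.DataFrame:
        c = self._load_simulate()
        mvpa = pd.read_csv(self.out / "mvpa.csv")
        df = c["cohort"].drop(columns=["mvpa_min_per_day"]).merge(
            mvpa[["child_id", "mvpa_min_per_day", "included",
                  "mean_valid_weartime_h"]], on="child_id")
        df = df[df["included"]]
        df["valid_weartime_h"] = df["mean_valid_weartime_h"]
        return df

    def stage_fit(self) -> None:
        df = self._analysis_cohort()
        fits = fit_basic_models(df, strata=self.config.strata)
        basic_models_table(fits).to_csv(self.out / "basic_models.csv",
                                        index=False)

    def stage_report(self) -> None:
        df = self._analysis_cohort()
        exposures = self._cache.get("exposures")
        if exposures is None:
            exposures = pd.read_csv(self.out / "exposures.csv")
        pattern = run_pattern_analysis(df, exposures,
                                       strata=self.config.strata)
        pattern.to_csv(self.out / "pattern.csv", index=False)
        for kind in self.config.layers:
            for stratum in self.config.strata:
                if stratum[1] == "all":
                    pattern_plot(pattern, kind, stratum,
                                 self.out / f"pattern_{kind}_{stratum[0]}.png")

    def run(self, stages: list | None = None) -> dict:
        logging.basicConfig(level=self.config.log_level)
        for stage in (stages or STAGES):
            if self._up_to_date(stage):
                logger.info("stage %s up to date, skipped", stage)
                continue
            logger.info("running stage %s", stage)
            self._input_state(stage)   # raises if dependencies missing
            getattr(self, f"stage_{stage}")()
            self._finish(stage)
            # downstream stages must read the written files, not in-memory
            # objects, so a resumed run is byte-identical to a fresh one
            self._cache.clear()
        return self.manifest


def run_pipeline(config: PipelineConfig, stages: list | None = None) -> dict:
    """Execute the configured pipeline and return the run manifest."""
    return Pipeline(config).run(stages)


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict) -> list[dict]:
    """Schema checks for the pipeline's file inputs.

    ``paths`` maps role → path for any of: cohort (CSV), epochs (CSV),
    points (GeoJSON), network (GeoJSON), density (ASCII grid). Returns a
    list of violations, each with a role, identifier and message; an empty
    list means the bundle is well-formed.
    """
    violations = []

    def bad(role, ident, msg):
        violations.append({"role": role, "id": ident, "message": msg})

    if "cohort" in paths:
        df = pd.read_csv(paths["cohort"])
        required = {"child_id", "home_x", "home_y", "age_years", "sex",
                    "bmi_z", "isced", "safety_concerns", "season"}
        for col in sorted(required - set(df.columns)):
            bad("cohort", col, "missing required column")
    if "epochs" in paths:
        df = pd.read_csv(paths["epochs"], parse_dates=["timestamp"])
        for cid, g in df.groupby("child_id"):
            dt = g["timestamp"].diff().dropna().dt.total_seconds()
            steps = dt[(dt != 15.0)]
            for i in steps.index[:5]:
                bad("epochs", f"{cid}@row{i}",
                    f"timestamp gap {steps[i]:.0f} s != 15 s")
            if (g["counts"] < 0).any():
                bad("epochs", str(cid), "negative counts")
    if "points" in paths:
        obj = json.loads(Path(paths["points"]).read_text())
        coords = []
        for i, f in enumerate(obj.get("features", [])):
            t = f["geometry"]["type"]
            if t != "Point":
                bad("points", f"feature {i}", f"geometry type {t}, expected Point")
            else:
                coords.append(f["geometry"]["coordinates"][:2])
        if coords and all(abs(x) <= 180 and abs(y) <= 90 for x, y in coords):
            bad("points", "layer", "coordinates look geographic (lon/lat)")
    if "network" in paths:
        obj = json.loads(Path(paths["network"]).read_text())
        for i, f in enumerate(obj.get("features", [])):
            t = f["geometry"]["type"]
            if t != "LineString":
                bad("network", f"feature {i}",
                    f"geometry type {t}, expected LineString")
    if "density" in paths:
        values, _, cell = mio.read_ascii_grid(paths["density"])
        if cell <= 0:
            bad("density", "cellsize", "non-positive cell size")
        if np.nanmin(values) < 0:
            bad("density", "values", "negative density")
    return violations
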