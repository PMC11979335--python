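"""End-to-end pipeline: simulate -> fc -> metrics -> compare -> nbs -> classify -> report.

Every stage writes plain-text artifacts (CSV/TSV/JSON; the subjects x edges
stack additionally as ``.npy``) into a stage subdirectory of the output
directory, and a manifest records the configuration hash, master seed and
package version, so two runs with identical (config, seed, version) produce
byte-identical outputs.  Stages can be run individually (each reloads its
inputs from the previous stage's artifacts) or composed with
:func:`run_pipeline`.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import child_seed
from .brainnet import export_brainnet
from .classify import ClassifierConfig, NBSPredict, contribution_map
from .cohort import (
    PATIENT,
    BlockStructure,
    CohortSpec,
    PlantedEffect,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .connectome import (
    DensityGrid,
    DensityRangeError,
    compute_fc,
    stack_fc,
    validate_density_range,
)
from .inference import (
    DEFAULT_COVARIATES,
    build_design,
    compare_global_aucs,
    compare_nodal_aucs,
    demographics_table,
)
from .metrics import GLOBAL_METRICS, auc_table, compute_metric_curves
from .nbs import NetworkBasedStatistic

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fc", "metrics", "compare", "nbs", "classify", "report")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run (YAML-serializable).

    Defaults follow the reference analysis: density grid 0.10-0.50 step 0.02,
    100 degree-preserving null networks, NBS t0 = 3.5 with 10,000
    permutations at alpha = 0.05, FDR q < 0.05 for nodal metrics.
    """

    output_dir: str = "fcnet_output"
    timeseries_dir: str | None = None
    phenotype_file: str | None = None
    coords_file: str | None = None
    simulate: dict | None = None
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    include_medication: bool = True
    d_min: float = 0.10
    d_max: float = 0.50
    d_step: float = 0.02
    n_random: int = 100
    swaps_per_edge: int = 10
    strict_density_range: bool = False
    nbs_t0: float = 3.5
    nbs_n_perm: int = 10_000
    nbs_alpha: float = 0.05
    nbs_scheme: str = "freedman-lane"
    fdr_q: float = 0.05
    classifier: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs are written and
        how verbosely is not part of the analysis identity)."""
        d = {k: v for k, v in self.to_dict().items() if k not in ("output_dir", "log_level")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def grid(self) -> DensityGrid:
        return DensityGrid(d_min=self.d_min, d_max=self.d_max, step=self.d_step)

    def classifier_config(self) -> ClassifierConfig:
        kw = dict(self.classifier)
        if "c_grid" in kw:
            kw["c_grid"] = tuple(kw["c_grid"])
        kw.setdefault("seed", child_seed(self.seed, 4))
        return ClassifierConfig(**kw)

    def cohort_spec(self) -> CohortSpec:
        if self.simulate is None:
            raise ValueError("no 'simulate' section in the configuration")
        sim = dict(self.simulate)
        effect = sim.pop("effect", None)
        structure = {
            k: sim.pop(k) for k in ("n_modules", "within_r", "between_r") if k in sim
        }
        kw: dict = {}
        if effect:
            kw["effect"] = PlantedEffect(
                edges=tuple(tuple(e) for e in effect["edges"]),
                delta=float(effect.get("delta", 0.0)),
                direction=effect.get("direction", "reduce"),
            )
        if structure:
            kw["base_structure"] = BlockStructure(**structure)
        sim.setdefault("seed", child_seed(self.seed, 0))
        return CohortSpec(**sim, **kw)

    def validate(self) -> None:
        if self.simulate is None:
            if self.timeseries_dir is None or self.phenotype_file is None:
                raise ValueError(
                    "configuration needs either a 'simulate' section or both "
                    "'timeseries_dir' and 'phenotype_file'"
                )
            for p in (self.timeseries_dir, self.phenotype_file):
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
            header = pd.read_csv(self.phenotype_file, nrows=0).columns
            missing = [c for c in _REQUIRED_PHENO + tuple(self.covariates) if c not in header]
            if missing:
                raise ValueError(
                    f"phenotype table lacks required column(s): {missing}"
                )
        if self.coords_file is not None and not Path(self.coords_file).exists():
            raise ValueError(f"coordinates file does not exist: {self.coords_file}")
        self.grid  # raises on an invalid grid
        if self.nbs_scheme not in ("freedman-lane", "labels"):
            raise ValueError(f"unknown NBS permutation scheme {self.nbs_scheme!r}")


_REQUIRED_PHENO = ("subject_id", "group")


class Pipeline:
    """Stage-wise execution with on-disk hand-off between stages."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
        self._write_manifest()

    # ---------- infrastructure ----------

    def _write_manifest(self) -> None:
        manifest = {
            "config": self.cfg.to_dict(),
            "config_hash": self.cfg.config_hash(),
            "seed": self.cfg.seed,
            "version": __version__,
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _write_json(self, path: Path, obj: dict) -> None:
        obj = dict(obj)
        obj["_provenance"] = {
            "config_hash": self.cfg.config_hash(),
            "seed": self.cfg.seed,
            "version": __version__,
        }
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")

    # ---------- inputs ----------

    def _load_phenotype(self) -> pd.DataFrame:
        if self.cfg.simulate is not None:
            path = self.out / "simulate" / "phenotype.csv"
        else:
            path = Path(self.cfg.phenotype_file)
        pheno = pd.read_csv(path)
        missing = [c for c in _REQUIRED_PHENO + tuple(self.cfg.covariates) if c not in pheno.columns]
        if missing:
            raise ValueError(f"phenotype table lacks required column(s): {missing}")
        return pheno

    def _load_timeseries(self):
        if self.cfg.simulate is not None:
            base = self.out / "simulate"
        else:
            # accept either a cohort directory or a flat layout
            ts_dir = Path(self.cfg.timeseries_dir)
            base = ts_dir.parent if ts_dir.name == "timeseries" else ts_dir
        if not (base / "phenotype.csv").exists():
            # flat layout: copy phenotype reference
            pheno = pd.read_csv(self.cfg.phenotype_file)
            from .cohort import TimeSeriesData

            series = []
            for sid in pheno["subject_id"]:
                p = Path(self.cfg.timeseries_dir) / f"{sid}.tsv"
                if not p.exists():
                    raise ValueError(f"time series for subject {sid!r} missing at {p}")
                df = pd.read_csv(p, sep="\t")
                series.append(
                    TimeSeriesData(subject_id=sid, data=df.to_numpy(), region_labels=list(df.columns))
                )
            return pheno, series
        return read_cohort(base)

    # ---------- stages ----------

    def stage_simulate(self) -> None:
        if self.cfg.simulate is None:
            logger.info("no simulate section; skipping simulation stage")
            return
        spec = self.cfg.cohort_spec()
        records, series = generate_cohort(spec)
        write_cohort(records, series, self._stage_dir("simulate"), spec=spec)

    def stage_fc(self) -> None:
        pheno, series = self._load_timeseries()
        ids = set(pheno["subject_id"])
        got = {ts.subject_id for ts in series}
        if ids != got:
            raise ValueError(
                f"subject IDs mismatch between phenotype and time series: "
                f"only in phenotype {sorted(ids - got)}, only in time series {sorted(got - ids)}"
            )
        fcs = [compute_fc(ts) for ts in series]
        d = self._stage_dir("fc")
        stack, eidx = stack_fc(fcs)
        np.save(d / "fc_stack.npy", stack)
        eidx.to_csv(d / "edge_index.csv", index=False)
        for fc in fcs:
            pd.DataFrame(fc.values, columns=fc.region_labels).to_csv(
                d / f"{fc.subject_id}_fc.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
        (d / "subjects.txt").write_text("\n".join(fc.subject_id for fc in fcs) + "\n")

    def _load_fc(self):
        d = self.out / "fc"
        stack = np.load(d / "fc_stack.npy")
        eidx = pd.read_csv(d / "edge_index.csv")
        subjects = (d / "subjects.txt").read_text().split()
        return stack, eidx, subjects

    def stage_metrics(self) -> None:
        d = self.out / "fc"
        subjects = (d / "subjects.txt").read_text().split()
        fcs = []
        from .connectome import FCMatrix

        for sid in subjects:
            df = pd.read_csv(d / f"{sid}_fc.tsv", sep="\t")
            vals = df.to_numpy()
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0.0)
            fcs.append(FCMatrix(subject_id=sid, values=vals, region_labels=list(df.columns)))
        grid = self.cfg.grid
        gdf, ndf = compute_metric_curves(
            fcs,
            grid,
            n_random=self.cfg.n_random,
            seed=child_seed(self.cfg.seed, 2),
            swaps_per_edge=self.cfg.swaps_per_edge,
        )
        md = self._stage_dir("metrics")
        gdf.to_csv(md / "global_curves.csv", index=False, float_format=_FLOAT_FMT)
        ndf.to_csv(md / "nodal_curves.csv", index=False, float_format=_FLOAT_FMT)

        sigma = (
            gdf[gdf["metric"] == "sigma"]
            .pivot(index="subject_id", columns="density", values="value")
            .loc[subjects]
            .to_numpy()
        )
        try:
            admissible, diag = validate_density_range(sigma, grid, n_nodes=len(fcs[0].region_labels))
        except DensityRangeError as err:
            if self.cfg.strict_density_range:
                raise
            logger.warning("density-range validation failed (%s); using the full grid", err)
            admissible, diag = grid.values, err.diagnostics
        diag.to_csv(md / "density_diagnostics.csv", index=False, float_format=_FLOAT_FMT)
        np.savetxt(md / "admissible_densities.txt", admissible, fmt=_FLOAT_FMT)

        g_auc = auc_table(gdf, admissible)
        n_auc = auc_table(ndf, admissible)
        g_auc.to_csv(md / "global_auc.csv", index=False, float_format=_FLOAT_FMT)
        n_auc.to_csv(md / "nodal_auc.csv", index=False, float_format=_FLOAT_FMT)

    def stage_compare(self) -> None:
        pheno = self._load_phenotype()
        md = self.out / "metrics"
        g_auc = pd.read_csv(md / "global_auc.csv")
        n_auc = pd.read_csv(md / "nodal_auc.csv")
        design = build_design(pheno, self.cfg.covariates, self.cfg.include_medication)
        cd = self._stage_dir("compare")
        demographics_table(pheno).to_csv(cd / "demographics.csv", index=False, float_format=_FLOAT_FMT)
        design.to_csv(cd / "design_matrix.csv", index=False, float_format=_FLOAT_FMT)
        glob = compare_global_aucs(g_auc, pheno, design, metrics=GLOBAL_METRICS)
        glob.to_csv(cd / "global_comparison.csv", index=False, float_format=_FLOAT_FMT)
        nodal = compare_nodal_aucs(n_auc, pheno, design, q=self.cfg.fdr_q)
        nodal.to_csv(cd / "nodal_comparison.csv", index=False, float_format=_FLOAT_FMT)
        self._write_json(
            cd / "compare_summary.json",
            {
                "design_columns": list(design.columns),
                "significant_global": glob.loc[glob["p"] < 0.05, "metric"].tolist(),
                "n_significant_nodal": int(nodal["significant"].sum()),
            },
        )

    def stage_nbs(self) -> None:
        pheno = self._load_phenotype()
        stack, eidx, subjects = self._load_fc()
        if list(pheno["subject_id"]) != subjects:
            pheno = pheno.set_index("subject_id").loc[subjects].reset_index()
        design = build_design(pheno, self.cfg.covariates, self.cfg.include_medication)
        pairs = eidx[["i", "j"]].to_numpy()
        labels = self._region_labels(eidx)
        nd = self._stage_dir("nbs")
        summary: dict = {}
        for contrast in ("patient_lt_control", "patient_gt_control"):
            model = NetworkBasedStatistic(stack, design, pairs)
            res = model.fit(
                t0=self.cfg.nbs_t0,
                n_perm=self.cfg.nbs_n_perm,
                seed=child_seed(self.cfg.seed, 3),
                contrast=contrast,
                scheme=self.cfg.nbs_scheme,
            )
            res.component_table(labels).to_csv(
                nd / f"components_{contrast}.csv", index=False, float_format=_FLOAT_FMT
            )
            np.savetxt(nd / f"null_max_extents_{contrast}.txt", res.null_max_extents, fmt="%g")
            summary[contrast] = [
                {"extent": c.extent, "n_nodes": len(c.nodes), "fwer_p": c.fwer_p}
                for c in res.components
            ]
            sig = res.significant_components(self.cfg.nbs_alpha)
            if sig and self.cfg.coords_file:
                coords = pd.read_csv(self.cfg.coords_file)
                pair_pos = {tuple(p): k for k, p in enumerate(pairs.tolist())}
                weights = {
                    e: float(res.edge_stats[pair_pos[e]]) for c in sig for e in c.edges
                }
                export_brainnet(sig, coords, labels, nd / f"subnetwork_{contrast}", weights)
        self._write_json(nd / "nbs_summary.json", summary)

    def _region_labels(self, eidx: pd.DataFrame) -> list[str]:
        n = int(eidx["j"].max()) + 1
        labels = [None] * n
        for _, row in eidx.iterrows():
            labels[int(row["i"])] = row["region_i"]
            labels[int(row["j"])] = row["region_j"]
        return [l if l is not None else f"ROI{k + 1:03d}" for k, l in enumerate(labels)]

    def stage_classify(self) -> None:
        pheno = self._load_phenotype()
        stack, eidx, subjects = self._load_fc()
        if list(pheno["subject_id"]) != subjects:
            pheno = pheno.set_index("subject_id").loc[subjects].reset_index()
        y = (pheno["group"] == PATIENT).astype(int).to_numpy()
        pairs = eidx[["i", "j"]].to_numpy()
        model = NBSPredict(stack, y, pairs, config=self.cfg.classifier_config())
        res = model.fit()
        cd = self._stage_dir("classify")
        res.fold_metrics.to_csv(cd / "fold_metrics.csv", index=False, float_format=_FLOAT_FMT)
        contribution_map(res, eidx).to_csv(cd / "contribution_map.csv", index=False, float_format=_FLOAT_FMT)
        self._write_json(
            cd / "classification_summary.json",
            {
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            },
        )

    def stage_report(self) -> None:
        report: dict = {"stages": {}}
        for stage, fname in [
            ("compare", "compare_summary.json"),
            ("nbs", "nbs_summary.json"),
            ("classify", "classification_summary.json"),
        ]:
            p = self.out / stage / fname
            if p.exists():
                data = json.loads(p.read_text())
                data.pop("_provenance", None)
                report["stages"][stage] = data
        self._write_json(self.out / "report.json", report)

    def run(self, stages: tuple[str, ...] = STAGES) -> Path:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")
            logger.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        return self.out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the configured stages in order; returns the output directory."""
    return Pipeline(config).run(stages)
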