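"""Synthetic two-group resting-state cohort generation.

Real multi-subject ROI time-series datasets of the kind analysed here (two
clinical groups, ~116 atlas regions, ~150 retained volumes at TR = 2 s) are
rarely public, so every downstream stage of the package is exercised on a
synthetic cohort with a known ground truth:

* per-group spatial correlation structure: a block-community ("module")
  correlation matrix, with higher within- than between-module correlation,
  standing in for resting-state network structure;
* a *planted effect*: a listed subnetwork of region pairs whose correlations
  are reduced (or increased) by ``delta`` in the patient group only, giving a
  recoverable target for the network-based statistic;
* temporal structure: stationary Gaussian AR(1) — the simplest model under
  which the Pearson correlation is the natural estimand, with the AR
  coefficient emulating the autocorrelation a band-pass filter leaves in the
  signal (filtering itself is upstream preprocessing, out of scope here);
* clinical covariates drawn per group from distributions matched to published
  demographic summary tables (normal for symmetric variables, log-normal
  matched to median/quartiles for skewed scores), independent of the time
  series unless the caller couples them.

All randomness flows through ``CohortSpec.seed``; each subject uses a derived
sub-seed, so cohorts are reproducible and subjects independent.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_seed, nearest_spd_correlation, rng_from

__all__ = [
    "PATIENT",
    "CONTROL",
    "PlantedEffect",
    "BlockStructure",
    "CohortSpec",
    "SubjectRecord",
    "TimeSeriesData",
    "tree_subnetwork",
    "default_planted_effect",
    "default_covariate_model",
    "build_group_covariance",
    "generate_timeseries",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "records_to_frame",
]

PATIENT = "patient"
CONTROL = "control"

#: z-score of the third quartile of a standard normal; converts an
#: inter-quartile range to the sigma of a matched (log-)normal.
_Q3_Z = 0.6744897501960817


@dataclass(frozen=True)
class PlantedEffect:
    """A subnetwork of region pairs whose patient-group correlation is shifted.

    Parameters
    ----------
    edges : tuple of (i, j)
        Region-index pairs (0-based) forming the affected subnetwork.
    delta : float
        Correlation-scale shift (>= 0) applied in the patient group.
    direction : {"reduce", "increase"}
        Whether patient correlations on the planted edges are lowered or raised.
    """

    edges: tuple[tuple[int, int], ...]
    delta: float
    direction: str = "reduce"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.direction not in ("reduce", "increase"):
            raise ValueError(f"direction must be 'reduce' or 'increase', got {self.direction!r}")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"planted edge ({i},{j}) is a self-pair")
            if i < 0 or j < 0:
                raise ValueError(f"planted edge ({i},{j}) has a negative region index")
        object.__setattr__(self, "edges", tuple((min(i, j), max(i, j)) for i, j in self.edges))


@dataclass(frozen=True)
class BlockStructure:
    """Block-community spatial correlation structure.

    ``n_modules`` contiguous blocks of regions; correlation is ``within_r``
    inside a block and ``between_r`` across blocks (unit diagonal).
    """

    n_modules: int = 4
    within_r: float = 0.4
    between_r: float = 0.1

    def __post_init__(self) -> None:
        if not (self.within_r > self.between_r):
            raise ValueError(
                f"within-community correlation ({self.within_r}) must exceed "
                f"between-community correlation ({self.between_r})"
            )
        if not (-1 < self.between_r and self.within_r < 1):
            raise ValueError("correlation levels must lie in (-1, 1)")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


def tree_subnetwork(nodes: list[int] | tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    """A two-hub tree on the given nodes (|nodes| - 1 edges).

    The first two nodes act as hubs: each remaining node attaches to one of
    them, and the hubs are joined — mirroring the hub-centred, tree-shaped
    subnetworks that NBS analyses typically report (k nodes, k-1 edges).
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes for a subnetwork")
    h1, h2 = nodes[0], nodes[1]
    rest = nodes[2:]
    half = (len(rest) + 1) // 2
    edges = [(h1, h2)]
    edges += [(h1, n) for n in rest[:half]]
    edges += [(h2, n) for n in rest[half:]]
    return tuple(edges)


def default_planted_effect(n_regions: int, delta: float = 0.3) -> PlantedEffect:
    """An 11-edge, 12-node reduced-connectivity tree spread across the atlas."""
    if n_regions < 12:
        raise ValueError("default planted effect needs >= 12 regions")
    nodes = np.linspace(0, n_regions - 1, 12).astype(int).tolist()
    if len(set(nodes)) < 12:  # pragma: no cover - guarded by n_regions >= 12
        nodes = list(range(12))
    return PlantedEffect(edges=tree_subnetwork(nodes), delta=delta, direction="reduce")


def default_covariate_model() -> dict:
    """Per-group covariate sampling models.

    Defaults target the demographic and clinical summary statistics of a
    127-patient / 102-control lupus cohort: symmetric variables are normal
    (mean, SD as printed), skewed scores log-normal matched to the printed
    median and quartiles, categorical treatment frequencies as printed.
    Mean framewise displacement is not tabulated in such summaries; a
    log-normal around 0.08 mm (typical for motion-screened resting-state
    data) is used for both groups.
    """
    return {
        PATIENT: {
            "age": {"kind": "normal", "mean": 29.84, "sd": 7.00, "low": 18.0},
            "sex": {"kind": "categorical", "levels": ["female", "male"], "p": [103 / 127, 24 / 127]},
            "education_years": {"kind": "lognormal", "median": 12.0, "q1": 9.0, "q3": 15.0, "integer": True},
            "mmse": {"kind": "capped_deficit", "cap": 30, "p_zero": 0.05, "median": 2.0, "q1": 1.0, "q3": 5.0, "integer": True},
            "hama": {"kind": "lognormal", "median": 7.0, "q1": 4.0, "q3": 11.0, "integer": True},
            "hamd": {"kind": "lognormal", "median": 8.0, "q1": 5.0, "q3": 13.0, "integer": True},
            "sledai": {"kind": "lognormal", "median": 10.0, "q1": 6.0, "q3": 14.0, "integer": True},
            "tiv": {"kind": "normal", "mean": 1400.98, "sd": 113.49, "low": 1.0},
            "gmv": {"kind": "normal", "mean": 628.22, "sd": 52.79, "low": 1.0},
            "wmv": {"kind": "normal", "mean": 473.64, "sd": 47.61, "low": 1.0},
            "mean_fd": {"kind": "lognormal", "median": 0.08, "q1": 0.06, "q3": 0.11},
            "medication": {
                "kind": "categorical",
                "levels": ["drug_naive", "gcs_alone", "gcs_hcq", "gcs_isa"],
                "p": [24 / 127, 22 / 127, 40 / 127, 41 / 127],
            },
        },
        CONTROL: {
            "age": {"kind": "normal", "mean": 30.63, "sd": 7.24, "low": 18.0},
            "sex": {"kind": "categorical", "levels": ["female", "male"], "p": [76 / 102, 26 / 102]},
            "education_years": {"kind": "lognormal", "median": 15.0, "q1": 12.0, "q3": 16.0, "integer": True},
            "mmse": {"kind": "capped_deficit", "cap": 30, "p_zero": 0.75, "median": 1.0, "q1": 0.5, "q3": 1.5, "integer": True},
            "hama": {"kind": "capped_deficit", "cap": 0, "p_zero": 0.75, "median": 0.25, "q1": 0.12, "q3": 0.5, "integer": True, "negate": True},
            "hamd": {"kind": "capped_deficit", "cap": 0, "p_zero": 0.9, "median": 0.25, "q1": 0.12, "q3": 0.5, "integer": True, "negate": True},
            "sledai": {"kind": "absent"},
            # control TIV/WMV are tabulated as median (IQR); matched normal with sd = IQR/1.349
            "tiv": {"kind": "normal", "mean": 1401.77, "sd": (1468.89 - 1347.13) / (2 * _Q3_Z), "low": 1.0},
            "gmv": {"kind": "normal", "mean": 652.47, "sd": 52.03, "low": 1.0},
            "wmv": {"kind": "normal", "mean": 489.00, "sd": (513.41 - 452.27) / (2 * _Q3_Z), "low": 1.0},
            "mean_fd": {"kind": "lognormal", "median": 0.08, "q1": 0.06, "q3": 0.11},
            "medication": {"kind": "constant", "value": "none"},
        },
    }


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group cohort.

    ``n_group1`` is the patient group (the planted effect applies there);
    ``n_group2`` the control group.
    """

    n_group1: int
    n_group2: int
    n_regions: int = 116
    n_timepoints: int = 150  # 160 acquired volumes minus 10 discarded
    tr_seconds: float = 2.0
    ar1_coefficient: float = 0.4
    base_structure: BlockStructure = field(default_factory=BlockStructure)
    effect: PlantedEffect | None = None
    covariate_model: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError(f"n_regions must be >= 3, got {self.n_regions}")
        if self.n_timepoints < 20:
            raise ValueError(f"n_timepoints must be >= 20, got {self.n_timepoints}")
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError(f"ar1_coefficient must lie in [0, 1), got {self.ar1_coefficient}")
        if self.effect is not None:
            bad = [e for e in self.effect.edges if e[1] >= self.n_regions]
            if bad:
                raise ValueError(f"planted edges reference regions outside the atlas: {bad}")

    @property
    def region_labels(self) -> list[str]:
        return [f"ROI{i + 1:03d}" for i in range(self.n_regions)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.effect is not None:
            d["effect"]["edges"] = [list(e) for e in self.effect.edges]
        return d


@dataclass
class SubjectRecord:
    """One participant's group label and clinical covariates."""

    subject_id: str
    group: str
    age: float
    sex: str
    education_years: float
    mmse: float
    hama: float
    hamd: float
    sledai: float | None
    gmv: float
    wmv: float
    tiv: float
    mean_fd: float
    medication: str

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}', got {self.group!r}")
        if self.group == CONTROL:
            if self.medication != "none":
                raise ValueError("controls must have medication='none'")
            if self.sledai is not None and not np.isnan(self.sledai):
                raise ValueError("controls have no disease-activity (sledai) score")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be >= 0")
        for name in ("gmv", "wmv", "tiv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class TimeSeriesData:
    """One subject's ROI time series (T timepoints x N regions)."""

    subject_id: str
    data: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (T x N)")
        if self.data.shape[1] != len(self.region_labels):
            raise ValueError("number of region labels must match the number of columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"time series for {self.subject_id} contains non-finite values")


def build_group_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """The generating spatial correlation matrix for one group.

    Starts from the block-community base matrix; for the patient group the
    planted edges are shifted by -delta (direction 'reduce') or +delta,
    clipped to (-1, 1), and the result is projected to the nearest SPD
    correlation matrix if the shift breaks positive definiteness.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    n = spec.n_regions
    bs = spec.base_structure
    block = np.array_split(np.arange(n), bs.n_modules)
    cov = np.full((n, n), bs.between_r, dtype=float)
    for idx in block:
        cov[np.ix_(idx, idx)] = bs.within_r
    np.fill_diagonal(cov, 1.0)
    if group == PATIENT and spec.effect is not None and spec.effect.delta > 0:
        shift = -spec.effect.delta if spec.effect.direction == "reduce" else spec.effect.delta
        for i, j in spec.effect.edges:
            val = np.clip(cov[i, j] + shift, -0.999, 0.999)
            cov[i, j] = cov[j, i] = val
    if np.linalg.eigvalsh(cov)[0] <= 0:
        cov = nearest_spd_correlation(cov)
    return cov


def generate_timeseries(
    cov: np.ndarray, spec: CohortSpec, subject_seed: int, subject_id: str = "sub-0000"
) -> TimeSeriesData:
    """Draw one subject's T x N series: Gaussian, spatial covariance ``cov``,
    AR(1) temporal autocorrelation ``spec.ar1_coefficient``.

    The innovation scaling sqrt(1 - phi^2) keeps the stationary marginal
    covariance equal to ``cov`` for every phi.
    """
    if spec.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if n < 3:
        raise ValueError("network analysis needs at least 3 regions")
    chol = np.linalg.cholesky(cov)
    rng = rng_from(subject_seed)
    innov = rng.standard_normal((spec.n_timepoints, n)) @ chol.T
    phi = spec.ar1_coefficient
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, spec.n_timepoints):
        x[t] = phi * x[t - 1] + scale * innov[t]
    labels = [f"ROI{i + 1:03d}" for i in range(n)]
    return TimeSeriesData(subject_id=subject_id, data=x, region_labels=labels)


def _sample_covariate(model: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = model["kind"]
    if kind == "absent":
        return np.full(size, np.nan)
    if kind == "constant":
        return np.full(size, model["value"], dtype=object)
    if kind == "categorical":
        return rng.choice(model["levels"], size=size, p=model["p"])
    if kind == "normal":
        vals = rng.normal(model["mean"], model["sd"], size)
    elif kind == "lognormal":
        mu = np.log(model["median"])
        sigma = (np.log(model["q3"]) - np.log(model["q1"])) / (2 * _Q3_Z)
        vals = rng.lognormal(mu, sigma, size)
    elif kind == "capped_deficit":
        # score = cap - deficit, deficit zero-inflated log-normal (ceiling-effect scales)
        mu = np.log(model["median"])
        sigma = (np.log(model["q3"]) - np.log(model["q1"])) / (2 * _Q3_Z)
        deficit = rng.lognormal(mu, sigma, size)
        deficit[rng.random(size) < model["p_zero"]] = 0.0
        vals = model["cap"] - deficit
        if model.get("negate"):
            vals = -vals  # cap 0, score = deficit itself (floor-effect scales)
        vals = np.clip(vals, 0.0, None)
    else:
        raise ValueError(f"unknown covariate model kind {kind!r}")
    if "low" in model:
        vals = np.clip(vals, model["low"], None)
    if model.get("integer"):
        vals = np.round(vals)
    return vals


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[TimeSeriesData]]:
    """Generate the full cohort: patient group first, then controls.

    Subject i uses seed ``child_seed(spec.seed, i)`` for its time series, so
    the cohort is reproducible and per-subject draws independent.
    """
    if spec.n_group1 < 2 or spec.n_group2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    cov_model = spec.covariate_model or default_covariate_model()
    covs = {PATIENT: build_group_covariance(spec, PATIENT), CONTROL: build_group_covariance(spec, CONTROL)}
    groups = [PATIENT] * spec.n_group1 + [CONTROL] * spec.n_group2

    # covariates are sampled per group as blocks from a dedicated sub-stream
    cov_samples: dict[str, dict[str, np.ndarray]] = {}
    for gi, (grp, n_grp) in enumerate([(PATIENT, spec.n_group1), (CONTROL, spec.n_group2)]):
        rng = rng_from(spec.seed, 1_000_000 + gi)
        cov_samples[grp] = {
            name: _sample_covariate(model, n_grp, rng) for name, model in cov_model[grp].items()
        }

    records: list[SubjectRecord] = []
    series: list[TimeSeriesData] = []
    group_pos = {PATIENT: 0, CONTROL: 0}
    for i, grp in enumerate(groups):
        sid = f"sub-{i + 1:04d}"
        ts = generate_timeseries(covs[grp], spec, child_seed(spec.seed, i), subject_id=sid)
        series.append(ts)
        k = group_pos[grp]
        group_pos[grp] += 1
        c = cov_samples[grp]
        sledai = float(c["sledai"][k]) if grp == PATIENT else None
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=grp,
                age=float(c["age"][k]),
                sex=str(c["sex"][k]),
                education_years=float(c["education_years"][k]),
                mmse=float(c["mmse"][k]),
                hama=float(c["hama"][k]),
                hamd=float(c["hamd"][k]),
                sledai=sledai,
                gmv=float(c["gmv"][k]),
                wmv=float(c["wmv"][k]),
                tiv=float(c["tiv"][k]),
                mean_fd=float(c["mean_fd"][k]),
                medication=str(c["medication"][k]),
            )
        )
    return records, series


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Phenotype table, one row per subject, columns = SubjectRecord fields."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_cohort(
    records: list[SubjectRecord],
    series: list[TimeSeriesData],
    outdir: str | Path,
    spec: CohortSpec | None = None,
) -> Path:
    """Write one TSV per subject, a phenotype CSV, and a manifest JSON."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts in series:
        df = pd.DataFrame(ts.data, columns=ts.region_labels)
        df.to_csv(ts_dir / f"{ts.subject_id}.tsv", sep="\t", index=False, float_format="%.10g")
    records_to_frame(records).to_csv(outdir / "phenotype.csv", index=False, float_format="%.10g")
    manifest = {"n_subjects": len(records)}
    if spec is not None:
        manifest["spec"] = spec.to_dict()
        manifest["seed"] = spec.seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, list[TimeSeriesData]]:
    """Read a cohort written by :func:`write_cohort` (or any matching layout)."""
    indir = Path(indir)
    pheno = pd.read_csv(indir / "phenotype.csv")
    series = []
    for sid in pheno["subject_id"]:
        path = indir / "timeseries" / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"time series for subject {sid!r} not found at {path}")
        df = pd.read_csv(path, sep="\t")
        series.append(TimeSeriesData(subject_id=sid, data=df.to_numpy(), region_labels=list(df.columns)))
    return pheno, series
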