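"""End-to-end orchestration: segment, measure, stratify, screen.

A run is described by a :class:`RunConfig` holding either real input paths
(slice manifest + cohort CSV, optionally expression TSV + GMT) or a
synthetic specification; demo mode generates a fully synthetic cohort,
runs every stage and writes diffable CSV outputs plus KM plots and a JSON
report with a provenance block (config hash, seed, versions).

One master seed drives all stochastic stages through per-stage derived
streams, so a run is bit-reproducible from its provenance block. Patients
or slices that fail a stage (e.g. empty necrosis after segmentation) are
logged, recorded in the report and skipped — never silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from necrofract import io as nfio  # noqa: E402
from necrofract.errors import (  # noqa: E402
    DegeneratePhantomError,
    EmptyRegionError,
    NecrofractError,
    ParameterError,
)
from necrofract.fractal import ScanProtocol, patient_features, slice_features  # noqa: E402
from necrofract.gene_screen import correlate_features, enrich, pearson_screen  # noqa: E402
from necrofract.segmentation import auto_seed, segment_necrosis  # noqa: E402
from necrofract.survival import (  # noqa: E402
    dichotomize_cohort,
    km_estimate,
    multivariate_table,
    univariate_table,
)
from necrofract.synthetic import (  # noqa: E402
    PLANTED_PREFIX,
    CohortSpec,
    make_cohort,
    make_expression,
    make_tumor_phantom,
    sample_phantom_specs,
)
from necrofract.util import derive_rng  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SyntheticSpec", "InputPaths", "RunReport", "Issue", "run_pipeline", "run_demo", "validate_inputs"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Synthetic-cohort parameters for demo runs."""

    n_patients: int = 60
    canvas_size: int = 128
    hr_lacunarity: float = 2.0
    hr_fd: float = 2.0
    baseline_hazard: float = 1.0 / 400.0
    censor_rate: float = 0.2
    n_genes: int = 2000
    n_correlated: int = 100
    rho: float = 0.6
    n_expression_patients: int = 32
    # synthetic lacunarity is on the empty-box-CV^2 scale, not the scale of
    # the published cutoffs (which coincide with that study's cohort
    # medians); demo runs therefore dichotomize at the cohort medians
    median_split: bool = True


@dataclass(frozen=True)
class InputPaths:
    """Real-data inputs.

    ``manifest`` is a CSV with columns patient_id, slice_id, image,
    tumor_mask and optionally necrosis_mask and seeds (scribble PNG);
    rows without a necrosis mask are segmented (scribble seeds if given,
    quantile auto-seeding otherwise).
    """

    manifest: str
    cohort: str
    expression: str | None = None
    gene_sets: str | None = None


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "necrofract_run"
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    inputs: InputPaths | None = None
    min_box: int = 2
    max_frac: float = 0.45
    n_grids: int = 12
    n_sizes: int = 12
    fd_cut: float = 1.56
    lac_cut: float = 0.46
    r_threshold: float = 0.3

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ParameterError("config must specify exactly one of synthetic spec or real inputs")

    @property
    def protocol(self) -> ScanProtocol:
        return ScanProtocol(
            min_box=self.min_box,
            max_frac=self.max_frac,
            n_grids=self.n_grids,
            n_sizes=self.n_sizes,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "inputs" in raw and raw["inputs"] is not None:
            raw["inputs"] = InputPaths(**raw["inputs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Issue:
    stage: str
    message: str
    patient_id: str | None = None
    slice_id: str | None = None


@dataclass
class RunReport:
    out_dir: str
    files: dict[str, str] = field(default_factory=dict)
    skipped: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_inputs(config: RunConfig) -> list[Issue]:
    """Structural checks on a run's inputs; returns issues, never raises."""
    issues: list[Issue] = []
    if config.synthetic is not None:
        return issues
    inp = config.inputs
    manifest_path = Path(inp.manifest)
    if not manifest_path.exists():
        return [Issue("inputs", f"manifest not found: {inp.manifest}")]
    manifest = pd.read_csv(manifest_path)
    for col in ("patient_id", "slice_id", "image", "tumor_mask"):
        if col not in manifest.columns:
            issues.append(Issue("inputs", f"manifest lacks column {col!r}"))
    if issues:
        return issues
    for _, row in manifest.iterrows():
        pid, sid = str(row["patient_id"]), str(row["slice_id"])
        try:
            image = nfio.read_image(row["image"])
            tumor = nfio.read_mask(row["tumor_mask"])
        except (FileNotFoundError, NecrofractError) as exc:
            issues.append(Issue("inputs", str(exc), pid, sid))
            continue
        if image.shape != tumor.shape:
            issues.append(Issue("inputs", "image/tumor-mask shape mismatch", pid, sid))
        if "necrosis_mask" in row and isinstance(row.get("necrosis_mask"), str):
            necrosis = nfio.read_mask(row["necrosis_mask"])
            if necrosis.shape != tumor.shape:
                issues.append(Issue("inputs", "necrosis-mask shape mismatch", pid, sid))
            elif (necrosis & ~tumor).any():
                issues.append(
                    Issue("inputs", "necrosis mask not a subset of the tumor mask", pid, sid)
                )
    cohort_path = Path(inp.cohort)
    if not cohort_path.exists():
        issues.append(Issue("inputs", f"cohort CSV not found: {inp.cohort}"))
    else:
        cohort = pd.read_csv(cohort_path)
        clinical = [c for c in nfio.COHORT_COLUMNS if c not in ("fd", "lacunarity")]
        for col in clinical:
            if col not in cohort.columns:
                issues.append(Issue("inputs", f"cohort missing {col} column"))
        if "patient_id" in cohort.columns:
            unmatched = set(manifest["patient_id"].astype(str)) - set(
                cohort["patient_id"].astype(str)
            )
            for pid in sorted(unmatched):
                issues.append(Issue("inputs", "patient absent from cohort CSV", pid))
    if inp.expression is not None and not Path(inp.expression).exists():
        issues.append(Issue("inputs", f"expression TSV not found: {inp.expression}"))
    if inp.gene_sets is not None and not Path(inp.gene_sets).exists():
        issues.append(Issue("inputs", f"GMT not found: {inp.gene_sets}"))
    return issues


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _synthetic_features(config: RunConfig, report: RunReport) -> pd.DataFrame:
    spec = config.synthetic
    specs = sample_phantom_specs(spec.n_patients, config.seed, spec.canvas_size)
    rows = []
    for i, ph in enumerate(specs):
        pid = f"P{i:04d}"
        try:
            image, tumor, truth = make_tumor_phantom(ph)
            seeds = auto_seed(image, tumor)
            necrosis = segment_necrosis(image, tumor, seeds)
            feats = slice_features(tumor, necrosis, config.protocol)
            dice = 2 * (necrosis & truth).sum() / max((necrosis.sum() + truth.sum()), 1)
        except (DegeneratePhantomError, EmptyRegionError, NecrofractError) as exc:
            logger.warning("patient %s skipped: %s", pid, exc)
            report.skipped.append({"stage": "features", "patient_id": pid, "reason": str(exc)})
            continue
        rows.append(
            {
                "patient_id": pid,
                "fd": feats.fd,
                "lacunarity": feats.lacunarity,
                "n_slices": feats.n_slices_aggregated,
                "dice_vs_truth": round(float(dice), 4),
            }
        )
    return pd.DataFrame(rows)


def _real_features(config: RunConfig, report: RunReport) -> pd.DataFrame:
    manifest = pd.read_csv(config.inputs.manifest)
    per_patient: dict[str, list] = {}
    for _, row in manifest.iterrows():
        pid, sid = str(row["patient_id"]), str(row["slice_id"])
        try:
            tumor = nfio.read_mask(row["tumor_mask"])
            if isinstance(row.get("necrosis_mask"), str) and row.get("necrosis_mask"):
                necrosis = nfio.read_mask(row["necrosis_mask"])
            else:
                image = nfio.read_image(row["image"])
                if isinstance(row.get("seeds"), str) and row.get("seeds"):
                    seeds = nfio.read_seed_scribble(row["seeds"])
                else:
                    seeds = auto_seed(image, tumor)
                necrosis = segment_necrosis(image, tumor, seeds)
            feats = slice_features(tumor, necrosis, config.protocol)
        except (FileNotFoundError, NecrofractError) as exc:
            logger.warning("slice %s/%s skipped: %s", pid, sid, exc)
            report.skipped.append(
                {"stage": "features", "patient_id": pid, "slice_id": sid, "reason": str(exc)}
            )
            continue
        per_patient.setdefault(pid, []).append(feats)
    rows = []
    for pid, slices in per_patient.items():
        agg = patient_features(slices)
        rows.append(
            {
                "patient_id": pid,
                "fd": agg.fd,
                "lacunarity": agg.lacunarity,
                "n_slices": agg.n_slices_aggregated,
            }
        )
    return pd.DataFrame(rows)


def _km_plot(cohort: pd.DataFrame, indicator: str, endpoint: str, path: Path) -> None:
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    fig, ax = plt.subplots(figsize=(5, 4))
    for value, label in ((0, f"{indicator}=0"), (1, f"{indicator}=1")):
        sub = cohort[cohort[indicator] == value]
        if sub.empty:
            continue
        km = km_estimate(sub[time_col], sub[event_col])
        ax.step(km.step_times, km.step_values, where="post", label=label)
    ax.set_xlabel(f"{endpoint.upper()} time (days)")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _multivariate_frame(fits: dict) -> pd.DataFrame:
    frames = []
    for endpoint, fit in fits.items():
        tbl = fit.table.reset_index(names="covariate")
        tbl.insert(0, "endpoint", endpoint)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def _demo_gene_sets(expr_index: pd.Index, seed: int) -> tuple[dict, dict]:
    """Gene sets for demo enrichment: one planted-heavy set, four null sets."""
    rng = derive_rng(seed, "demo_gene_sets")
    planted = [g for g in expr_index if g.startswith(PLANTED_PREFIX)]
    null = [g for g in expr_index if not g.startswith(PLANTED_PREFIX)]
    sets = {
        "NECROSIS_ASSOCIATED": sorted(
            list(rng.choice(planted, size=min(40, len(planted)), replace=False))
            + list(rng.choice(null, size=10, replace=False))
        )
    }
    for k in range(4):
        sets[f"RANDOM_SET_{k}"] = sorted(rng.choice(null, size=50, replace=False))
    desc = {"NECROSIS_ASSOCIATED": "planted lacunarity-correlated genes"}
    return sets, desc


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage of the configured run and write its artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=str(out))

    issues = validate_inputs(config)
    fatal = [i for i in issues if "not found" in i.message or "lacks" in i.message]
    if fatal:
        raise ParameterError("; ".join(i.message for i in fatal))
    for issue in issues:
        report.skipped.append(dataclasses.asdict(issue))

    # 1. features
    if config.synthetic is not None:
        features = _synthetic_features(config, report)
    else:
        features = _real_features(config, report)
    if features.empty:
        raise EmptyRegionError("no patient yielded usable fractal features")
    features_path = out / "features.csv"
    features.to_csv(features_path, index=False)
    report.files["features"] = str(features_path)

    # 2. cohort
    fd_cut, lac_cut = config.fd_cut, config.lac_cut
    if config.synthetic is not None:
        spec = config.synthetic
        if spec.median_split:
            fd_cut = float(features["fd"].median())
            lac_cut = float(features["lacunarity"].median())
            report.metrics["fd_cut"] = fd_cut
            report.metrics["lac_cut"] = lac_cut
        cohort = make_cohort(
            CohortSpec(
                n_patients=len(features),
                hr_lacunarity=spec.hr_lacunarity,
                hr_fd=spec.hr_fd,
                baseline_hazard=spec.baseline_hazard,
                censor_rate=spec.censor_rate,
                seed=config.seed,
            ),
            features,
            fd_cut=fd_cut,
            lac_cut=lac_cut,
        )
    else:
        clinical = pd.read_csv(config.inputs.cohort)
        clinical = clinical.drop(columns=[c for c in ("fd", "lacunarity") if c in clinical], errors="ignore")
        cohort = clinical.merge(
            features[["patient_id", "fd", "lacunarity"]], on="patient_id", how="inner"
        )
    cohort_path = out / "cohort.csv"
    nfio.write_cohort(cohort_path, cohort)
    report.files["cohort"] = str(cohort_path)

    r_fd_lac, p_fd_lac = correlate_features(cohort["fd"], cohort["lacunarity"])
    report.metrics["fd_lacunarity_r"] = r_fd_lac
    report.metrics["fd_lacunarity_p"] = p_fd_lac

    # 3. survival
    strat = dichotomize_cohort(cohort, fd_cut=fd_cut, lac_cut=lac_cut)
    uni = univariate_table(strat)
    uni_path = out / "univariate.csv"
    uni.to_csv(uni_path, index=False)
    report.files["univariate"] = str(uni_path)
    for param in ("fd", "lacunarity"):
        try:
            fits = multivariate_table(strat, param)
        except NecrofractError as exc:
            logger.warning("multivariate model for %s failed: %s", param, exc)
            report.skipped.append({"stage": "multivariate", "param": param, "reason": str(exc)})
            continue
        path = out / f"multivariate_{param}.csv"
        _multivariate_frame(fits).to_csv(path, index=False)
        report.files[f"multivariate_{param}"] = str(path)
    for indicator in ("fd_low", "lac_high"):
        for endpoint in ("pfs", "os"):
            path = out / f"km_{indicator}_{endpoint}.png"
            _km_plot(strat, indicator, endpoint, path)
            report.files[f"km_{indicator}_{endpoint}"] = str(path)

    # 4. gene screen
    expr = None
    sets = None
    if config.synthetic is not None:
        spec = config.synthetic
        n_expr = min(spec.n_expression_patients, len(cohort))
        lac = pd.Series(
            cohort["lacunarity"].to_numpy()[:n_expr],
            index=cohort["patient_id"].astype(str).to_numpy()[:n_expr],
        )
        expr = make_expression(spec.n_genes, spec.n_correlated, spec.rho, lac, config.seed)
        expr_path = out / "expression.tsv"
        nfio.write_expression(expr_path, expr)
        report.files["expression"] = str(expr_path)
        sets, desc = _demo_gene_sets(expr.index, config.seed)
        gmt_path = out / "gene_sets.gmt"
        nfio.write_gmt(gmt_path, sets, desc)
        report.files["gene_sets"] = str(gmt_path)
        lac_vector = lac
    elif config.inputs.expression is not None:
        expr = nfio.read_expression(config.inputs.expression)
        shared = [p for p in expr.columns if p in set(cohort["patient_id"].astype(str))]
        expr = expr[shared]
        lac_vector = pd.Series(
            cohort.set_index(cohort["patient_id"].astype(str)).loc[shared, "lacunarity"]
        )
        if config.inputs.gene_sets is not None:
            sets = nfio.read_gmt(config.inputs.gene_sets)
    if expr is not None:
        screened = pearson_screen(expr, lac_vector, r_threshold=config.r_threshold)
        screened_path = out / "screened_genes.csv"
        screened.to_csv(screened_path, index=False)
        report.files["screened_genes"] = str(screened_path)
        report.metrics["n_screened_genes"] = int(len(screened))
        if sets:
            enrichment = enrich(list(screened["gene_id"]), sets, list(expr.index))
            enrich_path = out / "enrichment.csv"
            enrichment.to_csv(enrich_path, index=False)
            report.files["enrichment"] = str(enrich_path)

    # 5. provenance + report
    import lifelines
    import scipy
    import skimage

    from necrofract import __version__

    report.provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "necrofract": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "lifelines": lifelines.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    report_path = out / "report.json"
    report_path.write_text(
        json.dumps(
            {
                "out_dir": report.out_dir,
                "files": report.files,
                "skipped": report.skipped,
                "metrics": report.metrics,
                "provenance": report.provenance,
            },
            indent=2,
            default=str,
        )
    )
    report.files["report"] = str(report_path)
    for name, path in report.files.items():
        assert Path(path).exists(), f"report lists missing file {name}: {path}"
    return report


def run_demo(seed: int, out_dir: str | Path, n_patients: int = 60, **overrides) -> RunReport:
    """Fully synthetic end-to-end run: phantoms in, survival tables and gene screen out."""
    config = RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        synthetic=SyntheticSpec(n_patients=n_patients, **overrides),
    )
    return run_pipeline(config)
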