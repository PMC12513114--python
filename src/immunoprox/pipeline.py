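"""End-to-end orchestration: ingest -> gate -> interact -> aggregate -> survive.

One :func:`run_pipeline` call reproduces the whole per-region prognostic
analysis on a cohort of cell tables plus a clinical table (or a synthetic
cohort generated in place):

1.  ingest cell tables and the clinical table, validate cross-references;
2.  phenotype gating (threshold rules) unless cells arrive pre-labeled;
3.  per image and tissue region: interaction variable of each configured
    (counted, anchor) phenotype pair, plus radial nearest-anchor profiles;
4.  per-patient aggregation (mean over image fields by default);
5.  median dichotomization of patients into high/low interaction groups,
    independently per region;
6.  Kaplan–Meier curves and the log-rank test per region and endpoint;
7.  univariate Cox screen over clinical covariates and the interaction
    group(s); factors at p < alpha enter one multivariate Cox model.

Each region is analysed fully independently and no cross-region multiplicity
correction is applied — the per-region p-values are reported as-is, which the
run manifest states explicitly.  Every stage writes its table under the
output directory and logs a one-line summary; the manifest records the seed,
the effective configuration and its hash, library versions, and row counts,
so re-running a manifest reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_tables import (
    ImageCellTable,
    PhenotypeRule,
    apply_phenotype_rules,
    default_rules,
    read_cell_table,
)
from .spatial import (
    SpatialParams,
    aggregate_patient,
    dichotomize_by_median,
    image_interaction,
    image_radial_profile,
    interactions_to_frame,
)
from .survival import (
    ScreenResult,
    administrative_censor,
    km_estimate,
    logrank_test,
    screen_then_model,
    ZeroEventsError,
)
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger("immunoprox")

RFS_HORIZON_MONTHS = 60.0


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    cells_path: str | None = None
    clinical_path: str | None = None
    dialect: str = "canonical"
    synthetic: bool = False
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_patients: int = 40
    rules: list[PhenotypeRule] = field(default_factory=default_rules)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("CD8T", "PDL1_TAM")]
    )
    aggregation: str = "mean"
    endpoints: list[str] = field(default_factory=lambda: ["RFS", "OS"])
    regions: list[str] = field(default_factory=lambda: ["T"])
    alpha: float = 0.05
    covariates: list[str] = field(
        default_factory=lambda: ["age", "sex", "afp_high"]
    )
    out_dir: str = "immunoprox_out"
    seed: int = 0
    #: copy the (synthetic) input tables into out_dir/inputs; disable for
    #: large simulation studies where only the result tables matter
    write_inputs: bool = True

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("need at least one (counted, anchor) pair")
        if not self.endpoints:
            raise ValueError("need at least one endpoint")
        if not self.regions:
            raise ValueError("need at least one region")
        for ep in self.endpoints:
            if ep not in ("RFS", "OS"):
                raise ValueError(f"unknown endpoint {ep!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rules"] = [
            {
                "label": r.label,
                "required_positive": sorted(r.required_positive),
                "required_negative": sorted(r.required_negative),
                "thresholds": dict(r.thresholds),
                "default_threshold": r.default_threshold,
            }
            for r in self.rules
        ]
        d["pairs"] = [list(p) for p in self.pairs]
        d["synthetic_config"]["rho_spread"] = list(
            d["synthetic_config"]["rho_spread"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rules" in d:
            d["rules"] = [
                PhenotypeRule(
                    label=r["label"],
                    required_positive=frozenset(r["required_positive"]),
                    required_negative=frozenset(r.get("required_negative", [])),
                    thresholds=r.get("thresholds", {}),
                    default_threshold=r.get("default_threshold", 1.0),
                )
                for r in d["rules"]
            ]
        if "spatial" in d and isinstance(d["spatial"], dict):
            d["spatial"] = SpatialParams(**d["spatial"])
        if "synthetic_config" in d and isinstance(d["synthetic_config"], dict):
            sc = dict(d["synthetic_config"])
            if "rho_spread" in sc:
                sc["rho_spread"] = tuple(sc["rho_spread"])
            d["synthetic_config"] = SyntheticConfig(**sc)
        if "pairs" in d:
            d["pairs"] = [tuple(p) for p in d["pairs"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded: two runs into different directories are the same analysis)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    findings: list[dict]
    fatal: bool

    def summary(self) -> str:
        if not self.findings:
            return "validation: clean (0 findings)"
        lines = [
            f"[{f['level']}] {f['message']} (n={f['count']})"
            for f in self.findings
        ]
        return "validation:\n" + "\n".join(lines)


def validate_inputs(tables: list[ImageCellTable],
                    clinical: pd.DataFrame) -> ValidationReport:
    """Cross-reference cell tables and clinical rows; list non-fatal findings.

    Fatal findings: missing mandatory clinical columns, duplicate patient
    rows, duplicate image ids.  Orphans (clinical rows without images or
    images without clinical rows) are warnings — the analysis proceeds on the
    intersection.  Duplicate cell ids within an image are rejected earlier,
    at :class:`ImageCellTable` construction.
    """
    findings: list[dict] = []
    fatal = False

    def add(level: str, message: str, count: int) -> None:
        nonlocal fatal
        findings.append({"level": level, "message": message, "count": count})
        if level == "fatal":
            fatal = True

    needed = {"patient_id"}
    missing_cols = needed - set(clinical.columns)
    if missing_cols:
        add("fatal", f"clinical table missing columns {sorted(missing_cols)}",
            len(missing_cols))
        return ValidationReport(findings, fatal)

    dup_pat = clinical["patient_id"].astype(str).duplicated()
    if dup_pat.any():
        add("fatal", "duplicate patient_id rows in clinical table",
            int(dup_pat.sum()))

    image_ids = [t.image_id for t in tables]
    if len(set(image_ids)) != len(image_ids):
        add("fatal", "duplicate image ids across cell tables",
            len(image_ids) - len(set(image_ids)))

    cell_patients = {t.patient_id for t in tables}
    clin_patients = set(clinical["patient_id"].astype(str))
    orphan_clin = clin_patients - cell_patients
    if orphan_clin:
        add("warning", "clinical rows without any image", len(orphan_clin))
    orphan_imgs = cell_patients - clin_patients
    if orphan_imgs:
        add("warning", "imaged patients without a clinical row",
            len(orphan_imgs))
    return ValidationReport(findings, fatal)


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    """In-memory handles to every table the run produced, plus the manifest."""

    interaction: pd.DataFrame
    patient_values: pd.DataFrame
    groups: pd.DataFrame
    logrank: dict
    screens: dict[str, ScreenResult]
    manifest: dict
    out_dir: Path


def _survival_arrays(clinical: pd.DataFrame, endpoint: str,
                     patient_ids: list[str]
                     ) -> tuple[np.ndarray, np.ndarray]:
    sub = clinical.set_index(clinical["patient_id"].astype(str)).loc[patient_ids]
    if endpoint == "RFS":
        t, e = administrative_censor(
            sub["rfs_months"], sub["rfs_event"], RFS_HORIZON_MONTHS
        )
    else:
        t = sub["os_months"].to_numpy(dtype=float)
        e = sub["os_event"].to_numpy(dtype=int)
    return t, e


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages; write tables and the run manifest under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # -- stage: ingest ------------------------------------------------------
    stage = "ingest"
    try:
        if config.synthetic:
            bundle = generate_cohort(
                config.synthetic_config, config.n_patients, seed=config.seed,
                spatial_params=config.spatial,
            )
            tables, clinical = bundle.tables, bundle.clinical
            if config.write_inputs:
                inputs = out / "inputs"
                inputs.mkdir(exist_ok=True)
                bundle.write(
                    inputs / "cells.csv", inputs / "clinical.csv",
                    inputs / "truth.json",
                )
        else:
            if not config.cells_path or not config.clinical_path:
                raise ValueError(
                    "cells_path and clinical_path required unless synthetic"
                )
            tables = read_cell_table(config.cells_path, dialect=config.dialect)
            clinical = pd.read_csv(config.clinical_path)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, str(err)) from err
    counts["images"] = len(tables)
    counts["cells"] = sum(len(t) for t in tables)
    counts["patients_clinical"] = len(clinical)
    logger.info("ingest: %d images, %d cells, %d clinical rows",
                counts["images"], counts["cells"], counts["patients_clinical"])

    report = validate_inputs(tables, clinical)
    (out / "validation.json").write_text(json.dumps(report.findings, indent=2))
    if report.fatal:
        raise PipelineError("validate", report.summary())
    logger.info("%s", report.summary())

    # -- stage: phenotype ---------------------------------------------------
    stage = "phenotype"
    try:
        tables = [apply_phenotype_rules(t, config.rules) for t in tables]
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    logger.info("phenotype: gated %d images with %d rules",
                len(tables), len(config.rules))

    # -- stage: interaction + radial profiles -------------------------------
    stage = "interaction"
    period = config.synthetic_config.period if config.synthetic else None
    results = []
    radial_rows = []
    for t in tables:
        if t.region not in config.regions:
            continue
        for counted, anchor in config.pairs:
            res = image_interaction(t, counted, anchor, config.spatial,
                                    period=period)
            results.append(res)
            prof = image_radial_profile(t, counted, anchor, config.spatial,
                                        period=period)
            if prof is not None and prof.n_a > 0:
                pf = prof.to_frame()
                pf.insert(0, "image_id", t.image_id)
                pf.insert(1, "region", t.region)
                pf.insert(2, "label_A", counted)
                pf.insert(3, "label_B", anchor)
                radial_rows.append(pf)
    if not results:
        raise PipelineError(stage, "no image matched the configured regions")
    interaction = interactions_to_frame(results)
    interaction.to_csv(out / "interaction.csv", index=False)
    if radial_rows:
        pd.concat(radial_rows, ignore_index=True).to_csv(
            out / "radial_profiles.csv", index=False
        )
    counts["interaction_rows"] = len(interaction)
    logger.info("interaction: %d image x pair rows", len(interaction))

    # -- stage: patient aggregation -----------------------------------------
    stage = "aggregate"
    agg_rows = []
    for (pid, region, la, lb), sub in interaction.groupby(
        ["patient_id", "region", "label_A", "label_B"], sort=False
    ):
        value, n_images = aggregate_patient(
            sub["value"].tolist(), method=config.aggregation
        )
        agg_rows.append(
            {
                "patient_id": pid, "region": region,
                "label_A": la, "label_B": lb,
                "value": value, "n_images": n_images,
            }
        )
    patient_values = pd.DataFrame(agg_rows)
    patient_values.to_csv(out / "patient_values.csv", index=False)
    counts["patient_values"] = len(patient_values)
    logger.info("aggregate: %d patient x region values (%s)",
                len(patient_values), config.aggregation)

    # -- stage: median dichotomization --------------------------------------
    stage = "dichotomize"
    group_rows = []
    medians: dict[str, float] = {}
    for region in config.regions:
        sub = patient_values[patient_values["region"] == region]
        if sub.empty:
            logger.warning("region %s: no patients; skipped", region)
            continue
        values = dict(zip(sub["patient_id"].astype(str), sub["value"]))
        try:
            groups, med = dichotomize_by_median(values)
        except ValueError as err:
            raise PipelineError(stage, f"region {region}: {err}") from err
        medians[region] = med
        for pid, g in groups.items():
            group_rows.append(
                {"patient_id": pid, "region": region, "group": g,
                 "value": values[pid], "median": med}
            )
    groups_df = pd.DataFrame(
        group_rows,
        columns=["patient_id", "region", "group", "value", "median"],
    )
    groups_df.to_csv(out / "groups.csv", index=False)
    logger.info("dichotomize: medians %s",
                {k: round(v, 3) for k, v in medians.items()})

    # -- stage: KM + log-rank per region/endpoint ----------------------------
    stage = "km_logrank"
    clin_idx = set(clinical["patient_id"].astype(str))
    logrank_out: dict[str, dict] = {}
    for region in config.regions:
        sub = groups_df[groups_df["region"] == region]
        if sub.empty:
            continue
        pids = [p for p in sub["patient_id"] if p in clin_idx]
        grp = sub.set_index("patient_id").loc[pids, "group"]
        for endpoint in config.endpoints:
            t, e = _survival_arrays(clinical, endpoint, pids)
            hi = (grp == "high").to_numpy()
            key = f"{endpoint}_{region}"
            for name, mask in (("high", hi), ("low", ~hi)):
                if mask.sum() == 0:
                    continue
                curve = km_estimate((t[mask], e[mask]), label=name)
                curve.to_frame().to_csv(
                    out / f"km_{endpoint}_{region}_{name}.csv", index=False
                )
            try:
                lr = logrank_test((t[hi], e[hi]), (t[~hi], e[~hi]))
                logrank_out[key] = {
                    "statistic": lr.statistic, "p_value": lr.p_value,
                    "n_high": int(hi.sum()), "n_low": int((~hi).sum()),
                }
            except (ZeroEventsError, ValueError) as err:
                logrank_out[key] = {"error": str(err)}
    (out / "logrank.json").write_text(json.dumps(logrank_out, indent=2))
    logger.info("km_logrank: %d region x endpoint tests", len(logrank_out))

    # -- stage: univariate screen -> multivariate Cox ------------------------
    stage = "screen"
    screens: dict[str, ScreenResult] = {}
    for endpoint in config.endpoints:
        design, pids = _build_design(config, clinical, groups_df)
        if design.empty:
            logger.warning("screen %s: empty design; skipped", endpoint)
            continue
        t, e = _survival_arrays(clinical, endpoint, pids)
        try:
            screen = screen_then_model(design, (t, e), alpha=config.alpha)
        except Exception as err:
            raise PipelineError(stage, f"{endpoint}: {err}") from err
        screens[endpoint] = screen
        screen.univariate.to_csv(
            out / f"univariate_{endpoint}.csv", index=False
        )
        if screen.multivariate is not None:
            screen.multivariate.to_frame().to_csv(
                out / f"multivariate_{endpoint}.csv", index=False
            )
        logger.info("screen %s: selected %s", endpoint, screen.selected)

    # -- manifest ------------------------------------------------------------
    manifest = {
        "package": "immunoprox",
        "version": __version__,
        "versions": _library_versions(),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "counts": counts,
        "medians": medians,
        "note": (
            "regions are analysed independently; no cross-region multiplicity "
            "correction is applied"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineReport(
        interaction=interaction,
        patient_values=patient_values,
        groups=groups_df,
        logrank=logrank_out,
        screens=screens,
        manifest=manifest,
        out_dir=out,
    )


def _build_design(config: PipelineConfig, clinical: pd.DataFrame,
                  groups_df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Candidate covariate matrix: clinical covariates (continuous ones
    median-dichotomized, matching the dichotomized-factor presentation of
    clinical screens) plus one high/low indicator per analysed region."""
    clin = clinical.copy()
    clin["patient_id"] = clin["patient_id"].astype(str)
    clin = clin.set_index("patient_id")
    pids = [
        p for p in clin.index
        if p in set(groups_df["patient_id"].astype(str))
    ]
    design = pd.DataFrame(index=pids)
    for cov in config.covariates:
        if cov not in clin.columns:
            continue
        x = pd.to_numeric(clin.loc[pids, cov], errors="coerce")
        vals = x.dropna().unique()
        if len(vals) > 2:
            x = (x >= x.median()).astype(float)
        design[cov] = x.to_numpy(dtype=float)
    for region in config.regions:
        sub = groups_df[groups_df["region"] == region].set_index("patient_id")
        col = f"interaction_{region}"
        indic = [
            1.0 if (p in sub.index and sub.loc[p, "group"] == "high") else 0.0
            for p in pids
        ]
        design[col] = indic
    design = design.dropna(axis=0)
    return design, list(design.index)


def _library_versions() -> dict[str, str]:
    import lifelines
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
    }
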