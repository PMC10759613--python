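"""End-to-end orchestration: generate -> quantify -> harmonize -> subgroup ->
screen -> network -> GED, as a configurable, logged, seed-pinned run.

Each stage consumes the previous stage's in-memory product and writes its
table/graph exports under the run's output directory; the final report
records provenance (config hash, seed), per-stage output paths, and summary
counts. A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so that disabling a downstream stage never
changes upstream randomness.

The quantify stage emulates the cytokine measurement layer: true
concentrations are mapped onto plate signals through per-panel ground-truth
standard curves (second-order polynomial for the 16-plex batch, 5PL for the
18-plex batch), duplicate wells are simulated with the configured CV, curves
are re-fitted from simulated standards, wells are back-calculated and
averaged, and the 16-plex batch carries a programmed scale/offset shift that
the harmonization stage must remove.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay, corrnet, ged as ged_mod
from .cohort import (
    CohortConfig,
    CohortTable,
    config_to_dict,
    generate_cohort,
    generate_duplicate_wells,
)
from .groupstats import ScreenResult, screen_measures
from .harmonize import harmonize_panels
from .subgroup import assign_groups, assignments_frame

logger = logging.getLogger("gwinet.pipeline")

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "validate_input_table",
    "ValidationReport",
    "STAGES",
]

STAGES = ("generate", "quantify", "harmonize", "subgroup", "screen",
          "network", "ged")

REQUIRED_COLUMNS = ("subject_id", "site", "group", "timepoint", "measure",
                    "family", "value")

# measurement-layer constants: concentration mapping and the 16-plex batch
# shift that harmonization must remove
CONC_OFFSET, CONC_SCALE = 20.0, 180.0
BATCH16_SCALE, BATCH16_OFFSET = 2.0, 5.0
TRUE_5PL = {"a": 30000.0, "d": 50.0, "c": 100.0, "b": -1.2, "g": 0.8}
TRUE_POLY2 = {"b0": 100.0, "b1": 8.0, "b2": 0.05}
STANDARDS_18 = 1000.0 / 3.0 ** np.arange(8)
STANDARDS_16 = np.linspace(5.0, 2000.0, 8)
STANDARD_CV = 0.04


@dataclass
class RunConfig:
    cohort: CohortConfig | str | Path
    output_dir: str | Path = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    alpha_omnibus: float = 0.05
    alpha_pairwise: float = 0.05
    q_threshold: float = 0.05
    min_pairs: int = 10
    scheme: str = "weight_difference"

    def validate(self) -> None:
        for thr in (self.alpha_omnibus, self.alpha_pairwise, self.q_threshold):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must respect dependency order")
        if self.scheme not in ged_mod.SCHEMES:
            raise ValueError(f"unknown edit-cost scheme {self.scheme!r}")


@dataclass
class RunReport:
    provenance: dict
    outputs: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    skipped_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "outputs": self.outputs,
            "summary": self.summary,
            "skipped_stages": self.skipped_stages,
            "failed_stage": self.failed_stage,
            "error": self.error,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


@dataclass
class ValidationReport:
    n_rows: int
    n_dropped: int
    problems: list[str] = field(default_factory=list)


def validate_input_table(path: str | Path) -> tuple[CohortTable, ValidationReport]:
    """Schema-check an observed-data CSV; malformed rows dropped with counts.

    Missing required columns are a hard failure naming the columns; rows
    with unparseable numeric values or unknown group/timepoint categories
    are dropped and counted in the validation report.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table missing required columns: {missing}")
    n_rows = len(df)
    problems: list[str] = []
    value = pd.to_numeric(df["value"], errors="coerce")
    bad_value = value.isna() & df["value"].notna()
    if bad_value.any():
        problems.append(f"{int(bad_value.sum())} rows with non-numeric value")
    bad_group = ~df["group"].isin(("HC", "GWI_L", "GWI_H"))
    if bad_group.any():
        problems.append(f"{int(bad_group.sum())} rows with unknown group")
    keep = ~(bad_value | bad_group)
    data = df[keep].copy()
    data["value"] = value[keep]
    if "panel" not in data.columns:
        data["panel"] = None
    subjects = (
        data[["subject_id", "site", "group"]]
        .drop_duplicates("subject_id")
        .reset_index(drop=True)
    )
    subjects["dts_total"] = pd.NA
    subjects["ptsd_dx"] = pd.NA
    subjects["cytokine_panel"] = pd.NA
    report = ValidationReport(
        n_rows=n_rows, n_dropped=int((~keep).sum()), problems=problems
    )
    for problem in problems:
        logger.warning("validate_input_table: %s", problem)
    return CohortTable(data=data, subjects=subjects, config=None), report


# ---------------------------------------------------------------------------
# quantify + harmonize stages
# ---------------------------------------------------------------------------

def _true_curves() -> dict[str, assay.StandardCurve]:
    return {
        "16plex": assay.StandardCurve(
            model="poly2", params=dict(TRUE_POLY2),
            calibrated_range=(float(STANDARDS_16.min()), float(STANDARDS_16.max())),
        ),
        "18plex": assay.StandardCurve(
            model="logistic5p", params=dict(TRUE_5PL),
            calibrated_range=(float(STANDARDS_18.min()), float(STANDARDS_18.max())),
        ),
    }


def simulate_and_fit_curves(rng: np.random.Generator) -> dict[str, assay.StandardCurve]:
    """Simulate standards on both panels and refit their calibration curves."""
    truth = _true_curves()
    fitted = {}
    for panel, standards in (("16plex", STANDARDS_16), ("18plex", STANDARDS_18)):
        signals = truth[panel].evaluate(standards)
        noisy = signals * (1.0 + rng.normal(0.0, STANDARD_CV, size=signals.shape))
        if panel == "16plex":
            fitted[panel] = assay.fit_poly2(standards, noisy)
        else:
            fitted[panel] = assay.fit_5pl(standards, np.maximum(noisy, 1.0),
                                          weighting="inverse_y")
    return fitted


def quantify_cytokines(
    cohort: CohortTable, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, assay.StandardCurve]]:
    """Push true cytokine values through the simulated measurement layer.

    Returns a tidy frame (subject_id, timepoint, measure, panel, value) of
    back-calculated, duplicate-averaged concentrations on each panel's own
    scale — the 16-plex scale carrying the programmed batch shift — plus the
    fitted standard curves.
    """
    truth = _true_curves()
    fitted = simulate_and_fit_curves(rng)
    cv = cohort.config.duplicate_cv if cohort.config is not None else 0.10
    panel_of = dict(
        zip(cohort.subjects["subject_id"], cohort.subjects["cytokine_panel"])
    )
    cyt = cohort.data[cohort.data["family"] == "cytokine"]
    rows = []
    for rec in cyt.itertuples(index=False):
        if pd.isna(rec.value):
            continue
        panel = panel_of.get(rec.subject_id, "18plex")
        conc = CONC_OFFSET + CONC_SCALE * rec.value
        if panel == "16plex":
            conc = BATCH16_SCALE * conc + BATCH16_OFFSET
            n_wells = 4  # run in duplicate in two separate assays
        else:
            n_wells = 2
        lo, hi = truth[panel].calibrated_range
        conc = float(np.clip(conc, lo, hi))
        signals = generate_duplicate_wells(conc, truth[panel], cv, seed=rng,
                                           n_wells=n_wells)
        concs, _flags = assay.back_calculate(fitted[panel], signals)
        value, n_used = assay.average_duplicates(concs)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "timepoint": rec.timepoint,
                "measure": rec.measure,
                "panel": panel,
                "value": value,
                "n_wells": n_used,
            }
        )
    return pd.DataFrame(rows), fitted


def harmonize_cytokines(measured: pd.DataFrame):
    """Merge the two panel batches onto the common [0, 1] scale.

    Input is the tidy quantify output; subject x timepoint pairs index the
    rows (pooling all timepoints per analyte, so one scaling per cytokine).
    """
    measured = measured.copy()
    measured["obs"] = (
        measured["subject_id"].astype(str) + "@" + measured["timepoint"].astype(str)
    )
    panels = {}
    for panel in ("16plex", "18plex"):
        sub = measured[measured["panel"] == panel]
        panels[panel] = sub.pivot_table(
            index="obs", columns="measure", values="value", aggfunc="first",
            dropna=False,
        )
    return harmonize_panels(panels["16plex"], panels["18plex"])


def _replace_cytokines(cohort: CohortTable, harmonized) -> CohortTable:
    """Swap true cytokine values for harmonized measured ones."""
    data = cohort.data.copy()
    values = harmonized.values
    obs = data["subject_id"].astype(str) + "@" + data["timepoint"].astype(str)
    is_cyt = data["family"] == "cytokine"
    stacked = values.stack(future_stack=True)
    keyed = pd.Series(
        stacked.to_numpy(),
        index=pd.MultiIndex.from_tuples(
            [(o, m) for o, m in stacked.index], names=["obs", "measure"]
        ),
    )
    lookup = pd.MultiIndex.from_arrays([obs[is_cyt], data.loc[is_cyt, "measure"]])
    data.loc[is_cyt, "value"] = keyed.reindex(lookup).to_numpy()
    return CohortTable(data=data, subjects=cohort.subjects, config=cohort.config)


# ---------------------------------------------------------------------------
# run_pipeline
# ---------------------------------------------------------------------------

def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order and write all exports.

    A stage failure produces a partial report naming the failed stage;
    downstream stages are skipped.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config.cohort, CohortConfig):
        cohort_payload = config_to_dict(config.cohort)
    else:
        cohort_payload = {"path": str(config.cohort)}
    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(
            {
                "cohort": cohort_payload,
                "thresholds": [config.alpha_omnibus, config.alpha_pairwise,
                               config.q_threshold, config.min_pairs],
                "scheme": config.scheme,
                "stages": list(config.stages),
            }
        ),
        "stages": list(config.stages),
    }
    report = RunReport(provenance=provenance)
    report.skipped_stages = [s for s in STAGES if s not in config.stages]
    seeds = {
        stage: child
        for stage, child in zip(
            STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES))
        )
    }

    cohort: CohortTable | None = None
    screens: dict[str, ScreenResult] = {}
    graphs: dict[tuple[str, str], corrnet.CorrelationGraph] = {}
    try:
        if "generate" in config.stages:
            stage = "generate"
            if isinstance(config.cohort, CohortConfig):
                cohort_cfg = CohortConfig(**{**config.cohort.__dict__})
                cohort_cfg.seed = int(
                    seeds["generate"].generate_state(1)[0] % (2**31)
                )
                cohort = generate_cohort(cohort_cfg)
            else:
                cohort, _validation = validate_input_table(config.cohort)
            path = outdir / "cohort.csv"
            cohort.write_csv(path)
            report.outputs["generate"] = [str(path)]
            report.summary["subjects"] = int(cohort.subjects.shape[0])
            report.summary["group_counts"] = (
                cohort.subjects["group"].value_counts().sort_index().to_dict()
            )
            logger.info("generate: %d subjects", cohort.subjects.shape[0])

        if "quantify" in config.stages:
            stage = "quantify"
            rng = np.random.default_rng(seeds["quantify"])
            measured, curves = quantify_cytokines(cohort, rng)
            mpath = outdir / "cytokines_measured.csv"
            measured.to_csv(mpath, index=False)
            cpath = outdir / "standard_curves.json"
            cpath.write_text(
                json.dumps(
                    {k: v.to_dict() for k, v in curves.items()},
                    indent=2, sort_keys=True,
                )
            )
            report.outputs["quantify"] = [str(mpath), str(cpath)]
            report.summary["cytokine_wells_averaged"] = int(len(measured))

        if "harmonize" in config.stages:
            stage = "harmonize"
            harmonized = harmonize_cytokines(measured)
            hpath = outdir / "cytokines_harmonized.csv"
            harmonized.values.to_csv(hpath)
            spath = outdir / "harmonization_params.json"
            spath.write_text(
                json.dumps(harmonized.scaling_params, indent=2, sort_keys=True)
            )
            cohort = _replace_cytokines(cohort, harmonized)
            report.outputs["harmonize"] = [str(hpath), str(spath)]
            report.summary["harmonized_analytes"] = int(
                harmonized.values.shape[1]
            )

        if "subgroup" in config.stages:
            stage = "subgroup"
            assignments = assign_groups(cohort)
            frame = assignments_frame(assignments)
            apath = outdir / "assignments.csv"
            frame.to_csv(apath, index=False)
            report.outputs["subgroup"] = [str(apath)]
            report.summary["assigned_counts"] = (
                frame["label"].value_counts().sort_index().to_dict()
            )

        if "screen" in config.stages:
            stage = "screen"
            paths = []
            sig_counts = {}
            for tp in cohort.config.timepoints if cohort.config else ("T0",):
                res = screen_measures(
                    cohort, tp,
                    alpha_omnibus=config.alpha_omnibus,
                    alpha_pairwise=config.alpha_pairwise,
                )
                screens[tp] = res
                opath = outdir / f"screen_omnibus_{tp}.csv"
                ppath = outdir / f"screen_pairwise_{tp}.csv"
                res.omnibus.to_csv(opath, index=False)
                res.pairwise.to_csv(ppath, index=False)
                paths += [str(opath), str(ppath)]
                sig_counts[tp] = (
                    int((res.omnibus["p"] < config.alpha_omnibus).sum())
                    if len(res.omnibus)
                    else 0
                )
            report.outputs["screen"] = paths
            report.summary["significant_omnibus"] = sig_counts

        if "network" in config.stages:
            stage = "network"
            paths = []
            edge_counts = {}
            tps = cohort.config.timepoints if cohort.config else ("T0",)
            for group in ("HC", "GWI_L", "GWI_H"):
                for tp in tps:
                    wide = cohort.wide(tp, group=group)
                    if wide.empty:
                        continue
                    graph = corrnet.build_graph(
                        wide, condition=group, timepoint=tp,
                        q_threshold=config.q_threshold,
                        min_pairs=config.min_pairs,
                    )
                    graphs[(group, tp)] = graph
                    epath = outdir / f"graph_{group}_{tp}.csv"
                    gpath = outdir / f"graph_{group}_{tp}.graphml"
                    graph.write_edgelist(epath)
                    graph.write_graphml(gpath)
                    paths += [str(epath), str(gpath)]
                    edge_counts[f"{group}@{tp}"] = graph.n_edges
            report.outputs["network"] = paths
            report.summary["edges_per_graph"] = edge_counts

        if "ged" in config.stages:
            stage = "ged"
            scheme = ged_mod.SCHEMES[config.scheme]
            matrix, results = ged_mod.ged_matrix(
                graphs, scheme=scheme, within_timepoint_only=True
            )
            dpath = outdir / "ged_matrix.csv"
            matrix.to_csv(dpath)
            bpath = outdir / "ged_breakdown.json"
            bpath.write_text(
                json.dumps(
                    {
                        "|".join("@".join(k) for k in pair): {
                            "distance": res.distance,
                            "scheme": res.scheme,
                            **res.edit_breakdown,
                        }
                        for pair, res in results.items()
                    },
                    indent=2, sort_keys=True,
                )
            )
            report.outputs["ged"] = [str(dpath), str(bpath)]
            report.summary["ged"] = {
                "@".join(pair[0]) + "|" + "@".join(pair[1]): round(res.distance, 6)
                for pair, res in results.items()
            }
    except Exception as err:  # partial report with diagnostics
        report.failed_stage = stage
        report.error = f"{type(err).__name__}: {err}"
        logger.exception("stage %s failed", stage)

    report.write_json(outdir / "report.json")
    return report
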