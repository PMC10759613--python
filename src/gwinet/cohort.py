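"""Synthetic cohort generation for the GWI / PTSD exercise-challenge study design.

The generator emulates a three-group veteran cohort — healthy controls (HC),
Gulf War Illness with low probability of comorbid PTSD (GWI_L), and GWI with
high probability of comorbid PTSD (GWI_H) — measured across an exercise
challenge (T0 rest, T1 peak exercise, T2 four hours post). Subjects at the
rest-only recruitment site contribute T0 data only, mirroring the study in
which only one site ran the graded exercise test.

Marginals are Gaussian with optional clipping; group/timepoint mean shifts are
programmed in standardized units; cross-measure dependence is induced by a
Gaussian copula whose Pearson correlations are derived from target Spearman
correlations through rho_P = 2*sin(pi*rho_S/6).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MeasureSpec",
    "Effect",
    "CohortConfig",
    "CohortTable",
    "generate_cohort",
    "generate_latent_network",
    "latent_from_edges",
    "generate_duplicate_wells",
    "spearman_to_pearson",
    "nearest_correlation",
]

FAMILIES = frozenset(
    {"symptom", "cytokine", "cbc", "flow", "hormone", "nk_activity"}
)
PANELS = frozenset({"16plex", "18plex", "both"})
GROUPS = ("HC", "GWI_L", "GWI_H")
EXERCISE_SITE = "exercise_site"
REST_ONLY_SITE = "rest_only_site"

DTS_MAX = 136


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class MeasureSpec:
    """One entry of the measure catalog.

    Parameters
    ----------
    name : str
        Measure identifier (e.g. ``"IL-15"`` or ``"MFI_general_fatigue"``).
    family : str
        One of ``symptom, cytokine, cbc, flow, hormone, nk_activity``.
    baseline_mean, baseline_sd : float
        HC marginal location/scale in native units.
    panel : str, optional
        For cytokines: ``"16plex"``, ``"18plex"`` or ``"both"``.
    bounds : tuple, optional
        ``(lo, hi)`` clipping range; either end may be ``None``.
    """

    name: str
    family: str
    baseline_mean: float
    baseline_sd: float
    panel: str | None = None
    bounds: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CohortConfigError(
                f"{self.name}: unknown family {self.family!r}"
            )
        if not self.baseline_sd > 0:
            raise CohortConfigError(f"{self.name}: baseline_sd must be > 0")
        if self.family == "cytokine":
            if self.panel not in PANELS:
                raise CohortConfigError(
                    f"{self.name}: cytokine requires panel in {sorted(PANELS)}"
                )
        elif self.panel is not None:
            raise CohortConfigError(
                f"{self.name}: panel only applies to cytokines"
            )
        if self.bounds is not None:
            lo, hi = self.bounds
            if lo is not None and hi is not None and not lo < hi:
                raise CohortConfigError(f"{self.name}: bounds lo must be < hi")


@dataclass(frozen=True)
class Effect:
    """Programmed group deviation for one measure at one timepoint.

    ``shift`` is the standardized mean shift (in units of the measure's
    ``baseline_sd``); ``sd_ratio`` scales the group's marginal SD relative to
    ``baseline_sd`` so that heteroscedastic designs (the motivation for the
    Welch/Games-Howell machinery) can be programmed directly.
    """

    shift: float
    sd_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.sd_ratio > 0:
            raise CohortConfigError("Effect sd_ratio must be > 0")


def _as_effect(value) -> Effect:
    if isinstance(value, Effect):
        return value
    if isinstance(value, (tuple, list)):
        return Effect(*value)
    return Effect(float(value))


def spearman_to_pearson(rho_s):
    """Map a Spearman target to the Gaussian-copula Pearson correlation.

    Uses the bivariate-normal identity rho_S = (6/pi) * arcsin(rho_P / 2),
    inverted as rho_P = 2*sin(pi*rho_S/6).
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def nearest_correlation(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalue clipping followed by re-normalization of the diagonal to 1.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def _check_correlation(mat: np.ndarray, what: str, tol: float = 1e-8) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise CohortConfigError(f"{what}: matrix must be square")
    if not np.allclose(mat, mat.T, atol=tol):
        raise CohortConfigError(f"{what}: matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=tol):
        raise CohortConfigError(f"{what}: matrix must have unit diagonal")
    min_eig = np.linalg.eigvalsh((mat + mat.T) / 2.0).min()
    if min_eig < -tol:
        raise CohortConfigError(
            f"{what}: matrix is not positive semi-definite "
            f"(smallest eigenvalue {min_eig:.3g})"
        )


def generate_latent_network(
    n_measures: int,
    n_edges: int,
    weight_range: tuple[float, float] = (0.3, 0.7),
    seed: int | np.random.Generator = 0,
    names: Sequence[str] | None = None,
    negative_fraction: float = 0.0,
    max_retries: int = 50,
) -> np.ndarray:
    """Draw a random sparse Spearman correlation target matrix.

    Exactly ``n_edges`` off-diagonal pairs receive a weight with magnitude
    uniform in ``weight_range`` (a ``negative_fraction`` of them negated)
    before projection to the nearest PSD correlation matrix. If projection
    moves any requested weight by more than half its magnitude the draw is
    retried with the weights shrunk.
    """
    rng = np.random.default_rng(seed)
    m = int(n_measures)
    max_edges = m * (m - 1) // 2
    if n_edges > max_edges:
        raise CohortConfigError(
            f"n_edges={n_edges} exceeds the {max_edges} pairs of {m} measures"
        )
    lo, hi = weight_range
    if not (0 < lo <= hi < 1):
        raise CohortConfigError("weight_range magnitudes must lie in (0, 1)")
    iu = np.triu_indices(m, k=1)
    order = rng.permutation(max_edges)[:n_edges]
    shrink = 1.0
    for _ in range(max_retries):
        mat = np.eye(m)
        w = rng.uniform(lo, hi, size=n_edges) * shrink
        signs = np.where(rng.uniform(size=n_edges) < negative_fraction, -1.0, 1.0)
        w = w * signs
        mat[iu[0][order], iu[1][order]] = w
        mat[iu[1][order], iu[0][order]] = w
        if n_edges == 0:
            return mat
        projected = nearest_correlation(mat)
        got = projected[iu[0][order], iu[1][order]]
        if np.all(np.abs(got - w) <= 0.5 * np.abs(w)):
            return projected
        shrink *= 0.8
    raise CohortConfigError(
        f"could not realize a PSD correlation matrix with {n_edges} edges in "
        f"{weight_range} after {max_retries} shrink retries (last shrink "
        f"{shrink:.3f}); lower the weights or the edge count"
    )


def latent_from_edges(
    measures: Sequence[str],
    edges: Sequence[tuple[str, str, float]],
) -> np.ndarray:
    """Build a Spearman target matrix from named edges, projected to PSD."""
    index = {name: i for i, name in enumerate(measures)}
    mat = np.eye(len(measures))
    for a, b, w in edges:
        i, j = index[a], index[b]
        if i == j:
            raise CohortConfigError(f"self-edge on {a}")
        mat[i, j] = mat[j, i] = float(w)
    return nearest_correlation(mat)


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    The defaults for ``group_sizes`` are the study's arm sizes. ``site_split``
    is the fraction of GWI subjects recruited at the exercise site (the rest
    contribute T0 only); all HC subjects sit at the exercise site by default,
    matching the study in which every control came from the exercising
    cohorts. ``latent_network`` maps ``(group, timepoint)`` — or ``group`` as
    a fallback for all timepoints — to a Spearman correlation target over the
    measure catalog (in catalog order).
    """

    measure_catalog: list[MeasureSpec] = field(default_factory=list)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 44, "GWI_L": 29, "GWI_H": 47}
    )
    site_split: float = 0.67
    hc_exercise_fraction: float = 1.0
    timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    effect_map: dict = field(default_factory=dict)
    latent_network: dict = field(default_factory=dict)
    within_subject_rho: float = 0.5
    missing_rate: float = 0.0
    duplicate_cv: float = 0.10
    panel16_fraction: float = 0.43
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for group, n in self.group_sizes.items():
            if group not in GROUPS:
                raise CohortConfigError(f"unknown group {group!r}")
            if n < 2:
                raise CohortConfigError(
                    f"group {group} has n={n}; at least 2 subjects required"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.site_split <= 1.0:
            raise CohortConfigError("site_split must lie in [0, 1]")
        if not 0.0 <= self.within_subject_rho <= 1.0:
            raise CohortConfigError("within_subject_rho must lie in [0, 1]")
        if self.duplicate_cv < 0:
            raise CohortConfigError("duplicate_cv must be >= 0")
        names = [spec.name for spec in self.measure_catalog]
        if len(set(names)) != len(names):
            raise CohortConfigError("duplicate measure names in catalog")
        unknown = set(self.effect_map) - set(names)
        if unknown:
            raise CohortConfigError(
                f"effect_map refers to measures not in the catalog: "
                f"{sorted(unknown)}"
            )
        m = len(names)
        for key, mat in self.latent_network.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (m, m):
                raise CohortConfigError(
                    f"latent_network[{key!r}] must be {m}x{m} over the catalog"
                )
            _check_correlation(mat, f"latent_network[{key!r}]")

    # -- effect / latent lookups ------------------------------------------
    def effect_for(self, measure: str, group: str, timepoint: str) -> Effect:
        per_measure = self.effect_map.get(measure, {})
        per_group = per_measure.get(group, {})
        if timepoint in per_group:
            return _as_effect(per_group[timepoint])
        if "*" in per_group:
            return _as_effect(per_group["*"])
        return Effect(0.0)

    def latent_for(self, group: str, timepoint: str) -> np.ndarray | None:
        for key in ((group, timepoint), group):
            if key in self.latent_network:
                return np.asarray(self.latent_network[key], dtype=float)
        return None


@dataclass
class CohortTable:
    """Tidy subject x timepoint x measure table plus the subject roster.

    ``data`` columns: subject_id, site, group, timepoint, measure, family,
    panel, value. ``subjects`` columns: subject_id, site, group, dts_total,
    ptsd_dx, cytokine_panel.
    """

    data: pd.DataFrame
    subjects: pd.DataFrame
    config: CohortConfig | None = None

    def wide(
        self, timepoint: str, group: str | None = None,
        measures: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Subject x measure matrix at one timepoint (NaN where missing)."""
        sel = self.data[self.data["timepoint"] == timepoint]
        if group is not None:
            sel = sel[sel["group"] == group]
        if measures is not None:
            sel = sel[sel["measure"].isin(measures)]
        return sel.pivot_table(
            index="subject_id", columns="measure", values="value",
            aggfunc="first", dropna=False,
        )

    def group_values(self, measure: str, timepoint: str) -> dict[str, np.ndarray]:
        """Non-missing values per group for one measure at one timepoint."""
        sel = self.data[
            (self.data["measure"] == measure)
            & (self.data["timepoint"] == timepoint)
            & self.data["value"].notna()
        ]
        return {
            g: sub["value"].to_numpy()
            for g, sub in sel.groupby("group", observed=True)
        }

    def write_csv(self, path: str | Path) -> None:
        """Write the tidy table; config provenance goes to a JSON sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        self.subjects.to_csv(path.with_suffix(".subjects.csv"), index=False)
        if self.config is not None:
            sidecar = path.with_suffix(".config.json")
            sidecar.write_text(
                json.dumps(config_to_dict(self.config), indent=2, sort_keys=True)
            )

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path)
        subjects_path = path.with_suffix(".subjects.csv")
        if subjects_path.exists():
            subjects = pd.read_csv(subjects_path)
        else:
            subjects = (
                data[["subject_id", "site", "group"]]
                .drop_duplicates()
                .reset_index(drop=True)
            )
        config = None
        sidecar = path.with_suffix(".config.json")
        if sidecar.exists():
            config = config_from_dict(json.loads(sidecar.read_text()))
        return cls(data=data, subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# serialization helpers (YAML / JSON round trip of CohortConfig)
# ---------------------------------------------------------------------------

def config_to_dict(config: CohortConfig) -> dict:
    def effect_dict(eff):
        eff = _as_effect(eff)
        return {"shift": eff.shift, "sd_ratio": eff.sd_ratio}

    return {
        "group_sizes": dict(config.group_sizes),
        "site_split": config.site_split,
        "hc_exercise_fraction": config.hc_exercise_fraction,
        "timepoints": list(config.timepoints),
        "within_subject_rho": config.within_subject_rho,
        "missing_rate": config.missing_rate,
        "duplicate_cv": config.duplicate_cv,
        "panel16_fraction": config.panel16_fraction,
        "label_noise": config.label_noise,
        "seed": config.seed,
        "measure_catalog": [
            {
                "name": s.name,
                "family": s.family,
                "baseline_mean": s.baseline_mean,
                "baseline_sd": s.baseline_sd,
                "panel": s.panel,
                "bounds": list(s.bounds) if s.bounds is not None else None,
            }
            for s in config.measure_catalog
        ],
        "effect_map": {
            meas: {
                grp: {tp: effect_dict(eff) for tp, eff in per_grp.items()}
                for grp, per_grp in per_meas.items()
            }
            for meas, per_meas in config.effect_map.items()
        },
        "latent_network": {
            "|".join(key) if isinstance(key, tuple) else key:
                np.asarray(mat, dtype=float).tolist()
            for key, mat in config.latent_network.items()
        },
    }


def config_from_dict(payload: Mapping) -> CohortConfig:
    catalog = [
        MeasureSpec(
            name=item["name"],
            family=item["family"],
            baseline_mean=item["baseline_mean"],
            baseline_sd=item["baseline_sd"],
            panel=item.get("panel"),
            bounds=tuple(item["bounds"]) if item.get("bounds") else None,
        )
        for item in payload.get("measure_catalog", [])
    ]
    effect_map = {
        meas: {
            grp: {
                tp: Effect(eff["shift"], eff.get("sd_ratio", 1.0))
                for tp, eff in per_grp.items()
            }
            for grp, per_grp in per_meas.items()
        }
        for meas, per_meas in payload.get("effect_map", {}).items()
    }
    latent = {}
    for key, mat in payload.get("latent_network", {}).items():
        parsed = tuple(key.split("|")) if "|" in key else key
        latent[parsed] = np.asarray(mat, dtype=float)
    return CohortConfig(
        measure_catalog=catalog,
        group_sizes=dict(payload.get("group_sizes", {"HC": 44, "GWI_L": 29, "GWI_H": 47})),
        site_split=payload.get("site_split", 0.67),
        hc_exercise_fraction=payload.get("hc_exercise_fraction", 1.0),
        timepoints=tuple(payload.get("timepoints", ("T0", "T1", "T2"))),
        effect_map=effect_map,
        latent_network=latent,
        within_subject_rho=payload.get("within_subject_rho", 0.5),
        missing_rate=payload.get("missing_rate", 0.0),
        duplicate_cv=payload.get("duplicate_cv", 0.10),
        panel16_fraction=payload.get("panel16_fraction", 0.43),
        label_noise=payload.get("label_noise", 0.0),
        seed=payload.get("seed", 0),
    )


def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def config_from_yaml(path: str | Path) -> CohortConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_dts(rng: np.random.Generator, group: str, n: int) -> np.ndarray:
    """DTS totals consistent with the subgrouping rule (cut at 70)."""
    if group == "GWI_H":
        raw = 70 + np.abs(rng.normal(25.0, 15.0, size=n))
        return np.clip(np.rint(raw), 70, DTS_MAX).astype(int)
    mu, sigma = (30.0, 18.0) if group == "GWI_L" else (10.0, 8.0)
    raw = np.abs(rng.normal(mu, sigma, size=n))
    return np.clip(np.rint(raw), 0, 69).astype(int)


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a cohort per ``config``; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = list(config.measure_catalog)
    names = [s.name for s in specs]
    m = len(specs)
    tps = list(config.timepoints)
    n_tp = len(tps)

    subject_rows = []
    value_frames = []
    counter = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        frac = (
            config.hc_exercise_fraction if group == "HC" else config.site_split
        )
        n_exercise = int(round(frac * n))
        sites = np.array(
            [EXERCISE_SITE] * n_exercise + [REST_ONLY_SITE] * (n - n_exercise)
        )
        subject_ids = [f"S{counter + i:04d}" for i in range(n)]
        counter += n

        dts = np.full(n, -1, dtype=int)
        ptsd = np.zeros(n, dtype=bool)
        exercise_mask = sites == EXERCISE_SITE
        dts_vals = _draw_dts(rng, group, int(exercise_mask.sum()))
        if config.label_noise > 0 and group != "HC":
            flip = rng.uniform(size=dts_vals.size) < config.label_noise
            dts_vals = np.where(
                flip,
                np.where(dts_vals >= 70, 69, 70),
                dts_vals,
            )
        dts[exercise_mask] = dts_vals
        rest_mask = ~exercise_mask
        ptsd[rest_mask] = group == "GWI_H"
        if config.label_noise > 0 and group != "HC":
            flip = rng.uniform(size=int(rest_mask.sum())) < config.label_noise
            ptsd[rest_mask] ^= flip

        panel = np.where(
            rng.uniform(size=n) < config.panel16_fraction, "16plex", "18plex"
        )

        # latent draws: shared subject effect + per-timepoint innovation,
        # pushed through the per-timepoint copula Cholesky factor
        w = config.within_subject_rho
        shared = rng.standard_normal((n, m))
        z_by_tp = {}
        for tp in tps:
            innov = rng.standard_normal((n, m))
            z = np.sqrt(w) * shared + np.sqrt(1.0 - w) * innov
            target = config.latent_for(group, tp)
            if target is not None:
                pearson = spearman_to_pearson(target)
                np.fill_diagonal(pearson, 1.0)
                pearson = nearest_correlation(pearson)
                chol = np.linalg.cholesky(
                    pearson + 1e-12 * np.eye(m)
                )
                z = z @ chol.T
            z_by_tp[tp] = z

        # symptom questionnaires are filled in once per subject; reuse T0 draw
        symptom_idx = [i for i, s in enumerate(specs) if s.family == "symptom"]
        for tp in tps[1:]:
            z_by_tp[tp][:, symptom_idx] = z_by_tp[tps[0]][:, symptom_idx]

        for i_tp, tp in enumerate(tps):
            z = z_by_tp[tp]
            values = np.empty((n, m))
            for j, spec in enumerate(specs):
                eff = config.effect_for(spec.name, group, tp)
                vals = spec.baseline_mean + spec.baseline_sd * (
                    eff.shift + eff.sd_ratio * z[:, j]
                )
                if spec.bounds is not None:
                    lo, hi = spec.bounds
                    vals = np.clip(
                        vals,
                        -np.inf if lo is None else lo,
                        np.inf if hi is None else hi,
                    )
                values[:, j] = vals
            # symptom values identical across timepoints by construction
            if i_tp > 0:
                values[:, symptom_idx] = value_frames_group[0][:, symptom_idx]
            if i_tp == 0:
                value_frames_group = [values]
            else:
                value_frames_group.append(values)

            if config.missing_rate > 0:
                mask = rng.uniform(size=(n, m)) < config.missing_rate
                values = values.copy()
                values[mask] = np.nan

            # rest-only subjects: no exercise timepoints at all
            available = exercise_mask if tp != tps[0] else np.ones(n, bool)
            frame = pd.DataFrame(
                {
                    "subject_id": np.repeat(subject_ids, m),
                    "site": np.repeat(sites, m),
                    "group": group,
                    "timepoint": tp,
                    "measure": np.tile(names, n),
                    "family": np.tile([s.family for s in specs], n),
                    "panel": np.tile(
                        np.array(
                            [s.panel if s.family == "cytokine" else np.nan
                             for s in specs],
                            dtype=object,
                        ),
                        n,
                    ),
                    "value": values.ravel(),
                }
            )
            frame = frame[np.repeat(available, m)]
            # 18plex-only analytes are unavailable for 16plex subjects & v.v.
            subj_panel = dict(zip(subject_ids, panel))
            meas_panel = frame["panel"].to_numpy()
            subj_assay = frame["subject_id"].map(subj_panel).to_numpy()
            incompatible = (
                ((meas_panel == "18plex") & (subj_assay == "16plex"))
                | ((meas_panel == "16plex") & (subj_assay == "18plex"))
            )
            frame = frame[~incompatible]
            value_frames.append(frame)

        subject_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "site": sites,
                    "group": group,
                    "dts_total": np.where(exercise_mask, dts, pd.NA),
                    "ptsd_dx": np.where(rest_mask, ptsd, pd.NA),
                    "cytokine_panel": panel,
                }
            )
        )

    data = pd.concat(value_frames, ignore_index=True)
    subjects = pd.concat(subject_rows, ignore_index=True)
    return CohortTable(data=data, subjects=subjects, config=config)


def generate_duplicate_wells(
    true_conc: float,
    curve,
    cv: float,
    seed: int | np.random.Generator = 0,
    n_wells: int = 2,
) -> np.ndarray:
    """Simulate duplicate well signals for a known concentration.

    Multiplicative signal noise with the given coefficient of variation; the
    expected signal equals the noiseless curve evaluation, so back-calculated
    concentrations average to the truth in expectation (to first order in cv).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    lo, hi = curve.calibrated_range
    if not lo <= true_conc <= hi:
        raise ValueError(
            f"true_conc {true_conc} outside calibrated range [{lo}, {hi}]"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    signal = curve.evaluate(true_conc)
    noise = rng.normal(0.0, cv, size=n_wells) if cv > 0 else np.zeros(n_wells)
    return signal * (1.0 + noise)
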