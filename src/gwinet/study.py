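"""The shipped demo study conditions.

This module encodes the cohort design the package was built around: three
trauma-defined arms (HC n=44, GWI_L n=29, GWI_H n=47), a two-site structure
in which only exercise-site subjects contribute the T1 (peak exercise) and
T2 (4 h post) timepoints, and group mean shifts programmed from the reported
group means +/- SEM of the measures that separated the arms (IL-15 across the
exercise challenge; basophil % and hematocrit at peak exercise; RDW, CD2+%,
CD3-CD56+ counts at rest; CD2+CD26+% and CD8+CD26+% at peak exercise).

SEMs are converted to SDs via SD = SEM * sqrt(n) using each group's n at that
timepoint; the exercise-site subgroup sizes at T1/T2 (not separately
reported) are taken proportional to the overall GWI_H:GWI_L split, giving
HC 44 / GWI_L 20 / GWI_H 31. Healthy-control baselines that the source
tables do not print (symptom scales, cytokines without group differences)
are set to typical values for sedentary middle-aged male veterans.

Group-specific latent Spearman networks couple fatigue scales, NK biology
(IL-15 -> NK counts -> cytotoxicity) and blood indices, with a handful of
group-specific immune-symptom edges so that the three correlation graphs are
genuinely different objects for the edit-distance comparison.
"""

from __future__ import annotations

import math

from .cohort import CohortConfig, Effect, MeasureSpec, latent_from_edges

__all__ = ["default_study_config", "N_T1", "GROUP_SIZES"]

GROUP_SIZES = {"HC": 44, "GWI_L": 29, "GWI_H": 47}
# exercise-site (T1/T2) group sizes implied by site_split ~ 51/76
N_T1 = {"HC": 44, "GWI_L": 20, "GWI_H": 31}


def _sd(sem: float, n: int) -> float:
    return sem * math.sqrt(n)


def default_study_config(seed: int = 2024, missing_rate: float = 0.05) -> CohortConfig:
    """Build the full demo cohort configuration."""
    catalog = [
        # symptoms (0-100 composite scores, measured once per subject)
        MeasureSpec("MFI_general_fatigue", "symptom", 30.0, 18.0, bounds=(0, 100)),
        MeasureSpec("MFI_mental_fatigue", "symptom", 28.0, 18.0, bounds=(0, 100)),
        MeasureSpec("MFI_reduced_motivation", "symptom", 25.0, 16.0, bounds=(0, 100)),
        MeasureSpec("SF36_physical_role", "symptom", 85.0, 25.0, bounds=(0, 100)),
        MeasureSpec("SF36_vitality", "symptom", 65.0, 18.0, bounds=(0, 100)),
        MeasureSpec("SF36_social_functioning", "symptom", 85.0, 18.0, bounds=(0, 100)),
        # cytokines on the harmonized [0, 1] reporting scale
        MeasureSpec("IL-15", "cytokine", 0.24, _sd(0.03, 44), panel="both"),
        MeasureSpec("IL-1b", "cytokine", 0.14, _sd(0.02, 44), panel="both"),
        MeasureSpec("IL-6", "cytokine", 0.20, 0.15, panel="both"),
        MeasureSpec("IL-8", "cytokine", 0.35, 0.20, panel="both"),
        MeasureSpec("TNFa", "cytokine", 0.25, 0.15, panel="both"),
        MeasureSpec("TNF-RI", "cytokine", 0.50, 0.20, panel="18plex"),
        # complete blood count
        MeasureSpec("basophil_pct", "cbc", 0.50, 0.30, bounds=(0, 100)),
        MeasureSpec("RDW", "cbc", 12.74, _sd(0.12, 44)),
        MeasureSpec("HCT", "cbc", 46.5, 3.5, bounds=(0, 100)),
        MeasureSpec("HGB", "cbc", 14.8, 1.0, bounds=(0, None)),
        # flow cytometry
        MeasureSpec("CD2_pct", "flow", 82.76, _sd(0.71, 44), bounds=(0, 100)),
        MeasureSpec("CD3neg_CD56pos_count", "flow", 201.48, _sd(17.94, 44),
                    bounds=(0, None)),
        MeasureSpec("CD2_CD26_pct", "flow", 36.0, 10.0, bounds=(0, 100)),
        MeasureSpec("CD8_CD26_pct", "flow", 8.5, 4.5, bounds=(0, 100)),
        # NK function and hormones
        MeasureSpec("NK_cytotoxicity_pct", "nk_activity", 20.0, 8.0,
                    bounds=(0, 100)),
        MeasureSpec("cortisol", "hormone", 0.30, 0.15, bounds=(0, None)),
        MeasureSpec("testosterone", "hormone", 500.0, 160.0, bounds=(0, None)),
    ]
    spec_by_name = {s.name: s for s in catalog}

    def eff(measure: str, mean: float, sem: float, n: int) -> Effect:
        """Effect from a reported group mean +/- SEM at group size n."""
        base = spec_by_name[measure]
        sd = _sd(sem, n)
        return Effect(
            shift=(mean - base.baseline_mean) / base.baseline_sd,
            sd_ratio=sd / base.baseline_sd,
        )

    effect_map = {
        # symptom scales: reported GWI values vs chosen HC baselines
        "MFI_general_fatigue": {
            "GWI_L": {"*": eff("MFI_general_fatigue", 60.42, 4.71, 29)},
            "GWI_H": {"*": eff("MFI_general_fatigue", 78.53, 2.73, 47)},
        },
        "MFI_mental_fatigue": {
            "GWI_L": {"*": eff("MFI_mental_fatigue", 58.48, 5.42, 29)},
            "GWI_H": {"*": eff("MFI_mental_fatigue", 76.55, 2.94, 47)},
        },
        "MFI_reduced_motivation": {
            "GWI_L": {"*": eff("MFI_reduced_motivation", 44.12, 4.91, 29)},
            "GWI_H": {"*": eff("MFI_reduced_motivation", 61.45, 3.46, 47)},
        },
        "SF36_physical_role": {
            "GWI_L": {"*": eff("SF36_physical_role", 43.89, 7.28, 29)},
            "GWI_H": {"*": eff("SF36_physical_role", 22.42, 4.12, 47)},
        },
        "SF36_vitality": {
            "GWI_L": {"*": eff("SF36_vitality", 33.75, 4.45, 29)},
            "GWI_H": {"*": eff("SF36_vitality", 20.68, 2.36, 47)},
        },
        "SF36_social_functioning": {
            "GWI_L": {"*": eff("SF36_social_functioning", 57.59, 5.90, 29)},
            "GWI_H": {"*": eff("SF36_social_functioning", 32.61, 3.76, 47)},
        },
        # IL-15: GWI_L depressed at every timepoint; GWI_H at control level
        "IL-15": {
            "HC": {
                "T1": eff("IL-15", 0.30, 0.04, 44),
                "T2": eff("IL-15", 0.22, 0.02, 44),
            },
            "GWI_L": {
                "T0": eff("IL-15", 0.15, 0.02, 29),
                "T1": eff("IL-15", 0.17, 0.01, N_T1["GWI_L"]),
                "T2": eff("IL-15", 0.14, 0.01, N_T1["GWI_L"]),
            },
            "GWI_H": {
                "T0": eff("IL-15", 0.22, 0.03, 47),
                "T1": eff("IL-15", 0.29, 0.04, N_T1["GWI_H"]),
                "T2": eff("IL-15", 0.22, 0.03, N_T1["GWI_H"]),
            },
        },
        "IL-1b": {
            "GWI_L": {"T0": eff("IL-1b", 0.08, 0.01, 29)},
            "GWI_H": {"T0": eff("IL-1b", 0.13, 0.03, 47)},
        },
        # basophils halved in both GWI arms at peak exercise only
        "basophil_pct": {
            "HC": {"T1": eff("basophil_pct", 0.40, 0.07, 44)},
            "GWI_L": {"T1": eff("basophil_pct", 0.15, 0.03, N_T1["GWI_L"])},
            "GWI_H": {"T1": eff("basophil_pct", 0.19, 0.03, N_T1["GWI_H"])},
        },
        "RDW": {
            "GWI_L": {"*": eff("RDW", 13.33, 0.24, 29)},
            "GWI_H": {"*": eff("RDW", 13.29, 0.16, 47)},
        },
        "HCT": {
            "HC": {"T1": eff("HCT", 47.23, 0.58, 44)},
            "GWI_H": {"T1": eff("HCT", 44.88, 0.48, N_T1["GWI_H"])},
        },
        "CD2_pct": {
            "GWI_L": {"*": eff("CD2_pct", 78.05, 1.82, 29)},
            "GWI_H": {"*": eff("CD2_pct", 78.54, 1.10, 47)},
        },
        "CD3neg_CD56pos_count": {
            "GWI_L": {"*": eff("CD3neg_CD56pos_count", 161.24, 12.47, 29)},
            "GWI_H": {"*": eff("CD3neg_CD56pos_count", 148.00, 11.44, 47)},
        },
        "CD2_CD26_pct": {
            "GWI_L": {"T1": eff("CD2_CD26_pct", 49.12, 3.05, N_T1["GWI_L"])},
            "GWI_H": {"T1": eff("CD2_CD26_pct", 39.64, 1.98, N_T1["GWI_H"])},
        },
        "CD8_CD26_pct": {
            "GWI_L": {"T1": eff("CD8_CD26_pct", 15.92, 2.47, N_T1["GWI_L"])},
        },
        # reduced NK lytic function for GWI_L at peak exercise
        "NK_cytotoxicity_pct": {
            "GWI_L": {"T1": Effect(shift=-0.60)},
            "GWI_H": {"T1": Effect(shift=-0.25)},
        },
    }

    names = [s.name for s in catalog]
    shared_edges = [
        ("MFI_general_fatigue", "MFI_mental_fatigue", 0.60),
        ("MFI_general_fatigue", "MFI_reduced_motivation", 0.50),
        ("SF36_vitality", "SF36_social_functioning", 0.50),
        ("SF36_physical_role", "SF36_vitality", 0.45),
        ("HCT", "HGB", 0.70),
        ("IL-1b", "TNFa", 0.40),
        ("IL-15", "CD3neg_CD56pos_count", 0.45),
        ("CD3neg_CD56pos_count", "NK_cytotoxicity_pct", 0.50),
    ]
    latent = {
        "HC": latent_from_edges(
            names,
            shared_edges
            + [("IL-6", "IL-8", 0.40),
               ("NK_cytotoxicity_pct", "SF36_physical_role", -0.43)],
        ),
        "GWI_H": latent_from_edges(
            names,
            shared_edges
            + [("IL-6", "IL-8", 0.40),
               ("IL-15", "MFI_general_fatigue", -0.42)],
        ),
        # GWI_L: rewired inflammatory block plus CD26/fatigue coupling
        "GWI_L": latent_from_edges(
            names,
            shared_edges
            + [("IL-6", "TNFa", 0.40),
               ("CD8_CD26_pct", "MFI_general_fatigue", -0.60),
               ("CD8_CD26_pct", "MFI_reduced_motivation", -0.55)],
        ),
    }

    return CohortConfig(
        measure_catalog=catalog,
        group_sizes=dict(GROUP_SIZES),
        site_split=0.67,
        hc_exercise_fraction=1.0,
        timepoints=("T0", "T1", "T2"),
        effect_map=effect_map,
        latent_network=latent,
        within_subject_rho=0.5,
        missing_rate=missing_rate,
        duplicate_cv=0.10,
        panel16_fraction=0.43,
        seed=seed,
    )
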