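"""Simulation experiments that characterize the pipeline's operating behavior.

Each function runs a self-contained study on synthetic data and returns
summary rates: type-I error of the omnibus screen, false-edge control of the
FDR-filtered correlation graphs, qualitative recovery of the programmed
group-difference pattern, separation of a perturbed latent network in the
edit-distance comparison, and removal of a programmed two-panel batch shift.
They are consumed by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import generate_cohort, nearest_correlation, spearman_to_pearson
from .corrnet import build_graph
from .ged import WEIGHT_DIFFERENCE, ged_fixed_nodes
from .groupstats import screen_measures, welch_anova_many
from .harmonize import harmonize_panels
from .study import default_study_config

__all__ = [
    "null_omnibus_type1",
    "false_edge_rate",
    "pattern_recovery",
    "ged_outlier_rate",
    "batch_shift_residual",
]


def null_omnibus_type1(
    n_replicates: int = 10_000,
    group_sizes: tuple[int, ...] = (44, 29, 47),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null measures rejected by the Welch omnibus screen."""
    rng = np.random.default_rng(seed)
    groups = [rng.standard_normal((n, n_replicates)) for n in group_sizes]
    _, p = welch_anova_many(groups)
    return float((p < alpha).mean())


def false_edge_rate(
    n_seeds: int = 200,
    n_subjects: int = 44,
    n_measures: int = 40,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean proportion of tested pairs kept as edges under an identity network."""
    rates = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        data = pd.DataFrame(
            rng.standard_normal((n_subjects, n_measures)),
            columns=[f"v{i}" for i in range(n_measures)],
        )
        graph = build_graph(data, q_threshold=q_threshold)
        rates.append(graph.n_edges / len(graph.tested))
    return float(np.mean(rates))


def pattern_recovery(n_seeds: int = 200, seed: int = 0) -> dict:
    """Recovery of the programmed group-difference pattern at peak exercise.

    Per seed: generate the demo cohort and screen IL-15 and basophil % at T1.
    Records, per seed, whether the IL-15 GWI_L < HC contrast is significant,
    whether it is significant with the estimated effect in the medium bin,
    and whether both GWI subgroups show significant basophil reductions;
    also collects the estimated IL-15 GWI_L vs HC Hedges g.
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    il15_sig, il15_sig_medium, basophil_both, gs = [], [], [], []
    for s in rng_seeds:
        cohort = generate_cohort(default_study_config(seed=int(s)))
        res = screen_measures(cohort, "T1", measures=["IL-15", "basophil_pct"])
        pw = res.pairwise
        sig = med = both = False
        if len(pw):
            il = pw[
                (pw["measure"] == "IL-15")
                & (pw["group_i"] == "HC")
                & (pw["group_j"] == "GWI_L")
            ]
            if len(il):
                row = il.iloc[0]
                sig = bool(row["significant"] and row["mean_diff"] > 0)
                med = bool(sig and row["g_bin"] == "medium")
                gs.append(float(row["g"]))
            ba = pw[pw["measure"] == "basophil_pct"]

            def _reduced(gj):
                s = ba[(ba["group_i"] == "HC") & (ba["group_j"] == gj)]
                return len(s) > 0 and bool(
                    s.iloc[0]["significant"] and s.iloc[0]["mean_diff"] > 0
                )

            both = _reduced("GWI_L") and _reduced("GWI_H")
        il15_sig.append(sig)
        il15_sig_medium.append(med)
        basophil_both.append(both)
    joint = [a and b for a, b in zip(il15_sig_medium, basophil_both)]
    return {
        "n_seeds": n_seeds,
        "il15_significant_rate": float(np.mean(il15_sig)),
        "il15_significant_medium_rate": float(np.mean(il15_sig_medium)),
        "basophil_both_reduced_rate": float(np.mean(basophil_both)),
        "strict_joint_rate": float(np.mean(joint)),
        "median_il15_g": float(np.median(gs)) if gs else float("nan"),
    }


def ged_outlier_rate(
    n_seeds: int = 200,
    n_subjects: int = 44,
    n_measures: int = 12,
    n_edges: int = 8,
    seed: int = 0,
) -> float:
    """Three-group comparison with one perturbed latent network.

    Two groups share a latent Spearman network; the third uses an
    independently drawn one. Returns the fraction of seeds in which the
    perturbed group's mean edit distance to the matched pair exceeds the
    distance between the two matched groups.
    """
    from .cohort import generate_latent_network

    base = generate_latent_network(n_measures, n_edges, (0.45, 0.6), seed=seed + 1)
    pert = generate_latent_network(
        n_measures, n_edges, (0.45, 0.6), seed=seed + 10_001
    )
    names = [f"v{i}" for i in range(n_measures)]

    def chol(net):
        p = nearest_correlation(spearman_to_pearson(net))
        return np.linalg.cholesky(p + 1e-12 * np.eye(n_measures))

    l_base, l_pert = chol(base), chol(pert)
    wins = 0
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)

        def sample(L):
            return pd.DataFrame(
                rng.standard_normal((n_subjects, n_measures)) @ L.T,
                columns=names,
            )

        g_a = build_graph(sample(l_base), "A", "T0")
        g_b = build_graph(sample(l_base), "B", "T0")
        g_c = build_graph(sample(l_pert), "C", "T0")
        d_ab = ged_fixed_nodes(g_a, g_b, WEIGHT_DIFFERENCE).distance
        d_ca = ged_fixed_nodes(g_c, g_a, WEIGHT_DIFFERENCE).distance
        d_cb = ged_fixed_nodes(g_c, g_b, WEIGHT_DIFFERENCE).distance
        wins += (d_ca + d_cb) / 2.0 > d_ab
    return wins / n_seeds


def batch_shift_residual(
    n_per_panel: int = 500,
    scale: float = 2.0,
    offset: float = 5.0,
    seed: int = 0,
) -> float:
    """Residual per-panel mean gap after harmonizing a programmed batch shift."""
    rng = np.random.default_rng(seed)
    base16 = rng.normal(10.0, 3.0, size=n_per_panel)
    base18 = rng.normal(10.0, 3.0, size=n_per_panel)
    p16 = pd.DataFrame(
        {"analyte": scale * base16 + offset},
        index=[f"a{i}" for i in range(n_per_panel)],
    )
    p18 = pd.DataFrame(
        {"analyte": base18}, index=[f"b{i}" for i in range(n_per_panel)]
    )
    result = harmonize_panels(p16, p18)
    values = result.values["analyte"]
    prov = result.provenance["analyte"]
    return float(
        abs(values[prov == "16plex"].mean() - values[prov == "18plex"].mean())
    )
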