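"""Cross-panel harmonization of multiplex cytokine measurements.

Two panel generations (a 16-plex and an 18-plex sharing 15 analytes) report
concentrations on different effective scales, so raw values cannot be pooled.
The harmonization pipeline, applied per analyte:

1. z-score each panel's values separately (sample SD, ddof=1);
2. map the 16-plex z-scores onto the 18-plex scale by reversing the z-score
   with the 18-plex mean and SD;
3. concatenate and min-max normalize the combined vector to [0, 1].

Each step is univariate and affine on the non-missing entries, so within-panel
rank order is preserved exactly and between-panel location/scale differences
are removed. Missing values pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateAnalyteError",
    "HarmonizedPanel",
    "zscore_within_panel",
    "rescale_to_reference",
    "minmax_normalize",
    "harmonize_panels",
]


class DegenerateAnalyteError(ValueError):
    """Raised when an analyte has too little spread to standardize."""


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D per-analyte vector")
    return arr


def zscore_within_panel(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (ddof=1) over non-missing entries."""
    arr = _clean(values)
    ok = ~np.isnan(arr)
    if ok.sum() < 2:
        raise DegenerateAnalyteError(
            "need >= 2 non-missing values to z-score"
        )
    mean = arr[ok].mean()
    sd = arr[ok].std(ddof=1)
    if sd == 0:
        raise DegenerateAnalyteError("zero spread; analyte withheld from merging")
    out = arr.copy()
    out[ok] = (arr[ok] - mean) / sd
    return out


def rescale_to_reference(z16, mean18: float, sd18: float) -> np.ndarray:
    """Reverse the z-score using the reference panel's moments: z*sd + mean."""
    if not sd18 > 0:
        raise ValueError("reference SD must be > 0")
    return _clean(z16) * sd18 + mean18


def minmax_normalize(values) -> np.ndarray:
    """Map non-missing entries to [0, 1] by (x - min)/(max - min)."""
    arr = _clean(values)
    ok = ~np.isnan(arr)
    if not ok.any():
        return arr.copy()
    lo, hi = arr[ok].min(), arr[ok].max()
    if hi == lo:
        raise DegenerateAnalyteError("max equals min; cannot min-max normalize")
    out = arr.copy()
    out[ok] = (arr[ok] - lo) / (hi - lo)
    return out


@dataclass
class HarmonizedPanel:
    """Unified cytokine matrix on [0, 1] with per-cell panel provenance."""

    values: pd.DataFrame  # subject x analyte, on [0, 1]
    provenance: pd.DataFrame  # subject x analyte, "16plex"/"18plex"/NaN
    scaling_params: dict[str, dict] = field(default_factory=dict)
    degenerate_analytes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def harmonize_panels(
    panel16: pd.DataFrame | None,
    panel18: pd.DataFrame | None,
    minmax_scope: str = "per_analyte",
) -> HarmonizedPanel:
    """Merge two panel matrices (subjects x analytes) onto a common [0, 1] scale.

    Analytes are matched by exact column name. Analytes present in only one
    panel (or with < 2 usable values in one panel) are carried through from
    the populated panel alone, with a warning. ``minmax_scope`` is
    ``"per_analyte"`` (default) or ``"global"`` (one min-max over all analytes
    jointly).
    """
    if minmax_scope not in ("per_analyte", "global"):
        raise ValueError("minmax_scope must be 'per_analyte' or 'global'")
    p16 = pd.DataFrame() if panel16 is None else panel16.astype(float)
    p18 = pd.DataFrame() if panel18 is None else panel18.astype(float)
    if not p16.empty and not p18.empty:
        overlap = p16.index.intersection(p18.index)
        if len(overlap):
            raise ValueError(
                f"subjects measured on both panels: {list(overlap)[:5]}"
            )
    analytes = list(dict.fromkeys([*p16.columns, *p18.columns]))
    index = p16.index.append(p18.index)

    merged = pd.DataFrame(np.nan, index=index, columns=analytes)
    provenance = pd.DataFrame(np.nan, index=index, columns=analytes, dtype=object)
    scaling: dict[str, dict] = {}
    degenerate: list[str] = []
    warnings: list[str] = []

    for analyte in analytes:
        v16 = p16[analyte].to_numpy() if analyte in p16.columns else np.array([])
        v18 = p18[analyte].to_numpy() if analyte in p18.columns else np.array([])
        n16 = int(np.sum(~np.isnan(v16))) if v16.size else 0
        n18 = int(np.sum(~np.isnan(v18))) if v18.size else 0
        params: dict = {"n16": n16, "n18": n18}
        try:
            if n16 >= 2 and n18 >= 2:
                z16 = zscore_within_panel(v16)
                ok18 = ~np.isnan(v18)
                mean18 = float(v18[ok18].mean())
                sd18 = float(v18[ok18].std(ddof=1))
                if sd18 == 0:
                    raise DegenerateAnalyteError("18plex panel has zero spread")
                scaled16 = rescale_to_reference(z16, mean18, sd18)
                combined = np.concatenate([scaled16, v18])
                ok16 = ~np.isnan(v16)
                params.update(
                    mean16=float(v16[ok16].mean()),
                    sd16=float(v16[ok16].std(ddof=1)),
                    mean18=mean18, sd18=sd18,
                )
            elif n18 >= 2 or (n18 and not n16):
                combined = np.concatenate([np.full(len(p16.index), np.nan), v18]) \
                    if len(p16.index) else v18
                warnings.append(
                    f"{analyte}: merged from 18plex only (n16={n16})"
                )
            elif n16 >= 2 or (n16 and not n18):
                combined = np.concatenate([v16, np.full(len(p18.index), np.nan)]) \
                    if len(p18.index) else v16
                warnings.append(
                    f"{analyte}: merged from 16plex only (n18={n18})"
                )
            else:
                raise DegenerateAnalyteError("too few values in either panel")

            if minmax_scope == "per_analyte":
                ok = ~np.isnan(combined)
                lo, hi = combined[ok].min(), combined[ok].max()
                params.update(min_combined=float(lo), max_combined=float(hi))
                normalized = minmax_normalize(combined)
            else:
                normalized = combined  # deferred to the joint pass below
        except DegenerateAnalyteError as err:
            degenerate.append(analyte)
            warnings.append(f"{analyte}: degenerate ({err}); withheld")
            scaling[analyte] = params
            continue

        merged[analyte] = normalized
        prov = np.where(
            np.arange(len(index)) < len(p16.index), "16plex", "18plex"
        ).astype(object)
        prov[np.isnan(normalized)] = np.nan
        if v16.size == 0:
            prov[: len(p16.index)] = np.nan
        if v18.size == 0:
            prov[len(p16.index):] = np.nan
        provenance[analyte] = prov
        scaling[analyte] = params

    if minmax_scope == "global":
        arr = merged.to_numpy()
        ok = ~np.isnan(arr)
        if ok.any():
            lo, hi = arr[ok].min(), arr[ok].max()
            if hi == lo:
                raise DegenerateAnalyteError("global max equals min")
            merged = (merged - lo) / (hi - lo)
            for analyte in merged.columns:
                scaling.setdefault(analyte, {}).update(
                    min_combined=float(lo), max_combined=float(hi)
                )

    return HarmonizedPanel(
        values=merged,
        provenance=provenance,
        scaling_params=scaling,
        degenerate_analytes=degenerate,
        warnings=warnings,
    )
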