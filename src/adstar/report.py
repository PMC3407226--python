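"""Reporting surfaces: percent change in relative rate and spatial classes.

Under the log link a dummy coefficient beta corresponds to a multiplicative
change exp(beta) in the visit rate relative to the reference level; it is
reported as 100*(exp(beta) - 1) percent with a Wald 95% CI transformed from
the log scale.  District spatial effects are classified three ways by the
posterior probability (under the approximate Gaussian posterior) that the
relative rate exceeds 1: positive / negative when at least 80% of the mass
lies above / below 1, non-significant otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FitResult

__all__ = [
    "percent_change",
    "effect_report",
    "classify_spatial",
    "report_tables",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.8
Z95 = 1.96


def percent_change(coef: float, se: float) -> dict:
    """Percent change in rate for a log-link coefficient, with 95% CI.

    point = 100*(exp(coef)-1); CI endpoints transform coef +/- 1.96*se;
    p is the two-sided normal Wald p-value (1.0 when se is 0 and coef is 0).
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    point = 100.0 * np.expm1(coef)
    lo = 100.0 * np.expm1(coef - Z95 * se)
    hi = 100.0 * np.expm1(coef + Z95 * se)
    if se == 0:
        p = 0.0 if coef != 0 else 1.0
    else:
        p = 2.0 * stats.norm.sf(abs(coef) / se)
    return {"percent": float(point), "lo": float(lo), "hi": float(hi),
            "p": float(p)}


def effect_report(result: FitResult) -> pd.DataFrame:
    """Percent-change table for all DOW and DSLI dummies of a fit."""
    fx = result.fixed_effects()
    fx = fx[fx["term"].isin(["dow", "dsli"])]
    rows = []
    for _, r in fx.iterrows():
        pc = percent_change(r["coef"], r["se"])
        rows.append({"term": r["term"], "variable": r["variable"], **pc})
    return pd.DataFrame(rows)


def classify_spatial(
    result: FitResult, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Three-way classification of district spatial effects.

    For each district the marginal posterior of the effect is N(mean, sd^2);
    p_above_1 = P(RR > 1) = P(effect > 0).  Class is ``positive`` when
    p_above_1 >= threshold, ``negative`` when 1 - p_above_1 >= threshold,
    otherwise ``nonsignificant``.
    """
    if not (0.5 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0.5, 1), got {threshold}")
    eff = result.spatial_effects()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(eff["sd"] > 0, eff["effect"] / eff["sd"],
                     np.inf * np.sign(eff["effect"]))
    z = np.where((eff["sd"].to_numpy() == 0) & (eff["effect"].to_numpy() == 0),
                 0.0, z)
    p_above = stats.norm.cdf(z)
    cls = np.where(
        p_above >= threshold,
        "positive",
        np.where(1.0 - p_above >= threshold, "negative", "nonsignificant"),
    )
    return pd.DataFrame(
        {
            "district": eff["district"],
            "effect": eff["effect"],
            "rr": np.exp(eff["effect"]),
            "sd": eff["sd"],
            "p_above_1": p_above,
            "class": cls,
        }
    )


def report_tables(
    results: Mapping[str, FitResult] | FitResult,
    outdir: Union[str, Path],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, Path]:
    """Write effect / spatial CSVs and a plain-text summary per age group.

    Emits ``effects_<group>.csv`` (variable, percent change, CI, p),
    ``spatial_<group>.csv`` and ``summary.txt``.  Numbers in the summary are
    formatted to 2 decimals; reference rows carry the literal text
    ``Reference level``.  Deterministic: identical inputs give byte-identical
    files.
    """
    if isinstance(results, FitResult):
        results = {"all": results}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    lines: list[str] = []
    for group in results:
        res = results[group]
        eff = effect_report(res)
        path_e = outdir / f"effects_{group}.csv"
        eff.to_csv(path_e, index=False, float_format="%.6f")
        written[f"effects_{group}"] = path_e

        spat = classify_spatial(res, threshold=threshold)
        path_s = outdir / f"spatial_{group}.csv"
        spat.to_csv(path_s, index=False, float_format="%.6f")
        written[f"spatial_{group}"] = path_s

        lines.append(f"== Percentage change in visit rates: {group} ==")
        for term, ref_label in (("dow", "Sunday"), ("dsli", "The other days")):
            sub = eff[eff["term"] == term]
            header = "Day-of-week" if term == "dow" else "Dust storm lag index"
            lines.append(f"-- {header} --")
            for _, r in sub.iterrows():
                lines.append(
                    f"{r['variable']:<12} {r['percent']:>8.2f} "
                    f"({r['lo']:.2f}, {r['hi']:.2f})  p={r['p']:.4f}"
                )
            lines.append(f"{ref_label:<12} Reference level")
        lines.append(f"-- Spatial classification (threshold {threshold:.2f}) --")
        for _, r in spat.iterrows():
            lines.append(
                f"{r['district']:<12} effect={r['effect']:>7.2f} "
                f"RR={r['rr']:.2f} P(RR>1)={r['p_above_1']:.2f} {r['class']}"
            )
        lines.append(
            f"overdispersion phi = {res.variance.phi:.2f}; "
            + "; ".join(
                f"tau2[{k}] = {v:.4g}" for k, v in res.variance.tau2.items()
            )
        )
        lines.append("")
    path_t = outdir / "summary.txt"
    path_t.write_text("\n".join(lines))
    written["summary"] = path_t
    return written
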