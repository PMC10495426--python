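"""Comparison diagnostics and conservation audits.

``relative_difference`` is the country-wise statistic used against external
survey rates: Dif = (rate - reference) / rate x 100, undefined where the
reconstructed rate is zero.  ``conservation_report`` audits the exact
mass-balance contracts of the pipeline stages (gridded vs national
harvested area, county vs national SN amounts, anchor-year crop-group
amounts vs the surveys, share and placement sums).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUDIT_TOL = 1e-9


def relative_difference(rate, reference):
    """Country-wise relative difference in percent.

    Accepts scalars, arrays, Series, or aligned DataFrames.  Entries with a
    zero reconstructed rate are undefined (NaN) and excluded from summaries.
    """
    rate_a = np.asarray(rate, dtype=float)
    ref_a = np.asarray(reference, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dif = np.where(rate_a != 0, (rate_a - ref_a) / np.where(rate_a != 0, rate_a, 1.0) * 100.0,
                       np.nan)
    n_undef = int(np.sum(rate_a == 0))
    if n_undef:
        logger.warning("%d entries with zero reconstructed rate; Dif undefined", n_undef)
    if isinstance(rate, pd.DataFrame):
        return pd.DataFrame(dif, index=rate.index, columns=rate.columns)
    if isinstance(rate, pd.Series):
        return pd.Series(dif, index=rate.index)
    if np.isscalar(rate) and np.isscalar(reference):
        return float(dif)
    return dif


def dif_summary(dif: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Mean, SD, and sample size of Dif grouped by the given index levels."""
    stacked = dif.stack(future_stack=True).rename("dif").reset_index()
    stacked = stacked.dropna(subset=["dif"])
    g = stacked.groupby(by)["dif"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})


@dataclass
class ValidationReport:
    """Conservation audit outcomes plus optional Dif tables."""

    conservation: pd.DataFrame
    dif: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    violations: list[tuple] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return bool((self.conservation["max_rel_err"] <= self.conservation["tol"]).all())

    def __str__(self) -> str:
        lines = ["conservation audits:"]
        for name, row in self.conservation.iterrows():
            status = "ok" if row["max_rel_err"] <= row["tol"] else "FAIL"
            lines.append(f"  {name:<28s} max_rel_err={row['max_rel_err']:.3e}  [{status}]")
        if self.violations:
            lines.append(f"  flagged: {self.violations[:10]}")
        return "\n".join(lines)


def _max_rel_err(actual: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    scale = np.maximum(np.abs(target), 1.0)
    err = np.abs(actual - target) / scale
    return (float(err.max()) if err.size else 0.0), err


def conservation_report(
    *,
    harea_cube=None,
    harea_national: pd.DataFrame | None = None,
    namount_panel=None,
    rates: pd.DataFrame | None = None,
    harea_county: pd.DataFrame | None = None,
    fubc: pd.DataFrame | None = None,
    type_shares=None,
    placement=None,
    hierarchy=None,
    vocab=None,
    tol: float = AUDIT_TOL,
) -> ValidationReport:
    """Audit the exact-conservation contracts of a completed pipeline run.

    Each audit reports the maximum relative error (relative to the target,
    floored at magnitude 1 so zero targets are compared absolutely).
    Country-years violating the harvested-area audit are listed in
    ``violations``.
    """
    rows = {}
    violations: list[tuple] = []

    if harea_cube is not None and harea_national is not None and hierarchy is not None:
        from .harvested_area import county_sums
        sums = county_sums(harea_cube, hierarchy)
        frame = sums.reset_index()
        frame["country"] = frame["county"].map(hierarchy.county_country)
        nat = frame.drop(columns="county").groupby(["crop", "country"]).sum()
        target = harea_national.reindex(nat.index).fillna(0.0)
        err_max, err = _max_rel_err(nat.to_numpy(), target.to_numpy())
        rows["harea_vs_national"] = err_max
        bad = np.argwhere(err > tol)
        for r, c in bad[:50]:
            violations.append(("harea", *nat.index[r], nat.columns[c]))

    if namount_panel is not None and namount_panel.corrected is not None and hierarchy is not None:
        corr = namount_panel.corrected.loc["SN"]
        frame = corr.copy()
        frame.index = [hierarchy.county_country[c] for c in corr.index]
        nat = frame.groupby(level=0).sum()
        target = namount_panel.national.loc["SN"].reindex(nat.index).fillna(0.0)
        err_max, err = _max_rel_err(nat.to_numpy(), target.to_numpy())
        rows["sn_county_vs_national"] = err_max
        bad = np.argwhere(err > tol)
        for r, c in bad[:50]:
            violations.append(("sn_amount", nat.index[r], nat.columns[c]))

    if rates is not None and harea_county is not None and fubc is not None and vocab is not None:
        from .n_application import fubc_reference_year
        sn = rates.xs("SN", level="class")
        errs = []
        for y0 in fubc.columns:
            if y0 not in sn.columns:
                continue
            amount = sn[y0] * harea_county.reindex(sn.index).fillna(0.0)[y0]
            frame = amount.reset_index()
            frame.columns = ["crop", "county", "amount"]
            frame["group"] = frame["crop"].map(vocab.crop_to_fubc)
            frame["country"] = frame["county"].map(hierarchy.county_country)
            got = frame.groupby(["group", "country"])["amount"].sum()
            target = fubc[y0].reindex(got.index).fillna(0.0)
            ok = (got.to_numpy() > 0) | (target.to_numpy() > 0)
            err_max, _ = _max_rel_err(got.to_numpy()[ok], target.to_numpy()[ok])
            # groups skipped for zero denominators keep their uncalibrated value
            skipped = (got.to_numpy() == 0) & (target.to_numpy() > 0)
            if skipped.any():
                keep = ok & ~skipped
                err_max, _ = _max_rel_err(got.to_numpy()[keep], target.to_numpy()[keep])
            errs.append(err_max)
        rows["fubc_anchor_amounts"] = max(errs) if errs else 0.0

    if type_shares is not None and namount_panel is not None and namount_panel.corrected is not None:
        total = namount_panel.corrected.groupby(level=1).sum()
        counties = list(type_shares.county.index.get_level_values(1).unique())
        share_sum = type_shares.county.groupby(level=1).sum().reindex(counties)
        total = total.reindex(counties)
        mask = total.to_numpy() > 0
        dev = np.abs(share_sum.to_numpy() - 1.0)[mask]
        rows["type_share_sum"] = float(dev.max()) if dev.size else 0.0

    if placement is not None:
        dev = 0.0
        for crop in placement.crops[:3]:
            for f in placement.fertilizer_types:
                s = placement.surface(crop, f) + placement.deep(crop, f) - 1.0
                dev = max(dev, float(np.abs(s).max()))
        rows["placement_sum"] = dev

    conservation = pd.DataFrame(
        {"max_rel_err": pd.Series(rows), "tol": tol}
    )
    report = ValidationReport(conservation=conservation, violations=violations)
    if not report.passed:
        logger.warning("conservation audit failures:\n%s", report)
    return report
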