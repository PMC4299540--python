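"""Location-error metrics and statistical comparison across template modes.

Errors are signed per-axis differences (left-right, anterior-posterior,
superior-inferior, mm) between estimated and reference tumor centroids, plus
the Euclidean distance.  Mode comparisons use the pooled-variance two-sample
Student t-test on means and the variance-ratio F-test on spreads, two-sided
at alpha = 0.05, with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorRecord",
    "location_error",
    "two_sample_t",
    "variance_f_test",
    "summarize",
]

AXES = ("lr", "ap", "si")


@dataclass
class ErrorRecord:
    """Per-(case, fraction, mode) localization error."""

    case: str
    fraction: int
    mode: str
    err_lr_mm: float
    err_ap_mm: float
    err_si_mm: float
    err_euclid_mm: float

    def __post_init__(self) -> None:
        vals = (self.err_lr_mm, self.err_ap_mm, self.err_si_mm, self.err_euclid_mm)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite error values: {vals}")
        expect = float(np.sqrt(self.err_lr_mm**2 + self.err_ap_mm**2 + self.err_si_mm**2))
        if abs(expect - self.err_euclid_mm) > 1e-9:
            raise ValueError(
                f"Euclidean distance {self.err_euclid_mm} inconsistent with axes ({expect})"
            )


def location_error(est, ref, case: str = "", fraction: int = 0,
                   mode: str = "none") -> ErrorRecord:
    """Signed per-axis errors est - ref (mm) and their Euclidean norm."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != (3,) or ref.shape != (3,):
        raise ValueError("est and ref must be length-3 mm triples")
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
        raise ValueError("non-finite coordinates")
    d = est - ref
    return ErrorRecord(case=case, fraction=fraction, mode=mode,
                       err_lr_mm=float(d[0]), err_ap_mm=float(d[1]),
                       err_si_mm=float(d[2]),
                       err_euclid_mm=float(np.linalg.norm(d)))


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance Student t-test; returns (t, dof, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t-test degenerate")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


def variance_f_test(a, b) -> tuple[float, tuple[int, int], float]:
    """Variance-ratio F-test; returns (F = s_a^2/s_b^2, dofs, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance; F-test degenerate")
    f = va / vb
    dfn, dfd = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f, dfn, dfd)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), (dfn, dfd), float(min(p, 1.0))


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def summarize(records, alpha: float = 0.05) -> dict:
    """Per-mode mean +/- SD for each axis and Euclidean distance, plus
    pairwise t/F tests across modes on the Euclidean errors.

    SDs use the sample convention (n-1); a single record reports SD 0 with
    an ``n=1`` flag.  Means are permutation-invariant in record order.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    cols = ["err_lr_mm", "err_ap_mm", "err_si_mm", "err_euclid_mm"]
    out: dict = {"modes": {}, "pairwise": {}, "alpha": alpha}
    for mode, grp in df.groupby("mode"):
        n = len(grp)
        stats_d = {"n": int(n)}
        for c in cols:
            stats_d[c] = {
                "mean": float(grp[c].mean()),
                "sd": 0.0 if n == 1 else float(grp[c].std(ddof=1)),
            }
        if n == 1:
            stats_d["single_record"] = True
        out["modes"][mode] = stats_d
    modes = sorted(out["modes"])
    for i, ma in enumerate(modes):
        for mb in modes[i + 1:]:
            ea = df.loc[df["mode"] == ma, "err_euclid_mm"].to_numpy()
            eb = df.loc[df["mode"] == mb, "err_euclid_mm"].to_numpy()
            pair: dict = {}
            try:
                t, dof, pt = two_sample_t(ea, eb)
                pair["t"] = {"stat": t, "dof": dof, "p": pt, "significant": pt < alpha}
            except ValueError as exc:
                pair["t"] = {"error": str(exc)}
            try:
                f, dofs, pf = variance_f_test(ea, eb)
                pair["f"] = {"stat": f, "dof": list(dofs), "p": pf, "significant": pf < alpha}
            except ValueError as exc:
                pair["f"] = {"error": str(exc)}
            out["pairwise"][f"{ma}_vs_{mb}"] = pair
    return out
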