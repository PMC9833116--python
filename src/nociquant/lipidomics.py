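"""Biopsy lipidomics preprocessing, univariate testing and adduct annotation.

The chain, in fixed order: tissue-weight normalisation -> pooled-QC
coefficient-of-variation filtering (30% default) -> per-sample median
scaling -> generalised-logarithm transform -> per-feature autoscaling ->
unpaired Welch t tests with Holm step-down correction.  Candidate lipid
identities are assigned by matching observed m/z against reference
monoisotopic masses under mode-appropriate adducts (M+H and M+Na in
positive mode, M-H in negative mode) within +/-0.05 Da, flagging matches
under 35 ppm as promising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

__all__ = [
    "normalize_by_weight",
    "qc_cv_filter",
    "transform_stack",
    "glog",
    "welch_holm",
    "LipidReference",
    "default_lipid_reference",
    "match_adducts",
    "AdductMatch",
    "run_pipeline",
    "PROTON_DA",
    "SODIUM_ION_DA",
]

PROTON_DA = 1.007276
SODIUM_ION_DA = 22.989218

#: adduct label -> (mass offset in Da, ionisation mode it applies to)
ADDUCTS = {
    "M+H": (PROTON_DA, "+"),
    "M+Na": (SODIUM_ION_DA, "+"),
    "M-H": (-PROTON_DA, "-"),
}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_by_weight(table: FeatureTable) -> FeatureTable:
    """Divide intensities by tissue weight (mg).

    QC samples, which are pools without their own weight, are divided by
    the arithmetic mean weight of all biological samples.
    """
    qc = table.qc_mask
    w = table.samples["weight_mg"].to_numpy(dtype=float).copy()
    if np.isnan(w[~qc]).any() or np.any(w[~qc] <= 0):
        raise ValueError("every biological sample needs a positive weight")
    w[qc] = w[~qc].mean()
    return table.with_intensities(table.intensities.to_numpy() / w[:, None])


def qc_cv_filter(table: FeatureTable, threshold: float = 0.30
                 ) -> tuple[FeatureTable, pd.DataFrame]:
    """Discard features whose CV across pooled-QC injections exceeds ``threshold``.

    CV is sample SD / mean over the QC samples.  A feature with QC mean 0
    has undefined CV and is discarded.  Returns the filtered table and a
    per-feature report (cv, kept, threshold).
    """
    qc = table.intensities.loc[table.qc_mask]
    if len(qc) < 2:
        raise ValueError("need at least 2 QC samples for a CV filter")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    kept = (mean != 0) & (cv <= threshold)
    report = pd.DataFrame(
        {"cv": cv, "kept": kept, "threshold": threshold},
        index=table.intensities.columns,
    )
    return table.subset_features(table.intensities.columns[kept]), report


def glog(x: np.ndarray, lam: float) -> np.ndarray:
    """Generalised logarithm g(x) = log2((x + sqrt(x^2 + lambda^2)) / 2)."""
    if lam <= 0:
        raise ValueError("glog lambda must be positive")
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def transform_stack(table: FeatureTable, glog_lambda: float | None = None
                    ) -> FeatureTable:
    """Median scaling -> glog -> autoscaling, on an already filtered table.

    * per-sample scaling so every sample's median equals the grand median
      of the biological samples;
    * elementwise generalised logarithm (lambda defaults to the smallest
      positive intensity in the table);
    * per-feature centring and unit-variance scaling, so every feature
      column leaves with mean 0 and variance 1.
    """
    X = table.intensities.to_numpy(dtype=float)
    bio = ~table.qc_mask
    med = np.median(X, axis=1)
    if np.any(med <= 0):
        raise ValueError("non-positive sample medians; run weight normalisation first")
    grand = np.median(med[bio])  # median of per-sample medians: sample-level
    X = X * (grand / med)[:, None]  # scale factors cancel exactly
    if glog_lambda is None:
        pos = X[X > 0]
        if pos.size == 0:
            raise ValueError("no positive intensities to set glog lambda")
        glog_lambda = float(pos.min())
    X = glog(X, glog_lambda)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature column cannot be autoscaled")
    X = (X - mu) / sd
    return table.with_intensities(X)


# ---------------------------------------------------------------------------
# univariate testing
# ---------------------------------------------------------------------------

def welch_holm(table: FeatureTable, alpha: float = 0.05,
               raw_table: FeatureTable | None = None) -> pd.DataFrame:
    """Per-feature unpaired Welch t tests (burn vs control) with Holm correction.

    Returns a frame with t statistic, Welch-Satterthwaite df, raw p, Holm
    adjusted q, significance at ``alpha``, and the log2 burn/control fold
    change.  Fold change is computed on ``raw_table`` (the weight-normalised,
    pre-transform intensities) when given, else on ``table`` itself.
    """
    bio = table.biological()
    cond = bio.samples["condition"].to_numpy()
    burn = bio.intensities.to_numpy()[cond == "burn"]
    ctrl = bio.intensities.to_numpy()[cond == "control"]
    if len(burn) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 samples per group")
    res = stats.ttest_ind(burn, ctrl, axis=0, equal_var=False)
    p = np.nan_to_num(res.pvalue, nan=1.0)  # zero-variance identical groups -> p = 1
    t = np.nan_to_num(res.statistic, nan=0.0)
    q = multipletests(p, method="holm")[1]
    fc_src = (raw_table or table).biological()
    fcond = fc_src.samples["condition"].to_numpy()
    mb = fc_src.intensities.to_numpy()[fcond == "burn"].mean(axis=0)
    mc = fc_src.intensities.to_numpy()[fcond == "control"].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mb / mc)
    return pd.DataFrame(
        {
            "t": t,
            "df": getattr(res, "df", np.full_like(p, np.nan)),
            "p": p,
            "q": q,
            "significant": q < alpha,
            "log2_fc": log2fc,
        },
        index=table.intensities.columns,
    )


# ---------------------------------------------------------------------------
# adduct annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidReference:
    """A reference lipid: name, molecular formula, monoisotopic mass (Da)."""

    name: str
    formula: str
    monoisotopic_mass: float

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "LipidReference":
        return cls(name, formula, float(_ptmass.calculate_mass(formula=formula)))


def default_lipid_reference() -> list[LipidReference]:
    """The LPC species of interest, masses computed from their formulas."""
    return [
        LipidReference.from_formula("14:0 LPC", "C22H46NO7P"),
        LipidReference.from_formula("16:0 LPC", "C24H50NO7P"),
        LipidReference.from_formula("18:0 LPC", "C26H54NO7P"),
    ]


@dataclass(frozen=True)
class AdductMatch:
    observed_mz: float
    name: str
    formula: str
    monoisotopic_mass: float
    adduct: str
    expected_mz: float
    delta_da: float
    delta_ppm: float
    promising: bool


def match_adducts(observed_mz: float, mode: str,
                  reference: list[LipidReference] | None = None,
                  tol_da: float = 0.05, flag_ppm: float = 35.0
                  ) -> list[AdductMatch]:
    """Match an observed m/z against reference lipids under the mode's adducts.

    Positive mode searches M+H and M+Na; negative mode only M-H.  Matches
    within ``tol_da`` are returned, each flagged promising when
    |delta| < ``flag_ppm`` ppm, sorted by |delta_da|.
    """
    if mode not in ("+", "-"):
        raise ValueError(f"unknown ionisation mode {mode!r}")
    reference = reference if reference is not None else default_lipid_reference()
    out = []
    for ref in reference:
        for adduct, (offset, amode) in ADDUCTS.items():
            if amode != mode:
                continue
            expected = ref.monoisotopic_mass + offset
            delta = observed_mz - expected
            if abs(delta) <= tol_da:
                ppm = delta / expected * 1e6
                out.append(
                    AdductMatch(
                        observed_mz=observed_mz, name=ref.name, formula=ref.formula,
                        monoisotopic_mass=ref.monoisotopic_mass, adduct=adduct,
                        expected_mz=expected, delta_da=delta, delta_ppm=ppm,
                        promising=abs(ppm) < flag_ppm,
                    )
                )
    return sorted(out, key=lambda m: abs(m.delta_da))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_pipeline(table: FeatureTable, qc_cv: float = 0.30, alpha: float = 0.05,
                 glog_lambda: float | None = None) -> dict:
    """Run the fixed chain and return all intermediate products.

    Order: weight normalisation -> QC CV filter -> median/glog/autoscale ->
    Welch + Holm.  Fold changes are taken on the weight-normalised scale.
    The returned dict records the step order for the report.
    """
    weighted = normalize_by_weight(table)
    filtered, qc_report = qc_cv_filter(weighted, threshold=qc_cv)
    transformed = transform_stack(filtered, glog_lambda=glog_lambda)
    results = welch_holm(transformed, alpha=alpha, raw_table=filtered)
    return {
        "steps": ["weight", "qc_filter", "median", "glog", "autoscale", "welch_holm"],
        "weighted": weighted,
        "qc_report": qc_report,
        "transformed": transformed,
        "results": results,
    }
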